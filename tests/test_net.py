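"""Unrolled network: structure, solver equivalence, gradients, training."""

import numpy as np
import pytest

from imri import autodiff as ad
from imri.autodiff import Tensor
from imri.net import (LSFPNet, NetConfig, TrainConfig, build_net, forward_net,
                      parameter_count, train)
from imri.solver import LSFPModel, LSFPParams
from imri.transforms import HaarFramelet

from conftest import make_operator, random_frames


def freeze_to_haar(net: LSFPNet, gamma, lam, lam_L, lam_s, lam_Lpsi, lam_Spsi):
    """Set every block to one exact PDFP iteration: conv stacks become the
    periodic undecimated Haar analysis/synthesis (8 channels = 4 complex
    subbands), scalars take the solver values."""
    haar = HaarFramelet._filters
    for blk in net.blocks:
        blk.gamma.data = np.array(gamma)
        blk.lam.data = np.array(lam)
        blk.tau_svt.data = np.array(gamma * lam_L)
        blk.tau_L.data = np.array(gamma / lam * lam_Lpsi)
        blk.tau_S.data = np.array(gamma / lam * lam_Spsi)
        blk.tau_T.data = np.array(gamma / lam * lam_s)
        for ana in (blk.psi_L, blk.psi_S):
            w, b = ana.layers[0]
            w.data[:] = 0.0
            b.data[:] = 0.0
            for k in range(4):
                for fy in (0, 1):
                    for fx in (0, 1):
                        w.data[2 * k, 0, 1, 1 + fy, 1 + fx] = haar[k, fy, fx]
                        w.data[2 * k + 1, 1, 1, 1 + fy, 1 + fx] = haar[k, fy, fx]
        for syn in (blk.psi_L_T, blk.psi_S_T):
            w, b = syn.layers[0]
            w.data[:] = 0.0
            b.data[:] = 0.0
            for k in range(4):
                for fy in (0, 1):
                    for fx in (0, 1):
                        w.data[0, 2 * k, 1, 1 - fy, 1 - fx] = haar[k, fy, fx]
                        w.data[1, 2 * k + 1, 1, 1 - fy, 1 - fx] = haar[k, fy, fx]


def make_toy_sample(op, seed, speed=2.0):
    """One normalised (k-space, truth) pair from the simulator."""
    from imri.simdata import (InterventionScenario, PhantomSpec,
                              simulate_intervention)
    n = op.matrix_size
    fov = float(n)
    spec = PhantomSpec(matrix_size=n, n_coils=op.sens.n_coils, seed=seed,
                       texture_sd=0.05)
    scen = InterventionScenario(
        n_frames=op.scheme.fpg, seed=seed, speed_mm_per_frame=speed,
        entry_point_mm=(0.15 * fov, 0.34 * fov),
        target_point_mm=(0.63 * fov, 0.34 * fov))
    truth = simulate_intervention(spec, scen).astype(complex)
    d = op.forward(truth)
    s = np.max(np.abs(op.adjoint(d, density_compensated=True)))
    return d / s, truth / s


class TestStructure:
    @pytest.mark.parametrize("nb,nc,nf", [(2, 3, 8), (1, 1, 4), (3, 2, 32)])
    def test_parameter_count_closed_form(self, nb, nc, nf):
        op = make_operator(matrix_size=8, spf=2, fpg=2, n_coils=1)
        cfg = NetConfig(n_blocks=nb, n_conv_layers=nc, n_features=nf, seed=0)
        assert build_net(cfg, op).n_parameters() == parameter_count(cfg)

    def test_fixed_seed_builds_identically(self):
        op = make_operator(matrix_size=8, spf=2, fpg=2, n_coils=1)
        cfg = NetConfig(n_blocks=2, n_conv_layers=2, n_features=4, seed=11)
        a, b = build_net(cfg, op), build_net(cfg, op)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(n_blocks=0)
        with pytest.raises(ValueError):
            NetConfig(n_features=7)
        with pytest.raises(ValueError):
            NetConfig(kernel=(2, 3, 3))


class TestForward:
    def test_zero_kspace_zero_thresholds_gives_zero(self):
        op = make_operator(matrix_size=8, spf=3, fpg=2, n_coils=2)
        net = build_net(NetConfig(2, 1, 8, seed=0), op)
        for blk in net.blocks:
            for t in (blk.tau_svt, blk.tau_L, blk.tau_S, blk.tau_T):
                t.data = np.array(0.0)
        dec, img = net.reconstruct(np.zeros((2, 6, 8), dtype=complex))
        assert np.all(img.frames == 0)

    def test_deterministic_forward(self, rng):
        op = make_operator(matrix_size=8, spf=3, fpg=2, n_coils=2)
        net = build_net(NetConfig(2, 2, 4, seed=0), op)
        d = rng.standard_normal((2, 6, 8)) + 1j * rng.standard_normal((2, 6, 8))
        _, img1 = forward_net(net, d)
        _, img2 = forward_net(net, d)
        assert np.array_equal(img1.frames, img2.frames)

    def test_output_sums_exactly(self, rng):
        op = make_operator(matrix_size=8, spf=3, fpg=2, n_coils=2)
        net = build_net(NetConfig(1, 1, 4, seed=0), op)
        d = rng.standard_normal((2, 6, 8)) + 1j * rng.standard_normal((2, 6, 8))
        dec, img = net.reconstruct(d)
        assert np.array_equal(img.frames, dec.L + dec.S)

    def test_wrong_shape_rejected(self, rng):
        op = make_operator(matrix_size=8, spf=3, fpg=2, n_coils=2)
        net = build_net(NetConfig(1, 1, 4, seed=0), op)
        with pytest.raises(ValueError):
            net.reconstruct(np.zeros((2, 5, 8), dtype=complex))

    def test_zeroed_convs_reduce_to_gradient_iterations(self, rng):
        # all conv weights and thresholds zero, matched steps: the net is
        # the pure data-consistency gradient iteration, i.e. the solver
        # with every regularisation weight at zero
        op = make_operator(matrix_size=8, spf=3, fpg=2, n_coils=2)
        net = build_net(NetConfig(2, 2, 4, seed=0), op)
        gamma = 0.9 / op.norm_squared()
        for blk in net.blocks:
            blk.gamma.data = np.array(gamma)
            blk.lam.data = np.array(0.2)
            for t in (blk.tau_svt, blk.tau_L, blk.tau_S, blk.tau_T):
                t.data = np.array(0.0)
            for stack in (blk.psi_L, blk.psi_L_T, blk.psi_S, blk.psi_S_T):
                for w, b in stack.layers:
                    w.data[:] = 0.0
                    b.data[:] = 0.0
        truth = random_frames(rng, 2, 8)
        d = op.forward(truth)
        _, img = net.reconstruct(d)
        p = LSFPParams(0.0, 0.0, 0.0, 0.0, gamma=gamma, lam=0.2,
                       max_iter=2, tol=0.0)
        res = LSFPModel(d, op, p).fit()
        assert np.max(np.abs(img.frames - res.x)) < 1e-10


class TestSolverEquivalence:
    def test_two_blocks_match_two_iterations(self, rng):
        op = make_operator(matrix_size=16, spf=4, fpg=3, n_coils=3)
        truth = random_frames(rng, 3, 16, complex_valued=False)
        d = op.forward(truth)
        d /= np.max(np.abs(op.adjoint(d)))
        gamma = 0.99 / op.norm_squared()
        lam = 0.2
        weights = dict(lam_L=0.01, lam_s=0.004, lam_Lpsi=0.005, lam_Spsi=0.006)
        net = build_net(NetConfig(n_blocks=2, n_conv_layers=1, n_features=8,
                                  seed=0), op)
        freeze_to_haar(net, gamma, lam, **weights)
        dec, img = net.reconstruct(d)
        p = LSFPParams(lambda_L=weights["lam_L"], lambda_s=weights["lam_s"],
                       lambda_L_psi=weights["lam_Lpsi"],
                       lambda_S_psi=weights["lam_Spsi"],
                       gamma=gamma, lam=lam, max_iter=2, tol=0.0)
        res = LSFPModel(d, op, p).fit()
        assert np.max(np.abs(dec.L - res.L)) < 1e-5
        assert np.max(np.abs(dec.S - res.S)) < 1e-5


class TestGradients:
    def test_autodiff_matches_numerical_gradients(self, rng):
        op = make_operator(matrix_size=8, spf=3, fpg=2, n_coils=2)
        net = build_net(NetConfig(1, 2, 4, seed=3), op)
        truth = random_frames(rng, 2, 8)
        d = op.forward(truth)
        d /= np.max(np.abs(op.adjoint(d, density_compensated=True)))
        tgt = ad.c2_from_complex(truth / np.max(np.abs(truth)))

        def loss_value():
            Lt, St = net.forward_graph(d)
            return ad.mse(ad.add(Lt, St), tgt)

        loss = loss_value()
        loss.backward()
        params = net.parameters()
        picks = rng.choice(len(params), size=min(10, len(params)),
                           replace=False)
        eps = 1e-6
        for pi in picks:
            p = params[pi]
            flat = p.data.reshape(-1)
            i = int(rng.integers(flat.size))
            ana = p.grad.reshape(-1)[i]
            orig = flat[i]
            flat[i] = orig + eps
            lp = float(loss_value().data)
            flat[i] = orig - eps
            lm = float(loss_value().data)
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - ana) <= 1e-3 * max(abs(num), 1e-4), \
                f"param {pi}: numerical {num} vs autodiff {ana}"


class TestTraining:
    def test_one_epoch_plumbing(self, tmp_path):
        op = make_operator(matrix_size=16, spf=4, fpg=3, n_coils=2)
        data = [make_toy_sample(op, s) for s in range(2)]
        net = build_net(NetConfig(1, 1, 4, seed=0), op)
        ckpt = tmp_path / "net.npz"
        res = train(net, data, TrainConfig(epochs=1, lr=1e-3),
                    val_dataset=data[:1], checkpoint_path=ckpt)
        assert len(res.train_loss) == 1
        assert len(res.val_loss) == 1
        assert ckpt.exists()
        # checkpoint reloads into a matching architecture
        net2 = build_net(LSFPNet.checkpoint_config(ckpt), op)
        net2.load_state(ckpt)
        for a, b in zip(net.parameters(), net2.parameters()):
            assert np.allclose(a.data, b.data)

    def test_nonfinite_loss_reports_batch(self):
        op = make_operator(matrix_size=16, spf=4, fpg=3, n_coils=2)
        data = [make_toy_sample(op, 0)]
        net = build_net(NetConfig(1, 1, 4, seed=0), op)
        w, _ = net.blocks[0].psi_S_T.layers[-1]
        w.data[:] = 1e200  # overflow to inf in the sparse-component path
        with pytest.raises(RuntimeError, match="batch"):
            train(net, data, TrainConfig(epochs=1))

    def test_training_reduces_loss(self):
        op = make_operator(matrix_size=16, spf=4, fpg=3, n_coils=2)
        data = [make_toy_sample(op, s, speed=1.5 + 0.5 * s) for s in range(4)]
        net = build_net(NetConfig(2, 2, 8, seed=0), op)
        res = train(net, data, TrainConfig(lr=1e-3, epochs=10),
                    shuffle_seed=0)
        assert res.train_loss[-1] < res.train_loss[0]

    def test_fixed_seeds_give_identical_histories(self):
        op = make_operator(matrix_size=16, spf=4, fpg=3, n_coils=2)
        data = [make_toy_sample(op, s) for s in range(2)]
        histories = []
        for _ in range(2):
            net = build_net(NetConfig(1, 1, 4, seed=0), op)
            res = train(net, data, TrainConfig(lr=1e-3, epochs=2),
                        shuffle_seed=7)
            histories.append(res.train_loss)
        assert histories[0] == histories[1]
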