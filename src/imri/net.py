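"""LSFP-Net: the PDFP iteration unrolled into a trainable network.

Each of the ``n_blocks`` blocks is structurally one LSFP iteration.  The
framelet analysis/synthesis pairs {psi_L, psi_L^T} and {psi_S, psi_S^T}
are replaced by four independent stacks of ``n_conv_layers`` 3D
convolutions (kernel 3x3x3 over frame-y-x, circular padding) with ReLU
between layers; complex images enter the stacks as two real channels and
are recombined on exit.  Hidden layers carry ``n_features`` channels,
read as ``n_features/2`` (real, imaginary) coefficient pairs so that the
learned soft-thresholding shrinks coefficient magnitudes exactly like the
solver's complex l1 prox.  The nuclear prox stays an exact SVT with a
learnable threshold; the temporal-difference dual block is kept exact
with a learnable threshold; both step sizes (gamma, lam) and all four
thresholds are per-block learnable scalars initialised from the solver
defaults.

Training is plain Adam on the mean squared error between the complex
reconstruction and the ground truth (an SSIM-augmented loss is available
as an option); inputs are expected normalised so that the zero-filled
adjoint has unit peak magnitude, which makes the threshold
initialisations data-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .operators import EncodingOperator, ImageGroup
from .solver import LSDecomposition

__all__ = ["NetConfig", "TrainConfig", "LSFPNet", "build_net", "forward_net",
           "train", "TrainResults", "parameter_count"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture of the unrolled network.

    ``n_blocks`` (N_b) unrolled iterations; ``n_conv_layers`` (N_c)
    convolutions per transform stack; 3x3x3 kernels; ``n_features`` even
    (channels pair up as complex coefficients).
    """

    n_blocks: int = 3
    n_conv_layers: int = 3
    n_features: int = 32
    kernel: tuple[int, int, int] = (3, 3, 3)
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1 or self.n_conv_layers < 1:
            raise ValueError("n_blocks and n_conv_layers must be >= 1")
        if self.n_features < 2 or self.n_features % 2:
            raise ValueError("n_features must be even and >= 2")
        if any(k < 1 or k % 2 == 0 for k in self.kernel):
            raise ValueError("kernel sizes must be odd and >= 1")


@dataclass
class TrainConfig:
    """Adam settings: defaults lr 1e-4, beta1 0.9, beta2 0.999, eps 1e-8,
    batch size 1."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 1
    epochs: int = 10
    loss: str = "mse"


def _conv_stack_shapes(cfg: NetConfig, analysis: bool):
    """Channel progression of one transform stack."""
    F = cfg.n_features
    if cfg.n_conv_layers == 1:
        chans = [(2, F)] if analysis else [(F, 2)]
    elif analysis:
        chans = [(2, F)] + [(F, F)] * (cfg.n_conv_layers - 1)
    else:
        chans = [(F, F)] * (cfg.n_conv_layers - 1) + [(F, 2)]
    return chans


def parameter_count(cfg: NetConfig) -> int:
    """Closed-form total learnable parameter count of the network."""
    kt, ky, kx = cfg.kernel
    kvol = kt * ky * kx
    per_stack_a = sum(ci * co * kvol + co for ci, co in
                      _conv_stack_shapes(cfg, True))
    per_stack_s = sum(ci * co * kvol + co for ci, co in
                      _conv_stack_shapes(cfg, False))
    scalars = 6  # gamma, lam, and the four thresholds per block
    return cfg.n_blocks * (2 * per_stack_a + 2 * per_stack_s + scalars)


class _ConvStack:
    """N_c convolutions with ReLU between layers (none after the last)."""

    def __init__(self, cfg: NetConfig, analysis: bool, rng):
        self.layers = []
        for ci, co in _conv_stack_shapes(cfg, analysis):
            fan = (ci + co) * np.prod(cfg.kernel)
            w = rng.standard_normal((co, ci) + cfg.kernel) * np.sqrt(2.0 / fan)
            self.layers.append((Tensor(w), Tensor(np.zeros(co))))

    def __call__(self, x: Tensor) -> Tensor:
        for i, (w, b) in enumerate(self.layers):
            x = ad.conv3d_circ(x, w, b)
            if i + 1 < len(self.layers):
                x = ad.relu(x)
        return x

    def parameters(self):
        for w, b in self.layers:
            yield w
            yield b


class _Block:
    """Learnable pieces of one unrolled iteration."""

    def __init__(self, cfg: NetConfig, rng, scalar_init: dict):
        self.psi_L = _ConvStack(cfg, True, rng)
        self.psi_L_T = _ConvStack(cfg, False, rng)
        self.psi_S = _ConvStack(cfg, True, rng)
        self.psi_S_T = _ConvStack(cfg, False, rng)
        self.gamma = Tensor(scalar_init["gamma"])
        self.lam = Tensor(scalar_init["lam"])
        self.tau_svt = Tensor(scalar_init["tau_svt"])
        self.tau_L = Tensor(scalar_init["tau_L"])
        self.tau_S = Tensor(scalar_init["tau_S"])
        self.tau_T = Tensor(scalar_init["tau_T"])

    def parameters(self):
        for stack in (self.psi_L, self.psi_L_T, self.psi_S, self.psi_S_T):
            yield from stack.parameters()
        yield from (self.gamma, self.lam, self.tau_svt, self.tau_L,
                    self.tau_S, self.tau_T)

    def scalar_parameters(self):
        return [self.gamma, self.lam, self.tau_svt, self.tau_L, self.tau_S,
                self.tau_T]


class LSFPNet:
    """Unrolled LSFP reconstruction network bound to one encoding operator.

    The operator fixes the trajectory, coil maps and group scheme the net
    was configured for; feeding k-space of a different shape is an error.
    """

    def __init__(self, cfg: NetConfig, op: EncodingOperator,
                 scalar_init: dict | None = None):
        self.cfg = cfg
        self.op = op
        self.fpg = op.scheme.fpg
        if scalar_init is None:
            gamma0 = 0.99 / op.norm_squared()
            lam0 = 0.2
            scalar_init = dict(gamma=gamma0, lam=lam0,
                               tau_svt=gamma0 * 0.01,
                               tau_L=(gamma0 / lam0) * 0.005,
                               tau_S=(gamma0 / lam0) * 0.005,
                               tau_T=(gamma0 / lam0) * 0.005)
        rng = np.random.default_rng(cfg.seed)
        self.blocks = [_Block(cfg, rng, scalar_init)
                       for _ in range(cfg.n_blocks)]

    # -- parameters ----------------------------------------------------
    def parameters(self) -> list[Tensor]:
        out = []
        for blk in self.blocks:
            out.extend(blk.parameters())
        return out

    def scalar_parameters(self) -> list[Tensor]:
        out = []
        for blk in self.blocks:
            out.extend(blk.scalar_parameters())
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward -------------------------------------------------------
    def forward_graph(self, d: np.ndarray) -> tuple[Tensor, Tensor]:
        """Run the unrolled iteration, returning (L, S) graph tensors of
        shape (2, fpg, N, N)."""
        d = np.asarray(d, dtype=np.complex128)
        expect = (self.op.scheme.spokes_per_group,
                  self.op.trajectory.readout_points)
        if d.shape[1:] != expect:
            raise ValueError(f"k-space shape {d.shape[1:]} does not match "
                             f"the operator this net was built for {expect}")
        L = Tensor(ad.c2_from_complex(
            self.op.adjoint(d, density_compensated=True)))
        S = Tensor(np.zeros_like(L.data))
        vL = vS = vT = None
        for blk in self.blocks:
            x = ad.add(L, S)
            g = ad.encode_normal_residual(x, self.op, d)
            zbL = ad.sub(L, ad.scale(blk.gamma, g))
            zbS = ad.sub(S, ad.scale(blk.gamma, g))

            def bh(vl, vs, vt):
                bl = blk.psi_L_T(vl)
                bs = ad.add(blk.psi_S_T(vs),
                            ad.tdiff_adjoint(vt, self.fpg))
                return bl, bs

            if vL is None:
                yL = ad.svt_pairs(zbL, blk.tau_svt, self.fpg)
                yS = zbS
            else:
                bl, bs = bh(vL, vS, vT)
                yL = ad.svt_pairs(ad.sub(zbL, ad.scale(blk.lam, bl)),
                                  blk.tau_svt, self.fpg)
                yS = ad.sub(zbS, ad.scale(blk.lam, bs))
            wL = blk.psi_L(yL) if vL is None else ad.add(blk.psi_L(yL), vL)
            wS = blk.psi_S(yS) if vS is None else ad.add(blk.psi_S(yS), vS)
            wT = ad.tdiff(yS) if vT is None else ad.add(ad.tdiff(yS), vT)
            vL = ad.sub(wL, ad.soft_mag(wL, blk.tau_L))
            vS = ad.sub(wS, ad.soft_mag(wS, blk.tau_S))
            vT = ad.sub(wT, ad.soft_mag(wT, blk.tau_T))
            bl, bs = bh(vL, vS, vT)
            L = ad.svt_pairs(ad.sub(zbL, ad.scale(blk.lam, bl)),
                             blk.tau_svt, self.fpg)
            S = ad.sub(zbS, ad.scale(blk.lam, bs))
        return L, S

    def reconstruct(self, d: np.ndarray) -> tuple[LSDecomposition, ImageGroup]:
        """Inference: deterministic given parameters and input."""
        Lt, St = self.forward_graph(d)
        L = ad.complex_from_c2(Lt.data)
        S = ad.complex_from_c2(St.data)
        dec = LSDecomposition(L=L, S=S)
        return dec, ImageGroup(frames=dec.x)

    # -- persistence ---------------------------------------------------
    def state_dict(self) -> dict:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def save(self, path: str | Path) -> None:
        cfg = self.cfg
        np.savez(path, __cfg__=np.array([cfg.n_blocks, cfg.n_conv_layers,
                                         cfg.n_features, *cfg.kernel,
                                         cfg.seed]),
                 **self.state_dict())

    def load_state(self, path: str | Path) -> None:
        data = np.load(path)
        for i, p in enumerate(self.parameters()):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint does not match architecture")
            p.data = arr.astype(float)

    @staticmethod
    def checkpoint_config(path: str | Path) -> NetConfig:
        raw = np.load(path)["__cfg__"]
        return NetConfig(n_blocks=int(raw[0]), n_conv_layers=int(raw[1]),
                         n_features=int(raw[2]),
                         kernel=(int(raw[3]), int(raw[4]), int(raw[5])),
                         seed=int(raw[6]))


def build_net(cfg: NetConfig, op: EncodingOperator,
              scalar_init: dict | None = None) -> LSFPNet:
    """Construct an :class:`LSFPNet`; fixed ``cfg.seed`` gives bit-identical
    initial parameters across builds."""
    return LSFPNet(cfg, op, scalar_init)


def forward_net(net: LSFPNet, d: np.ndarray,
                op: EncodingOperator | None = None):
    """Functional inference wrapper; ``op`` must be the operator the net
    was built with (accepted for interface symmetry)."""
    if op is not None and op is not net.op:
        raise ValueError("net was built for a different encoding operator")
    return net.reconstruct(d)


# ---------------------------------------------------------------- training
@dataclass
class TrainResults:
    """Loss history and checkpoint bookkeeping from :func:`train`."""

    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    checkpoint: str | None

    def summary(self) -> str:
        lines = ["LSFP-Net training", "=" * 40,
                 f"epochs:         {len(self.train_loss)}",
                 f"initial loss:   {self.train_loss[0]:.6g}",
                 f"final loss:     {self.train_loss[-1]:.6g}"]
        if self.val_loss:
            lines.append(f"best val loss:  {min(self.val_loss):.6g} "
                         f"(epoch {self.best_epoch + 1})")
        if self.checkpoint:
            lines.append(f"checkpoint:     {self.checkpoint}")
        return "\n".join(lines)


class _Adam:
    def __init__(self, params, tcfg: TrainConfig, nonneg: set[int]):
        self.params = params
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.cfg = tcfg
        self.nonneg = nonneg

    def step(self):
        c = self.cfg
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = c.beta1 * self.m[i] + (1 - c.beta1) * g
            self.v[i] = c.beta2 * self.v[i] + (1 - c.beta2) * g * g
            mhat = self.m[i] / (1 - c.beta1 ** self.t)
            vhat = self.v[i] / (1 - c.beta2 ** self.t)
            p.data = p.data - c.lr * mhat / (np.sqrt(vhat) + c.epsilon)
            if i in self.nonneg:
                p.data = np.maximum(p.data, 0.0)


def _ssim_penalty(x: Tensor, target: np.ndarray) -> Tensor:
    """Crude magnitude-similarity augmentation: squared error of frame
    means/variances; keeps the loss differentiable within this engine."""
    # magnitude proxy: mean of squared channels
    sq = Tensor(x.data ** 2, (x,), lambda g: (2 * g * x.data,), "sq")
    tmag = target ** 2
    return ad.mse(sq, tmag)


def train(net: LSFPNet, dataset, tcfg: TrainConfig,
          val_dataset=None, checkpoint_path: str | Path | None = None,
          shuffle_seed: int = 0) -> TrainResults:
    """Train on (k-space group, ground-truth complex frames) pairs.

    Minimises the configured loss (default complex MSE, real+imaginary
    channels) sample by sample with Adam; records per-epoch mean training
    and validation loss and checkpoints the best validation epoch.  A
    non-finite loss aborts with the offending batch index.
    """
    params = net.parameters()
    scalar_ids = {id(p) for p in net.scalar_parameters()}
    nonneg = {i for i, p in enumerate(params) if id(p) in scalar_ids}
    opt = _Adam(params, tcfg, nonneg)
    rng = np.random.default_rng(shuffle_seed)
    history_tr, history_val = [], []
    best = (np.inf, -1)
    checkpoint = None

    def sample_loss(d, truth):
        Lt, St = net.forward_graph(d)
        x = ad.add(Lt, St)
        tgt = ad.c2_from_complex(np.asarray(truth, dtype=np.complex128))
        loss = ad.mse(x, tgt)
        if tcfg.loss == "mse_ssim":
            loss = ad.add(loss, _ssim_penalty(x, tgt))
        elif tcfg.loss != "mse":
            raise ValueError(f"unknown loss '{tcfg.loss}'")
        return loss

    for epoch in range(tcfg.epochs):
        order = rng.permutation(len(dataset))
        ep_losses = []
        for j, idx in enumerate(order):
            d, truth = dataset[idx]
            loss = sample_loss(d, truth)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {j} "
                    f"(sample {idx})")
            loss.backward()
            opt.step()
            ep_losses.append(lv)
        history_tr.append(float(np.mean(ep_losses)))
        if val_dataset:
            vl = float(np.mean([float(sample_loss(d, t).data)
                                for d, t in val_dataset]))
            history_val.append(vl)
            if vl < best[0]:
                best = (vl, epoch)
                if checkpoint_path is not None:
                    net.save(checkpoint_path)
                    checkpoint = str(checkpoint_path)
        elif checkpoint_path is not None:
            net.save(checkpoint_path)
            checkpoint = str(checkpoint_path)
    return TrainResults(train_loss=history_tr, val_loss=history_val,
                        best_epoch=best[1], checkpoint=checkpoint)
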