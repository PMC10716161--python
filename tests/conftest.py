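import numpy as np
import pytest

from imri.operators import EncodingOperator, simulate_coilmaps
from imri.trajectory import GroupScheme, TrajectoryConfig, make_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_operator(matrix_size=16, spf=4, fpg=3, n_coils=2,
                  readout_points=None, angle_modulus=360.0):
    """Small encoding operator used across the suite."""
    cfg = TrajectoryConfig(matrix_size, readout_points=readout_points,
                           angle_modulus_deg=angle_modulus)
    scheme = GroupScheme(spf=spf, fpg=fpg)
    traj = make_trajectory(cfg, scheme)
    sens = simulate_coilmaps(n_coils, matrix_size)
    return EncodingOperator(sens, traj, scheme)


def random_frames(rng, fpg, n, complex_valued=True, offset=0.5, sd=0.2):
    x = rng.normal(offset, sd, (fpg, n, n))
    if complex_valued:
        x = x + 1j * rng.normal(0.0, sd, (fpg, n, n))
    return x


def ndft2(x, kcoords):
    """Brute-force non-uniform DFT oracle: (1/N) sum_r x[r] e^{-2pi i k.(r-c)}.

    Independent of the package's gridding path; kept quadratic and
    explicit on purpose.
    """
    x = np.asarray(x)
    N = x.shape[-1]
    c = N // 2
    ii, jj = np.meshgrid(np.arange(N) - c, np.arange(N) - c, indexing="ij")
    kcoords = np.asarray(kcoords).reshape(-1, 2)
    out = np.empty(x.shape[:-2] + (len(kcoords),), dtype=complex)
    for m, (kx, ky) in enumerate(kcoords):
        phase = np.exp(-2j * np.pi * (kx * ii + ky * jj))
        out[..., m] = np.sum(x * phase, axis=(-2, -1)) / N
    return out
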