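"""Multi-coil radial encoding: E = Omega F C.

``E`` maps a group of complex image frames to the radial k-space samples
of every coil: frame ``t`` is weighted by each coil sensitivity ``C_c``,
transformed by the non-uniform Fourier operator ``F`` and sampled on the
spokes assigned to that frame (spoke ``i`` belongs to frame ``i // spf``).
Frames are encoded independently.  The adjoint ``E^H`` is the exact
conjugate transpose, so gradient steps in the solver are consistent; a
density-compensated variant exists only for initialisation and display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nufft import NufftPlan2D
from .trajectory import AcquisitionTiming, GroupScheme, RadialTrajectory

__all__ = [
    "CoilSensitivities",
    "KSpaceGroup",
    "ImageGroup",
    "EncodingOperator",
    "simulate_coilmaps",
    "detangle_stack_of_stars",
]


@dataclass
class CoilSensitivities:
    """Complex coil maps, (coils, y, x), sum-of-squares normalised to 1."""

    maps: np.ndarray

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim != 3 or self.maps.shape[0] < 1:
            raise ValueError("maps must be (coils, y, x) with >= 1 coil")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def matrix_size(self) -> int:
        return self.maps.shape[-1]


@dataclass
class ImageGroup:
    """One group of complex image frames, (fpg, y, x)."""

    frames: np.ndarray
    pixel_mm: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.complex128)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (fpg, y, x)")
        if self.frames.shape[-1] != self.frames.shape[-2]:
            raise ValueError("spatial dims must be square")

    @property
    def fpg(self) -> int:
        return self.frames.shape[0]

    @property
    def matrix_size(self) -> int:
        return self.frames.shape[-1]


@dataclass
class KSpaceGroup:
    """Acquired radial samples of one group, (coils, spokes, readout)."""

    data: np.ndarray
    trajectory: RadialTrajectory
    scheme: GroupScheme
    timing: AcquisitionTiming | None = None
    noise_sd: float = 0.0
    pixel_mm: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3:
            raise ValueError("data must be (coils, spokes, readout)")
        expect = (self.trajectory.n_spokes, self.trajectory.readout_points)
        if self.data.shape[1:] != expect:
            raise ValueError(
                f"k-space shape {self.data.shape[1:]} inconsistent with "
                f"trajectory {expect}")
        if self.trajectory.n_spokes != self.scheme.spokes_per_group:
            raise ValueError("trajectory spokes != scheme spokes_per_group")
        if not np.all(np.isfinite(self.data.view(float))):
            raise ValueError("k-space data contains non-finite entries")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]


def simulate_coilmaps(n_coils: int, matrix_size: int,
                      rel_width: float = 0.6) -> CoilSensitivities:
    """Smooth synthetic coil maps on a ring around the field of view.

    Each coil is a complex Gaussian lobe centred on a circle of radius
    0.55 N just outside the image, with a gentle linear phase pointing at
    the coil; maps are then normalised so sum_c |C_c|^2 = 1 per pixel.
    A single coil degenerates to the uniform unit map.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    N = matrix_size
    if n_coils == 1:
        return CoilSensitivities(np.ones((1, N, N), dtype=np.complex128))
    yy, xx = np.meshgrid(np.arange(N) - N / 2, np.arange(N) - N / 2,
                         indexing="ij")
    sigma = rel_width * N
    maps = np.empty((n_coils, N, N), dtype=np.complex128)
    for c in range(n_coils):
        th = 2 * np.pi * c / n_coils
        cy, cx = 0.55 * N * np.sin(th), 0.55 * N * np.cos(th)
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
        phase = 0.8 * np.pi * (np.cos(th) * yy + np.sin(th) * xx) / N
        maps[c] = mag * np.exp(1j * phase)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return CoilSensitivities(maps / sos)


class EncodingOperator:
    """Forward/adjoint multi-coil radial encoding for one group.

    One NUFFT plan is built per frame (each frame owns ``spf`` spokes of
    the periodic group trajectory); the plans are reused for every group
    of an acquisition, which is the point of the periodic scheme.
    """

    def __init__(self, sens: CoilSensitivities, trajectory: RadialTrajectory,
                 scheme: GroupScheme, oversamp: float = 2.0, width: int = 6):
        if trajectory.n_spokes != scheme.spokes_per_group:
            raise ValueError("trajectory/scheme spoke count mismatch")
        self.sens = sens
        self.trajectory = trajectory
        self.scheme = scheme
        N = sens.matrix_size
        self.matrix_size = N
        self._plans = []
        for t in range(scheme.fpg):
            sl = trajectory.frame_slice(t)
            kc = trajectory.kcoords[sl].reshape(-1, 2)
            self._plans.append(NufftPlan2D(N, kc, oversamp=oversamp, width=width))
        self._norm = None

    # spoke i -> frame i // spf
    def frame_of_spoke(self, i: int) -> int:
        return i // self.scheme.spf

    def forward(self, x: ImageGroup | np.ndarray) -> np.ndarray:
        """(fpg, N, N) image frames -> (coils, spokes, readout) samples."""
        frames = x.frames if isinstance(x, ImageGroup) else np.asarray(x)
        fpg, spf = self.scheme.fpg, self.scheme.spf
        P = self.trajectory.readout_points
        if frames.shape != (fpg, self.matrix_size, self.matrix_size):
            raise ValueError(f"expected frames of shape "
                             f"({fpg},{self.matrix_size},{self.matrix_size})")
        out = np.empty((self.sens.n_coils, fpg * spf, P), dtype=np.complex128)
        for t in range(fpg):
            coil_imgs = self.sens.maps * frames[t]
            samp = self._plans[t].forward(coil_imgs)  # (coils, spf*P)
            out[:, t * spf:(t + 1) * spf, :] = samp.reshape(-1, spf, P)
        return out

    def adjoint(self, d: np.ndarray,
                density_compensated: bool = False) -> np.ndarray:
        """(coils, spokes, readout) samples -> (fpg, N, N) image frames."""
        d = np.asarray(d)
        fpg, spf = self.scheme.fpg, self.scheme.spf
        P = self.trajectory.readout_points
        if d.shape[1:] != (fpg * spf, P):
            raise ValueError("k-space shape inconsistent with scheme")
        N = self.matrix_size
        frames = np.empty((fpg, N, N), dtype=np.complex128)
        for t in range(fpg):
            dt = d[:, t * spf:(t + 1) * spf, :].reshape(d.shape[0], -1)
            if density_compensated:
                imgs = self._plans[t].adjoint_dcf(dt)
            else:
                imgs = self._plans[t].adjoint(dt)
            frames[t] = np.sum(np.conj(self.sens.maps) * imgs, axis=0)
        return frames

    def norm_squared(self, n_iter: int = 20, seed: int = 0) -> float:
        """Largest eigenvalue of E^H E (squared operator norm of E), by
        power iteration on a random start; cached."""
        if self._norm is None:
            rng = np.random.default_rng(seed)
            fpg, N = self.scheme.fpg, self.matrix_size
            x = rng.standard_normal((fpg, N, N)) \
                + 1j * rng.standard_normal((fpg, N, N))
            lam = 1.0
            for _ in range(n_iter):
                x = self.adjoint(self.forward(x))
                lam = np.linalg.norm(x.ravel())
                x /= lam
            self._norm = float(lam)
        return self._norm


def detangle_stack_of_stars(kdata_3d: np.ndarray) -> list[np.ndarray]:
    """Decouple a stack-of-stars acquisition into per-slice 2D k-space.

    Input is (coils, spokes, readout, partitions); a centred orthonormal
    inverse FFT along the partition axis returns one (coils, spokes,
    readout) array per slice.  Total energy is preserved.
    """
    kdata_3d = np.asarray(kdata_3d, dtype=np.complex128)
    if kdata_3d.ndim != 4:
        raise ValueError("expected (coils, spokes, readout, partitions)")
    n_part = kdata_3d.shape[-1]
    if n_part == 1:
        return [kdata_3d[..., 0]]
    slices = np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(kdata_3d, axes=-1), axis=-1, norm="ortho"),
        axes=-1)
    return [np.ascontiguousarray(slices[..., z]) for z in range(n_part)]
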