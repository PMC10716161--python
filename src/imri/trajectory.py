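"""Golden-angle radial trajectories and group-based acquisition arithmetic.

Interventional MRI trades spatial for temporal resolution by undersampling
k-space along radial spokes whose azimuth advances by the golden angle
(about 111.25 deg) from one spoke to the next.  Any contiguous run of
spokes then covers k-space near-uniformly.  Acquisition is organised in
*groups*: ``p = m x n`` spokes, reconstructed jointly as ``n`` frames of
``m`` spokes each (SPF = m spokes per frame, FPG = n frames per group).
The trajectory repeats with a period of one group, so reconstruction never
has to recompute sampling operators on the fly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "TrajectoryConfig",
    "GroupScheme",
    "RadialTrajectory",
    "AcquisitionTiming",
    "golden_angle_value",
    "make_trajectory",
    "full_spoke_count",
    "acceleration_factor",
    "frame_duration_ms",
    "group_duration_and_total",
]

#: Exact golden-angle increment in degrees: 180/phi = 90 * (sqrt(5) - 1).
GOLDEN_ANGLE_DEG: float = 90.0 * (math.sqrt(5.0) - 1.0)


def golden_angle_value(precision_decimals: int = 2) -> float:
    """Golden-angle increment in degrees, rounded to ``precision_decimals``.

    The unrounded constant is 180/phi = 90 * (sqrt(5) - 1) = 111.2461...;
    the conventional display value is 111.25 deg.
    """
    if precision_decimals < 0:
        raise ValueError("precision_decimals must be >= 0")
    return round(GOLDEN_ANGLE_DEG, precision_decimals)


@dataclass(frozen=True)
class TrajectoryConfig:
    """Geometry of one radial readout.

    Parameters
    ----------
    matrix_size : int
        Reconstructed image matrix (pixels per dimension).
    readout_points : int, optional
        Complex samples per spoke; defaults to ``matrix_size``.
    golden_angle_deg : float
        Angular increment between consecutive spokes; defaults to the
        exact golden angle.
    angle_modulus_deg : float
        Modulus applied to accumulated angles: 360 (default, spokes are
        oriented diameters covering the full circle) or 180.
    """

    matrix_size: int
    readout_points: int | None = None
    golden_angle_deg: float = GOLDEN_ANGLE_DEG
    angle_modulus_deg: float = 360.0

    def __post_init__(self):
        if self.matrix_size < 1:
            raise ValueError("matrix_size must be positive")
        if self.readout_points is None:
            object.__setattr__(self, "readout_points", self.matrix_size)
        if self.readout_points < self.matrix_size:
            raise ValueError("readout_points must be >= matrix_size")
        if self.angle_modulus_deg not in (180.0, 360.0):
            raise ValueError("angle_modulus_deg must be 180 or 360")


@dataclass(frozen=True)
class GroupScheme:
    """Spokes-per-frame / frames-per-group combination (p = m x n)."""

    spf: int
    fpg: int

    def __post_init__(self):
        if self.spf < 1 or self.fpg < 1:
            raise ValueError("spf and fpg must be positive")

    @property
    def spokes_per_group(self) -> int:
        return self.spf * self.fpg


@dataclass
class AcquisitionTiming:
    """Repetition time and acquisition bookkeeping.

    ``n_partitions`` is the number of z phase-encodes for stack-of-stars
    (1 for plain 2D imaging).
    """

    tr_ms: float
    n_partitions: int = 1
    n_groups: int = 1

    def __post_init__(self):
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be > 0")
        if self.n_partitions < 1 or self.n_groups < 1:
            raise ValueError("n_partitions and n_groups must be >= 1")


@dataclass
class RadialTrajectory:
    """One group of golden-angle radial spokes.

    Attributes
    ----------
    angles_deg : (spokes,) float array
        Spoke azimuths in acquisition order, reduced modulo
        ``angle_modulus_deg``.
    kcoords : (spokes, readout_points, 2) float array
        Normalised k-space coordinates (kx, ky) in cycles/pixel, within
        [-0.5, 0.5).  Sample ``readout_points // 2`` of every spoke is the
        k-space origin.
    periodic : bool
        The trajectory for group g+1 is identical to group g; spokes here
        describe every group.
    """

    angles_deg: np.ndarray
    kcoords: np.ndarray
    config: TrajectoryConfig
    scheme: GroupScheme
    periodic: bool = True

    @property
    def n_spokes(self) -> int:
        return self.angles_deg.shape[0]

    @property
    def readout_points(self) -> int:
        return self.kcoords.shape[1]

    def frame_slice(self, t: int) -> slice:
        """Spoke range belonging to frame ``t`` (spoke i -> frame i // spf)."""
        if not 0 <= t < self.scheme.fpg:
            raise IndexError(f"frame {t} out of range (fpg={self.scheme.fpg})")
        return slice(t * self.scheme.spf, (t + 1) * self.scheme.spf)


def make_trajectory(config: TrajectoryConfig, scheme: GroupScheme) -> RadialTrajectory:
    """Build the periodic golden-angle trajectory for one group.

    Spoke ``i`` has azimuth ``(i * golden_angle_deg) mod angle_modulus_deg``.
    The accumulation uses the exact increment; rounding is display-only.
    Radial sample radii are ``(j - P//2)/P`` for ``j = 0..P-1`` so every
    spoke passes through the origin and max |k| <= 0.5 cycles/pixel.
    """
    p = scheme.spokes_per_group
    idx = np.arange(p, dtype=float)
    angles = np.mod(idx * config.golden_angle_deg, config.angle_modulus_deg)
    P = config.readout_points
    radii = (np.arange(P) - P // 2) / P  # cycles/pixel, in [-0.5, 0.5)
    theta = np.deg2rad(angles)
    kx = radii[None, :] * np.cos(theta)[:, None]
    ky = radii[None, :] * np.sin(theta)[:, None]
    kcoords = np.stack([kx, ky], axis=-1)
    return RadialTrajectory(angles_deg=angles, kcoords=kcoords,
                            config=config, scheme=scheme, periodic=True)


def full_spoke_count(matrix_size: int) -> int:
    """Number of radial spokes needed for full (Nyquist) angular sampling.

    ``round(matrix_size * pi / 2)``: 201 for a 128 matrix, 402 for 256.
    """
    if matrix_size < 1:
        raise ValueError("matrix_size must be >= 1")
    return int(round(matrix_size * math.pi / 2.0))


def acceleration_factor(matrix_size: int, spf: int) -> int:
    """Acceleration factor R = full_spoke_count / spokes-per-frame.

    Reported rounded to the nearest integer, e.g. 10 spokes per frame at a
    128 matrix gives R = 20.
    """
    if spf < 1:
        raise ValueError("spf must be >= 1")
    return int(round(full_spoke_count(matrix_size) / spf))


def frame_duration_ms(timing: AcquisitionTiming, scheme: GroupScheme) -> float:
    """Duration of one frame (2D) or one volume (stack-of-stars), in ms.

    Each spoke costs one TR per partition: spf * n_partitions * tr_ms.
    """
    return scheme.spf * timing.n_partitions * timing.tr_ms


def group_duration_and_total(timing: AcquisitionTiming,
                             scheme: GroupScheme) -> tuple[float, float]:
    """(seconds per group, total acquisition seconds for n_groups)."""
    group_s = scheme.fpg * frame_duration_ms(timing, scheme) / 1000.0
    return group_s, timing.n_groups * group_s
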