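"""Synthetic interventional image sequences and their radial k-space.

The generator emulates a needle (or DBS-electrode) insertion into a
static head: a deterministic nested-ellipse brain phantom (skull rim,
hemispheres, ventricles) with smooth random texture stands in for the
anatomical background, and per frame a line feature advances from an
entry point toward a target at constant speed.  The ceramic needle of
the targeted-intervention setting appears as a signal void (contrast
0.1 by default); the DBS-electrode variant uses a hyperintense tip.
Multi-coil golden-angle radial k-space is produced by the package's
NUFFT-based encoding operator, group by group, with optional circular
Gaussian noise.

The programmed needle depth is exactly linear in the frame index until
the target is reached, which is what makes tip-tracking accuracy
measurable downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .operators import (CoilSensitivities, EncodingOperator, ImageGroup,
                        KSpaceGroup, simulate_coilmaps)
from .trajectory import (AcquisitionTiming, GroupScheme, RadialTrajectory,
                         TrajectoryConfig, make_trajectory)

__all__ = ["PhantomSpec", "InterventionScenario", "make_background",
           "simulate_intervention", "simulate_dbs_sequence", "acquire",
           "needle_depths_mm", "SETUPS"]

SETUPS = ("unilateral-left", "unilateral-right", "bilateral-A", "bilateral-B")


@dataclass
class PhantomSpec:
    """Static background and acquisition-side parameters."""

    matrix_size: int = 128
    pixel_mm: float = 1.0
    background: str = "ellipse-brain"  # or "user-image"
    texture_sd: float = 0.05
    n_coils: int = 11
    noise_sd: float = 0.0
    user_image: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.matrix_size < 16:
            raise ValueError("matrix_size must be >= 16")
        if self.texture_sd < 0 or self.noise_sd < 0:
            raise ValueError("texture_sd and noise_sd must be >= 0")
        if self.background not in ("ellipse-brain", "user-image"):
            raise ValueError(f"unknown background '{self.background}'")
        if self.background == "user-image" and self.user_image is None:
            raise ValueError("user-image background requires user_image")


@dataclass
class InterventionScenario:
    """One insertion: geometry, speed and contrast of the moving feature.

    Coordinates are (y, x) in mm from the image corner; the needle
    advances ``speed_mm_per_frame`` along the entry->target line each
    frame (one simulated frame corresponds to one reconstruction frame;
    physical time comes from :class:`AcquisitionTiming`).
    """

    setup: str = "unilateral-left"
    entry_point_mm: tuple[float, float] = (20.0, 44.0)
    target_point_mm: tuple[float, float] = (81.0, 44.0)
    speed_mm_per_frame: float = 1.525
    needle_width_mm: float = 1.5
    needle_contrast: float = 0.1
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.setup not in SETUPS:
            raise ValueError(f"setup must be one of {SETUPS}")
        if np.allclose(self.entry_point_mm, self.target_point_mm):
            raise ValueError("target must differ from entry")
        if self.speed_mm_per_frame <= 0 or self.needle_width_mm <= 0:
            raise ValueError("speed and width must be > 0")
        if not 0 <= self.needle_contrast <= 2:
            raise ValueError("needle_contrast must be in [0, 2]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def make_background(spec: PhantomSpec) -> np.ndarray:
    """Deterministic head phantom in [0, 1]: elliptical skull rim, two
    hemispheres, hypointense ventricles, plus smooth random texture whose
    realisation depends on ``spec.seed`` (the geometry does not)."""
    if spec.background == "user-image":
        img = np.asarray(spec.user_image, dtype=float)
        if img.shape != (spec.matrix_size, spec.matrix_size):
            raise ValueError("user_image shape mismatch")
        lo, hi = img.min(), img.max()
        return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    N = spec.matrix_size
    yy, xx = np.meshgrid(np.linspace(-1, 1, N), np.linspace(-1, 1, N),
                         indexing="ij")

    def ellipse(cy, cx, ry, rx):
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    img = np.zeros((N, N))
    skull = ellipse(0, 0, 0.92, 0.78)
    brain = ellipse(0, 0, 0.82, 0.68)
    img[skull] = 0.9          # bright rim
    img[brain] = 0.55         # parenchyma
    img[ellipse(0, -0.30, 0.62, 0.26)] = 0.62   # left hemisphere
    img[ellipse(0, 0.30, 0.62, 0.26)] = 0.62    # right hemisphere
    img[ellipse(-0.18, -0.14, 0.22, 0.07)] = 0.18  # ventricles
    img[ellipse(-0.18, 0.14, 0.22, 0.07)] = 0.18
    if spec.texture_sd > 0:
        rng = np.random.default_rng(spec.seed)
        tex = gaussian_filter(rng.standard_normal((N, N)), N / 32.0)
        tex *= spec.texture_sd / max(tex.std(), 1e-12)
        img = img + tex * brain
    return np.clip(img, 0.0, 1.0)


def _needle_mask(N: int, pixel_mm: float, entry, target, depth_mm: float,
                 width_mm: float) -> np.ndarray:
    """Pixels within width/2 of the segment from entry toward target of
    length ``depth_mm``."""
    if depth_mm <= 0:
        return np.zeros((N, N), dtype=bool)
    e = np.asarray(entry, dtype=float)
    t = np.asarray(target, dtype=float)
    u = (t - e) / np.linalg.norm(t - e)
    tip = e + u * depth_mm
    yy, xx = np.meshgrid((np.arange(N) + 0.5) * pixel_mm,
                         (np.arange(N) + 0.5) * pixel_mm, indexing="ij")
    py = yy - e[0]
    px = xx - e[1]
    proj = np.clip(py * u[0] + px * u[1], 0.0, depth_mm)
    dy = py - proj * u[0]
    dx = px - proj * u[1]
    return dy ** 2 + dx ** 2 <= (width_mm / 2) ** 2


def _mirror_x(point, N, pixel_mm):
    """Reflect an (y, x) mm point across the vertical midline."""
    return (point[0], N * pixel_mm - point[1])


def needle_depths_mm(scenario: InterventionScenario) -> np.ndarray:
    """Programmed insertion depth per frame: linear in the frame index at
    ``speed_mm_per_frame`` until the target distance is reached."""
    full = float(np.linalg.norm(
        np.asarray(scenario.target_point_mm)
        - np.asarray(scenario.entry_point_mm)))
    t = np.arange(scenario.n_frames, dtype=float)
    return np.minimum(t * scenario.speed_mm_per_frame, full)


def simulate_intervention(spec: PhantomSpec,
                          scenario: InterventionScenario) -> np.ndarray:
    """Frame stack (n_frames, N, N) in [0, ~1]: static background with the
    needle feature grown frame by frame; bilateral setups insert two
    mirrored needles."""
    N, pm = spec.matrix_size, spec.pixel_mm
    bg = make_background(spec)
    fov = N * pm
    for p in (scenario.entry_point_mm, scenario.target_point_mm):
        if not (0 <= p[0] <= fov and 0 <= p[1] <= fov):
            raise ValueError("needle path leaves the image support")
    lines = [(scenario.entry_point_mm, scenario.target_point_mm)]
    if scenario.setup.startswith("bilateral"):
        lines.append((_mirror_x(scenario.entry_point_mm, N, pm),
                      _mirror_x(scenario.target_point_mm, N, pm)))
    elif scenario.setup == "unilateral-right":
        lines = [(_mirror_x(scenario.entry_point_mm, N, pm),
                  _mirror_x(scenario.target_point_mm, N, pm))]
    depths = needle_depths_mm(scenario)
    frames = np.empty((scenario.n_frames, N, N))
    for t, depth in enumerate(depths):
        img = bg.copy()
        for entry, target in lines:
            mask = _needle_mask(N, pm, entry, target, depth,
                                scenario.needle_width_mm)
            img[mask] *= scenario.needle_contrast
        frames[t] = img
    return frames


def simulate_dbs_sequence(spec: PhantomSpec, scenario: InterventionScenario,
                          frames_per_slice: int = 5,
                          tip_length_mm: float = 3.0,
                          tip_gain: float = 1.8) -> np.ndarray:
    """Electrode-placement variant: thin hyperintense tip ahead of a
    signal-void shaft, emitted as ``frames_per_slice`` frames per slice
    (grouping convention of post-operative electrode series)."""
    N, pm = spec.matrix_size, spec.pixel_mm
    bg = make_background(spec)
    e = np.asarray(scenario.entry_point_mm, dtype=float)
    tgt = np.asarray(scenario.target_point_mm, dtype=float)
    depths = needle_depths_mm(scenario)[:frames_per_slice]
    frames = np.empty((frames_per_slice, N, N))
    for t, depth in enumerate(depths):
        img = bg.copy()
        shaft_len = max(depth - tip_length_mm, 0.0)
        if shaft_len > 0:
            img[_needle_mask(N, pm, e, tgt, shaft_len,
                             scenario.needle_width_mm)] *= scenario.needle_contrast
        if depth > 0:
            u = (tgt - e) / np.linalg.norm(tgt - e)
            tip_entry = e + u * shaft_len
            tip = _needle_mask(N, pm, tuple(tip_entry), tuple(tgt),
                               depth - shaft_len,
                               scenario.needle_width_mm * 0.7)
            img[tip] = np.clip(bg[tip] * tip_gain, 0, 1)
        frames[t] = img
    return frames


def acquire(sequence: np.ndarray, spec: PhantomSpec, scheme: GroupScheme,
            timing: AcquisitionTiming | None = None,
            trajectory: RadialTrajectory | None = None,
            readout_points: int | None = None,
            sens: CoilSensitivities | None = None,
            out_dir: str | Path | None = None,
            ) -> tuple[list[KSpaceGroup], list[ImageGroup], EncodingOperator]:
    """Encode a frame sequence into per-group radial k-space.

    The frame count must divide into groups of ``scheme.fpg``.  Returns
    (k-space groups, matched ground-truth image groups, the encoding
    operator); when ``out_dir`` is given the pairs are also written as
    HDF5 + NIfTI files with a manifest JSON recording every parameter.
    """
    sequence = np.asarray(sequence)
    n_frames = sequence.shape[0]
    if n_frames % scheme.fpg:
        raise ValueError(f"{n_frames} frames do not divide into groups "
                         f"of fpg={scheme.fpg}")
    if trajectory is None:
        cfg = TrajectoryConfig(spec.matrix_size, readout_points=readout_points)
        trajectory = make_trajectory(cfg, scheme)
    if sens is None:
        sens = simulate_coilmaps(spec.n_coils, spec.matrix_size)
    op = EncodingOperator(sens, trajectory, scheme)
    rng = np.random.default_rng(spec.seed + 7919)
    kgroups: list[KSpaceGroup] = []
    truths: list[ImageGroup] = []
    n_groups = n_frames // scheme.fpg
    for g in range(n_groups):
        frames = sequence[g * scheme.fpg:(g + 1) * scheme.fpg].astype(complex)
        d = op.forward(frames)
        if spec.noise_sd > 0:
            d = d + spec.noise_sd * (rng.standard_normal(d.shape)
                                     + 1j * rng.standard_normal(d.shape)) \
                / np.sqrt(2)
        kgroups.append(KSpaceGroup(data=d, trajectory=trajectory,
                                   scheme=scheme, timing=timing,
                                   noise_sd=spec.noise_sd,
                                   pixel_mm=spec.pixel_mm))
        truths.append(ImageGroup(frames=frames, pixel_mm=spec.pixel_mm))
    if out_dir is not None:
        from .kspace_io import write_kspace_h5, write_nifti
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for g, (kg, tg) in enumerate(zip(kgroups, truths)):
            write_kspace_h5(out / f"group{g:03d}_kspace.h5", kg)
            write_nifti(out / f"group{g:03d}_truth.nii.gz", tg.frames,
                        pixel_mm=spec.pixel_mm)
        manifest = {
            "matrix_size": spec.matrix_size, "pixel_mm": spec.pixel_mm,
            "n_coils": spec.n_coils, "noise_sd": spec.noise_sd,
            "seed": spec.seed, "spf": scheme.spf, "fpg": scheme.fpg,
            "n_groups": n_groups, "n_frames": n_frames,
            "readout_points": trajectory.readout_points,
            "background": spec.background, "texture_sd": spec.texture_sd,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return kgroups, truths, op
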