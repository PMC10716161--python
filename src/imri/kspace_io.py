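"""On-disk formats: HDF5 k-space container and NIfTI image sequences.

HDF5 layout (one group of radial data per file):

* ``/kdata``       complex64 as a two-field compound (re, im), shape
                   (coils, spokes, readout)
* ``/ktraj``       float32 (spokes, readout, 2), cycles/pixel
* ``/angles_deg``  float32 (spokes,)
* root attributes: tr_ms, spf, fpg, partitions, matrix_size, pixel_mm,
  noise_sd, modulus_deg

Images travel as NIfTI with axes (x, y, frame) or (x, y, z, frame);
magnitude is mandatory, phase optional, pixel_mm goes in the header.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .operators import ImageGroup, KSpaceGroup
from .trajectory import (AcquisitionTiming, GroupScheme, RadialTrajectory,
                         TrajectoryConfig)

__all__ = ["write_kspace_h5", "read_kspace_h5", "write_nifti", "read_nifti"]

log = logging.getLogger("imri")

_COMPLEX64 = np.dtype([("re", "<f4"), ("im", "<f4")])


def _to_compound(arr: np.ndarray) -> np.ndarray:
    out = np.empty(arr.shape, dtype=_COMPLEX64)
    out["re"] = arr.real.astype(np.float32)
    out["im"] = arr.imag.astype(np.float32)
    return out


def _from_compound(arr: np.ndarray) -> np.ndarray:
    return arr["re"].astype(np.complex128) + 1j * arr["im"].astype(np.complex128)


def write_kspace_h5(path: str | Path, group: KSpaceGroup) -> None:
    traj = group.trajectory
    with h5py.File(path, "w") as f:
        f.create_dataset("kdata", data=_to_compound(group.data))
        f.create_dataset("ktraj", data=traj.kcoords.astype(np.float32))
        f.create_dataset("angles_deg", data=traj.angles_deg.astype(np.float32))
        f.attrs["tr_ms"] = group.timing.tr_ms if group.timing else 0.0
        f.attrs["partitions"] = group.timing.n_partitions if group.timing else 1
        f.attrs["spf"] = group.scheme.spf
        f.attrs["fpg"] = group.scheme.fpg
        f.attrs["matrix_size"] = traj.config.matrix_size
        f.attrs["pixel_mm"] = group.pixel_mm
        f.attrs["noise_sd"] = group.noise_sd
        f.attrs["modulus_deg"] = traj.config.angle_modulus_deg


def read_kspace_h5(path: str | Path) -> KSpaceGroup:
    with h5py.File(path, "r") as f:
        for name in ("kdata", "ktraj", "angles_deg"):
            if name not in f:
                raise KeyError(
                    f"{path}: required dataset '/{name}' is missing")
        data = _from_compound(f["kdata"][()])
        ktraj = f["ktraj"][()].astype(float)
        angles = f["angles_deg"][()].astype(float)
        attrs = dict(f.attrs)
    scheme = GroupScheme(spf=int(attrs["spf"]), fpg=int(attrs["fpg"]))
    if "noise_sd" in attrs:
        noise_sd = float(attrs["noise_sd"])
    else:
        noise_sd = 0.0
        log.warning("%s: no noise_sd attribute; assuming 0", path)
    cfg = TrajectoryConfig(
        matrix_size=int(attrs["matrix_size"]),
        readout_points=int(ktraj.shape[1]),
        angle_modulus_deg=float(attrs.get("modulus_deg", 360.0)))
    traj = RadialTrajectory(angles_deg=angles, kcoords=ktraj,
                            config=cfg, scheme=scheme)
    timing = None
    if attrs.get("tr_ms", 0.0) > 0:
        timing = AcquisitionTiming(tr_ms=float(attrs["tr_ms"]),
                                   n_partitions=int(attrs.get("partitions", 1)))
    return KSpaceGroup(data=data, trajectory=traj, scheme=scheme,
                       timing=timing, noise_sd=noise_sd,
                       pixel_mm=float(attrs.get("pixel_mm", 1.0)))


def write_nifti(path: str | Path, frames: np.ndarray, pixel_mm: float = 1.0,
                phase_path: str | Path | None = None) -> None:
    """Write a complex frame stack (frames, y, x) as magnitude NIfTI with
    axes (x, y, frame); phase is written separately when requested."""
    frames = np.asarray(frames)
    vol = np.abs(frames).transpose(2, 1, 0)
    aff = np.diag([pixel_mm, pixel_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), str(path))
    if phase_path is not None:
        ph = np.angle(frames).transpose(2, 1, 0)
        nib.save(nib.Nifti1Image(ph.astype(np.float32), aff), str(phase_path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a NIfTI written by :func:`write_nifti`; returns (frames, y, x)
    float data and the pixel size in mm."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 2:
        data = data[..., None]
    pixel_mm = float(img.header.get_zooms()[0])
    return data.transpose(2, 1, 0), pixel_mm
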