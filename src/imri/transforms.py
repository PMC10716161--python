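"""Sparsifying transforms: undecimated Haar framelet and temporal TV.

The framelet is a single-level undecimated (shift-invariant) Haar tight
frame over the two spatial dimensions, applied frame by frame.  With taps
scaled to +-1/4 and periodic boundaries the four subbands form a Parseval
frame: ``synthesis(analysis(x)) == x`` and energy is preserved exactly,
which keeps prox steps on coefficients equivalent to prox steps on the
image side.  Temporal total variation uses forward first differences with
zero boundary (intervention sequences are not periodic in time).
"""

from __future__ import annotations

import numpy as np

__all__ = ["HaarFramelet", "temporal_diff", "temporal_diff_adjoint"]


class HaarFramelet:
    """Single-level undecimated 2D Haar tight frame (redundancy 4).

    Analysis maps ``(..., ny, nx)`` to ``(4, ..., ny, nx)`` (subband order
    LL, LH, HL, HH); synthesis is the exact adjoint and inverse.
    Correlation convention: ``coeff[r] = sum_f filt[f] * x[r + f]`` with
    periodic wrap, filter taps on offsets {0,1}^2.
    """

    redundancy = 4
    #: (subband, dy, dx) taps; rows/cols are (offset 0, offset 1)
    _filters = np.array([
        [[0.25, 0.25], [0.25, 0.25]],    # LL
        [[0.25, -0.25], [0.25, -0.25]],  # LH (detail along x)
        [[0.25, 0.25], [-0.25, -0.25]],  # HL (detail along y)
        [[0.25, -0.25], [-0.25, 0.25]],  # HH
    ])

    def analysis(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        shifted = np.empty((2, 2) + x.shape, dtype=x.dtype)
        for dy in (0, 1):
            for dx in (0, 1):
                shifted[dy, dx] = np.roll(x, (-dy, -dx), axis=(-2, -1))
        return np.einsum("kij,ij...->k...", self._filters, shifted)

    def synthesis(self, coeffs: np.ndarray) -> np.ndarray:
        coeffs = np.asarray(coeffs)
        if coeffs.shape[0] != 4:
            raise ValueError("expected 4 leading subbands")
        out = np.zeros(coeffs.shape[1:], dtype=coeffs.dtype)
        for k in range(4):
            for dy in (0, 1):
                for dx in (0, 1):
                    out += self._filters[k, dy, dx] * np.roll(
                        coeffs[k], (dy, dx), axis=(-2, -1))
        return out


def temporal_diff(S: np.ndarray) -> np.ndarray:
    """Forward first differences along the frame axis: (fpg-1, y, x).

    A single frame yields an empty difference array.
    """
    S = np.asarray(S)
    return S[1:] - S[:-1]


def temporal_diff_adjoint(u: np.ndarray, fpg: int) -> np.ndarray:
    """Exact adjoint (negative divergence) of :func:`temporal_diff`."""
    u = np.asarray(u)
    if u.shape[0] != fpg - 1:
        raise ValueError(f"expected {fpg - 1} difference frames")
    out = np.zeros((fpg,) + u.shape[1:], dtype=u.dtype)
    out[1:] += u
    out[:-1] -= u
    return out
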