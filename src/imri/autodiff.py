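"""Minimal reverse-mode automatic differentiation over real numpy arrays.

The unrolled reconstruction network needs gradients through 3D
convolutions, ReLUs, complex-magnitude soft-thresholding, singular-value
thresholding and the (linear) encoding normal operator.  This module
provides exactly that: a tape of :class:`Tensor` nodes, each carrying a
closure that maps the output cotangent to cotangents of its parents.

Complex quantities are carried as real arrays with a leading channel axis
holding interleaved (real, imaginary) pairs; ops with complex internals
(SVT, the encoding operator) convert at their boundary and implement
their vector-Jacobian products explicitly.  Every custom VJP here is
covered by a finite-difference test.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "add", "sub", "scale", "relu", "conv3d_circ",
           "soft_mag", "svt_pairs", "tdiff", "tdiff_adjoint",
           "encode_normal_residual", "mse", "c2_from_complex",
           "complex_from_c2"]


class Tensor:
    """A node in the computation graph (real data only)."""

    __slots__ = ("data", "grad", "parents", "vjp", "name")

    def __init__(self, data, parents=(), vjp=None, name=""):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.parents = tuple(parents)
        self.vjp = vjp  # callable(grad_out) -> tuple of parent cotangents
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Accumulate gradients of this (scalar) tensor into the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in order:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.vjp is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node.vjp(node.grad)):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad = parent.grad + g


# ------------------------------------------------------------ helpers
def c2_from_complex(z: np.ndarray) -> np.ndarray:
    """Complex array -> real array with a new leading (re, im) axis."""
    return np.stack([z.real, z.imag], axis=0)


def complex_from_c2(a: np.ndarray) -> np.ndarray:
    return a[0] + 1j * a[1]


def _pairs_view(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split leading channel axis into (re, im) halves of each pair."""
    if a.shape[0] % 2:
        raise ValueError("leading channel axis must be even (re/im pairs)")
    return a[0::2], a[1::2]


# ------------------------------------------------------------ basic ops
def add(x: Tensor, y: Tensor) -> Tensor:
    return Tensor(x.data + y.data, (x, y), lambda g: (g, g), "add")


def sub(x: Tensor, y: Tensor) -> Tensor:
    return Tensor(x.data - y.data, (x, y), lambda g: (g, -g), "sub")


def scale(s: Tensor, x: Tensor) -> Tensor:
    """Multiply tensor ``x`` by scalar tensor ``s``."""
    sd = float(s.data)
    return Tensor(sd * x.data, (s, x),
                  lambda g: (np.sum(g * x.data).reshape(s.data.shape), sd * g),
                  "scale")


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,), "relu")


def mse(x: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    diff = x.data - target
    n = diff.size
    return Tensor(np.sum(diff ** 2) / n, (x,),
                  lambda g: (float(g) * 2.0 * diff / n,), "mse")


# ----------------------------------------------------- 3D convolution
def conv3d_circ(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Channel-mixing 3D correlation with circular padding.

    ``x``: (Cin, T, Y, X); ``w``: (Cout, Cin, kt, ky, kx); ``b``: (Cout,).
    ``out[o, r] = b[o] + sum_{i,d} w[o,i,d] * x[i, r + d - center]`` with
    periodic wrap along T, Y, X.
    """
    xd, wd = x.data, w.data
    Cout, Cin, kt, ky, kx = wd.shape
    if xd.shape[0] != Cin:
        raise ValueError(f"conv3d: {xd.shape[0]} input channels, "
                         f"weight expects {Cin}")
    ct, cy, cx = kt // 2, ky // 2, kx // 2
    out = np.broadcast_to(b.data[:, None, None, None],
                          (Cout,) + xd.shape[1:]).copy()
    shifts = [(dt, dy, dx) for dt in range(kt) for dy in range(ky)
              for dx in range(kx)]
    rolled = {}
    for dt, dy, dx in shifts:
        xs = np.roll(xd, (-(dt - ct), -(dy - cy), -(dx - cx)), axis=(1, 2, 3))
        rolled[(dt, dy, dx)] = xs
        out += np.tensordot(wd[:, :, dt, dy, dx], xs, axes=([1], [0]))

    def vjp(g):
        gx = np.zeros_like(xd)
        gw = np.empty_like(wd)
        for dt, dy, dx in shifts:
            gx += np.tensordot(wd[:, :, dt, dy, dx].T, np.roll(
                g, (dt - ct, dy - cy, dx - cx), axis=(1, 2, 3)),
                axes=([1], [0]))
            gw[:, :, dt, dy, dx] = np.tensordot(
                g, rolled[(dt, dy, dx)], axes=([1, 2, 3], [1, 2, 3]))
        gb = g.sum(axis=(1, 2, 3))
        return gx, gw, gb

    return Tensor(out, (x, w, b), vjp, "conv3d")


# ------------------------------------------- magnitude soft-threshold
def soft_mag(x: Tensor, tau: Tensor) -> Tensor:
    """Soft-threshold complex magnitudes of channel pairs.

    Channels (2i, 2i+1) of the leading axis are one complex number;
    output is ``z * max(|z| - tau, 0)/|z|`` per pair, with a learnable
    scalar threshold ``tau`` (clamped at 0).
    """
    t = max(float(tau.data), 0.0)
    a, bb = _pairs_view(x.data)
    r = np.sqrt(a ** 2 + bb ** 2)
    active = r > t
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(active, 1.0 - t / np.where(r > 0, r, 1.0), 0.0)
    out = np.empty_like(x.data)
    out[0::2], out[1::2] = a * s, bb * s

    def vjp(g):
        ga, gb = _pairs_view(g)
        with np.errstate(invalid="ignore", divide="ignore"):
            r3 = np.where(active, r ** 3, 1.0)
            daa = s + np.where(active, t * a ** 2 / r3, 0.0)
            dbb = s + np.where(active, t * bb ** 2 / r3, 0.0)
            dab = np.where(active, t * a * bb / r3, 0.0)
        gx = np.empty_like(x.data)
        gx[0::2] = ga * daa + gb * dab
        gx[1::2] = ga * dab + gb * dbb
        if float(tau.data) >= 0:
            rr = np.where(active, r, 1.0)
            gt = -np.sum(np.where(active, (ga * a + gb * bb) / rr, 0.0))
        else:
            gt = 0.0  # clamped region
        return gx, np.asarray(gt).reshape(tau.data.shape)

    return Tensor(out, (x, tau), vjp, "soft_mag")


# ------------------------------------------- singular value threshold
def _svt_core(M: np.ndarray, t: float):
    """SVT of complex Casorati M (P x F, P >= F) via the small Gram
    matrix: SVT(M) = M V h(Lam) V^H with A = M^H M = V Lam V^H and
    h(lam) = max(1 - t/sqrt(lam), 0)."""
    A = M.conj().T @ M
    lam, V = np.linalg.eigh(A)
    lam = np.maximum(lam, 0.0)
    s = np.sqrt(lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(s > t, 1.0 - t / np.where(s > 0, s, 1.0), 0.0)
    W = (V * h) @ V.conj().T
    return M @ W, lam, s, h, V, W


def svt_pairs(x: Tensor, tau: Tensor, fpg: int) -> Tensor:
    """Singular-value thresholding of a (2, fpg, N, N) re/im stack.

    The complex frames are reshaped to the (pixels x fpg) Casorati matrix,
    thresholded exactly, and reshaped back.  The vector-Jacobian product
    is computed through the eigendecomposition of the small fpg x fpg
    Gram matrix with the Daleckii-Krein formula, so the cost of the
    backward pass is independent of the pixel count.
    """
    t = max(float(tau.data), 0.0)
    z = complex_from_c2(x.data)  # (fpg, N, N)
    if not np.all(np.isfinite(x.data)):
        # pass non-finite states through so the caller's loss check can
        # report them instead of the eigensolver aborting
        return Tensor(x.data.copy(), (x, tau),
                      lambda g: (g, np.zeros_like(tau.data)), "svt")
    shape = z.shape
    M = z.reshape(fpg, -1).T  # pixels x fpg
    Y, lam, s, h, V, W = _svt_core(M, t)
    out = c2_from_complex(Y.T.reshape(shape))

    def vjp(gc2):
        G = complex_from_c2(gc2).reshape(fpg, -1).T  # pixels x fpg
        # dh/dlam, and the divided-difference matrix Gamma
        with np.errstate(divide="ignore", invalid="ignore"):
            hp = np.where(s > t, t / np.where(lam > 0, 2 * lam * s, 1.0), 0.0)
        F = len(lam)
        dl = lam[:, None] - lam[None, :]
        close = np.abs(dl) < 1e-12 * max(lam.max(), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            Gam = np.where(close, 0.0, (h[:, None] - h[None, :]) /
                           np.where(close, 1.0, dl))
        Gam[close] = np.broadcast_to(0.5 * (hp[:, None] + hp[None, :]),
                                     (F, F))[close]
        Qt = V.conj().T @ (G.conj().T @ M) @ V
        C = Gam * Qt
        gM = G @ W + M @ (V @ (C + C.conj().T) @ V.conj().T)
        gx = c2_from_complex(gM.T.reshape(shape))
        if t > 0:
            act = s > t
            gt = -np.sum(np.real(np.diag(Qt))[act] / s[act])
        else:
            gt = 0.0
        return gx, np.asarray(gt).reshape(tau.data.shape)

    return Tensor(out, (x, tau), vjp, "svt")


# ----------------------------------------------- temporal differences
def tdiff(x: Tensor, frame_axis: int = 1) -> Tensor:
    """Forward temporal differences along ``frame_axis`` (zero boundary)."""
    ax = frame_axis

    def diff(a):
        sl1 = [slice(None)] * a.ndim
        sl0 = [slice(None)] * a.ndim
        sl1[ax], sl0[ax] = slice(1, None), slice(None, -1)
        return a[tuple(sl1)] - a[tuple(sl0)]

    def adj(u, n):
        out = np.zeros(u.shape[:ax] + (n,) + u.shape[ax + 1:], dtype=u.dtype)
        sl1 = [slice(None)] * out.ndim
        sl0 = [slice(None)] * out.ndim
        sl1[ax], sl0[ax] = slice(1, None), slice(None, -1)
        out[tuple(sl1)] += u
        out[tuple(sl0)] -= u
        return out

    n = x.data.shape[ax]
    return Tensor(diff(x.data), (x,), lambda g: (adj(g, n),), "tdiff")


def tdiff_adjoint(u: Tensor, n_frames: int, frame_axis: int = 1) -> Tensor:
    """Adjoint of :func:`tdiff` (negative divergence along the frame axis)."""
    ax = frame_axis

    def adj(a):
        out = np.zeros(a.shape[:ax] + (n_frames,) + a.shape[ax + 1:],
                       dtype=a.dtype)
        sl1 = [slice(None)] * out.ndim
        sl0 = [slice(None)] * out.ndim
        sl1[ax], sl0[ax] = slice(1, None), slice(None, -1)
        out[tuple(sl1)] += a
        out[tuple(sl0)] -= a
        return out

    def diff(a):
        sl1 = [slice(None)] * a.ndim
        sl0 = [slice(None)] * a.ndim
        sl1[ax], sl0[ax] = slice(1, None), slice(None, -1)
        return a[tuple(sl1)] - a[tuple(sl0)]

    return Tensor(adj(u.data), (u,), lambda g: (diff(g),), "tdiff_adj")


# --------------------------------------------- encoding normal operator
def encode_normal_residual(x: Tensor, op, d: np.ndarray) -> Tensor:
    """``E^H (E x - d)`` on a (2, fpg, N, N) re/im stack.

    Affine in ``x`` with self-adjoint Jacobian ``E^H E``, so the VJP is
    one more normal-operator application.
    """
    z = complex_from_c2(x.data)
    out = op.adjoint(op.forward(z) - d)

    def vjp(g):
        gz = complex_from_c2(g)
        return (c2_from_complex(op.adjoint(op.forward(gz))),)

    return Tensor(c2_from_complex(out), (x,), vjp, "EHE")
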