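"""Forward-mode automatic differentiation on numpy arrays.

The differentiable simulator needs derivatives of simulated trajectories with
respect to a handful of kinetic parameters (never more than ~7 here). For such
small parameter vectors, forward-mode tangent propagation is as accurate as
reverse mode and avoids taping: every :class:`Dual` carries a value array of
shape ``s`` and a tangent array of shape ``s + (P,)``, the Jacobian of the
value with respect to ``P`` seed directions.

Plain numpy arrays and scalars mix freely with duals and are treated as
constants (zero tangent). The module-level helpers (:func:`exp`, :func:`log`,
:func:`where`, ...) dispatch on type so simulation code can be written once
and run with or without gradients.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Dual",
    "seed_duals",
    "value",
    "tangent",
    "exp",
    "log",
    "sqrt",
    "sigmoid",
    "where",
    "vsum",
    "vmean",
    "clip_nonneg",
    "stack_last",
]


class Dual:
    """A numpy array paired with its Jacobian w.r.t. P seed directions."""

    __slots__ = ("val", "tan")

    # make numpy defer to the reflected operators instead of broadcasting
    # Duals into object arrays
    __array_ufunc__ = None

    def __init__(self, val, tan):
        self.val = np.asarray(val, dtype=float)
        self.tan = np.asarray(tan, dtype=float)
        if self.tan.ndim != self.val.ndim + 1:
            raise ValueError(
                f"tangent must have one trailing seed axis: val {self.val.shape}, "
                f"tan {self.tan.shape}"
            )

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.val.shape

    @property
    def nseeds(self):
        return self.tan.shape[-1]

    def __repr__(self):
        return f"Dual(val={self.val!r}, nseeds={self.nseeds})"

    def __getitem__(self, idx):
        # Basic indexing on the value axes; the trailing seed axis is untouched.
        if isinstance(idx, tuple):
            tidx = idx + (slice(None),)
        else:
            tidx = idx
        return Dual(self.val[idx], self.tan[tidx])

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, Dual):
            return Dual(self.val + other.val, self.tan + other.tan)
        return Dual(self.val + other, self.tan + np.zeros_like(np.asarray(other, dtype=float))[..., None])

    __radd__ = __add__

    def __neg__(self):
        return Dual(-self.val, -self.tan)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Dual) else -np.asarray(other, dtype=float))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, Dual):
            return Dual(
                self.val * other.val,
                self.tan * other.val[..., None] + other.tan * self.val[..., None],
            )
        other = np.asarray(other, dtype=float)
        return Dual(self.val * other, self.tan * other[..., None])

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Dual):
            inv = 1.0 / other.val
            val = self.val * inv
            tan = (self.tan - other.tan * val[..., None]) * inv[..., None]
            return Dual(val, tan)
        other = np.asarray(other, dtype=float)
        return Dual(self.val / other, self.tan / other[..., None])

    def __rtruediv__(self, other):
        other = np.asarray(other, dtype=float)
        inv = 1.0 / self.val
        val = other * inv
        return Dual(val, -self.tan * (val * inv)[..., None])

    def __pow__(self, k):
        if isinstance(k, Dual):
            raise TypeError("dual exponents are not supported")
        k = float(k)
        if k == 1.0:
            return Dual(self.val.copy(), self.tan.copy())
        if k == 2.0:
            return Dual(self.val**2, 2.0 * self.val[..., None] * self.tan)
        return Dual(self.val**k, k * (self.val ** (k - 1.0))[..., None] * self.tan)

    # -- comparisons act on values (used for masks; not differentiated) ----
    def __lt__(self, other):
        return self.val < value(other)

    def __le__(self, other):
        return self.val <= value(other)

    def __gt__(self, other):
        return self.val > value(other)

    def __ge__(self, other):
        return self.val >= value(other)


def seed_duals(theta):
    """Lift a length-P parameter vector into a Dual with identity tangents."""
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1:
        raise ValueError("seed_duals expects a 1-D parameter vector")
    return Dual(theta, np.eye(theta.size))


def value(x):
    return x.val if isinstance(x, Dual) else np.asarray(x, dtype=float)


def tangent(x, nseeds=None):
    if isinstance(x, Dual):
        return x.tan
    shape = np.asarray(x, dtype=float).shape + ((nseeds,) if nseeds else (0,))
    return np.zeros(shape)


# -- elementwise functions -------------------------------------------------

def exp(x):
    if isinstance(x, Dual):
        e = np.exp(x.val)
        return Dual(e, e[..., None] * x.tan)
    return np.exp(x)


def log(x):
    if isinstance(x, Dual):
        return Dual(np.log(x.val), x.tan / x.val[..., None])
    return np.log(x)


def sqrt(x):
    if isinstance(x, Dual):
        s = np.sqrt(x.val)
        return Dual(s, x.tan / (2.0 * s)[..., None])
    return np.sqrt(x)


def sigmoid(x):
    if isinstance(x, Dual):
        s = expit(x.val)
        return Dual(s, (s * (1.0 - s))[..., None] * x.tan)
    return expit(x)


def where(cond, a, b):
    """Select between two branches; the condition itself is never differentiated."""
    cond = np.asarray(cond)
    if isinstance(a, Dual) or isinstance(b, Dual):
        n = a.nseeds if isinstance(a, Dual) else b.nseeds
        ta = tangent(a, n)
        tb = tangent(b, n)
        return Dual(np.where(cond, value(a), value(b)), np.where(cond[..., None], ta, tb))
    return np.where(cond, a, b)


def _posaxis(axis, ndim):
    return axis % ndim


def vsum(x, axis=None):
    if isinstance(x, Dual):
        if axis is None:
            return Dual(x.val.sum(), x.tan.reshape(-1, x.nseeds).sum(axis=0))
        return Dual(x.val.sum(axis=axis), x.tan.sum(axis=_posaxis(axis, x.val.ndim)))
    return np.sum(x, axis=axis)


def vmean(x, axis=None):
    if isinstance(x, Dual):
        if axis is None:
            return Dual(x.val.mean(), x.tan.reshape(-1, x.nseeds).mean(axis=0))
        return Dual(x.val.mean(axis=axis), x.tan.mean(axis=_posaxis(axis, x.val.ndim)))
    return np.mean(x, axis=axis)


def clip_box(x, lo, hi):
    """Clip values into [lo, hi]; tangents are zeroed on clipped entries."""
    hi_finite = np.where(np.isfinite(hi), hi, np.inf)
    if isinstance(x, Dual):
        inside = (x.val > lo) & (x.val < hi_finite)
        return Dual(np.clip(x.val, lo, hi_finite), x.tan * inside[..., None])
    return np.clip(x, lo, hi_finite)


def take_rows(x, idx):
    """Select leading-axis rows (Dual-aware)."""
    if isinstance(x, Dual):
        return Dual(x.val[idx], x.tan[idx])
    return np.asarray(x)[idx]


def put_rows(x, idx, sub):
    """Copy of ``x`` with leading-axis rows ``idx`` replaced by ``sub``."""
    if isinstance(x, Dual):
        val = x.val.copy()
        tan = x.tan.copy()
        val[idx] = value(sub)
        tan[idx] = sub.tan if isinstance(sub, Dual) else 0.0
        return Dual(val, tan)
    out = np.array(x, dtype=float, copy=True)
    out[idx] = value(sub)
    return out


def clip_nonneg(x):
    """max(x, 0) with zero tangent on the clipped branch."""
    if isinstance(x, Dual):
        pos = x.val > 0.0
        return Dual(np.where(pos, x.val, 0.0), np.where(pos[..., None], x.tan, 0.0))
    return np.maximum(x, 0.0)


def expand_last(x):
    """Insert a new trailing value axis (like ``x[..., None]``)."""
    if isinstance(x, Dual):
        return Dual(x.val[..., None], np.expand_dims(x.tan, axis=-2))
    return np.asarray(x, dtype=float)[..., None]


def dot_last(w, A):
    """Contract the last value axis of ``w`` with the first axis of constant ``A``."""
    A = np.asarray(A, dtype=float)
    if isinstance(w, Dual):
        return Dual(
            np.tensordot(w.val, A, axes=([-1], [0])),
            np.einsum("...np,nm->...mp", w.tan, A),
        )
    return np.tensordot(w, A, axes=([-1], [0]))


def stack_last(items):
    """Stack a list of same-shaped values along a new trailing value axis."""
    if any(isinstance(it, Dual) for it in items):
        n = next(it.nseeds for it in items if isinstance(it, Dual))
        ref = next(it for it in items if isinstance(it, Dual))
        vals = [np.broadcast_to(value(it), ref.shape) for it in items]
        tans = [
            it.tan if isinstance(it, Dual) else np.zeros(ref.shape + (n,))
            for it in items
        ]
        tans = [np.broadcast_to(t, ref.shape + (n,)) for t in tans]
        return Dual(np.stack(vals, axis=-1), np.stack(tans, axis=-2))
    return np.stack([np.asarray(it, dtype=float) for it in items], axis=-1)
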