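"""Integer-supported probability mass functions and divergence metrics.

Used to quantify how well the smoothed (differentiable) simulator reproduces
the exact steady-state copy-number distribution: empirical pmfs are built from
ensembles, and accuracy is reported as the Jensen–Shannon divergence between
the approximate and exact pmfs normalized by the Shannon entropy of the exact
one. All information measures are in nats (natural log); the JSD/H ratio is
base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EmptySampleError(ValueError):
    pass


class InfiniteDivergenceError(ValueError):
    pass


@dataclass(frozen=True)
class Pmf:
    """A probability mass function on a strictly increasing integer support."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        support = np.asarray(self.support, dtype=int)
        probs = np.asarray(self.probs, dtype=float)
        if support.ndim != 1 or probs.shape != support.shape:
            raise ValueError("support and probs must be matching 1-D arrays")
        if support.size and np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(probs < -1e-12):
            raise ValueError("probabilities must be nonnegative")
        total = probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", np.clip(probs, 0.0, None))

    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    def var(self) -> float:
        mu = self.mean()
        return float(np.dot((self.support - mu) ** 2, self.probs))

    def fano(self) -> float:
        return self.var() / self.mean()

    def raw_moment(self, order: int) -> float:
        return float(np.dot(self.support.astype(float) ** order, self.probs))

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.support, self.probs])

    @classmethod
    def from_table(cls, table: np.ndarray) -> "Pmf":
        table = np.asarray(table, dtype=float)
        return cls(table[:, 0].astype(int), table[:, 1])


def empirical_pmf(samples) -> Pmf:
    """Tabulate samples into a pmf.

    Real-valued samples (e.g. the differentiable simulator's continuous
    abundances) are rounded to the nearest integer; negative values clip to 0.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise EmptySampleError("cannot build a pmf from zero samples")
    counts_int = np.maximum(np.rint(samples).astype(int), 0)
    support, counts = np.unique(counts_int, return_counts=True)
    return Pmf(support, counts / counts.sum())


def _harmonize(p: Pmf, q: Pmf):
    """Zero-pad two pmfs onto the union of their supports."""
    support = np.union1d(p.support, q.support)
    pp = np.zeros(support.size)
    qq = np.zeros(support.size)
    pp[np.searchsorted(support, p.support)] = p.probs
    qq[np.searchsorted(support, q.support)] = q.probs
    return support, pp, qq


def kl(p: Pmf, q: Pmf) -> float:
    """Kullback–Leibler divergence D_KL(P||Q) in nats; 0·ln0 := 0."""
    _, pp, qq = _harmonize(p, q)
    mask = pp > 0.0
    if np.any(qq[mask] <= 0.0):
        raise InfiniteDivergenceError("P places mass where Q has none")
    return float(np.sum(pp[mask] * np.log(pp[mask] / qq[mask])))


def jsd(p: Pmf, q: Pmf) -> float:
    """Jensen–Shannon divergence in nats: ½KL(P||M)+½KL(Q||M), M=(P+Q)/2."""
    support, pp, qq = _harmonize(p, q)
    mm = 0.5 * (pp + qq)
    m = Pmf(support[mm > 0], mm[mm > 0] / mm[mm > 0].sum())
    p2 = Pmf(support[pp > 0], pp[pp > 0] / pp[pp > 0].sum()) if np.any(pp == 0) else Pmf(support, pp)
    q2 = Pmf(support[qq > 0], qq[qq > 0] / qq[qq > 0].sum()) if np.any(qq == 0) else Pmf(support, qq)
    return 0.5 * kl(p2, m) + 0.5 * kl(q2, m)


def entropy(p: Pmf) -> float:
    """Shannon entropy −Σ p ln p in nats."""
    probs = p.probs[p.probs > 0]
    return float(-np.sum(probs * np.log(probs)))


def jsd_over_entropy(p_approx: Pmf, p_exact: Pmf) -> float:
    """Dimensionless accuracy ratio JSD(p_approx||p_exact)/H(p_exact)."""
    h = entropy(p_exact)
    if h <= 0.0:
        raise ZeroDivisionError("reference pmf has zero entropy")
    return jsd(p_approx, p_exact) / h


def moments(samples, orders=(1, 2, 3, 4)) -> np.ndarray:
    """Raw moments ⟨mⁿ⟩ of a sample set for the requested orders."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise EmptySampleError("cannot compute moments of zero samples")
    return np.array([np.mean(samples**k) for k in orders])


def sample_stats(samples):
    """(mean, std, Fano) of a sample set; std is the population std."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise EmptySampleError("cannot compute statistics of zero samples")
    mean = float(samples.mean())
    std = float(samples.std())
    fano = std**2 / mean if mean > 0 else np.nan
    return mean, std, fano
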