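"""Reaction networks, the exact Gillespie simulator, and a CME oracle.

A :class:`ReactionSystem` is a list of species, an N×M stoichiometric matrix
``S`` (row i = change in each species when reaction i fires), and one
propensity rule per reaction. Propensities are restricted to products of rate
constants, species counts, and 0/1-indicator complements — enough for the
promoter models studied here — with arbitrary callables accepted but flagged
as untested.

Two oracles live here: :func:`simulate_exact`, the classic direct-method SSA,
and :func:`cme_steady_state`, which solves the global-balance equations of the
truncated chemical master equation. Both serve as ground truth for the
smoothed differentiable simulator in :mod:`dgasim.dga_engine`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import autodiff as ad
from .distribution_metrics import Pmf

__all__ = [
    "Propensity",
    "ReactionSystem",
    "SimConfig",
    "ExactEnsemble",
    "NoiseSource",
    "AbsorbingStateError",
    "NegativePropensityError",
    "TruncationError",
    "total_rate",
    "exact_step",
    "simulate_exact",
    "cme_steady_state",
]


class AbsorbingStateError(RuntimeError):
    """Raised when the total rate is zero and no further step is possible."""


class NegativePropensityError(ValueError):
    pass


class TruncationError(ValueError):
    def __init__(self, boundary_mass, message=None):
        self.boundary_mass = boundary_mass
        super().__init__(
            message
            or f"CME truncation too small: boundary mass {boundary_mass:.3e}"
        )


@dataclass(frozen=True)
class Propensity:
    """A mass-action-style propensity rule.

    rate(x) = coeff · Π_p θ_p · Π_α x_α^order · Π_s (1 − x_s)

    ``params`` are names of rate constants multiplied together, ``coeff`` a
    fixed numeric prefactor (e.g. an activator concentration), ``orders`` maps
    species names to count exponents, and ``complements`` lists 0/1 indicator
    species entering as (1 − x). A ``custom`` callable (x, θ) → rate may be
    supplied instead; it bypasses the structured path and is flagged untested.
    """

    params: tuple = ()
    coeff: float = 1.0
    orders: tuple = ()  # ((species, exponent), ...)
    complements: tuple = ()
    custom: object = None

    def __post_init__(self):
        if isinstance(self.params, str):
            object.__setattr__(self, "params", (self.params,))
        else:
            object.__setattr__(self, "params", tuple(self.params))
        object.__setattr__(
            self, "orders", tuple((s, int(e)) for s, e in dict(self.orders).items())
        )
        object.__setattr__(self, "complements", tuple(self.complements))
        if self.custom is not None:
            warnings.warn(
                "custom propensity callables are accepted but untested; the "
                "differentiable path requires structured rules",
                stacklevel=2,
            )

    def to_dict(self):
        return {
            "params": list(self.params),
            "coeff": self.coeff,
            "orders": {s: e for s, e in self.orders},
            "complements": list(self.complements),
        }


class ReactionSystem:
    """Species, stoichiometric matrix S (N reactions × M species), propensities, θ."""

    def __init__(self, species, S, propensities, params, bounds=None):
        self.species = list(species)
        self.S = np.asarray(S, dtype=int)
        self.propensities = list(propensities)
        self.params = dict(params)
        # physical range per species; the differentiable simulator clips its
        # real-valued abundances to these (indicators get (0, 1))
        self.bounds = {s: (0.0, np.inf) for s in self.species}
        if bounds:
            for s, (lo, hi) in bounds.items():
                self.idx(s)
                self.bounds[s] = (float(lo), float(hi))
        if self.S.ndim != 2 or self.S.shape != (len(self.propensities), len(self.species)):
            raise ValueError(
                f"S must be (n_reactions, n_species); got {self.S.shape} for "
                f"{len(self.propensities)} reactions, {len(self.species)} species"
            )
        if self.S.shape[0] < 1 or self.S.shape[1] < 1:
            raise ValueError("need at least one reaction and one species")
        for prop in self.propensities:
            if prop.custom is None:
                for name in prop.params:
                    if name not in self.params:
                        raise KeyError(f"unknown rate constant {name!r}")
                for s, _ in prop.orders:
                    self.idx(s)
                for s in prop.complements:
                    self.idx(s)
        for name, val in self.params.items():
            if val < 0:
                raise ValueError(f"rate constant {name!r} must be nonnegative")

    @property
    def n_reactions(self):
        return self.S.shape[0]

    @property
    def n_species(self):
        return self.S.shape[1]

    def idx(self, species_name):
        try:
            return self.species.index(species_name)
        except ValueError:
            raise KeyError(f"unknown species {species_name!r}") from None

    def rates(self, x, params=None, rate_scale=None):
        """Propensity vector r(x) with trailing reaction axis.

        ``x`` has shape (..., M) (plain array or :class:`~dgasim.autodiff.Dual`).
        ``params`` may override rate constants (scalars or Duals), which is how
        the differentiable path injects parameters with tangents.
        ``rate_scale`` optionally multiplies reaction i by a per-row factor
        (shape (...,) per reaction, passed as a length-N list/array), used to
        batch e.g. different ligand concentrations in one ensemble.
        """
        theta = dict(self.params)
        if params:
            theta.update(params)
        out = []
        for i, prop in enumerate(self.propensities):
            if prop.custom is not None:
                r = prop.custom(x, theta)
            else:
                r = prop.coeff
                for name in prop.params:
                    r = r * theta[name]
                for s, e in prop.orders:
                    r = r * x[..., self.idx(s)] ** e if e != 1 else r * x[..., self.idx(s)]
                for s in prop.complements:
                    r = r * (1.0 - x[..., self.idx(s)])
            if rate_scale is not None:
                r = r * rate_scale[i]
            if np.ndim(ad.value(r)) == 0 and np.ndim(ad.value(x)) > 1:
                r = r * np.ones(ad.value(x).shape[:-1])
            out.append(r)
        return ad.stack_last(out)

    def bounds_arrays(self):
        lo = np.array([self.bounds[s][0] for s in self.species])
        hi = np.array([self.bounds[s][1] for s in self.species])
        return lo, hi

    def to_dict(self):
        return {
            "species": list(self.species),
            "bounds": {s: [b[0], None if np.isinf(b[1]) else b[1]]
                       for s, b in self.bounds.items()},
            "params": {k: float(v) for k, v in self.params.items()},
            "reactions": [
                {"stoich": {s: int(c) for s, c in zip(self.species, row) if c != 0},
                 **prop.to_dict()}
                for row, prop in zip(self.S, self.propensities)
            ],
        }

    @classmethod
    def from_dict(cls, d):
        species = list(d["species"])
        rows, props = [], []
        for rx in d["reactions"]:
            rows.append([rx.get("stoich", {}).get(s, 0) for s in species])
            props.append(
                Propensity(
                    params=tuple(rx.get("params", ())),
                    coeff=float(rx.get("coeff", 1.0)),
                    orders=tuple(dict(rx.get("orders", {})).items()),
                    complements=tuple(rx.get("complements", ())),
                )
            )
        bounds = {
            s: (lo, np.inf if hi is None else hi)
            for s, (lo, hi) in d.get("bounds", {}).items()
        }
        return cls(species, np.array(rows, dtype=int), props, d.get("params", {}),
                   bounds=bounds)


@dataclass(frozen=True)
class SimConfig:
    """Ensemble-simulation settings: horizon, step cap, size, master seed."""

    t_end: float
    n_traj: int = 1
    max_steps: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.n_traj < 1 or self.max_steps < 1:
            raise ValueError("n_traj and max_steps must be >= 1")


@dataclass
class ExactEnsemble:
    """Final states of an exact-SSA ensemble, one row per trajectory."""

    final_states: np.ndarray  # (n_traj, M) ints
    final_times: np.ndarray  # (n_traj,)
    fired_counts: np.ndarray  # (n_traj, N) events fired per reaction
    flagged: np.ndarray  # trajectories that hit max_steps before t_end
    dwell_fractions: np.ndarray = None  # (n_traj, M) time-fraction-weighted states

    def counts(self, system, species_name):
        return self.final_states[:, system.idx(species_name)]

    def to_table(self):
        return np.column_stack([self.final_states, self.final_times])


class NoiseSource:
    """Per-trajectory streams of (u, u′) pairs, one pair per simulation step.

    Each trajectory owns an independent generator spawned from the master
    seed, so enlarging the ensemble extends it without reshuffling existing
    trajectories. ``u`` is drawn from (0, 1] (so −ln u is finite), ``u′`` from
    [0, 1). Pairs are consumed in lockstep by every trajectory, which keeps
    the exact and differentiable simulators on the same sample path.
    """

    def __init__(self, seed, n_traj, chunk=128, max_chunk=2048):
        self.seed = int(seed)
        self.n_traj = int(n_traj)
        self.chunk = int(chunk)  # grows geometrically on refills
        self.max_chunk = int(max_chunk)
        children = np.random.SeedSequence(self.seed).spawn(self.n_traj)
        self._gens = [np.random.Generator(np.random.PCG64(c)) for c in children]
        self._buf = None
        self._pos = 0
        self.steps_drawn = 0

    def _refill(self):
        buf = np.empty((self.n_traj, self.chunk, 2))
        for j, g in enumerate(self._gens):
            buf[j] = g.random((self.chunk, 2))
        self._buf = buf
        self._pos = 0

    def next_pair(self):
        """Return (u, u′), each shape (n_traj,), for the next step."""
        if self._buf is None or self._pos >= self._buf.shape[1]:
            self._refill()
            self.chunk = min(self.chunk * 2, self.max_chunk)
        u = 1.0 - self._buf[:, self._pos, 0]  # in (0, 1]
        u_prime = self._buf[:, self._pos, 1]  # in [0, 1)
        self._pos += 1
        self.steps_drawn += 1
        return u, u_prime


def total_rate(system, x, params=None):
    """Total propensity R = Σ_i r_i(x)."""
    r = np.asarray(ad.value(system.rates(x, params=params)), dtype=float)
    if np.any(r < 0):
        raise NegativePropensityError(f"negative propensity in {r}")
    return r.sum(axis=-1)


def exact_step(system, x, rng, params=None):
    """One exact SSA step: (dt, reaction_index, x_next); raises at absorbing states.

    The waiting time is dt = −ln(u)/R with u ~ U(0,1]; the reaction index is
    the smallest i with Σ_{j≤i} r_j/R > u′ (ties resolve upward).
    """
    x = np.asarray(x)
    r = np.asarray(ad.value(system.rates(x.astype(float), params=params)))
    if np.any(r < 0):
        raise NegativePropensityError(f"negative propensity in {r}")
    R = r.sum()
    if R <= 0.0:
        raise AbsorbingStateError("total rate is zero; no step possible")
    u = 1.0 - rng.random()
    u_prime = rng.random()
    dt = -np.log(u) / R
    cum = np.cumsum(r) / R
    cum[-1] = 1.0  # guard against round-off at the top of the ladder
    i = int(np.argmax(cum > u_prime))
    x_next = x + system.S[i]
    return dt, i, x_next


def simulate_exact(system, x0, config, params=None, noise=None, record_dwell=False):
    """Evolve an ensemble of exact-SSA trajectories to time t_end.

    All trajectories are advanced in a vectorized lockstep loop; a trajectory
    whose next waiting time would cross ``t_end`` freezes at its current state
    (the ensemble therefore samples the state *at* t_end). Absorbing states
    freeze a trajectory early; hitting ``max_steps`` flags it.

    With ``record_dwell=True``, time-fraction-weighted state occupancies are
    accumulated per trajectory (used for promoter-state dwell statistics).
    """
    x0 = np.asarray(x0, dtype=int)
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    n, M = config.n_traj, system.n_species
    x = np.tile(x0, (n, 1)).astype(float)
    t = np.zeros(n)
    fired = np.zeros((n, system.n_reactions), dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    flagged = np.zeros(n, dtype=bool)
    dwell = np.zeros((n, M)) if record_dwell else None
    dwell_t = np.zeros(n) if record_dwell else None
    if noise is None:
        noise = NoiseSource(config.seed, n)
    for _ in range(config.max_steps):
        if done.all():
            break
        r = np.asarray(ad.value(system.rates(x, params=params)))
        if np.any(r < -1e-12):
            raise NegativePropensityError("negative propensity during simulation")
        r = np.maximum(r, 0.0)
        R = r.sum(axis=1)
        absorbed = (~done) & (R <= 0.0)
        done |= absorbed
        u, u_prime = noise.next_pair()
        with np.errstate(divide="ignore", invalid="ignore"):
            dt = np.where(R > 0.0, -np.log(u) / R, np.inf)
        crossing = (~done) & (t + dt >= config.t_end)
        active = (~done) & ~crossing
        if record_dwell:
            # credit the sojourn in the current state, truncated at t_end
            credit = np.where(active, dt, np.where(crossing, config.t_end - t, 0.0))
            dwell += credit[:, None] * x
            dwell_t += credit
        done |= crossing
        if active.any():
            cum = np.cumsum(r[active], axis=1) / R[active, None]
            cum[:, -1] = 1.0
            i = (cum > u_prime[active, None]).argmax(axis=1)
            x[active] += system.S[i]
            fired[np.flatnonzero(active), i] += 1
            t[active] += dt[active]
    else:
        flagged = ~done
    # frozen trajectories are observed at t_end; flagged ones report where they stopped
    t = np.where(flagged, t, config.t_end)
    result = ExactEnsemble(
        final_states=x.astype(int),
        final_times=t,
        fired_counts=fired,
        flagged=flagged,
    )
    if record_dwell:
        with np.errstate(invalid="ignore"):
            result.dwell_fractions = dwell / dwell_t[:, None]
    return result


def cme_steady_state(system, truncation, params=None, boundary_tol=1e-6):
    """Steady state of the truncated chemical master equation.

    ``truncation`` maps species names to inclusive count caps (indicator
    species get cap 1). Transitions leaving the truncated box are blocked
    (reflecting truncation), so the generator conserves probability and the
    global-balance system πQ = 0, Σπ = 1 has a proper solution. If the
    probability mass on the truncation boundary exceeds ``boundary_tol``, a
    :class:`TruncationError` carrying that mass is raised.
    """
    caps = np.array([int(truncation[s]) for s in system.species])
    if np.any(caps < 0):
        raise ValueError("truncation caps must be nonnegative")
    dims = caps + 1
    n_states = int(np.prod(dims))
    if n_states > 2 * 10**5:
        raise ValueError(f"truncated state space too large ({n_states} states)")
    # state index = ravel_multi_index over per-species counts
    grids = np.indices(dims).reshape(len(dims), -1).T  # (K, M)
    x = grids.astype(float)
    rows, cols, vals = [], [], []
    diag = np.zeros(n_states)
    r_all = np.asarray(ad.value(system.rates(x, params=params)))
    if np.any(r_all < 0):
        raise NegativePropensityError("negative propensity on truncated grid")
    for i in range(system.n_reactions):
        target = grids + system.S[i]
        ok = np.all((target >= 0) & (target <= caps), axis=1)
        ok &= r_all[:, i] > 0
        src = np.flatnonzero(ok)
        dst = np.ravel_multi_index(target[ok].T, dims)
        rows.append(dst)
        cols.append(src)
        vals.append(r_all[ok, i])
        np.add.at(diag, src, -r_all[ok, i])
    A = sp.csc_matrix(
        (
            np.concatenate(vals + [diag]),
            (np.concatenate(rows + [np.arange(n_states)]),
             np.concatenate(cols + [np.arange(n_states)])),
        ),
        shape=(n_states, n_states),
    )
    # Replace one balance equation with normalization Σπ = 1.
    A = A.tolil()
    A[-1, :] = 1.0
    b = np.zeros(n_states)
    b[-1] = 1.0
    pi = spla.spsolve(A.tocsc(), b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    # boundary mass is assessed only along genuinely truncated (cap > 1) species
    big = caps > 1
    if big.any():
        boundary = (grids[:, big] == caps[big]).any(axis=1)
        boundary_mass = float(pi[boundary].sum())
    else:
        boundary_mass = 0.0
    if boundary_mass > boundary_tol:
        raise TruncationError(boundary_mass)
    return CMEDistribution(system, grids, pi, boundary_mass)


@dataclass
class CMEDistribution:
    """Joint steady-state distribution on the truncated lattice."""

    system: ReactionSystem
    states: np.ndarray  # (K, M) integer states
    probs: np.ndarray  # (K,)
    boundary_mass: float

    def marginal(self, species_name) -> Pmf:
        j = self.system.idx(species_name)
        vals = self.states[:, j]
        support = np.arange(vals.max() + 1)
        probs = np.bincount(vals, weights=self.probs, minlength=support.size)
        keep = probs > 1e-300
        keep[0] = True
        return Pmf(support[keep], probs[keep] / probs.sum())

    def mean(self, species_name) -> float:
        j = self.system.idx(species_name)
        return float(np.dot(self.states[:, j], self.probs))

    def var(self, species_name) -> float:
        j = self.system.idx(species_name)
        mu = self.mean(species_name)
        return float(np.dot((self.states[:, j] - mu) ** 2, self.probs))

    def fano(self, species_name) -> float:
        return self.var(species_name) / self.mean(species_name)
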