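"""Benchmark promoter architectures and their analytic/stationary oracles.

Two stochastic gene-expression models:

* **Two-state (telegraph) repressed promoter** — a promoter toggling between a
  transcribing state (indicator d = 1) and a repressor-bound silent state
  (d = 0). A repressor binds at rate kon_R·d and unbinds at koff_R·(1−d)
  (time is measured in units of the unbinding rate, koff_R = 1 by
  convention); mRNA is transcribed at r·d and degraded at γ·m. Mean and Fano
  factor of the stationary mRNA count have the classic closed forms

      ⟨m⟩ = (r/γ) · koff/(kon+koff),
      F    = 1 + r·kon / ((kon+koff)(kon+koff+γ)).

* **Four-state nonequilibrium activated promoter** — a locus that is ON
  (transcribing at rate r) or OFF, with an activator at concentration c bound
  or unbound. Binding occurs at c·kb (OFF) and c·η_ba·kb (ON); unbinding at
  ku (OFF) and η_ua·ku (ON); OFF→ON activation at k_act (unbound) and
  η_ab·k_act (bound); ON→OFF deactivation at k_deact (unbound) and
  η_ib·k_deact (bound). The multiplicative η factors break detailed balance:
  the cycle drive is Δμ = ln(η_ab·η_ua/(η_ib·η_ba)), the stationary cycle
  flux J = π₀·kb·c − π₁·ku, and the dissipated power Φ = J·Δμ ≥ 0.

State labels for the four-state chain: 0 = OFF·unbound, 1 = OFF·bound,
2 = ON·bound, 3 = ON·unbound (the ON states are 2 and 3).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .reaction_core import Propensity, ReactionSystem, SimConfig, cme_steady_state, simulate_exact

__all__ = [
    "TwoStateParams",
    "FourStateParams",
    "Response",
    "build_two_state",
    "two_state_mean_fano",
    "two_state_cme",
    "build_four_state",
    "build_four_state_with_mrna",
    "four_state_stationary",
    "four_state_occupancy_ssa",
    "response_from_stationary",
    "sharpness",
    "dissipation",
]


def _check_positive(**kwargs):
    for name, v in kwargs.items():
        if not (v > 0):
            raise ValueError(f"parameter {name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class TwoStateParams:
    """Telegraph-model rates (per unit time; koff_r = 1 sets the time unit)."""

    kon_r: float = 0.5
    koff_r: float = 1.0
    r: float = 10.0
    gamma: float = 1.0

    def __post_init__(self):
        _check_positive(**asdict(self))

    def as_dict(self):
        return {"kon": self.kon_r, "koff": self.koff_r, "r": self.r, "gamma": self.gamma}


def build_two_state(p: TwoStateParams) -> ReactionSystem:
    """Reaction system for the telegraph promoter.

    Species: promoter-ON indicator ``d`` ∈ {0,1} and mRNA count ``m``.
    Reaction order is (bind, unbind, transcribe, degrade): the rare promoter
    flips sit at the bottom of the cumulative selection ladder, which
    minimizes the smoothed simulator's event-thinning bias.
    """
    species = ["d", "m"]
    S = np.array(
        [
            [-1, 0],  # repressor binds: ON -> OFF
            [1, 0],  # repressor unbinds: OFF -> ON
            [0, 1],  # transcription (requires ON)
            [0, -1],  # mRNA degradation
        ]
    )
    props = [
        Propensity(params="kon", orders={"d": 1}),
        Propensity(params="koff", complements=("d",)),
        Propensity(params="r", orders={"d": 1}),
        Propensity(params="gamma", orders={"m": 1}),
    ]
    return ReactionSystem(species, S, props, p.as_dict(), bounds={"d": (0, 1)})


TWO_STATE_X0 = np.array([1, 0])  # start transcribing with no mRNA


def two_state_mean_fano(p: TwoStateParams):
    """Closed-form stationary mean and Fano factor of the mRNA count."""
    kon, koff, r, g = p.kon_r, p.koff_r, p.r, p.gamma
    p_on = koff / (kon + koff)
    mean = r / g * p_on
    fano = 1.0 + r * kon / ((kon + koff) * (kon + koff + g))
    return mean, fano


def two_state_cme(p: TwoStateParams, n_sigma: float = 10.0, min_cap: int = 50):
    """Truncated-CME steady state with the default moment-based mRNA cap.

    The cutoff is ⟨m⟩ + n_sigma·σ_m from the closed-form moments, at least
    ``min_cap``.
    """
    mean, fano = two_state_mean_fano(p)
    sd = np.sqrt(fano * mean)
    cap = max(min_cap, int(np.ceil(mean + n_sigma * sd)))
    system = build_two_state(p)
    return cme_steady_state(system, {"d": 1, "m": cap})


# ---------------------------------------------------------------------------
# four-state nonequilibrium promoter


@dataclass(frozen=True)
class FourStateParams:
    """Four-state promoter rates; kb is per concentration per time (default 0.02)."""

    kb: float = 0.02
    ku: float = 1.0
    k_act: float = 1.0
    k_deact: float = 1.0
    eta_ab: float = 1.0
    eta_ib: float = 1.0
    eta_ba: float = 1.0
    eta_ua: float = 1.0
    r: float = 1.0

    def __post_init__(self):
        _check_positive(**asdict(self))

    @property
    def drive(self) -> float:
        """Nonequilibrium drive Δμ = ln(η_ab·η_ua/(η_ib·η_ba))."""
        return float(np.log(self.eta_ab * self.eta_ua / (self.eta_ib * self.eta_ba)))

    def as_dict(self):
        return {k: float(v) for k, v in asdict(self).items()}


FOUR_STATE_SPECIES = ["s0", "s1", "s2", "s3"]

# (from, to, params, uses concentration) — the eight promoter transitions
_FOUR_STATE_EDGES = [
    (0, 1, ("kb",), True),  # activator binds (OFF)
    (1, 0, ("ku",), False),  # activator unbinds (OFF)
    (1, 2, ("eta_ab", "k_act"), False),  # activation while bound
    (2, 1, ("eta_ib", "k_deact"), False),  # deactivation while bound
    (2, 3, ("eta_ua", "ku"), False),  # activator unbinds (ON)
    (3, 2, ("eta_ba", "kb"), True),  # activator binds (ON)
    (3, 0, ("k_deact",), False),  # deactivation while unbound
    (0, 3, ("k_act",), False),  # activation while unbound
]


def build_four_state(p: FourStateParams, c: float) -> ReactionSystem:
    """Promoter-state-only reaction system at activator concentration ``c``.

    The four states are one-hot species s0..s3; each of the eight transitions
    moves one unit of occupancy. mRNA is deliberately absent: the design loss
    uses only promoter-state occupancies (the mean transcription rate is
    r·(π₂+π₃)); see :func:`build_four_state_with_mrna` for the full variant.
    """
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    S = np.zeros((len(_FOUR_STATE_EDGES), 4), dtype=int)
    props = []
    for i, (src, dst, names, conc) in enumerate(_FOUR_STATE_EDGES):
        S[i, src] = -1
        S[i, dst] = 1
        props.append(
            Propensity(params=names, coeff=c if conc else 1.0, orders={f"s{src}": 1})
        )
    bounds = {s: (0, 1) for s in FOUR_STATE_SPECIES}
    return ReactionSystem(FOUR_STATE_SPECIES, S, props, p.as_dict(), bounds=bounds)


FOUR_STATE_X0 = np.array([1, 0, 0, 0])


def build_four_state_with_mrna(p: FourStateParams, c: float) -> ReactionSystem:
    """Five-species variant including mRNA birth (rate r in ON states) and decay.

    Provided for completeness; the design loop and its tests use the
    promoter-only system. mRNA decay rate is fixed at 1 (time unit).
    """
    base = build_four_state(p, c)
    species = FOUR_STATE_SPECIES + ["m"]
    n_rx = base.S.shape[0]
    S = np.zeros((n_rx + 3, 5), dtype=int)
    S[:n_rx, :4] = base.S
    S[n_rx, 4] = 1  # transcription from s2
    S[n_rx + 1, 4] = 1  # transcription from s3
    S[n_rx + 2, 4] = -1  # degradation
    props = list(base.propensities) + [
        Propensity(params="r", orders={"s2": 1}),
        Propensity(params="r", orders={"s3": 1}),
        Propensity(params="gamma_m", orders={"m": 1}),
    ]
    params = dict(p.as_dict(), gamma_m=1.0)
    bounds = {s: (0, 1) for s in FOUR_STATE_SPECIES}
    return ReactionSystem(species, S, props, params, bounds=bounds)


def _generator(p: FourStateParams, c: float, params=None) -> np.ndarray:
    """4×4 CTMC generator Q (rows = from-state, Q[i,j] = rate i→j)."""
    theta = p.as_dict()
    if params:
        theta.update(params)
    Q = np.zeros((4, 4))
    for src, dst, names, conc in _FOUR_STATE_EDGES:
        rate = c if conc else 1.0
        for name in names:
            rate = rate * theta[name]
        Q[src, dst] += rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def four_state_stationary(p: FourStateParams, c: float, params=None):
    """Exact stationary occupancies (π₀..π₃) and mean transcription rate r(π₂+π₃).

    Solves πQ = 0, Σπ = 1 by linear solve on the generator.
    """
    Q = _generator(p, c, params=params)
    A = np.vstack([Q.T[:3], np.ones(4)])
    try:
        pi = np.linalg.solve(A, np.array([0.0, 0.0, 0.0, 1.0]))
    except np.linalg.LinAlgError as e:
        raise ValueError(f"degenerate four-state generator at c={c}") from e
    if np.any(pi < -1e-9):
        raise ValueError("stationary solve produced negative occupancy")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    theta = p.as_dict()
    if params:
        theta.update(params)
    mean_rate = theta["r"] * (pi[2] + pi[3])
    return pi, float(mean_rate)


def four_state_occupancy_ssa(p: FourStateParams, c: float, config: SimConfig, burn_in=0.0):
    """Hard dwell-time state occupancies from the exact simulator.

    Returns (w, pi): per-trajectory dwell fractions (n×4) and their average.
    """
    system = build_four_state(p, c)
    ens = simulate_exact(system, FOUR_STATE_X0, config, record_dwell=True)
    w = ens.dwell_fractions
    return w, w.mean(axis=0)


@dataclass(frozen=True)
class Response:
    """A dose–response curve: activator concentrations and mean transcription rates."""

    conc: np.ndarray
    rate: np.ndarray

    def __post_init__(self):
        conc = np.asarray(self.conc, dtype=float)
        rate = np.asarray(self.rate, dtype=float)
        if conc.ndim != 1 or rate.shape != conc.shape:
            raise ValueError("conc and rate must be matching 1-D arrays")
        if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "rate", rate)


def response_from_stationary(p: FourStateParams, conc_grid) -> Response:
    """Exact stationary dose–response over a concentration grid."""
    rates = [four_state_stationary(p, c)[1] for c in np.asarray(conc_grid, dtype=float)]
    return Response(np.asarray(conc_grid, dtype=float), np.array(rates))


def sharpness(resp: Response) -> float:
    """max over the grid of c·d⟨r̄⟩/dc = d⟨r̄⟩/d ln c (centered finite differences)."""
    if resp.conc.size < 3:
        raise ValueError("sharpness needs at least 3 grid points")
    slope = np.gradient(resp.rate, np.log(resp.conc))
    return float(slope.max())


def dissipation(p: FourStateParams, c: float, params=None):
    """Stationary cycle flux J, drive Δμ, and dissipated power Φ = J·Δμ.

    J = π₀·kb·c − π₁·ku is the net flux on the OFF-binding edge (equal around
    the cycle at stationarity); Φ ≥ 0 always, with equality at detailed
    balance (Δμ = 0).
    """
    theta = p.as_dict()
    if params:
        theta.update(params)
    pi, _ = four_state_stationary(p, c, params=params)
    dmu = float(
        np.log(theta["eta_ab"] * theta["eta_ua"] / (theta["eta_ib"] * theta["eta_ba"]))
    )
    J = float(pi[0] * theta["kb"] * c - pi[1] * theta["ku"])
    return J, dmu, J * dmu
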