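"""Three-state kinetics of reversible anaerobic (in)activation.

This module implements the linear kinetic scheme

    A1  <-- k_-1 / k_1 -->  A2  <-- k_react / k_inact -->  H_inact

used to model the reversible conversion between two catalytically active
conformers (A1, A2) and the inactive, oxygen-protected H_inact state of a
cysteine-capped [FeFe]-hydrogenase adsorbed on an electrode.  All four
rate constants are first order (s^-1); the catalytic current is
proportional to a weighted sum of the active-state populations, with A2
roughly half as active as A1.

Everything here is pure computation on in-memory objects: exact
propagation of the master equation under piecewise-constant conditions,
steady states, relaxation rates, and the current model for potential-step
and potential-sweep (cyclic voltammetry) experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "RateConstants",
    "TwoStateRateConstants",
    "StateFractions",
    "ActivityWeights",
    "PotentialStep",
    "Protocol",
    "KReactLaw",
    "Trace",
    "build_generator",
    "propagate",
    "propagate_many",
    "steady_state",
    "relaxation_rates",
    "propagate_two_state",
    "simulate_current",
    "simulate_cv",
]

# relative eigenvalue gap below which eigendecomposition is considered
# degenerate and propagation falls back to scaling-and-squaring expm
_EIG_DEGENERACY_RTOL = 1e-9


def _check_rate(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"rate constant {name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class RateConstants:
    """First-order rate constants of the three-state scheme, in s^-1.

    ``k1``/``k_neg1`` interconvert the active conformers A1 and A2;
    ``k_inact``/``k_react`` interconvert A2 and the inactive state.
    Degenerate chains (zero rates) are allowed.
    """

    k1: float
    k_neg1: float
    k_inact: float
    k_react: float

    def __post_init__(self) -> None:
        for name in ("k1", "k_neg1", "k_inact", "k_react"):
            object.__setattr__(self, name, _check_rate(name, getattr(self, name)))

    def scaled(self, c: float) -> "RateConstants":
        return RateConstants(self.k1 * c, self.k_neg1 * c, self.k_inact * c, self.k_react * c)

    def with_k_react(self, k_react: float) -> "RateConstants":
        return replace(self, k_react=k_react)

    def as_dict(self) -> dict[str, float]:
        return {
            "k1": self.k1,
            "k_neg1": self.k_neg1,
            "k_inact": self.k_inact,
            "k_react": self.k_react,
        }


@dataclass(frozen=True)
class TwoStateRateConstants:
    """Rate constants of the rejected two-species (bound/unbound) model."""

    k_inact: float
    k_react: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_inact", _check_rate("k_inact", self.k_inact))
        object.__setattr__(self, "k_react", _check_rate("k_react", self.k_react))


@dataclass(frozen=True)
class StateFractions:
    """Populations of (A1, A2, H_inact); non-negative, summing to one."""

    a1: float
    a2: float
    h_inact: float

    def __post_init__(self) -> None:
        vec = np.array([self.a1, self.a2, self.h_inact], dtype=float)
        if not np.all(np.isfinite(vec)):
            raise ValueError("state fractions must be finite")
        if np.any(vec < -1e-9) or np.any(vec > 1 + 1e-9):
            raise ValueError(f"state fractions must lie in [0, 1], got {vec}")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(f"state fractions must sum to 1, got sum {vec.sum()!r}")

    @classmethod
    def from_array(cls, vec: np.ndarray) -> "StateFractions":
        vec = np.clip(np.asarray(vec, dtype=float), 0.0, 1.0)
        vec = vec / vec.sum()
        return cls(float(vec[0]), float(vec[1]), float(vec[2]))

    def to_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.h_inact], dtype=float)


PURE_A1 = StateFractions(1.0, 0.0, 0.0)


@dataclass(frozen=True)
class ActivityWeights:
    """Relative catalytic activity of each state.

    A1 defines the activity scale (weight 1); H_inact is inactive
    (weight 0).  ``alpha2`` is the activity of A2 relative to A1,
    about one half by experimental estimate.
    """

    alpha2: float = 0.5
    alpha1: float = field(default=1.0, init=False)
    alpha_inact: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha2 <= 1.0):
            raise ValueError(f"alpha2 must be in [0, 1], got {self.alpha2!r}")

    def weight_vector(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha_inact])


@dataclass(frozen=True)
class PotentialStep:
    """One constant-potential hold: potential in V vs SHE, duration in s."""

    potential: float
    duration: float

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError(f"step duration must be > 0, got {self.duration!r}")


@dataclass(frozen=True)
class Protocol:
    """Ordered potential-step program with solution conditions."""

    steps: tuple[PotentialStep, ...]
    pH: float = 7.0
    temperature: float = 278.15
    rotation_rate: float = 3000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        if len(self.steps) == 0:
            raise ValueError("protocol must contain at least one step")
        if not (0.0 <= self.pH <= 14.0):
            raise ValueError(f"pH must be in [0, 14], got {self.pH!r}")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.steps))

    @property
    def step_starts(self) -> np.ndarray:
        durations = np.array([s.duration for s in self.steps])
        return np.concatenate([[0.0], np.cumsum(durations)[:-1]])

    @property
    def potentials(self) -> np.ndarray:
        return np.array([s.potential for s in self.steps])

    def distinct_potentials(self) -> list[float]:
        seen: list[float] = []
        for s in self.steps:
            if s.potential not in seen:
                seen.append(s.potential)
        return seen

    def potential_at(self, t: np.ndarray) -> np.ndarray:
        """Potential of the step active at each time (boundaries belong to the new step)."""
        edges = np.concatenate([self.step_starts, [self.total_duration]])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.steps) - 1)
        return self.potentials[idx]


@dataclass(frozen=True)
class KReactLaw:
    """Potential dependence of the reactivation rate constant.

    ``per_step_table`` mode looks the rate up per distinct protocol
    potential; ``exponential`` mode uses a Tafel-like law

        k_react(E) = k0 * exp(-slope * (E - E_ref)),

    the minimal form for a reactivation triggered by a reduction step
    (rate increases as the electrode potential is lowered).
    """

    mode: str = "per_step_table"
    table: Mapping[float, float] | None = None
    k0: float = 0.17
    E_ref: float = -0.196
    slope: float = 23.0259  # one decade per 100 mV

    def __post_init__(self) -> None:
        if self.mode not in ("per_step_table", "exponential"):
            raise ValueError(f"unknown KReactLaw mode {self.mode!r}")
        if self.mode == "per_step_table" and not self.table:
            raise ValueError("per_step_table mode requires a non-empty table")
        if self.mode == "exponential" and not (self.k0 > 0):
            raise ValueError("exponential mode requires k0 > 0")

    def k_react(self, potential: float) -> float:
        if self.mode == "per_step_table":
            assert self.table is not None
            try:
                return float(self.table[potential])
            except KeyError:
                raise KeyError(
                    f"k_react table has no entry for potential {potential} V; "
                    f"known potentials: {sorted(self.table)}"
                ) from None
        return float(self.k0 * math.exp(-self.slope * (potential - self.E_ref)))

    def rates_at(self, base: RateConstants, potential: float) -> RateConstants:
        return base.with_k_react(self.k_react(potential))


@dataclass
class Trace:
    """Sampled (time, potential, current) series with experiment metadata."""

    time: np.ndarray
    potential: np.ndarray
    current: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if not (self.time.shape == self.potential.shape == self.current.shape):
            raise ValueError("time, potential and current must have equal length")
        if self.time.ndim != 1:
            raise ValueError("trace columns must be one-dimensional")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("trace time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def copy(self) -> "Trace":
        return Trace(self.time.copy(), self.potential.copy(), self.current.copy(), dict(self.metadata))


# ---------------------------------------------------------------------------
# master-equation machinery


def build_generator(rc: RateConstants) -> np.ndarray:
    """Rate-generator matrix of the linear chain over (A1, A2, H_inact).

    Columns index the source state and sum to zero; there is no direct
    A1 <-> H_inact edge.
    """
    return np.array(
        [
            [-rc.k1, rc.k_neg1, 0.0],
            [rc.k1, -(rc.k_neg1 + rc.k_inact), rc.k_react],
            [0.0, rc.k_inact, -rc.k_react],
        ]
    )


def build_two_state_generator(rc2: TwoStateRateConstants) -> np.ndarray:
    return np.array([[-rc2.k_inact, rc2.k_react], [rc2.k_inact, -rc2.k_react]])


def _propagator_factors(generator: np.ndarray):
    """Eigen-factorisation (V, lam, Vinv) of the generator, or None if degenerate.

    Degenerate means two eigenvalues closer than _EIG_DEGENERACY_RTOL in
    relative terms, in which case the caller should use ``expm`` instead.
    """
    lam, V = np.linalg.eig(generator)
    scale = np.max(np.abs(lam)) or 1.0
    lam_sorted = np.sort_complex(lam)
    if np.min(np.abs(np.diff(lam_sorted))) < _EIG_DEGENERACY_RTOL * scale:
        return None
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return None
    return V, lam, Vinv


class Propagator:
    """Reusable exact propagator for one rate-constant set.

    Factors the generator once so repeated propagation (e.g. across the
    many steps of a protocol sharing a potential) costs only the
    per-time exponentials.
    """

    def __init__(self, rc: RateConstants):
        self.generator = build_generator(rc)
        self._factors = _propagator_factors(self.generator)

    def propagate(self, p0: np.ndarray, dts: np.ndarray) -> np.ndarray:
        dts = np.asarray(dts, dtype=float)
        p0 = np.asarray(p0, dtype=float)
        if self._factors is not None:
            V, lam, Vinv = self._factors
            coef = Vinv @ p0.astype(complex)
            out = np.real(V @ (np.exp(np.outer(lam, dts)) * coef[:, None])).T
        else:
            out = np.empty((len(dts), len(p0)))
            for i, dt in enumerate(dts):
                out[i] = expm(self.generator * dt) @ p0
        out = np.clip(out, 0.0, None)
        out /= out.sum(axis=1, keepdims=True)
        return out


def propagate_many(p0: np.ndarray, rc: RateConstants, dts: np.ndarray) -> np.ndarray:
    """Exact state populations at multiple elapsed times from one origin.

    Returns an array of shape (len(dts), 3).  Uses eigendecomposition of
    the generator; falls back to matrix exponentials when eigenvalues are
    (numerically) repeated.
    """
    dts = np.asarray(dts, dtype=float)
    if np.any(dts < 0):
        raise ValueError("elapsed times must be >= 0")
    return Propagator(rc).propagate(p0, dts)


def propagate(state: StateFractions, rc: RateConstants, dt: float) -> StateFractions:
    """Propagate the master equation exactly over a time dt >= 0."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt!r}")
    if dt == 0:
        return state
    out = propagate_many(state.to_array(), rc, np.array([dt]))[0]
    return StateFractions.from_array(out)


def steady_state(rc: RateConstants) -> StateFractions:
    """Stationary populations of the chain.

    For a fully reversible chain these are proportional to
    (1, k1/k_-1, k1*k_inact/(k_-1*k_react)); rendered here with the
    common denominator cleared so absorbing limits (zero backward rates)
    come out naturally.  All-zero rates have no unique steady state.
    """
    w = np.array(
        [
            rc.k_neg1 * rc.k_react,
            rc.k1 * rc.k_react,
            rc.k1 * rc.k_inact,
        ]
    )
    if w.sum() > 0:
        return StateFractions.from_array(w / w.sum())
    if rc.k1 == rc.k_neg1 == rc.k_inact == rc.k_react == 0:
        raise ValueError("all rates are zero: no unique steady state")
    # degenerate but non-trivial chain (e.g. k1 = k_react = 0): take the
    # null space of the generator directly
    G = build_generator(rc)
    _, _, vh = np.linalg.svd(G)
    null = np.abs(vh[-1])
    return StateFractions.from_array(null / null.sum())


def relaxation_rates(rc: RateConstants) -> tuple[float, float]:
    """Magnitudes of the two non-zero generator eigenvalues, ascending.

    These are the observable relaxation rates of the bi-exponential
    current transients after a potential step.
    """
    lam = np.linalg.eigvals(build_generator(rc))
    lam = np.sort(np.abs(lam))
    # smallest magnitude is the conserved (zero) mode
    return float(lam[1]), float(lam[2])


def propagate_two_state(active_fraction: float, rc2: TwoStateRateConstants, dt: float) -> float:
    """Analytic mono-exponential relaxation of the two-species model."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt!r}")
    k_tot = rc2.k_inact + rc2.k_react
    if k_tot == 0:
        return float(active_fraction)
    a_inf = rc2.k_react / k_tot
    return float(a_inf + (active_fraction - a_inf) * math.exp(-k_tot * dt))


# ---------------------------------------------------------------------------
# current models


def weighted_activity(states: np.ndarray, weights: ActivityWeights) -> np.ndarray:
    """Catalytically weighted population: alpha1*a1 + alpha2*a2 (H_inact inert)."""
    return states[..., 0] * weights.alpha1 + states[..., 1] * weights.alpha2


def simulate_current(
    protocol: Protocol,
    rates_per_step: Sequence[RateConstants],
    weights: ActivityWeights = ActivityWeights(),
    amplitudes: Mapping[float, float] | None = None,
    t_grid: np.ndarray | None = None,
    initial_state: StateFractions = PURE_A1,
    film_loss_tau: float | None = None,
) -> Trace:
    """Catalytic current of a film under a potential-step program.

    The state vector evolves continuously through step boundaries; the
    current jumps at each boundary because the per-potential amplitude
    (the turnover frequency at that potential) changes instantly:

        i(t) = amplitude(E_step) * (a1(t) + alpha2*a2(t)) [* exp(-t/film_loss_tau)]

    Boundary samples belong to the step that begins there.
    """
    if len(rates_per_step) != len(protocol.steps):
        raise ValueError(
            f"need one RateConstants per step: got {len(rates_per_step)} "
            f"for {len(protocol.steps)} steps"
        )
    if amplitudes is None:
        amplitudes = {E: 1.0 for E in protocol.distinct_potentials()}
    for E in protocol.distinct_potentials():
        if E not in amplitudes:
            raise KeyError(f"no amplitude defined for step potential {E} V")
    if t_grid is None:
        t_grid = np.arange(0.0, protocol.total_duration + 1e-12, 0.1)
    t_grid = np.asarray(t_grid, dtype=float)

    starts = protocol.step_starts
    edges = np.concatenate([starts, [protocol.total_duration]])
    states = np.empty((len(t_grid), 3))
    potential = np.empty(len(t_grid))
    amp = np.empty(len(t_grid))

    p = initial_state.to_array()
    for i, step in enumerate(protocol.steps):
        lo, hi = edges[i], edges[i + 1]
        if i == len(protocol.steps) - 1:
            mask = (t_grid >= lo) & (t_grid <= hi + 1e-12)
        else:
            mask = (t_grid >= lo) & (t_grid < hi)
        if mask.any():
            states[mask] = propagate_many(p, rates_per_step[i], t_grid[mask] - lo)
        potential[mask] = step.potential
        amp[mask] = amplitudes[step.potential]
        p = propagate_many(p, rates_per_step[i], np.array([step.duration]))[0]

    current = amp * weighted_activity(states, weights)
    if film_loss_tau is not None:
        current = current * np.exp(-t_grid / film_loss_tau)
    meta = {
        "pH": protocol.pH,
        "temperature_K": protocol.temperature,
        "rotation_rpm": protocol.rotation_rate,
        "units": "normalized",
    }
    return Trace(t_grid, potential, current, meta)


def simulate_cv(
    sweep: Mapping[str, float],
    law: KReactLaw,
    base_rates: RateConstants,
    weights: ActivityWeights = ActivityWeights(),
    waveshape: Mapping[str, float] | None = None,
    initial_state: StateFractions | None = None,
    dt: float = 0.1,
    pH: float = 7.0,
    temperature: float = 278.15,
) -> Trace:
    """Cyclic voltammogram of the inactivating film (qualitative model).

    The potential ramps linearly from ``E_start`` to ``E_vertex`` and
    back at ``scan_rate`` (V/s).  The three-state populations are
    integrated along E(t) with k_react evaluated from ``law`` (k1, k_-1
    and k_inact fixed), on a piecewise-constant grid of width ``dt``.
    The current is a sigmoidal reversible-catalysis waveshape scaled by
    the weighted active population:

        i(E, t) = i_lim * tanh(steepness * (E - E_eq)) * activity(t)

    Hysteresis between the branches appears whenever (in)activation is
    not fast compared to the sweep.
    """
    E_start = float(sweep["E_start"])
    E_vertex = float(sweep["E_vertex"])
    scan_rate = float(sweep["scan_rate"])
    if not (scan_rate > 0):
        raise ValueError(f"scan_rate must be > 0, got {scan_rate!r}")
    if waveshape is None:
        waveshape = {"E_eq": -0.426, "steepness": 20.0, "i_lim": 1.0}

    half = abs(E_vertex - E_start) / scan_rate
    t = np.arange(0.0, 2 * half + dt / 2, dt)
    sgn = 1.0 if E_vertex >= E_start else -1.0
    E = np.where(
        t <= half,
        E_start + sgn * scan_rate * t,
        E_vertex - sgn * scan_rate * (t - half),
    )

    if initial_state is None:
        initial_state = steady_state(law.rates_at(base_rates, E_start))
    p = initial_state.to_array()
    states = np.empty((len(t), 3))
    states[0] = p
    for i in range(1, len(t)):
        # midpoint potential of the sub-interval, piecewise-constant rates
        rc = law.rates_at(base_rates, 0.5 * (E[i - 1] + E[i]))
        p = propagate_many(p, rc, np.array([t[i] - t[i - 1]]))[0]
        states[i] = p

    shape = waveshape["i_lim"] * np.tanh(waveshape["steepness"] * (E - waveshape["E_eq"]))
    current = shape * weighted_activity(states, weights)
    meta = {
        "pH": pH,
        "temperature_K": temperature,
        "scan_rate_V_s": scan_rate,
        "units": "normalized",
    }
    return Trace(t, E, current, meta)
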