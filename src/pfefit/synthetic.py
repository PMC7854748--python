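"""Synthetic protein-film-electrochemistry experiments with known truth.

Generators for the data the inference stage consumes: potential-step
chronoamperograms (with capacitive step transients, additive noise and
optional film loss), enzyme-free blanks, the five-phase O2-exposure
protocol with irreversible damage to the unprotected active states, and
cyclic voltammograms.  Every generator is deterministic under a fixed
seed and returns a truth record holding every parameter used, so that
parameter-recovery and protection-logic claims can be tested end to end
without any measured data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import (
    ActivityWeights,
    KReactLaw,
    PotentialStep,
    Protocol,
    RateConstants,
    StateFractions,
    PURE_A1,
    Trace,
    simulate_current,
    simulate_cv,
)

__all__ = [
    "NoiseSpec",
    "CapacitiveSpec",
    "O2ExperimentSpec",
    "make_step_protocol",
    "generate_chronoamperogram",
    "generate_blank",
    "generate_o2_experiment",
    "generate_cv",
    "rates_for_protocol",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise, sd = relative_sd x max |noise-free current|."""

    relative_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")

    def apply(self, current: np.ndarray) -> np.ndarray:
        if self.relative_sd == 0:
            return current.copy()
        scale = float(np.max(np.abs(current)))
        if scale == 0.0:
            scale = 1.0
        rng = np.random.default_rng(self.seed)
        return current + rng.normal(0.0, self.relative_sd * scale, size=current.shape)


@dataclass(frozen=True)
class CapacitiveSpec:
    """Exponential electrode-charging transient after each potential change."""

    peak_amplitude: float = 0.5
    tau: float = 0.5

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError("capacitive tau must be > 0")


def make_step_protocol(
    low_E: float = -0.31,
    high_E: float = -0.21,
    n_cycles: int = 3,
    durations: float | Sequence[float] = 50.0,
    pH: float = 7.0,
    T: float = 278.15,
    rotation_rate: float = 3000.0,
) -> Protocol:
    """Alternating potential-step program starting and ending at ``low_E``.

    ``n_cycles`` oxidative excursions give 2*n_cycles + 1 steps
    (low, high, low, ..., low).  ``durations`` is one hold length for all
    steps or a per-step sequence.
    """
    n_steps = 2 * n_cycles + 1
    if np.isscalar(durations):
        durations = [float(durations)] * n_steps
    durations = list(durations)
    if len(durations) != n_steps:
        raise ValueError(f"need {n_steps} durations, got {len(durations)}")
    potentials = [low_E if i % 2 == 0 else high_E for i in range(n_steps)]
    steps = tuple(PotentialStep(E, d) for E, d in zip(potentials, durations))
    return Protocol(steps, pH=pH, temperature=T, rotation_rate=rotation_rate)


def rates_for_protocol(
    protocol: Protocol,
    truth: Mapping[float, RateConstants] | tuple[RateConstants, KReactLaw],
) -> list[RateConstants]:
    """Resolve per-step rate constants from a per-potential table or a k_react law."""
    if isinstance(truth, tuple):
        base, law = truth
        return [law.rates_at(base, s.potential) for s in protocol.steps]
    out = []
    for s in protocol.steps:
        if s.potential not in truth:
            raise KeyError(f"no rate constants supplied for potential {s.potential} V")
        out.append(truth[s.potential])
    return out


def _capacitive_component(
    t: np.ndarray, step_starts: np.ndarray, potentials: np.ndarray, cap: CapacitiveSpec
) -> np.ndarray:
    """Charging spikes at every potential change, signed by the step direction."""
    out = np.zeros_like(t)
    for i in range(1, len(step_starts)):
        dE = potentials[i] - potentials[i - 1]
        if dE == 0:
            continue
        t0 = step_starts[i]
        mask = t >= t0
        out[mask] += math.copysign(cap.peak_amplitude, dE) * np.exp(-(t[mask] - t0) / cap.tau)
    return out


def generate_chronoamperogram(
    protocol: Protocol,
    truth: Mapping[float, RateConstants] | tuple[RateConstants, KReactLaw],
    weights: ActivityWeights = ActivityWeights(),
    amplitudes: Mapping[float, float] | None = None,
    noise: NoiseSpec = NoiseSpec(),
    capacitive: CapacitiveSpec | None = None,
    film_loss_tau: float | None = None,
    sample_rate: float = 10.0,
    initial_state: StateFractions = PURE_A1,
) -> tuple[Trace, dict]:
    """Potential-step chronoamperogram with known ground truth.

    The noise-free core is the exact three-state current model; a signed
    capacitive transient is optionally added after each potential change,
    then additive Gaussian noise scaled to the maximum absolute current.
    Returns the trace and a truth record holding every parameter.
    """
    rates = rates_for_protocol(protocol, truth)
    if amplitudes is None:
        amplitudes = {E: 1.0 for E in protocol.distinct_potentials()}
    t_grid = np.arange(0.0, protocol.total_duration + 1e-9, 1.0 / sample_rate)
    clean = simulate_current(
        protocol, rates, weights, amplitudes, t_grid, initial_state, film_loss_tau
    )
    current = clean.current.copy()
    if capacitive is not None:
        current = current + _capacitive_component(
            t_grid, protocol.step_starts, protocol.potentials, capacitive
        )
    noisy = noise.apply(current)
    trace = Trace(t_grid, clean.potential, noisy, dict(clean.metadata))
    truth_record = {
        "rates_per_potential": {
            E: rc.as_dict()
            for E, rc in zip([s.potential for s in protocol.steps], rates)
        },
        "alpha2": weights.alpha2,
        "amplitudes": dict(amplitudes),
        "noise_relative_sd": noise.relative_sd,
        "seed": noise.seed,
        "capacitive": None if capacitive is None else (capacitive.peak_amplitude, capacitive.tau),
        "film_loss_tau": film_loss_tau,
        "clean_current": clean.current,
        "sample_rate": sample_rate,
    }
    return trace, truth_record


def generate_blank(
    protocol: Protocol,
    capacitive: CapacitiveSpec = CapacitiveSpec(),
    noise: NoiseSpec = NoiseSpec(),
    sample_rate: float = 10.0,
) -> Trace:
    """Enzyme-free control: capacitive step transients plus noise only."""
    t_grid = np.arange(0.0, protocol.total_duration + 1e-9, 1.0 / sample_rate)
    potential = protocol.potential_at(t_grid)
    core = _capacitive_component(t_grid, protocol.step_starts, protocol.potentials, capacitive)
    meta = {
        "pH": protocol.pH,
        "temperature_K": protocol.temperature,
        "rotation_rpm": protocol.rotation_rate,
        "units": "normalized",
    }
    return Trace(t_grid, potential, noise.apply(core), meta)


@dataclass(frozen=True)
class O2ExperimentSpec:
    """Five-phase O2-exposure chronoamperometry protocol.

    Phases: (1) reductive hold to record the reference H2-production
    current, (2) step to an oxidizing potential, (3) O2 injection at
    ``o2_concentration``, (4) buffer exchange modelled as exponential O2
    washout, (5) step back to the reductive potential to read the
    residual current.  ``damage_rate`` is the second-order rate constant
    of irreversible O2 damage to the unprotected (active) states; the
    capped H_inact state is immune.
    """

    phase_times: tuple[float, float, float, float, float] = (0.0, 200.0, 480.0, 900.0, 1300.0)
    end_time: float = 1600.0
    reductive_E: float = -0.8
    oxidative_E: float = 0.0
    o2_concentration: float = 50e-6  # mol/L
    o2_washout_tau: float = 60.0
    damage_rate: float = 200.0  # L mol^-1 s^-1
    sample_rate: float = 10.0

    def __post_init__(self) -> None:
        times = self.phase_times
        if any(b <= a for a, b in zip(times, times[1:])) or self.end_time <= times[-1]:
            raise ValueError("phase times must be strictly increasing")
        if self.o2_concentration < 0 or self.damage_rate < 0:
            raise ValueError("concentrations and damage rate must be >= 0")
        if not (self.o2_washout_tau > 0):
            raise ValueError("o2_washout_tau must be > 0")

    def o2_profile(self, t: float | np.ndarray) -> float | np.ndarray:
        """Dissolved O2 concentration: step at injection, exponential washout."""
        t3, t4 = self.phase_times[2], self.phase_times[3]
        return np.where(
            np.asarray(t) < t3,
            0.0,
            np.where(
                np.asarray(t) < t4,
                self.o2_concentration,
                self.o2_concentration * np.exp(-(np.asarray(t) - t4) / self.o2_washout_tau),
            ),
        )

    def potential_of_phase(self, phase_index: int) -> float:
        return self.reductive_E if phase_index in (0, 4) else self.oxidative_E


def generate_o2_experiment(
    spec: O2ExperimentSpec,
    truth: Mapping[float, RateConstants],
    weights: ActivityWeights = ActivityWeights(),
    amplitudes: Mapping[float, float] | None = None,
    noise: NoiseSpec = NoiseSpec(),
    initial_state: StateFractions = PURE_A1,
) -> tuple[Trace, dict]:
    """Simulate the O2-exposure protocol on a four-species model.

    The state is (A1, A2, H_inact, Dead).  The three-state exchange runs
    with the rate constants of the phase potential; O2 converts A1 and A2
    to Dead at rate damage_rate*[O2](t) while H_inact is protected; Dead
    never recovers and carries no current.
    """
    for E in (spec.reductive_E, spec.oxidative_E):
        if E not in truth:
            raise KeyError(f"no rate constants supplied for potential {E} V")
    if amplitudes is None:
        amplitudes = {spec.reductive_E: -1.0, spec.oxidative_E: 0.5}

    edges = list(spec.phase_times) + [spec.end_time]
    dt = 1.0 / spec.sample_rate
    t_grid = np.arange(0.0, spec.end_time + 1e-9, dt)

    def rhs_factory(rc: RateConstants):
        def rhs(t, y):
            a1, a2, h, dead = y
            dmg = spec.damage_rate * float(spec.o2_profile(t))
            da1 = -rc.k1 * a1 + rc.k_neg1 * a2 - dmg * a1
            da2 = rc.k1 * a1 - (rc.k_neg1 + rc.k_inact) * a2 + rc.k_react * h - dmg * a2
            dh = rc.k_inact * a2 - rc.k_react * h
            ddead = dmg * (a1 + a2)
            return [da1, da2, dh, ddead]

        return rhs

    y = np.concatenate([initial_state.to_array(), [0.0]])
    states = np.empty((len(t_grid), 4))
    potential = np.empty(len(t_grid))
    pos = 0
    for phase in range(5):
        lo, hi = edges[phase], edges[phase + 1]
        mask = (t_grid >= lo - 1e-12) & (t_grid < hi - 1e-12 if phase < 4 else t_grid <= hi + 1e-9)
        t_eval = t_grid[mask]
        E = spec.potential_of_phase(phase)
        sol = solve_ivp(
            rhs_factory(truth[E]),
            (lo, hi),
            y,
            t_eval=np.clip(t_eval, lo, hi),
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed in phase {phase + 1}: {sol.message}")
        states[pos : pos + len(t_eval)] = sol.y.T
        potential[pos : pos + len(t_eval)] = E
        pos += len(t_eval)
        end = solve_ivp(
            rhs_factory(truth[E]), (lo, hi), y, t_eval=[hi], method="LSODA", rtol=1e-10, atol=1e-12
        )
        y = end.y[:, -1]

    amp = np.array([amplitudes[E] for E in potential])
    clean = amp * (states[:, 0] * weights.alpha1 + states[:, 1] * weights.alpha2)
    noisy = noise.apply(clean)
    meta = {"pH": 7.0, "temperature_K": 278.15, "rotation_rpm": 1000.0, "units": "normalized"}
    trace = Trace(t_grid, potential, noisy, meta)
    truth_record = {
        "spec": spec,
        "rates_per_potential": {E: rc.as_dict() for E, rc in truth.items()},
        "alpha2": weights.alpha2,
        "amplitudes": dict(amplitudes),
        "noise_relative_sd": noise.relative_sd,
        "seed": noise.seed,
        "states": states,
        "clean_current": clean,
        "dead_fraction_final": float(states[-1, 3]),
        "h_inact_at_injection": float(
            states[np.searchsorted(t_grid, spec.phase_times[2]) - 1, 2]
        ),
    }
    return trace, truth_record


def generate_cv(
    sweep: Mapping[str, float],
    law: KReactLaw,
    base_rates: RateConstants,
    weights: ActivityWeights = ActivityWeights(),
    waveshape: Mapping[str, float] | None = None,
    noise: NoiseSpec = NoiseSpec(),
    dt: float = 0.1,
) -> tuple[Trace, dict]:
    """Cyclic voltammogram with noise and a truth record of the clean sweep."""
    clean = simulate_cv(sweep, law, base_rates, weights, waveshape, dt=dt)
    noisy = noise.apply(clean.current)
    trace = Trace(clean.time, clean.potential, noisy, dict(clean.metadata))
    half = len(clean.time) // 2
    fwd = slice(0, half + 1)
    truth_record = {
        "sweep": dict(sweep),
        "law": law,
        "base_rates": base_rates.as_dict(),
        "alpha2": weights.alpha2,
        "noise_relative_sd": noise.relative_sd,
        "seed": noise.seed,
        "clean_current": clean.current,
        "forward_peak_potential": float(
            clean.potential[fwd][np.argmax(clean.current[fwd])]
        ),
    }
    return trace, truth_record
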