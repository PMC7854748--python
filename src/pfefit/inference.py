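"""Model fitting and summary statistics for potential-step electrochemistry.

The central objects are two scikit-learn style regressors that map
(time, potential) samples to catalytic current:

* :class:`TwoStateCurrentModel` — mono-exponential relaxations of a
  bound/unbound two-species model;
* :class:`ThreeStateCurrentModel` — the A1 <-> A2 <-> H_inact scheme with
  k1, k_-1, k_inact shared across potentials and k_react free per
  distinct potential (its only rate constant that depends on potential).

Both profile the per-potential amplitudes out of the least-squares
problem (the current is linear in them), optimise the rate constants on
a log scale for positivity, and use seeded multistart to avoid local
minima.  Around the estimators sit the pipeline helpers: background
subtraction, nested-model comparison (F-test and AIC), k_react(E, pH)
profiling, seeded parameter-recovery studies, the residual-activity
readout of the O2-exposure protocol, and the CV inactivation-onset
summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .kinetics import (
    ActivityWeights,
    Propagator,
    Protocol,
    PotentialStep,
    RateConstants,
    StateFractions,
    PURE_A1,
    Trace,
    TwoStateRateConstants,
    weighted_activity,
)

__all__ = [
    "FitResult",
    "ModelComparison",
    "PhaseBoundaries",
    "TwoStateCurrentModel",
    "ThreeStateCurrentModel",
    "subtract_background",
    "fit_model",
    "compare_models",
    "estimate_kreact_profile",
    "recovery_study",
    "residual_activity",
    "cv_onset",
]

_LOG_BOUNDS = (math.log(1e-6), math.log(1e3))


@dataclass
class FitResult:
    """Outcome of fitting a kinetic current model to one trace."""

    model_kind: str
    rates: RateConstants | TwoStateRateConstants
    k_react_per_potential: dict[float, float]
    amplitudes: dict[float, float]
    alpha2: float
    ssr: float
    n_points: int
    n_params: int
    covariance: np.ndarray | None
    param_names: list[str]
    stderr: dict[str, float]
    fitted_trace: Trace

    def __post_init__(self) -> None:
        if self.ssr < 0:
            raise ValueError("ssr must be >= 0")
        if self.n_params >= self.n_points:
            raise ValueError("fit must have fewer parameters than points")

    @property
    def aic(self) -> float:
        return self.n_points * math.log(self.ssr / self.n_points) + 2 * self.n_params


@dataclass(frozen=True)
class ModelComparison:
    """Nested-model comparison between the two- and three-state fits."""

    f_statistic: float
    f_pvalue: float
    aic_delta: float  # AIC(two_state) - AIC(three_state); > 0 favours three-state
    preferred: str


@dataclass(frozen=True)
class PhaseBoundaries:
    """Start times (s) of the five phases of the O2-exposure protocol."""

    times: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.times) != 5 or any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("need five strictly increasing phase start times")


# ---------------------------------------------------------------------------
# protocol recovery and masking


def protocol_from_samples(time: np.ndarray, potential: np.ndarray, **conditions) -> Protocol:
    """Reconstruct the step program from sampled (time, potential) columns."""
    time = np.asarray(time, dtype=float)
    potential = np.asarray(potential, dtype=float)
    change = np.flatnonzero(np.diff(potential) != 0) + 1
    starts = np.concatenate([[0], change])
    # assume the last step extends one sampling interval past the last point
    dt = time[-1] - time[-2] if len(time) > 1 else 1.0
    edges = np.concatenate([time[starts], [time[-1] + dt]])
    steps = tuple(
        PotentialStep(potential[s], edges[i + 1] - edges[i]) for i, s in enumerate(starts)
    )
    return Protocol(steps, **conditions)


def _step_mask(time: np.ndarray, step_starts: np.ndarray, mask_after_step: float) -> np.ndarray:
    """True for samples retained in the fit (capacitive window after each step removed)."""
    keep = np.ones(len(time), dtype=bool)
    if mask_after_step > 0:
        for t0 in step_starts:
            keep &= ~((time >= t0 - 1e-12) & (time < t0 + mask_after_step))
    return keep


def subtract_background(trace: Trace, blank: Trace) -> Trace:
    """Subtract the enzyme-free capacitive control from a trace.

    The blank is interpolated onto the trace's time grid; the grids must
    overlap fully.
    """
    if blank.time[0] > trace.time[0] + 1e-9 or blank.time[-1] < trace.time[-1] - 1e-9:
        raise ValueError(
            "blank does not cover the trace time range "
            f"([{blank.time[0]}, {blank.time[-1]}] vs [{trace.time[0]}, {trace.time[-1]}])"
        )
    bg = np.interp(trace.time, blank.time, blank.current)
    return Trace(trace.time.copy(), trace.potential.copy(), trace.current - bg, dict(trace.metadata))


# ---------------------------------------------------------------------------
# estimators


class _KineticCurrentModel:
    """Shared machinery of the kinetic current regressors.

    X is an array of shape (n, 2) with columns (time_s, potential_V);
    y is the catalytic current.  Per-potential amplitudes are profiled
    out analytically at every residual evaluation.
    """

    def __init__(
        self,
        mask_after_step: float = 2.0,
        multistart: int = 8,
        seed: int = 0,
        alpha2: float = 0.5,
        fit_alpha2: bool = False,
        initial_state: StateFractions = PURE_A1,
        explore_max_nfev: int = 120,
    ):
        self.mask_after_step = mask_after_step
        self.multistart = multistart
        self.seed = seed
        self.alpha2 = alpha2
        self.fit_alpha2 = fit_alpha2
        self.initial_state = initial_state
        self.explore_max_nfev = explore_max_nfev

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "mask_after_step": self.mask_after_step,
            "multistart": self.multistart,
            "seed": self.seed,
            "alpha2": self.alpha2,
            "fit_alpha2": self.fit_alpha2,
            "initial_state": self.initial_state,
            "explore_max_nfev": self.explore_max_nfev,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- model-specific hooks ----------------------------------------------
    model_kind: str = ""

    def _n_shared(self) -> int:
        raise NotImplementedError

    def _activity(self, theta: np.ndarray, time: np.ndarray) -> np.ndarray:
        """Weighted active population at every sample, for rate parameters theta."""
        raise NotImplementedError

    def _random_start(self, rng: np.random.Generator) -> np.ndarray:
        n = self._n_shared() + len(self._potentials)
        return np.log(rng.uniform(1e-3, 10.0, size=n))

    def _extra_starts(self, y: np.ndarray) -> list[np.ndarray]:
        return []

    # -- fitting ------------------------------------------------------------
    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: time_s and potential_V")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        return X, y

    def _prepare(self, X, y):
        time, potential = X[:, 0], X[:, 1]
        self._protocol = protocol_from_samples(time, potential)
        self._potentials = self._protocol.distinct_potentials()
        keep = _step_mask(time, self._protocol.step_starts, self.mask_after_step)
        pts_per_step = []
        edges = np.concatenate([self._protocol.step_starts, [np.inf]])
        for i in range(len(self._protocol.steps)):
            in_step = (time >= edges[i]) & (time < edges[i + 1]) & keep
            pts_per_step.append(int(in_step.sum()))
        if min(pts_per_step) < 10:
            raise ValueError(
                f"fewer than 10 usable points in some step after masking: {pts_per_step}"
            )
        self._time = time
        self._pot = potential
        self._keep = keep
        # column index of the amplitude group of every kept sample
        pot_index = {E: j for j, E in enumerate(self._potentials)}
        self._amp_group = np.array([pot_index[E] for E in potential])
        return time, potential, keep

    def _theta_to_vector(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        if self.fit_alpha2:
            return theta[:-1], 1.0 / (1.0 + math.exp(-theta[-1]))
        return theta, self.alpha2

    def _profiled_residual(self, theta: np.ndarray, y: np.ndarray):
        """Residuals on kept samples with amplitudes solved per potential group."""
        rate_theta, alpha2 = self._theta_to_vector(theta)
        act = self._activity(rate_theta, alpha2)
        amps = np.zeros(len(self._potentials))
        for j in range(len(self._potentials)):
            m = self._keep & (self._amp_group == j)
            denom = float(act[m] @ act[m])
            amps[j] = float(act[m] @ y[m]) / denom if denom > 0 else 0.0
        model = amps[self._amp_group] * act
        resid = (y - model)[self._keep]
        return resid, amps, model

    def fit(self, X, y):
        X, y = self._validate(X, y)
        self._prepare(X, y)
        rng = np.random.default_rng(self.seed)
        n_theta = self._n_shared() + len(self._potentials) + (1 if self.fit_alpha2 else 0)
        lo = np.full(n_theta, _LOG_BOUNDS[0])
        hi = np.full(n_theta, _LOG_BOUNDS[1])
        if self.fit_alpha2:
            lo[-1], hi[-1] = -10.0, 10.0

        starts = []
        for _ in range(max(1, self.multistart)):
            s = self._random_start(rng)
            if self.fit_alpha2:
                s = np.append(s, 0.0)
            starts.append(np.clip(s, lo, hi))
        for s in self._extra_starts(y):
            if self.fit_alpha2:
                s = np.append(s, 0.0)
            starts.append(np.clip(s, lo, hi))

        # exploration passes are iteration-capped; the best start is then
        # polished to full convergence
        best = None
        failures = []
        fun = lambda th: self._profiled_residual(th, y)[0]
        for s in starts:
            try:
                sol = least_squares(
                    fun, s, bounds=(lo, hi), method="trf",
                    xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=self.explore_max_nfev,
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            ssr = float(sol.cost * 2)
            if best is None or ssr < best[0]:
                best = (ssr, sol)
        if best is None:
            raise RuntimeError(f"all {len(starts)} starts failed to converge: {failures}")
        sol = least_squares(
            fun, best[1].x, bounds=(lo, hi), method="trf",
            xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )
        ssr = float(sol.cost * 2)
        if ssr > best[0]:  # pragma: no cover - polish can only tie or improve
            ssr, sol = best
        theta = sol.x
        rate_theta, alpha2_hat = self._theta_to_vector(theta)
        resid, amps, model_full = self._profiled_residual(theta, y)

        n_kept = int(self._keep.sum())
        n_params = n_theta + len(self._potentials)  # + profiled amplitudes
        cov = self._covariance(sol, ssr, n_kept, n_theta)
        self._store_fit(rate_theta, alpha2_hat, amps, ssr, n_kept, n_params, cov, model_full)
        return self

    def _covariance(self, sol, ssr, n, p):
        try:
            JTJ = sol.jac.T @ sol.jac
            cov = np.linalg.inv(JTJ) * (ssr / max(n - p, 1))
        except np.linalg.LinAlgError:
            cov = None
        return cov

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "fitted_current_"):
            raise RuntimeError("model is not fitted")
        # exact re-simulation on the requested grid
        return self._predict_current(X[:, 0], X[:, 1])

    def score(self, X, y):
        y = np.asarray(y, dtype=float)
        pred = self.predict(X)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


class ThreeStateCurrentModel(_KineticCurrentModel):
    """A1 <-> A2 <-> H_inact current model.

    Fitted parameters (log scale): k1, k_-1, k_inact shared over the
    whole trace and one k_react per distinct potential; per-potential
    amplitudes are profiled.  ``fit_alpha2`` optionally frees the
    relative activity of A2 (default fixed at 0.5).
    """

    model_kind = "aai"

    def _n_shared(self) -> int:
        return 3

    def _activity(self, rate_theta: np.ndarray, alpha2: float) -> np.ndarray:
        k1, kneg1, kinact = np.exp(rate_theta[:3])
        propagators = {
            E: Propagator(RateConstants(k1, kneg1, kinact, float(np.exp(rate_theta[3 + j]))))
            for j, E in enumerate(self._potentials)
        }
        weights = ActivityWeights(alpha2=alpha2)
        edges = np.concatenate([self._protocol.step_starts, [np.inf]])
        act = np.empty(len(self._time))
        p = self.initial_state.to_array()
        for i, step in enumerate(self._protocol.steps):
            prop = propagators[step.potential]
            m = (self._time >= edges[i]) & (self._time < edges[i + 1])
            if m.any():
                states = prop.propagate(p, self._time[m] - edges[i])
                act[m] = weighted_activity(states, weights)
            p = prop.propagate(p, np.array([step.duration]))[0]
        return act

    def _extra_starts(self, y: np.ndarray) -> list[np.ndarray]:
        # starts in the pooled two-state limit (fast A1<->A2
        # pre-equilibrium, effective k_inact doubled), one of them seeded
        # from a quick two-state fit of the same data so the three-state
        # optimum can never be worse than the nested two-state one
        k_fast = math.log(200.0)
        starts = [
            np.concatenate(
                [[k_fast, k_fast, math.log(0.5)], np.full(len(self._potentials), math.log(0.2))]
            )
        ]
        try:
            quick = TwoStateCurrentModel(
                mask_after_step=self.mask_after_step,
                multistart=3,
                seed=self.seed + 10_007,
                alpha2=self.alpha2,
            )
            quick.fit(np.column_stack([self._time, self._pot]), y)
            starts.append(
                np.concatenate(
                    [
                        [k_fast, k_fast, math.log(2.0 * quick.rates_.k_inact)],
                        np.log([quick.k_react_per_potential_[E] for E in self._potentials]),
                    ]
                )
            )
        except Exception:
            pass
        return starts

    def _store_fit(self, rate_theta, alpha2, amps, ssr, n_kept, n_params, cov, model_full):
        k1, kneg1, kinact = np.exp(rate_theta[:3])
        kreact = {E: float(np.exp(rate_theta[3 + j])) for j, E in enumerate(self._potentials)}
        # representative RateConstants: k_react at the most oxidative potential
        E_ox = max(self._potentials)
        self.rates_ = RateConstants(float(k1), float(kneg1), float(kinact), kreact[E_ox])
        self.k_react_per_potential_ = kreact
        self.amplitudes_ = {E: float(a) for E, a in zip(self._potentials, amps)}
        self.alpha2_ = float(alpha2)
        self.ssr_ = ssr
        self.n_points_ = n_kept
        self.n_params_ = n_params
        self.covariance_ = cov
        self.param_names_ = (
            ["log_k1", "log_k_neg1", "log_k_inact"]
            + [f"log_k_react@{E:g}V" for E in self._potentials]
            + (["logit_alpha2"] if self.fit_alpha2 else [])
        )
        self.fitted_current_ = model_full
        self._fitted_theta = np.concatenate(
            [rate_theta, [math.log(alpha2 / (1 - alpha2))] if self.fit_alpha2 else []]
        )

    def _predict_current(self, time, potential):
        rate_theta = np.concatenate(
            [
                np.log([self.rates_.k1, self.rates_.k_neg1, self.rates_.k_inact]),
                np.log([self.k_react_per_potential_[E] for E in self._potentials]),
            ]
        )
        saved = self._time
        self._time = np.asarray(time, dtype=float)
        try:
            act = self._activity(rate_theta, self.alpha2_)
        finally:
            self._time = saved
        amps = np.array([self.amplitudes_[E] for E in potential])
        return amps * act


class TwoStateCurrentModel(_KineticCurrentModel):
    """Bound/unbound two-species model: mono-exponential per step.

    k_inact is shared across potentials, k_react free per distinct
    potential (mirroring the three-state parametrisation); the active
    fraction is continuous across step boundaries.
    """

    model_kind = "two_state"

    def _n_shared(self) -> int:
        return 1

    def _activity(self, rate_theta: np.ndarray, alpha2: float) -> np.ndarray:
        kinact = float(np.exp(rate_theta[0]))
        kreact = {E: float(np.exp(rate_theta[1 + j])) for j, E in enumerate(self._potentials)}
        edges = np.concatenate([self._protocol.step_starts, [np.inf]])
        act = np.empty(len(self._time))
        a = 1.0  # fully active start
        for i, step in enumerate(self._protocol.steps):
            kr = kreact[step.potential]
            ktot = kinact + kr
            a_inf = kr / ktot if ktot > 0 else a
            m = (self._time >= edges[i]) & (self._time < edges[i + 1])
            if m.any():
                dt = self._time[m] - edges[i]
                act[m] = a_inf + (a - a_inf) * np.exp(-ktot * dt)
            a = a_inf + (a - a_inf) * math.exp(-ktot * step.duration)
        return act

    def _store_fit(self, rate_theta, alpha2, amps, ssr, n_kept, n_params, cov, model_full):
        kinact = float(np.exp(rate_theta[0]))
        kreact = {E: float(np.exp(rate_theta[1 + j])) for j, E in enumerate(self._potentials)}
        E_ox = max(self._potentials)
        self.rates_ = TwoStateRateConstants(kinact, kreact[E_ox])
        self.k_react_per_potential_ = kreact
        self.amplitudes_ = {E: float(a) for E, a in zip(self._potentials, amps)}
        self.alpha2_ = float(alpha2)
        self.ssr_ = ssr
        self.n_points_ = n_kept
        self.n_params_ = n_params
        self.covariance_ = cov
        self.param_names_ = ["log_k_inact"] + [
            f"log_k_react@{E:g}V" for E in self._potentials
        ]
        self.fitted_current_ = model_full

    def _predict_current(self, time, potential):
        rate_theta = np.concatenate(
            [
                [math.log(self.rates_.k_inact)],
                np.log([self.k_react_per_potential_[E] for E in self._potentials]),
            ]
        )
        saved = self._time
        self._time = np.asarray(time, dtype=float)
        try:
            act = self._activity(rate_theta, self.alpha2_)
        finally:
            self._time = saved
        amps = np.array([self.amplitudes_[E] for E in potential])
        return amps * act


# ---------------------------------------------------------------------------
# functional front-ends


def _stderr_from_cov(cov, param_names, rates_log):
    out = {}
    if cov is None:
        return {name: float("nan") for name in param_names}
    diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    for name, se_log, val in zip(param_names, diag, rates_log):
        # delta method back to the rate scale for log-parametrised rates
        out[name] = float(se_log * val) if name.startswith("log_") else float(se_log)
    return out


def fit_model(
    trace: Trace,
    protocol: Protocol | None = None,
    model_kind: str = "aai",
    mask_after_step: float = 2.0,
    multistart: int = 8,
    seed: int = 0,
    alpha2: float = 0.5,
    fit_alpha2: bool = False,
    blank: Trace | None = None,
) -> FitResult:
    """Fit a kinetic current model to a chronoamperogram.

    If a blank is given it is subtracted first; otherwise the default
    2 s after each potential step are masked to exclude the capacitive
    transient.  Returns a :class:`FitResult`; the estimator itself is
    attached as ``result.estimator`` for further use.
    """
    if blank is not None:
        trace = subtract_background(trace, blank)
    cls = {"aai": ThreeStateCurrentModel, "two_state": TwoStateCurrentModel}.get(model_kind)
    if cls is None:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    est = cls(
        mask_after_step=mask_after_step,
        multistart=multistart,
        seed=seed,
        alpha2=alpha2,
        fit_alpha2=fit_alpha2,
    )
    X = np.column_stack([trace.time, trace.potential])
    est.fit(X, trace.current)
    fitted = Trace(
        trace.time.copy(), trace.potential.copy(), est.fitted_current_.copy(), dict(trace.metadata)
    )
    if model_kind == "aai":
        vals = [est.rates_.k1, est.rates_.k_neg1, est.rates_.k_inact] + [
            est.k_react_per_potential_[E] for E in est._potentials
        ]
    else:
        vals = [est.rates_.k_inact] + [est.k_react_per_potential_[E] for E in est._potentials]
    if est.fit_alpha2:
        vals = vals + [est.alpha2_]
    stderr = _stderr_from_cov(est.covariance_, est.param_names_, vals)
    result = FitResult(
        model_kind=model_kind,
        rates=est.rates_,
        k_react_per_potential=dict(est.k_react_per_potential_),
        amplitudes=dict(est.amplitudes_),
        alpha2=est.alpha2_,
        ssr=est.ssr_,
        n_points=est.n_points_,
        n_params=est.n_params_,
        covariance=est.covariance_,
        param_names=list(est.param_names_),
        stderr=stderr,
        fitted_trace=fitted,
    )
    result.estimator = est
    return result


def compare_models(fit2: FitResult, fit3: FitResult) -> ModelComparison:
    """F-test and AIC comparison of the nested two- vs three-state fits.

    Both fits must be on the same masked data.  The three-state model is
    preferred only when both criteria favour it (F-test at p < 0.05 and
    a lower AIC).
    """
    if fit2.n_points != fit3.n_points:
        raise ValueError(
            f"fits are not on the same data: n = {fit2.n_points} vs {fit3.n_points}"
        )
    n = fit3.n_points
    p2, p3 = fit2.n_params, fit3.n_params
    if p3 <= p2:
        raise ValueError("three-state fit must have more parameters than two-state fit")
    num = max(fit2.ssr - fit3.ssr, 0.0) / (p3 - p2)
    den = fit3.ssr / (n - p3)
    f_stat = num / den if den > 0 else math.inf
    pval = float(f_dist.sf(f_stat, p3 - p2, n - p3)) if math.isfinite(f_stat) else 0.0
    aic_delta = n * math.log(fit2.ssr / fit3.ssr) + 2 * (p2 - p3)
    preferred = "aai" if (pval < 0.05 and aic_delta > 0) else "two_state"
    return ModelComparison(f_statistic=f_stat, f_pvalue=pval, aic_delta=aic_delta, preferred=preferred)


def estimate_kreact_profile(
    fits: Sequence[FitResult],
    pH_values: Sequence[float] | None = None,
    fit_law: bool = False,
):
    """Tabulate k_react against potential (and pH) across fits.

    Returns a pandas DataFrame with columns (potential_V, pH, k_react);
    with ``fit_law`` a weighted log-linear Tafel-like fit
    ln k_react = ln k0 - slope * (E - E_ref) is added, returned as a dict
    with keys k0, E_ref, slope.
    """
    import pandas as pd

    rows = []
    for i, fr in enumerate(fits):
        pH = pH_values[i] if pH_values is not None else fr.fitted_trace.metadata.get("pH", float("nan"))
        for E, kr in fr.k_react_per_potential.items():
            se = fr.stderr.get(f"log_k_react@{E:g}V", float("nan"))
            rows.append({"potential_V": E, "pH": pH, "k_react": kr, "stderr": se})
    table = pd.DataFrame(rows)
    if not fit_law:
        return table
    if table["potential_V"].nunique() < 2:
        raise ValueError("law fitting needs at least two distinct potentials")
    E = table["potential_V"].to_numpy()
    y = np.log(table["k_react"].to_numpy())
    w = np.ones_like(y)
    se = table["stderr"].to_numpy()
    kr = table["k_react"].to_numpy()
    rel = np.where((se > 0) & np.isfinite(se), se / kr, np.nan)
    if np.isfinite(rel).all() and (rel > 0).all():
        w = 1.0 / rel**2
    E_ref = float(np.average(E, weights=w))
    slope, intercept = np.polyfit(E - E_ref, y, 1, w=np.sqrt(w))
    law = {"k0": float(math.exp(intercept)), "E_ref": E_ref, "slope": float(-slope)}
    return table, law


def recovery_study(
    truth: Mapping[float, RateConstants],
    protocol: Protocol,
    noise_sd: float = 0.01,
    n_reps: int = 50,
    seed: int = 0,
    multistart: int = 8,
    mask_after_step: float = 0.0,
    amplitudes: Mapping[float, float] | None = None,
):
    """Seeded parameter-recovery simulation.

    Generates ``n_reps`` noisy chronoamperograms from ``truth``, fits the
    three-state model to each, and summarises recovery per rate constant
    (median, relative bias of the median, relative RMSE).  Deterministic
    given the seed.  The generated traces carry no capacitive transient,
    so no post-step masking is applied by default.
    """
    from .synthetic import NoiseSpec, generate_chronoamperogram

    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    E_ox = max(truth)
    truth_flat = {
        "k1": truth[E_ox].k1,
        "k_neg1": truth[E_ox].k_neg1,
        "k_inact": truth[E_ox].k_inact,
        "k_react": truth[E_ox].k_react,
    }
    root = np.random.default_rng(seed)
    rep_seeds = root.integers(0, 2**31 - 1, size=n_reps)
    estimates = {k: [] for k in truth_flat}
    for r in range(n_reps):
        trace, _ = generate_chronoamperogram(
            protocol,
            truth,
            noise=NoiseSpec(relative_sd=noise_sd, seed=int(rep_seeds[r])),
            amplitudes=amplitudes,
        )
        fr = fit_model(
            trace,
            model_kind="aai",
            multistart=multistart,
            seed=int(rep_seeds[r]),
            mask_after_step=mask_after_step,
        )
        estimates["k1"].append(fr.rates.k1)
        estimates["k_neg1"].append(fr.rates.k_neg1)
        estimates["k_inact"].append(fr.rates.k_inact)
        estimates["k_react"].append(fr.k_react_per_potential[E_ox])
    summary = {}
    for k, vals in estimates.items():
        vals = np.array(vals)
        true = truth_flat[k]
        summary[k] = {
            "truth": true,
            "median": float(np.median(vals)),
            "bias_rel": float((np.median(vals) - true) / true),
            "rmse_rel": float(np.sqrt(np.mean((vals - true) ** 2)) / true),
            "estimates": vals,
        }
    return summary


def residual_activity(
    trace: Trace,
    phases: PhaseBoundaries | Sequence[float],
    plateau_window: float = 50.0,
) -> float:
    """Residual activity (%) after the O2-exposure protocol.

    Ratio of the mean absolute current over the last ``plateau_window``
    seconds of phase 5 to the same readout at the end of phase 1,
    times 100.  Scale-invariant by construction.
    """
    if not isinstance(phases, PhaseBoundaries):
        phases = PhaseBoundaries(tuple(float(x) for x in phases))
    t = trace.time
    if phases.times[0] < t[0] - 1e-9 or phases.times[-1] > t[-1] + 1e-9:
        raise ValueError("phase boundaries lie outside the trace")
    p1_end = phases.times[1]
    p5_end = t[-1]
    if plateau_window >= (p1_end - phases.times[0]) or plateau_window >= (p5_end - phases.times[4]):
        raise ValueError("plateau_window must be shorter than phases 1 and 5")
    before = (t >= p1_end - plateau_window) & (t < p1_end)
    after = t >= p5_end - plateau_window
    if not before.any() or not after.any():
        raise ValueError("empty plateau window")
    ref = float(np.mean(np.abs(trace.current[before])))
    res = float(np.mean(np.abs(trace.current[after])))
    if ref == 0:
        raise ValueError("reference plateau current is zero")
    return 100.0 * res / ref


def _split_sweeps(trace: Trace) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of the forward (E increasing) and backward branches."""
    from scipy.signal import medfilt

    dE = np.gradient(trace.potential)
    sign = np.sign(medfilt(dE, kernel_size=5))
    fwd = sign > 0
    bwd = sign < 0
    return fwd, bwd


def cv_onset(cv: Trace, smooth_window: int = 11) -> float:
    """Potential of the forward-sweep current maximum of a voltammogram.

    On an inactivating film this peak sits below the vertex potential:
    the current collapses at higher potential as the inactive state
    accumulates faster than the sweep proceeds.
    """
    fwd, _ = _split_sweeps(cv)
    if fwd.sum() < smooth_window + 2:
        raise ValueError("no forward sweep detected in the voltammogram")
    E = cv.potential[fwd]
    i = cv.current[fwd]
    if smooth_window > 1:
        w = min(smooth_window, len(i) if len(i) % 2 else len(i) - 1)
        kernel = np.ones(w) / w
        i = np.convolve(i, kernel, mode="same")
    return float(E[np.argmax(i)])
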