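"""Plain-text trace files, fit reports, run configuration, and unit helpers.

Traces are stored as comma-separated tables with ``# key: value``
metadata headers and the fixed columns time_s, potential_V, current.
Fit results go to JSON documents that validate on read-back.  Run
configurations are flat TOML documents with a closed key set.  All
potentials are stored versus the standard hydrogen electrode (SHE);
converters from the common reference electrodes are provided.
"""

from __future__ import annotations

import json
import math
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import FitResult, ModelComparison
from .kinetics import RateConstants, Trace, TwoStateRateConstants

__all__ = [
    "read_trace",
    "write_trace",
    "write_fit_report",
    "read_fit_report",
    "load_config",
    "she_from_calomel",
    "she_from_ag_agcl",
    "TraceParseError",
]

COLUMNS = ["time_s", "potential_V", "current"]

# reference-electrode offsets to SHE (V)
CALOMEL_TO_SHE = 0.244
AG_AGCL_TO_SHE = 0.205


def she_from_calomel(potential: float) -> float:
    """Convert a potential measured vs the saturated calomel electrode to SHE."""
    return potential + CALOMEL_TO_SHE


def she_from_ag_agcl(potential: float) -> float:
    """Convert a potential measured vs Ag/AgCl (3.5 M KCl, 20 C) to SHE."""
    return potential + AG_AGCL_TO_SHE


class TraceParseError(ValueError):
    """Malformed trace file; the message names the offending line."""


def write_trace(trace: Trace, path) -> None:
    path = Path(path)
    lines = []
    for key, value in trace.metadata.items():
        lines.append(f"# {key}: {value}")
    lines.append(",".join(COLUMNS))
    for t, e, i in zip(trace.time, trace.potential, trace.current):
        lines.append(f"{t:.15g},{e:.15g},{i:.15g}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path) -> Trace:
    path = Path(path)
    metadata: dict = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" not in body:
                raise TraceParseError(f"{path}:{lineno}: metadata line without ':'")
            key, _, value = body.partition(":")
            value = value.strip()
            try:
                metadata[key.strip()] = float(value)
            except ValueError:
                metadata[key.strip()] = value
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            missing = [c for c in COLUMNS if c not in header]
            if missing:
                raise TraceParseError(f"{path}:{lineno}: missing columns {missing}")
            continue
        parts = line.split(",")
        if len(parts) != len(header):
            raise TraceParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        try:
            rows.append([float(x) for x in parts])
        except ValueError as exc:
            raise TraceParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if header is None or not rows:
        raise TraceParseError(f"{path}: no data rows found")
    frame = pd.DataFrame(rows, columns=header)
    return Trace(
        frame["time_s"].to_numpy(),
        frame["potential_V"].to_numpy(),
        frame["current"].to_numpy(),
        metadata,
    )


# ---------------------------------------------------------------------------
# fit reports

_REPORT_REQUIRED = {"model_kind", "rates", "k_react_per_potential", "amplitudes", "ssr",
                    "n_points", "n_params", "stderr", "alpha2"}


def fit_report_dict(fit: FitResult, comparison: ModelComparison | None = None) -> dict:
    doc = {
        "model_kind": fit.model_kind,
        "rates": (
            fit.rates.as_dict()
            if isinstance(fit.rates, RateConstants)
            else {"k_inact": fit.rates.k_inact, "k_react": fit.rates.k_react}
        ),
        "k_react_per_potential": {f"{E:g}": v for E, v in fit.k_react_per_potential.items()},
        "amplitudes": {f"{E:g}": v for E, v in fit.amplitudes.items()},
        "alpha2": fit.alpha2,
        "ssr": fit.ssr,
        "n_points": fit.n_points,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "stderr": {k: (None if not math.isfinite(v) else v) for k, v in fit.stderr.items()},
        "covariance": None if fit.covariance is None else np.asarray(fit.covariance).tolist(),
        "param_names": fit.param_names,
    }
    if comparison is not None:
        doc["comparison"] = {
            "f_statistic": comparison.f_statistic,
            "f_pvalue": comparison.f_pvalue,
            "aic_delta": comparison.aic_delta,
            "preferred": comparison.preferred,
        }
    return doc


def write_fit_report(fit: FitResult, path, comparison: ModelComparison | None = None) -> None:
    Path(path).write_text(json.dumps(fit_report_dict(fit, comparison), indent=2) + "\n")


def read_fit_report(path) -> dict:
    doc = json.loads(Path(path).read_text())
    missing = _REPORT_REQUIRED - doc.keys()
    if missing:
        raise ValueError(f"fit report {path} is missing keys: {sorted(missing)}")
    if doc["ssr"] < 0:
        raise ValueError("fit report has negative ssr")
    for key, value in doc["stderr"].items():
        if value is not None and value < 0:
            raise ValueError(f"negative uncertainty for {key}")
    return doc


# ---------------------------------------------------------------------------
# run configuration

_KNOWN_CONFIG_KEYS = {
    # rates / truth
    "k1", "k_neg1", "k_inact", "k_react", "k_react_low", "k_react_high",
    "alpha2", "fit_alpha2",
    # protocol
    "low_E", "high_E", "n_cycles", "duration", "pH", "temperature_K", "rotation_rpm",
    # sampling & noise
    "sample_rate", "noise_relative_sd", "seed",
    "capacitive_peak", "capacitive_tau", "film_loss_tau",
    # fitting
    "mask_after_step", "multistart", "model",
    # recovery
    "n_reps",
    # CV
    "E_start", "E_vertex", "scan_rate", "E_eq", "steepness", "i_lim",
    "kreact_k0", "kreact_E_ref", "kreact_slope",
    # O2 protocol
    "damage_rate", "o2_concentration", "o2_washout_tau", "plateau_window",
    "reductive_E", "oxidative_E",
    # structure
    "structure", "chain", "cys", "fe_serial",
}


def load_config(path) -> dict:
    """Read a flat TOML run configuration, rejecting unknown keys."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    flat: dict = {}
    for key, value in doc.items():
        if isinstance(value, dict):
            raise ValueError(f"config must be flat; found table {key!r}")
        if key not in _KNOWN_CONFIG_KEYS:
            raise ValueError(f"unknown config key {key!r}")
        flat[key] = value
    return flat
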