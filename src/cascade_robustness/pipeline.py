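"""Parameter-sweep orchestration.

A sweep varies one rate (or total) of a cascade over a descending log grid
and, at every grid point, recomputes the pre-stimulus steady state, the
relaxation trajectory, the half-life, the consecutive-profile similarity
and the logarithmic gain of the half-life.  Derived summaries — robust
intervals, the maximal activating rate, the rate-limiting crossover and the
analytic condition report — are attached to the result, which round-trips
through CSV + JSON.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import metrics, models, relaxation
from .metrics import GAIN_STEP_LOG10, ROBUSTNESS_THRESHOLD, SimilarityConfig
from .models import CascadeParameters, HFParameters, effective_alphas
from .relaxation import TauGrid

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "kinase_effect_scan",
    "export_results",
    "load_results",
    "get_param",
    "set_param",
    "validate_report",
    "REPORT_SCHEMA",
]

logger = logging.getLogger(__name__)

#: Columns of the per-grid-point record table, in order.
RECORD_COLUMNS = (
    "param_value", "g2", "activated", "duration", "similarity", "gain",
    "gain_refined", "failed",
)


# ---------------------------------------------------------------------------
# Parameter targeting: flat dotted names -> fields
# ---------------------------------------------------------------------------


def get_param(params, target: str) -> float:
    """Read a parameter by flat dotted name (``beta.0``, ``p_tot.2``...)."""
    name, _, idx = target.partition(".")
    if isinstance(params, CascadeParameters):
        if name == "e0_init":
            return params.e0_init
        if name == "alpha":
            # effective kinase activity of that layer
            return float(effective_alphas(params).alpha[int(idx)])
        if name in ("alpha_bar", "beta", "m_tot"):
            return float(getattr(params, name)[int(idx)])
    if isinstance(params, HFParameters):
        if name == "e0_init":
            return params.e0_init
        mapping = {"p_tot": "phosphatase_totals", "substrate_tot": "substrate_totals"}
        if name in mapping:
            return float(getattr(params, mapping[name])[int(idx)])
        if name in ("a", "d", "k"):
            return float(getattr(params, name)[int(idx) - 1])  # 1-indexed reactions
    raise ValueError(f"unknown parameter target {target!r} for {type(params).__name__}")


def set_param(params, target: str, value: float):
    """Return a copy of ``params`` with the targeted entry replaced."""
    name, _, idx = target.partition(".")
    if isinstance(params, CascadeParameters):
        if name == "e0_init":
            return params.replace(e0_init=float(value))
        if name == "alpha":
            # effective activity: alpha_0 = alpha_bar_0 e0_init,
            # alpha_i = alpha_bar_i m_tot[i-1]
            i = int(idx)
            scale = params.e0_init if i == 0 else params.m_tot[i - 1]
            arr = params.alpha_bar.copy()
            arr[i] = float(value) / scale
            return params.replace(alpha_bar=arr)
        if name in ("alpha_bar", "beta", "m_tot"):
            arr = getattr(params, name).copy()
            arr[int(idx)] = float(value)
            return params.replace(**{name: arr})
    if isinstance(params, HFParameters):
        if name == "e0_init":
            return params.replace(e0_init=float(value))
        mapping = {"p_tot": "phosphatase_totals", "substrate_tot": "substrate_totals"}
        if name in mapping:
            arr = getattr(params, mapping[name]).copy()
            arr[int(idx)] = float(value)
            return params.replace(**{mapping[name]: arr})
        if name in ("a", "d", "k"):
            arr = getattr(params, name).copy()
            arr[int(idx) - 1] = float(value)
            return params.replace(**{name: arr})
    raise ValueError(f"unknown parameter target {target!r} for {type(params).__name__}")


# ---------------------------------------------------------------------------
# Sweep specification and result
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter log-grid sweep.

    The grid runs 10^log_start, 10^(log_start - log_step), ..., down to
    10^log_stop inclusive (descending by default, matching how phosphatase
    sweeps are usually presented).
    """

    model: str
    target: str
    base: object
    log_start: float = 4.0
    log_stop: float = -3.6
    log_step: float = 0.2
    grid: TauGrid = field(default_factory=TauGrid)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    activation_threshold: float = 0.5
    refined_gain: bool = False
    gain_step_log10: float = GAIN_STEP_LOG10
    stimulus_removal: str = "hard"

    def __post_init__(self) -> None:
        if self.model not in relaxation.MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.log_step <= 0:
            raise ValueError("log_step must be positive")
        if self.log_start == self.log_stop:
            raise ValueError("log_start and log_stop must differ")

    @property
    def values(self) -> np.ndarray:
        n = int(round(abs(self.log_start - self.log_stop) / self.log_step)) + 1
        sign = 1.0 if self.log_stop >= self.log_start else -1.0
        exponents = self.log_start + sign * self.log_step * np.arange(n)
        return 10.0 ** exponents

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "target": self.target,
            "log_start": self.log_start,
            "log_stop": self.log_stop,
            "log_step": self.log_step,
            "base": models.params_to_flat_dict(self.base),
            "activation_threshold": self.activation_threshold,
            "refined_gain": self.refined_gain,
            "gain_step_log10": self.gain_step_log10,
            "stimulus_removal": self.stimulus_removal,
        }


@dataclass
class SweepResult:
    """Per-grid-point records plus derived robustness summaries."""

    spec: Optional[SweepSpec]
    records: pd.DataFrame
    robust_intervals: list = field(default_factory=list)
    beta_max: Optional[float] = None
    crossover: Optional[float] = None
    condition_report: Optional[metrics.ConditionReport] = None

    def derived_to_dict(self) -> dict:
        return {
            "robust_intervals": [iv.to_dict() for iv in self.robust_intervals],
            "beta_max": self.beta_max,
            "crossover": self.crossover,
            "condition_report": (
                self.condition_report.to_dict() if self.condition_report else None
            ),
        }


def _other_rates(spec: SweepSpec):
    """Rates competing with the swept one for 'minimum rate' status."""
    name, _, idx = spec.target.partition(".")
    if spec.model in ("heinrich", "linearized") and name == "beta":
        return np.delete(spec.base.beta, int(idx))
    if spec.model == "hf" and name == "p_tot":
        return np.delete(spec.base.phosphatase_totals, int(idx))
    return None


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Execute a sweep; per-point failures are recorded, never fatal."""
    values = spec.values
    rows = []
    prev_traj = None
    prev_log = None

    for value in values:
        row = {c: np.nan for c in RECORD_COLUMNS}
        row["param_value"] = value
        row["activated"] = False
        row["failed"] = False
        try:
            params = set_param(spec.base, spec.target, value)
            result = relaxation.relax(
                spec.model, params, grid=spec.grid,
                activation_threshold=spec.activation_threshold,
                stimulus_removal=spec.stimulus_removal,
            )
            row["g2"] = result.g_output
            row["activated"] = result.activated
            row["duration"] = result.duration if result.duration is not None else np.nan
            if prev_traj is not None:
                delta = math.log10(value) - prev_log
                row["similarity"] = metrics.consecutive_similarity(
                    result.trajectory, prev_traj, delta, spec.similarity
                )
            if spec.refined_gain and result.duration is not None:
                row["gain_refined"] = metrics.log_gain(
                    lambda v: relaxation.half_life(
                        spec.model, set_param(spec.base, spec.target, v),
                        stimulus_removal=spec.stimulus_removal,
                    ),
                    value, spec.gain_step_log10,
                )
            prev_traj = result.trajectory
            prev_log = math.log10(value)
        except Exception as exc:  # per-point failure: record and continue
            logger.warning("sweep point %s=%g failed: %s", spec.target, value, exc)
            row["failed"] = True
            prev_traj, prev_log = None, None
        rows.append(row)

    records = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))

    # central-difference gain of the duration on the sweep grid itself
    log_v = np.log10(records["param_value"].to_numpy())
    log_d = np.log10(records["duration"].to_numpy())
    gain = np.full(len(records), np.nan)
    with np.errstate(invalid="ignore"):
        if len(records) >= 2:
            valid = np.isfinite(log_d)
            for j in range(len(records)):
                lo = j + 1 if j + 1 < len(records) else j
                hi = j - 1 if j - 1 >= 0 else j
                if lo != hi and valid[lo] and valid[hi]:
                    gain[j] = (log_d[hi] - log_d[lo]) / (log_v[hi] - log_v[lo])
    records["gain"] = gain

    gain_for_intervals = records["gain_refined"].to_numpy() if spec.refined_gain else gain
    intervals = metrics.robustness_interval(
        records["param_value"].to_numpy(), gain_for_intervals,
        records["activated"].to_numpy(dtype=bool),
        threshold=spec.similarity.threshold,
    )

    other = _other_rates(spec)
    crossover = (
        metrics.min_rate_crossover(records["param_value"].to_numpy(), other)
        if other is not None else None
    )

    bmax = None
    report = None
    name, _, idx = spec.target.partition(".")
    if spec.model in ("heinrich", "linearized") and name == "beta":
        i = int(idx)
        bmax = metrics.beta_max(
            spec.base, i, model=spec.model,
            activation_threshold=spec.activation_threshold,
        )
        report = metrics.check_conditions(
            effective_alphas(spec.base), spec.base.beta, i
        )
    elif spec.model == "hf" and name == "p_tot":
        bmax = metrics.beta_max(
            spec.base, int(idx), model="hf",
            activation_threshold=spec.activation_threshold,
        )

    return SweepResult(
        spec=spec, records=records, robust_intervals=intervals,
        beta_max=bmax, crossover=crossover, condition_report=report,
    )


def kinase_effect_scan(
    base: CascadeParameters,
    alpha_index: int,
    alpha_values,
    beta_indices,
    model: str = "heinrich",
    sweep_kwargs: dict | None = None,
) -> dict:
    """Duration curves and beta_i_max across kinase-activity values.

    For each effective kinase activity in ``alpha_values`` (applied to layer
    ``alpha_index``), recomputes beta_i_max for every requested module and,
    when ``sweep_kwargs`` is given, the full duration-vs-beta_i sweep.
    Returns {"beta_max": DataFrame, "sweeps": {(alpha, i): SweepResult}}.
    """
    rows = []
    sweeps = {}
    for alpha in alpha_values:
        params = set_param(base, f"alpha.{alpha_index}", alpha)
        for i in beta_indices:
            bmax = metrics.beta_max(params, i, model=model)
            rows.append({"alpha_index": alpha_index, "alpha": alpha,
                         "beta_index": i, "beta_max": bmax})
            if sweep_kwargs is not None:
                spec = SweepSpec(model=model, target=f"beta.{i}",
                                 base=params, **sweep_kwargs)
                sweeps[(alpha, i)] = run_sweep(spec)
    return {"beta_max": pd.DataFrame(rows), "sweeps": sweeps}


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

#: Minimal structural schema for the JSON report (checked by validate_report).
REPORT_SCHEMA = {
    "spec": dict,
    "derived": {
        "robust_intervals": list,
        "beta_max": (float, int, type(None)),
        "crossover": (float, int, type(None)),
        "condition_report": (dict, type(None)),
    },
}


def validate_report(report: dict) -> None:
    """Raise ValueError if a report does not match REPORT_SCHEMA."""

    def check(node, schema, path):
        if isinstance(schema, dict):
            if not isinstance(node, dict):
                raise ValueError(f"{path}: expected object, got {type(node).__name__}")
            for key, sub in schema.items():
                if key not in node:
                    raise ValueError(f"{path}: missing key {key!r}")
                check(node[key], sub, f"{path}.{key}")
        else:
            if not isinstance(node, schema):
                raise ValueError(f"{path}: wrong type {type(node).__name__}")

    check(report, REPORT_SCHEMA, "report")


def export_results(result: SweepResult, path, formats=("csv", "json")) -> dict:
    """Write the record table (CSV) and derived report (JSON) under ``path``.

    ``path`` is a directory; files are named records.csv and report.json.
    Returns {format: written path}.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = {}
    if "csv" in formats:
        csv_path = path / "records.csv"
        result.records.to_csv(csv_path, index=False)
        written["csv"] = csv_path
    if "json" in formats:
        report = {
            "spec": result.spec.to_dict() if result.spec else {},
            "derived": result.derived_to_dict(),
        }
        validate_report(report)
        json_path = path / "report.json"
        json_path.write_text(json.dumps(report, indent=2))
        written["json"] = json_path
    return written


def load_results(path) -> SweepResult:
    """Read back a sweep exported by :func:`export_results`."""
    path = Path(path)
    records = pd.read_csv(path / "records.csv")
    report = json.loads((path / "report.json").read_text())
    validate_report(report)
    derived = report["derived"]
    intervals = [
        metrics.RobustInterval(iv["lower"], iv["upper"])
        for iv in derived["robust_intervals"]
    ]
    cond = derived["condition_report"]
    return SweepResult(
        spec=None,
        records=records,
        robust_intervals=intervals,
        beta_max=derived["beta_max"],
        crossover=derived["crossover"],
        condition_report=metrics.ConditionReport(**cond) if cond else None,
    )
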