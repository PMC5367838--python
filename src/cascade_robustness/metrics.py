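"""Robustness metrics.

Dynamics robustness is quantified by the L2 distance between consecutive
output profiles on the log-time axis, scaled by the log-parameter step;
duration robustness by the logarithmic gain of the half-life with respect
to a rate parameter.  This module also provides the activation criterion,
the maximal activating phosphatase rate beta_i_max, the rate-limiting
duration approximation of the linearized theory and its gain formula, and
the three analytic conditions under which a module's phosphatase rate can
be perturbed without changing the response duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import models, relaxation
from .models import (
    EffectiveParameters,
    LinearizedSolution,
    effective_alphas,
    steady_state_gains,
)
from .relaxation import TAU_LOWER, TAU_UPPER, Trajectory

__all__ = [
    "SimilarityConfig",
    "ConditionReport",
    "RobustInterval",
    "DurationApproxInvalid",
    "consecutive_similarity",
    "log_gain",
    "is_activated",
    "beta_max",
    "duration_approx",
    "gain_from_coefficients",
    "check_conditions",
    "robustness_interval",
]

#: Magnitude of logarithmic gain below which the duration counts as robust.
ROBUSTNESS_THRESHOLD = 0.3

#: Default central-difference step in log10 for logarithmic gains.
GAIN_STEP_LOG10 = 0.05


class DurationApproxInvalid(ValueError):
    """The rate-limiting duration approximation requires c_min > 1/2."""


@dataclass(frozen=True)
class SimilarityConfig:
    """Settings of the consecutive-profile similarity measure.

    ``use_sqrt`` selects the conventional L2 norm (square root of the
    integrated squared difference); switching it off returns the un-rooted
    integral.  ``profile_normalized`` divides each profile by its initial
    value before comparing, for cross-model comparisons; the default
    compares raw output concentrations.
    """

    tau_lower: float = TAU_LOWER
    tau_upper: float = TAU_UPPER
    threshold: float = ROBUSTNESS_THRESHOLD
    use_sqrt: bool = True
    profile_normalized: bool = False

    def __post_init__(self) -> None:
        if not self.tau_lower < self.tau_upper:
            raise ValueError("require tau_lower < tau_upper")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class ConditionReport:
    """Outcome of the three duration-robustness conditions for module i.

    1. rate-limiting: some other module is slower (min beta < beta_i);
    2. initial condition: (b_N/a_N)(1 + b_{N-1}/a_{N-1})...(1 + b_0/a_0) < 1,
       i.e. the output layer is strongly activated;
    3. fast downstream kinase: some k >= i has beta_k << alpha_k.

    Margins are signed, positive when the condition holds:
    condition 1 and 3 margins are log10 ratios, condition 2's margin is
    1 minus the product.
    """

    module: int
    rate_limiting_ok: bool
    initial_condition_ok: bool
    fast_downstream_ok: bool
    rate_limiting_margin: float
    initial_condition_margin: float
    fast_downstream_margin: float

    @property
    def all_ok(self) -> bool:
        return self.rate_limiting_ok and self.initial_condition_ok and self.fast_downstream_ok

    def to_dict(self) -> dict:
        return {
            "module": self.module,
            "rate_limiting_ok": self.rate_limiting_ok,
            "initial_condition_ok": self.initial_condition_ok,
            "fast_downstream_ok": self.fast_downstream_ok,
            "rate_limiting_margin": self.rate_limiting_margin,
            "initial_condition_margin": self.initial_condition_margin,
            "fast_downstream_margin": self.fast_downstream_margin,
        }


@dataclass(frozen=True)
class RobustInterval:
    """Contiguous parameter range that is activated and duration-robust."""

    lower: float
    upper: float

    def to_dict(self) -> dict:
        return {"lower": self.lower, "upper": self.upper}


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------


def consecutive_similarity(
    profile_a: Trajectory,
    profile_b: Trajectory,
    delta_log_beta: float,
    config: SimilarityConfig | None = None,
) -> float:
    """Scaled L2 distance between two output profiles on the tau grid.

    Returns ``||out_a - out_b||_2 / |delta_log_beta|`` with the norm taken
    over tau in [tau_lower, tau_upper] by the trapezoid rule.  Both profiles
    must be sampled on the identical tau grid.
    """
    config = config or SimilarityConfig()
    if delta_log_beta == 0:
        raise ValueError("delta_log_beta must be nonzero")
    tau_a, tau_b = profile_a.tau_grid, profile_b.tau_grid
    if tau_a.shape != tau_b.shape or not np.allclose(tau_a, tau_b, rtol=0, atol=1e-12):
        raise ValueError("profiles must share the same tau grid")

    mask = (tau_a >= config.tau_lower - 1e-12) & (tau_a <= config.tau_upper + 1e-12)
    tau = tau_a[mask]
    out_a = profile_a.output[mask]
    out_b = profile_b.output[mask]
    if config.profile_normalized:
        out_a = out_a / out_a[0]
        out_b = out_b / out_b[0]
    integral = float(np.trapezoid((out_a - out_b) ** 2, tau))
    value = math.sqrt(integral) if config.use_sqrt else integral
    return value / abs(delta_log_beta)


# ---------------------------------------------------------------------------
# Logarithmic gain
# ---------------------------------------------------------------------------


def log_gain(
    f: Callable[[float], float],
    x0: float,
    step_log10: float = GAIN_STEP_LOG10,
) -> float:
    """Logarithmic gain d log(y) / d log(x) at x0, by central differences.

    The slope of log10 f against log10 x over a symmetric step of
    ``step_log10`` decades; exact for power laws.
    """
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    hi = f(x0 * 10.0 ** step_log10)
    lo = f(x0 * 10.0 ** (-step_log10))
    if hi <= 0 or lo <= 0:
        raise ValueError("f must be positive at both evaluation points")
    return (math.log10(hi) - math.log10(lo)) / (2.0 * step_log10)


def is_activated(g2: float, threshold: float = 0.5) -> bool:
    """Strict activation criterion on the output-layer fraction."""
    return g2 > threshold


# ---------------------------------------------------------------------------
# beta_i_max: the largest activating phosphatase rate
# ---------------------------------------------------------------------------


def _inv_g_output(eff: EffectiveParameters, beta: np.ndarray) -> float:
    return 1.0 / steady_state_gains(eff, beta).g[-1]


def beta_max(
    params,
    i: int,
    model: str = "heinrich",
    activation_threshold: float = 0.5,
    log_bracket: tuple = (-8.0, 8.0),
    rtol: float = 1e-6,
):
    """Largest value of the module-i phosphatase rate keeping g2 > threshold.

    For the Heinrich (and linearized) cascade, 1/g2 is affine in beta_i, so
    the boundary solves in closed form.  For the Huang-Ferrell model the
    phosphatase total of layer i is bisected on a log scale using steady
    states of the stimulated system.  Returns None when the cascade is not
    activated at any rate (absent).
    """
    if model in ("heinrich", "linearized"):
        eff = effective_alphas(params)
        beta = params.beta.astype(float).copy()
        target = 1.0 / activation_threshold
        b0, b1 = beta.copy(), beta.copy()
        b0[i] = 0.0
        b1[i] = 1.0
        h0 = _inv_g_output(eff, b0)
        slope = _inv_g_output(eff, b1) - h0
        if h0 >= target:
            return None  # deactivated even with no dephosphorylation in layer i
        return (target - h0) / slope

    if model != "hf":
        raise ValueError(f"unknown model {model!r}")
    lo, hi = log_bracket

    def g2_at(log_p):
        p = params.phosphatase_totals.copy()
        p[i] = 10.0 ** log_p
        ss = relaxation.hf_pre_stimulus_steady_state(params.replace(phosphatase_totals=p))
        return relaxation.hf_g2(ss, params)

    if g2_at(lo) <= activation_threshold:
        return None
    if g2_at(hi) > activation_threshold:
        return 10.0 ** hi  # activated over the whole bracket
    while hi - lo > rtol / math.log(10.0):
        mid = 0.5 * (lo + hi)
        if g2_at(mid) > activation_threshold:
            lo = mid
        else:
            hi = mid
    return 10.0 ** (0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# Linearized duration theory
# ---------------------------------------------------------------------------


def duration_approx(lin: LinearizedSolution) -> float:
    """Rate-limiting approximation of the half-life.

    With k the slowest mode, theta ~ (1/beta_k) * log(2 c_k): after the
    faster exponentials die out, the output is c_k e^{-beta_k t} and reaches
    one half at that time.  Valid only when c_k > 1/2.
    """
    k = int(np.argmin(lin.rates))
    c_k = float(lin.coefficients[k])
    if c_k <= 0.5:
        raise DurationApproxInvalid(
            f"slow-mode coefficient c_{k}={c_k:.6g} <= 1/2; approximation invalid"
        )
    return math.log(2.0 * c_k) / float(lin.rates[k])


def gain_from_coefficients(
    eff: EffectiveParameters,
    beta: Sequence[float],
    i: int,
    step_log10: float = GAIN_STEP_LOG10,
) -> float:
    """Gain of the approximated duration via the slow-mode coefficient.

    For beta_k minimal and i != k, d log(theta)/d log(beta_i) equals
    (1/(log 2 + log c_k)) * d log(c_k)/d log(beta_i); the partial is taken
    by central differences, recomputing the steady-state fractions (and
    hence the chain coefficients) at the perturbed beta_i.
    """
    beta = np.asarray(beta, dtype=float)
    k = int(np.argmin(beta))
    if i == k:
        raise ValueError("formula assumes the perturbed rate is not the minimum")

    def c_k_of(beta_i: float) -> float:
        b = beta.copy()
        b[i] = beta_i
        lin = models.linearized_solution(eff, b)
        return float(lin.coefficients[k])

    c_k = c_k_of(beta[i])
    if c_k <= 0.5:
        raise DurationApproxInvalid(
            f"slow-mode coefficient c_{k}={c_k:.6g} <= 1/2; gain formula invalid"
        )
    partial = log_gain(c_k_of, float(beta[i]), step_log10)
    return partial / (math.log(2.0) + math.log(c_k))


def check_conditions(
    eff: EffectiveParameters,
    beta: Sequence[float],
    i: int,
    fast_factor: float = 0.1,
) -> ConditionReport:
    """Evaluate the three duration-robustness conditions for module i.

    ``fast_factor`` operationalizes "beta_k much smaller than alpha_k" as
    beta_k/alpha_k < fast_factor.
    """
    alpha = eff.alpha
    beta = np.asarray(beta, dtype=float)
    n = len(beta)
    if not 0 <= i < n:
        raise ValueError(f"module index {i} out of range for {n} stages")

    others = np.delete(beta, i)
    min_other = float(np.min(others)) if len(others) else math.inf
    rate_ok = min_other < beta[i]
    rate_margin = math.log10(beta[i] / min_other) if min_other > 0 else math.inf

    product = (beta[-1] / alpha[-1]) * float(np.prod(1.0 + beta[:-1] / alpha[:-1]))
    init_ok = product < 1.0
    init_margin = 1.0 - product

    ratios = beta[i:] / alpha[i:]
    best = float(np.min(ratios))
    fast_ok = best < fast_factor
    fast_margin = math.log10(fast_factor / best)

    return ConditionReport(
        module=i,
        rate_limiting_ok=bool(rate_ok),
        initial_condition_ok=bool(init_ok),
        fast_downstream_ok=bool(fast_ok),
        rate_limiting_margin=float(rate_margin),
        initial_condition_margin=float(init_margin),
        fast_downstream_margin=float(fast_margin),
    )


# ---------------------------------------------------------------------------
# Robust intervals on sweep results
# ---------------------------------------------------------------------------


def robustness_interval(
    values: Sequence[float],
    gains: Sequence[float],
    activated: Sequence[bool],
    threshold: float = ROBUSTNESS_THRESHOLD,
) -> list:
    """Maximal contiguous sub-intervals of a sweep that are duration-robust.

    A grid point is robust when the cascade is activated there and the
    magnitude of the half-life's logarithmic gain is below ``threshold``.
    ``values`` may be in any monotone order; intervals are returned with
    lower < upper, ordered by lower edge.
    """
    values = np.asarray(values, dtype=float)
    gains = np.asarray(gains, dtype=float)
    activated = np.asarray(activated, dtype=bool)
    order = np.argsort(values)
    v, g, act = values[order], gains[order], activated[order]
    ok = act & np.isfinite(g) & (np.abs(g) < threshold)

    intervals = []
    start = None
    for j, flag in enumerate(ok):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            intervals.append(RobustInterval(float(v[start]), float(v[j - 1])))
            start = None
    if start is not None:
        intervals.append(RobustInterval(float(v[start]), float(v[-1])))
    return intervals


def min_rate_crossover(values: Sequence[float], other_rates: Sequence[float]):
    """Largest swept value at which the swept rate is the minimum of all rates.

    Marks the boundary below which the swept module is rate limiting (the
    magenta-triangle point of the duration curves).  Returns None if the
    swept rate never becomes the minimum on the grid.
    """
    values = np.asarray(values, dtype=float)
    floor = float(np.min(np.asarray(other_rates, dtype=float)))
    below = values[values < floor]
    return float(np.max(below)) if len(below) else None
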