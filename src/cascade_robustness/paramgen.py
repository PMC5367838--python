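"""Synthetic parameter generation.

The base parameter sets emulate the stated kinetic organization of a
biologically motivated MAPK cascade — fast kinase activities, phosphatase
rates organized fast-slow-fast across the three layers, and a strongly
activated pre-stimulus steady state — without reproducing any particular
published table.  Randomized ensembles for property testing are sampled
log-uniformly over declared rate ranges and filtered to constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import relaxation
from .models import CascadeParameters, HFParameters, effective_alphas, steady_state_gains

__all__ = [
    "GeneratorSpec",
    "heinrich_base",
    "hf_base",
    "random_ensemble",
]

#: Default log-uniform sampling range for rates in ensembles.
RATE_RANGE = (1e-4, 1e4)


@dataclass(frozen=True)
class GeneratorSpec:
    """Settings of the deterministic base-parameter generators.

    kinase_speed_factor is the ratio of the effective kinase activities to
    the slow phosphatase rate; activation_floor is the required output-layer
    steady-state fraction g2 of the generated set.
    """

    seed: int = 0
    organization: str = "fast-slow-fast"
    kinase_speed_factor: float = 1e5
    activation_floor: float = 0.9

    def __post_init__(self) -> None:
        if self.organization not in ("fast-slow-fast", "custom"):
            raise ValueError("organization must be 'fast-slow-fast' or 'custom'")
        if self.kinase_speed_factor <= 1:
            raise ValueError("kinase_speed_factor must exceed 1")
        if not 0 < self.activation_floor < 1:
            raise ValueError("activation_floor must lie in (0, 1)")


def _jitter(rng: np.random.Generator, half_decades: float = 0.05) -> float:
    """Multiplicative jitter within +/- half_decades in log10."""
    return 10.0 ** rng.uniform(-half_decades, half_decades)


def heinrich_base(spec: GeneratorSpec | None = None) -> CascadeParameters:
    """Three-stage Heinrich parameter set with fast-slow-fast phosphatases.

    The slow middle phosphatase sets the relaxation timescale (beta_1 = 0.01
    in inverse time units) and the flanking phosphatases are 100x faster.
    The effective kinase activities follow the abundance hierarchy of a real
    MAPK cascade: the receptor layer is driven at ``kinase_speed_factor``
    times the slow rate, the output layer a decade slower, and the middle
    layer's kinase — the scarce substrate of the layer above — only a few
    times the slow rate.  That scarcity bounds the largest activating
    middle-layer phosphatase rate near the other rates, so the rate-limiting
    module shows no duration-robust window while the flanking modules do; a
    uniformly fast kinase vector would instead open a robust window for the
    middle phosphatase as well.  The cascade is strongly activated
    (g2 > activation_floor).  Deterministic per seed; seeded jitter (under
    12% per rate) preserves the ordering constraints.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)

    beta_slow = 0.01
    beta = np.array([
        beta_slow * 100.0 * _jitter(rng),
        beta_slow,
        beta_slow * 100.0 * _jitter(rng),
    ])
    alpha_eff = beta_slow * np.array([
        spec.kinase_speed_factor * _jitter(rng),
        3.0 * _jitter(rng),
        0.1 * spec.kinase_speed_factor * _jitter(rng),
    ])
    m_tot = np.ones(3)
    # choose e0_init = alpha_eff[0] with alpha_bar_0 = 1, so the effective
    # activities are exactly alpha_eff
    e0_init = float(alpha_eff[0])
    alpha_bar = np.array([1.0, alpha_eff[1] / m_tot[0], alpha_eff[2] / m_tot[1]])

    params = CascadeParameters(alpha_bar=alpha_bar, beta=beta, m_tot=m_tot, e0_init=e0_init)
    g2 = steady_state_gains(effective_alphas(params), params.beta, params.m_tot).g_output
    if g2 <= spec.activation_floor:
        raise ValueError(
            f"generated set has g2={g2:.4f} <= activation floor "
            f"{spec.activation_floor}; increase kinase_speed_factor"
        )
    return params


def hf_base(spec: GeneratorSpec | None = None, max_tries: int = 8) -> HFParameters:
    """Huang-Ferrell parameter set with fast-slow-fast phosphatase totals.

    All ten enzymatic steps share one Michaelis-type scale (a = 1000 per
    concentration per time, d = k = 150 per time, so Km = 0.3 in
    concentration units).  Phosphatase totals are organized fast-slow-fast;
    the stimulus is scaled up by decades (a bounded search) until the
    stimulated steady state is activated, then the set is frozen.
    Deterministic per seed.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed + 1)

    a = np.full(10, 1000.0)
    d = np.full(10, 150.0)
    k = np.full(10, 150.0)
    substrate_totals = np.array([0.3, 1.2, 1.2])
    p_slow = 1e-4 * _jitter(rng)
    phosphatase_totals = np.array([100.0 * p_slow * _jitter(rng),
                                   p_slow,
                                   100.0 * p_slow * _jitter(rng)])

    e0 = 1e-3
    for _ in range(max_tries):
        params = HFParameters(
            a=a, d=d, k=k,
            substrate_totals=substrate_totals,
            phosphatase_totals=phosphatase_totals,
            e0_init=e0,
        )
        ss = relaxation.hf_pre_stimulus_steady_state(params)
        if relaxation.hf_g2(ss, params) > 0.5:
            return params
        e0 *= 10.0
    raise ValueError(
        f"no activated stimulated steady state found up to e0_init={e0:g}"
    )


def random_ensemble(
    n: int,
    seed: int = 0,
    constraints: Sequence[Callable[[CascadeParameters], bool]] = (),
    n_stages: int = 3,
    rate_range: tuple = RATE_RANGE,
    max_draw_factor: int = 100,
) -> list:
    """Random Heinrich parameter sets, log-uniform rates, constraint filtered.

    ``constraints`` is a sequence of predicates; a draw is kept only if all
    hold.  Raises if the acceptance fraction falls below 1% before ``n``
    sets are collected.  Reproducible per seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    lo, hi = math.log10(rate_range[0]), math.log10(rate_range[1])

    out: list = []
    drawn = 0
    while len(out) < n:
        if drawn >= max_draw_factor * n and len(out) < max(1, drawn // 100):
            raise RuntimeError(
                f"constraint acceptance below 1% ({len(out)}/{drawn} draws kept)"
            )
        drawn += 1
        alpha_bar = 10.0 ** rng.uniform(lo, hi, n_stages)
        beta = 10.0 ** rng.uniform(lo, hi, n_stages)
        e0 = 10.0 ** rng.uniform(lo, hi)
        params = CascadeParameters(
            alpha_bar=alpha_bar, beta=beta, m_tot=np.ones(n_stages), e0_init=e0
        )
        if all(c(params) for c in constraints):
            out.append(params)
    return out


# Common constraint predicates for random_ensemble.

def activated(threshold: float = 0.5) -> Callable[[CascadeParameters], bool]:
    def check(params: CascadeParameters) -> bool:
        g = steady_state_gains(effective_alphas(params), params.beta, params.m_tot)
        return g.g_output > threshold
    return check


def distinct_beta(rtol: float = 1e-3) -> Callable[[CascadeParameters], bool]:
    def check(params: CascadeParameters) -> bool:
        b = np.sort(params.beta)
        return bool(np.all(np.diff(b) > rtol * b[1:]))
    return check
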