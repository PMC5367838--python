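"""Cascade model definitions.

Three descriptions of a linear signaling cascade are provided:

* the Heinrich model — each layer is a phosphorylation/dephosphorylation
  cycle in which the phosphorylated substrate of layer ``i-1`` acts as the
  kinase of layer ``i``; enzyme-substrate complexes are neglected, so the
  state is just the phosphorylated concentration ``M_i^p`` per layer;
* its normalization (state divided by the pre-stimulus steady values) and
  the linearization of that normalized system about the origin, whose
  output is an exponential chain (Bateman-type) closed form;
* the Huang-Ferrell mass-action model of a three-layer MAPK cascade with
  explicit phosphatases, enzyme-substrate complexes, and double
  phosphorylation in the two downstream layers.

Units are arbitrary but must be used consistently: second-order rate
constants in concentration^-1 time^-1, first-order rates in time^-1,
concentrations in one common unit.  All derived quantities are returned in
those input units (or dimensionless).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "CascadeParameters",
    "EffectiveParameters",
    "SteadyState",
    "LinearizedSolution",
    "HFParameters",
    "HF_SPECIES",
    "HF_REACTIONS",
    "hf_state_index",
    "effective_alphas",
    "steady_state_gains",
    "heinrich_rhs",
    "normalized_rhs",
    "linearized_solution",
    "linearized_output",
    "hf_rhs",
    "hf_stimulated_initial_state",
    "hf_conserved_totals",
    "params_to_flat_dict",
    "params_from_flat_dict",
    "save_config",
    "load_config",
]

# Relative tolerance below which two dephosphorylation rates are treated as
# coincident and the confluent (t^p e^{-bt}) closed form is used.
RATE_TIE_RTOL = 1e-9


def _as_positive_array(
    values: Sequence[float], name: str, n: int, allow_zero: bool = False
) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0 if allow_zero else arr <= 0):
        kind = "nonnegative" if allow_zero else "strictly positive"
        raise ValueError(f"{name} entries must be {kind} and finite")
    return arr


@dataclass(frozen=True)
class CascadeParameters:
    """Kinetic constants and totals of an N-stage Heinrich cascade.

    Parameters
    ----------
    alpha_bar : second-order kinase rate constants, one per layer.
    beta : first-order phosphatase rates, one per layer.
    m_tot : total substrate concentration per layer.
    e0_init : receptor/stimulus concentration applied for t < 0.
    """

    alpha_bar: np.ndarray
    beta: np.ndarray
    m_tot: np.ndarray
    e0_init: float

    def __post_init__(self) -> None:
        n = len(self.alpha_bar)
        if n < 1:
            raise ValueError("cascade needs at least one stage")
        object.__setattr__(self, "alpha_bar", _as_positive_array(self.alpha_bar, "alpha_bar", n))
        object.__setattr__(self, "beta", _as_positive_array(self.beta, "beta", n))
        object.__setattr__(self, "m_tot", _as_positive_array(self.m_tot, "m_tot", n))
        if not (np.isfinite(self.e0_init) and self.e0_init >= 0):
            raise ValueError("e0_init must be nonnegative and finite")

    @property
    def n_stages(self) -> int:
        return len(self.beta)

    def replace(self, **kwargs) -> "CascadeParameters":
        data = {
            "alpha_bar": self.alpha_bar.copy(),
            "beta": self.beta.copy(),
            "m_tot": self.m_tot.copy(),
            "e0_init": self.e0_init,
        }
        data.update(kwargs)
        return CascadeParameters(**data)


@dataclass(frozen=True)
class EffectiveParameters:
    """Effective first-order kinase activities alpha_i (time^-1).

    alpha_0 = alpha_bar_0 * E0_init, alpha_i = alpha_bar_i * M_{i-1}^tot.
    """

    alpha: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.alpha, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("alpha must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("alpha entries must be nonnegative and finite")
        object.__setattr__(self, "alpha", arr)

    @property
    def n_stages(self) -> int:
        return len(self.alpha)


@dataclass(frozen=True)
class SteadyState:
    """Pre-stimulus steady state: concentrations M~_i and fractions g_i."""

    m_tilde: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "m_tilde", np.asarray(self.m_tilde, dtype=float))
        object.__setattr__(self, "g", np.asarray(self.g, dtype=float))

    @property
    def g_output(self) -> float:
        """Activation level of the output layer (g_2 for a 3-stage cascade)."""
        return float(self.g[-1])


def effective_alphas(params: CascadeParameters) -> EffectiveParameters:
    """Effective kinase activities of the Heinrich cascade.

    The second-order kinase constants are folded with the (constant) kinase
    concentration seen by each layer: the stimulus for layer 0, the total
    substrate of the layer above for layers i >= 1.
    """
    alpha = np.empty(params.n_stages)
    alpha[0] = params.alpha_bar[0] * params.e0_init
    if params.n_stages > 1:
        alpha[1:] = params.alpha_bar[1:] * params.m_tot[:-1]
    return EffectiveParameters(alpha=alpha)


def steady_state_gains(
    eff: EffectiveParameters,
    beta: Sequence[float],
    m_tot: Sequence[float] | None = None,
) -> SteadyState:
    """Pre-stimulus steady state by forward iteration down the cascade.

    g_0 = 1 / (1 + beta_0/alpha_0), g_i = 1 / (1 + (beta_i/alpha_i)/g_{i-1}).
    The fractions only depend on upstream parameters; the concentrations are
    M~_i = g_i * M_i^tot (totals default to 1).
    """
    alpha = eff.alpha
    beta = np.asarray(beta, dtype=float)
    if beta.shape != alpha.shape:
        raise ValueError("alpha and beta must have equal lengths")
    if np.any(alpha <= 0):
        raise ValueError("effective kinase activities must be strictly positive")
    if np.any(beta < 0):
        raise ValueError("phosphatase rates must be nonnegative")
    if m_tot is None:
        m_tot = np.ones_like(alpha)
    m_tot = np.asarray(m_tot, dtype=float)

    g = np.empty_like(alpha)
    g_prev = 1.0  # the stimulus is fully "active"
    for i in range(len(alpha)):
        g[i] = 1.0 / (1.0 + (beta[i] / alpha[i]) / g_prev)
        g_prev = g[i]
    return SteadyState(m_tilde=g * m_tot, g=g)


def heinrich_rhs(t: float, state: np.ndarray, params: CascadeParameters) -> np.ndarray:
    """Post-stimulus Heinrich dynamics for the phosphorylated forms.

    dM_0^p/dt = -beta_0 M_0^p;
    dM_i^p/dt = alpha_bar_i M_{i-1}^p (M_i^tot - M_i^p) - beta_i M_i^p.

    Substrate conservation (M_i + M_i^p = M_i^tot) is built in; the inactive
    forms are never integrated.
    """
    state = np.asarray(state, dtype=float)
    d = np.empty_like(state)
    d[0] = -params.beta[0] * state[0]
    for i in range(1, params.n_stages):
        d[i] = (
            params.alpha_bar[i] * state[i - 1] * (params.m_tot[i] - state[i])
            - params.beta[i] * state[i]
        )
    return d


def normalized_rhs(
    t: float,
    state: np.ndarray,
    eff: EffectiveParameters,
    beta: Sequence[float],
    gains: SteadyState,
) -> np.ndarray:
    """Normalized post-stimulus dynamics, m_i^p = M_i^p / M~_i, m_i^p(0) = 1.

    dm_0^p/dt = -beta_0 m_0^p;
    dm_i^p/dt = alpha_i g_{i-1} m_{i-1}^p (1/g_i - m_i^p) - beta_i m_i^p.
    """
    beta = np.asarray(beta, dtype=float)
    g = gains.g
    if np.any(g == 0):
        raise ValueError("normalized model undefined for zero steady-state fraction")
    state = np.asarray(state, dtype=float)
    d = np.empty_like(state)
    d[0] = -beta[0] * state[0]
    for i in range(1, len(beta)):
        d[i] = (
            eff.alpha[i] * g[i - 1] * state[i - 1] * (1.0 / g[i] - state[i])
            - beta[i] * state[i]
        )
    return d


# ---------------------------------------------------------------------------
# Linearized model: exponential-chain closed form
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearizedSolution:
    """Closed-form output of the linearized normalized cascade.

    The output layer solves a chain of first-order linear ODEs, so it is a
    combination of ``t^p exp(-r t)`` terms.  For pairwise-distinct rates the
    polynomials are constants ``c_i`` with sum 1 (the normalized initial
    condition); coincident rates produce the confluent ``t exp(-r t)`` terms.

    Attributes
    ----------
    rates : the phosphatase rates beta_i, as supplied.
    terms : list of (rate, poly) pairs; ``poly[p]`` multiplies ``t^p e^{-rate t}``.
    """

    rates: np.ndarray
    terms: tuple

    @property
    def is_degenerate(self) -> bool:
        return any(len(poly) > 1 for _, poly in self.terms)

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients c_i aligned with ``rates`` (pairwise-distinct case).

        Raises for degenerate (tied-rate) solutions, where per-rate constants
        do not characterize the solution.
        """
        if self.is_degenerate:
            raise ValueError("coefficients undefined for coincident rates; use terms")
        by_rate = {rate: poly[0] for rate, poly in self.terms}
        out = np.empty(len(self.rates))
        for i, b in enumerate(self.rates):
            # map each input rate to its representative term
            match = min(by_rate, key=lambda r: abs(r - b))
            out[i] = by_rate[match]
        return out

    def evaluate(self, t):
        """Value of the normalized output m_{N-1}^p at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for rate, poly in self.terms:
            out = out + np.polynomial.polynomial.polyval(t, poly) * np.exp(-rate * t)
        return out if out.shape else float(out)


def _advance_chain(terms: dict, beta: float, amp: float) -> dict:
    """Solve dm/dt = -beta m + amp * f(t), m(0) = 1, for f a sum of
    polynomial-times-exponential terms; returns the new term dict
    {rate: {degree: coeff}}."""
    new: dict = {}

    def add(rate, deg, coef):
        new.setdefault(rate, {})
        new[rate][deg] = new[rate].get(deg, 0.0) + coef

    hom = 1.0  # coefficient of e^{-beta t} from the initial condition
    for r, poly in terms.items():
        mu = beta - r
        if abs(mu) <= RATE_TIE_RTOL * max(abs(beta), abs(r)):
            # resonant forcing: integral of s^p gives t^{p+1}/(p+1)
            for p, c in poly.items():
                add(beta, p + 1, amp * c / (p + 1))
        else:
            for p, c in poly.items():
                for q in range(p + 1):
                    coeff = ((-1.0) ** (p - q)) * math.factorial(p) / math.factorial(q)
                    add(r, q, amp * c * coeff / mu ** (p - q + 1))
                hom -= amp * c * ((-1.0) ** p) * math.factorial(p) / mu ** (p + 1)
    add(beta, 0, hom)
    return new


def _group_rates(beta: np.ndarray) -> np.ndarray:
    """Snap rates that coincide within RATE_TIE_RTOL to a shared representative."""
    rep = beta.astype(float).copy()
    for i in range(len(rep)):
        for j in range(i):
            if abs(rep[i] - rep[j]) <= RATE_TIE_RTOL * max(abs(rep[i]), abs(rep[j])):
                rep[i] = rep[j]
                break
    return rep

def linearized_solution(
    eff: EffectiveParameters,
    beta: Sequence[float],
    gains: SteadyState | None = None,
) -> LinearizedSolution:
    """Closed-form output of the cascade linearized about the origin.

    Linearization drops the saturation term of the normalized model, giving
    dm_i^p/dt = (alpha_i g_{i-1}/g_i) m_{i-1}^p - beta_i m_i^p with
    m_i^p(0) = 1.  The output layer is then the Bateman-type chain solution.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != eff.alpha.shape:
        raise ValueError("alpha and beta must have equal lengths")
    if gains is None:
        gains = steady_state_gains(eff, beta)
    g = gains.g

    rep = _group_rates(beta)
    terms = {rep[0]: {0: 1.0}}
    for i in range(1, len(beta)):
        amp = eff.alpha[i] * g[i - 1] / g[i]
        terms = _advance_chain(terms, rep[i], amp)

    packed = tuple(
        (rate, np.array([poly.get(p, 0.0) for p in range(max(poly) + 1)]))
        for rate, poly in sorted(terms.items())
    )
    return LinearizedSolution(rates=beta, terms=packed)


def linearized_output(
    t,
    eff: EffectiveParameters,
    beta: Sequence[float],
    gains: SteadyState | None = None,
):
    """Normalized output m_{N-1}^p(t) of the linearized cascade."""
    return linearized_solution(eff, beta, gains).evaluate(t)


# ---------------------------------------------------------------------------
# Huang-Ferrell mass-action model
# ---------------------------------------------------------------------------

#: State-vector species ordering: free substrates in every phosphorylation
#: state, free enzymes, then the 10 enzyme-substrate complexes in reaction
#: order.
HF_SPECIES = (
    "M0", "M0p",
    "M1", "M1p", "M1pp",
    "M2", "M2p", "M2pp",
    "E0", "P0", "P1", "P2",
    "E0_M0", "P0_M0p",
    "M0p_M1", "M0p_M1p", "P1_M1pp", "P1_M1p",
    "M1pp_M2", "M1pp_M2p", "P2_M2pp", "P2_M2p",
)

_IDX = {name: i for i, name in enumerate(HF_SPECIES)}

#: The 10 enzymatic steps (enzyme, substrate, product, complex).  Layer 0 has
#: one phosphorylation (by E0) and one dephosphorylation (by P0); layers 1 and
#: 2 each have two of each, reflecting double phosphorylation.
HF_REACTIONS = (
    ("E0", "M0", "M0p", "E0_M0"),
    ("P0", "M0p", "M0", "P0_M0p"),
    ("M0p", "M1", "M1p", "M0p_M1"),
    ("M0p", "M1p", "M1pp", "M0p_M1p"),
    ("P1", "M1pp", "M1p", "P1_M1pp"),
    ("P1", "M1p", "M1", "P1_M1p"),
    ("M1pp", "M2", "M2p", "M1pp_M2"),
    ("M1pp", "M2p", "M2pp", "M1pp_M2p"),
    ("P2", "M2pp", "M2p", "P2_M2pp"),
    ("P2", "M2p", "M2", "P2_M2p"),
)


def hf_state_index(name: str) -> int:
    """Index of a species in the Huang-Ferrell state vector."""
    return _IDX[name]


@dataclass(frozen=True)
class HFParameters:
    """Huang-Ferrell rate constants and totals.

    Each of the 10 enzymatic steps E + S <->(a, d) ES ->(k) E + P carries an
    association rate ``a`` (conc^-1 time^-1), dissociation rate ``d`` and
    catalytic rate ``k`` (time^-1), indexed in ``HF_REACTIONS`` order.
    """

    a: np.ndarray
    d: np.ndarray
    k: np.ndarray
    substrate_totals: np.ndarray
    phosphatase_totals: np.ndarray
    e0_init: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", _as_positive_array(self.a, "a", 10))
        object.__setattr__(self, "d", _as_positive_array(self.d, "d", 10))
        object.__setattr__(self, "k", _as_positive_array(self.k, "k", 10))
        object.__setattr__(
            self, "substrate_totals",
            _as_positive_array(self.substrate_totals, "substrate_totals", 3),
        )
        # the no-dephosphorylation limit (zero phosphatase) is admitted
        object.__setattr__(
            self, "phosphatase_totals",
            _as_positive_array(self.phosphatase_totals, "phosphatase_totals", 3,
                               allow_zero=True),
        )
        if not (np.isfinite(self.e0_init) and self.e0_init >= 0):
            raise ValueError("e0_init must be nonnegative and finite")

    def replace(self, **kwargs) -> "HFParameters":
        data = {
            "a": self.a.copy(), "d": self.d.copy(), "k": self.k.copy(),
            "substrate_totals": self.substrate_totals.copy(),
            "phosphatase_totals": self.phosphatase_totals.copy(),
            "e0_init": self.e0_init,
        }
        data.update(kwargs)
        return HFParameters(**data)


def hf_rhs(t: float, state: np.ndarray, params: HFParameters) -> np.ndarray:
    """Mass-action derivatives of the full Huang-Ferrell state."""
    x = np.asarray(state, dtype=float)
    d = np.zeros_like(x)
    for j, (enz, sub, prod, cplx) in enumerate(HF_REACTIONS):
        e, s, p, c = _IDX[enz], _IDX[sub], _IDX[prod], _IDX[cplx]
        bind = params.a[j] * x[e] * x[s]
        unbind = params.d[j] * x[c]
        cat = params.k[j] * x[c]
        d[c] += bind - unbind - cat
        d[e] += -bind + unbind + cat
        d[s] += -bind + unbind
        d[p] += cat
    return d


def hf_stimulated_initial_state(params: HFParameters) -> np.ndarray:
    """All substrate unphosphorylated, all enzymes free, stimulus applied."""
    x = np.zeros(len(HF_SPECIES))
    x[_IDX["M0"]], x[_IDX["M1"]], x[_IDX["M2"]] = params.substrate_totals
    x[_IDX["E0"]] = params.e0_init
    x[_IDX["P0"]], x[_IDX["P1"]], x[_IDX["P2"]] = params.phosphatase_totals
    return x


#: Species participating in each conservation law (substrate per layer and
#: each enzyme, counting every complex containing the molecule).
HF_CONSERVATIONS = {
    "M0": ("M0", "M0p", "E0_M0", "P0_M0p", "M0p_M1", "M0p_M1p"),
    "M1": ("M1", "M1p", "M1pp", "M0p_M1", "M0p_M1p", "P1_M1pp", "P1_M1p",
           "M1pp_M2", "M1pp_M2p"),
    "M2": ("M2", "M2p", "M2pp", "M1pp_M2", "M1pp_M2p", "P2_M2pp", "P2_M2p"),
    "E0": ("E0", "E0_M0"),
    "P0": ("P0", "P0_M0p"),
    "P1": ("P1", "P1_M1pp", "P1_M1p"),
    "P2": ("P2", "P2_M2pp", "P2_M2p"),
}


def hf_conserved_totals(state: np.ndarray) -> dict:
    """Evaluate every conservation-law total on a state vector."""
    x = np.asarray(state, dtype=float)
    return {
        key: float(sum(x[_IDX[s]] for s in species))
        for key, species in HF_CONSERVATIONS.items()
    }


# ---------------------------------------------------------------------------
# Flat-key config I/O
# ---------------------------------------------------------------------------


def params_to_flat_dict(params) -> dict:
    """Serialize a parameter set to flat string keys (``beta.0``, ``a.1``...)."""
    if isinstance(params, CascadeParameters):
        out = {"model": "heinrich"}
        for i in range(params.n_stages):
            out[f"alpha_bar.{i}"] = float(params.alpha_bar[i])
            out[f"beta.{i}"] = float(params.beta[i])
            out[f"m_tot.{i}"] = float(params.m_tot[i])
        out["e0_init"] = float(params.e0_init)
        return out
    if isinstance(params, HFParameters):
        out = {"model": "hf"}
        for j in range(10):
            out[f"a.{j + 1}"] = float(params.a[j])
            out[f"d.{j + 1}"] = float(params.d[j])
            out[f"k.{j + 1}"] = float(params.k[j])
        for i in range(3):
            out[f"substrate_tot.{i}"] = float(params.substrate_totals[i])
            out[f"p_tot.{i}"] = float(params.phosphatase_totals[i])
        out["e0_init"] = float(params.e0_init)
        return out
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def params_from_flat_dict(data: dict):
    """Inverse of :func:`params_to_flat_dict`."""
    kind = data.get("model", "heinrich")
    if kind in ("heinrich", "linearized"):
        stages = sorted(int(k.split(".")[1]) for k in data if k.startswith("beta."))
        n = len(stages)
        if stages != list(range(n)):
            raise ValueError("beta.* keys must cover 0..n-1")
        return CascadeParameters(
            alpha_bar=[data[f"alpha_bar.{i}"] for i in range(n)],
            beta=[data[f"beta.{i}"] for i in range(n)],
            m_tot=[data.get(f"m_tot.{i}", 1.0) for i in range(n)],
            e0_init=data["e0_init"],
        )
    if kind == "hf":
        return HFParameters(
            a=[data[f"a.{j}"] for j in range(1, 11)],
            d=[data[f"d.{j}"] for j in range(1, 11)],
            k=[data[f"k.{j}"] for j in range(1, 11)],
            substrate_totals=[data[f"substrate_tot.{i}"] for i in range(3)],
            phosphatase_totals=[data[f"p_tot.{i}"] for i in range(3)],
            e0_init=data["e0_init"],
        )
    raise ValueError(f"unknown model kind {kind!r}")


def save_config(params, path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_flat_dict(params), sort_keys=True))


def load_config(path):
    return params_from_flat_dict(yaml.safe_load(Path(path).read_text()))
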