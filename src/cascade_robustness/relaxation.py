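"""Stimulus-on / stimulus-removed relaxation protocol.

A constant stimulus is applied until the cascade reaches its activated
steady state; at t = 0 the stimulus is removed and the system relaxes
toward the deactivated state.  This module produces output trajectories on
a logarithmic time grid and measures the response duration, defined as the
half-life: the first time at which the output falls to half its
pre-stimulus steady value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import models
from .models import (
    CascadeParameters,
    HFParameters,
    SteadyState,
    effective_alphas,
    steady_state_gains,
)

__all__ = [
    "TauGrid",
    "Trajectory",
    "RelaxationResult",
    "HalfLifeUnresolved",
    "SteadyStateNotConverged",
    "MODELS",
    "pre_stimulus_steady_state",
    "simulate_relaxation",
    "relax",
    "half_life",
]

#: Supported model names.
MODELS = ("heinrich", "linearized", "hf")

#: Default log10-time sampling window; the upper bound is log10(6e4).
TAU_LOWER = -2.0
TAU_UPPER = 4.0 + math.log10(6.0)

#: Integrator defaults: stiff-capable, tight tolerances.
RTOL = 1e-8
ATOL = 1e-12

#: Default half-life search horizon (= 10^TAU_UPPER) and the factor by which
#: it may be extended when the output has not yet crossed one half.
HORIZON = 6.0e4
HORIZON_EXTENSION = 100.0


class HalfLifeUnresolved(RuntimeError):
    """The output never fell to half its initial value within the horizon."""


class SteadyStateNotConverged(RuntimeError):
    """Stimulated integration did not converge to a steady state."""


@dataclass(frozen=True)
class TauGrid:
    """Uniform grid in tau = log10(t)."""

    lower: float = TAU_LOWER
    upper: float = TAU_UPPER
    n: int = 600

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("require lower < upper")
        if self.n < 2:
            raise ValueError("need at least two grid points")

    @property
    def tau(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n)

    @property
    def times(self) -> np.ndarray:
        return 10.0 ** self.tau


@dataclass(frozen=True)
class Trajectory:
    """Output time course sampled on a log-time grid.

    ``output`` is the response variable: M2p for the Heinrich model, the
    normalized m2p for the linearized model, and free M2pp for Huang-Ferrell.
    """

    tau_grid: np.ndarray
    times: np.ndarray
    output: np.ndarray
    full_state: Optional[np.ndarray] = None
    model: str = "heinrich"

    def to_frame(self) -> pd.DataFrame:
        data = {"tau": self.tau_grid, "t": self.times, "output": self.output}
        if self.full_state is not None:
            if self.model == "hf":
                names = models.HF_SPECIES
            else:
                names = [f"state_{i}" for i in range(self.full_state.shape[0])]
            for i, name in enumerate(names):
                data[name] = self.full_state[i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


@dataclass(frozen=True)
class RelaxationResult:
    """Trajectory plus the scalar summaries of one relaxation run."""

    trajectory: Trajectory
    steady: object  # SteadyState, or the HF steady state vector
    duration: Optional[float]
    activated: bool
    g_output: float
    output_initial: float


# ---------------------------------------------------------------------------
# Pre-stimulus steady states
# ---------------------------------------------------------------------------


def _check_model(model: str) -> None:
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def hf_g2(state: np.ndarray, params: HFParameters, include_bound: bool = False) -> float:
    """Output-layer activation fraction for a Huang-Ferrell state."""
    m2pp = state[models.hf_state_index("M2pp")]
    if include_bound:
        m2pp = m2pp + state[models.hf_state_index("P2_M2pp")]
    return float(m2pp / params.substrate_totals[2])


def hf_pre_stimulus_steady_state(
    params: HFParameters,
    tol: float = 1e-9,
    horizon_cap: float = 1.0e9,
) -> np.ndarray:
    """Integrate the stimulated Huang-Ferrell system to steady state.

    Integration proceeds over doubling time windows until the maximum
    relative state change across a window falls below ``tol`` (concentrations
    below atol are compared absolutely).  Non-convergence within the horizon
    cap raises with the residual.
    """
    x = models.hf_stimulated_initial_state(params)
    t0, t1 = 0.0, 100.0
    scale = float(np.max(params.substrate_totals))
    while True:
        sol = solve_ivp(
            models.hf_rhs, (t0, t1), x, args=(params,),
            method="BDF", rtol=RTOL, atol=ATOL * scale,
        )
        if not sol.success:
            raise SteadyStateNotConverged(f"integrator failure: {sol.message}")
        x_new = sol.y[:, -1]
        denom = np.maximum(np.abs(x_new), 1e-12 * scale)
        residual = float(np.max(np.abs(x_new - x) / denom))
        x = x_new
        if residual < tol:
            return x
        if t1 >= horizon_cap:
            raise SteadyStateNotConverged(
                f"no steady state by t={t1:g}; max relative residual {residual:.3e}"
            )
        t0, t1 = t1, t1 * 2.0


def pre_stimulus_steady_state(model: str, params, **kwargs):
    """Steady state under constant stimulus, per model.

    Heinrich and linearized cascades admit the forward-iteration closed form;
    the Huang-Ferrell steady state is found by integrating the stimulated
    mass-action system until the state stops changing.
    """
    _check_model(model)
    if model == "hf":
        return hf_pre_stimulus_steady_state(params, **kwargs)
    eff = effective_alphas(params)
    return steady_state_gains(eff, params.beta, params.m_tot)


# ---------------------------------------------------------------------------
# Relaxation simulation
# ---------------------------------------------------------------------------


def _hf_remove_stimulus(state: np.ndarray, mode: str = "hard") -> np.ndarray:
    """Remove the stimulus from a Huang-Ferrell state at t = 0.

    ``hard``: free E0 and the E0.M0 complex are removed; the substrate bound
    in that complex returns to the free unphosphorylated pool, preserving
    substrate conservation.  ``free_only``: only free E0 is removed and
    existing complexes turn over normally.
    """
    x = np.asarray(state, dtype=float).copy()
    i_e0 = models.hf_state_index("E0")
    i_c = models.hf_state_index("E0_M0")
    i_m0 = models.hf_state_index("M0")
    x[i_e0] = 0.0
    if mode == "hard":
        x[i_m0] += x[i_c]
        x[i_c] = 0.0
    elif mode != "free_only":
        raise ValueError("stimulus_removal must be 'hard' or 'free_only'")
    return x


def _integrate(rhs, y0, times, args, horizon, method="LSODA", scale=1.0):
    t_end = max(horizon, float(times[-1]) if len(times) else 0.0)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, args=args, method=method,
        rtol=RTOL, atol=ATOL * scale, dense_output=True,
        t_eval=np.asarray(times, dtype=float),
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol


def simulate_relaxation(
    model: str,
    params,
    grid: TauGrid | None = None,
    steady=None,
    stimulus_removal: str = "hard",
    include_bound_output: bool = False,
    keep_full_state: bool = True,
) -> Trajectory:
    """Integrate the post-stimulus system and sample the output on the grid.

    The initial condition is the stimulated steady state; for the Heinrich
    model the stimulus simply no longer appears in the equations, for the
    Huang-Ferrell model the receptor is removed per ``stimulus_removal``.
    """
    _check_model(model)
    grid = grid or TauGrid()
    times = grid.times

    if model == "heinrich":
        ss = steady if steady is not None else pre_stimulus_steady_state(model, params)
        sol = _integrate(
            models.heinrich_rhs, ss.m_tilde, times, (params,),
            horizon=times[-1], scale=float(np.max(params.m_tot)),
        )
        full = sol.y
        output = full[-1]
    elif model == "linearized":
        ss = steady if steady is not None else pre_stimulus_steady_state(model, params)
        eff = effective_alphas(params)
        lin = models.linearized_solution(eff, params.beta, ss)
        output = lin.evaluate(times)
        full = None
    else:
        ss = steady if steady is not None else pre_stimulus_steady_state(model, params)
        y0 = _hf_remove_stimulus(ss, stimulus_removal)
        sol = _integrate(
            models.hf_rhs, y0, times, (params,),
            horizon=times[-1], method="BDF",
            scale=float(np.max(params.substrate_totals)),
        )
        full = sol.y
        output = full[models.hf_state_index("M2pp")]
        if include_bound_output:
            output = output + full[models.hf_state_index("P2_M2pp")]

    return Trajectory(
        tau_grid=grid.tau, times=times, output=np.asarray(output, dtype=float),
        full_state=full if keep_full_state else None, model=model,
    )


# ---------------------------------------------------------------------------
# Half-life
# ---------------------------------------------------------------------------


def _first_crossing(f, target, horizon, t_floor=1e-12, n_scan=2000):
    """Bracket and refine the first downward crossing of ``target``.

    Scans a log-spaced grid for the first sign change of f(t) - target, then
    refines with Brent's method to relative tolerance 1e-8.
    """
    ts = np.geomspace(t_floor, horizon, n_scan)
    vals = f(ts) - target
    if vals[0] <= 0:
        # output already at/below half at the scan floor; refine toward 0
        return float(brentq(lambda t: f(t) - target, 0.0, ts[0], rtol=1e-10))
    idx = np.nonzero(vals <= 0)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    root = brentq(lambda t: f(t) - target, ts[i - 1], ts[i], rtol=1e-8)
    return float(root)


def half_life(
    model: str,
    params,
    steady=None,
    horizon: float = HORIZON,
    stimulus_removal: str = "hard",
    include_bound_output: bool = False,
) -> float:
    """Response duration: first t > 0 with output(t) = half its initial value.

    Raises :class:`HalfLifeUnresolved` if the output has not crossed one half
    by ``horizon`` extended by the allowed factor.
    """
    _check_model(model)
    if model == "linearized":
        ss = steady if steady is not None else pre_stimulus_steady_state(model, params)
        lin = models.linearized_solution(effective_alphas(params), params.beta, ss)
        f, target = lin.evaluate, 0.5
    elif model == "heinrich":
        ss = steady if steady is not None else pre_stimulus_steady_state(model, params)
        sol = _integrate(
            models.heinrich_rhs, ss.m_tilde, [], (params,),
            horizon=horizon * HORIZON_EXTENSION,
            scale=float(np.max(params.m_tot)),
        )
        f = lambda t: sol.sol(t)[-1]
        target = 0.5 * float(ss.m_tilde[-1])
    else:
        ss = steady if steady is not None else pre_stimulus_steady_state(model, params)
        y0 = _hf_remove_stimulus(ss, stimulus_removal)
        sol = _integrate(
            models.hf_rhs, y0, [], (params,),
            horizon=horizon * HORIZON_EXTENSION, method="BDF",
            scale=float(np.max(params.substrate_totals)),
        )
        i_out = models.hf_state_index("M2pp")
        i_bound = models.hf_state_index("P2_M2pp")

        def f(t):
            y = sol.sol(t)
            out = y[i_out]
            return out + y[i_bound] if include_bound_output else out

        target = 0.5 * float(f(0.0))

    root = _first_crossing(f, target, horizon)
    if root is None:
        root = _first_crossing(f, target, horizon * HORIZON_EXTENSION)
    if root is None:
        raise HalfLifeUnresolved(
            f"output did not reach half its initial value by "
            f"t={horizon * HORIZON_EXTENSION:g}"
        )
    return root


def relax(
    model: str,
    params,
    grid: TauGrid | None = None,
    activation_threshold: float = 0.5,
    horizon: float = HORIZON,
    stimulus_removal: str = "hard",
    include_bound_output: bool = False,
) -> RelaxationResult:
    """Full protocol: steady state, relaxation trajectory, half-life, activation."""
    _check_model(model)
    steady = pre_stimulus_steady_state(model, params)
    if model == "hf":
        g_out = hf_g2(steady, params, include_bound_output)
        out0 = g_out * float(params.substrate_totals[2])
    else:
        g_out = steady.g_output
        out0 = 1.0 if model == "linearized" else float(steady.m_tilde[-1])
    traj = simulate_relaxation(
        model, params, grid=grid, steady=steady,
        stimulus_removal=stimulus_removal,
        include_bound_output=include_bound_output,
    )
    try:
        theta = half_life(
            model, params, steady=steady, horizon=horizon,
            stimulus_removal=stimulus_removal,
            include_bound_output=include_bound_output,
        )
    except HalfLifeUnresolved:
        theta = None
    return RelaxationResult(
        trajectory=traj, steady=steady, duration=theta,
        activated=g_out > activation_threshold,
        g_output=g_out, output_initial=out0,
    )
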