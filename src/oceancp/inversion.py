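"""Bayesian tracer-misfit objective and parameter optimization.

The objective is the negative log posterior (up to a constant) over six
observed tracer fields,

    f = 1/2 * sum_x  e_x' W_x e_x,
    x in {DIP, DOP, DIC, DOC, ALK, O2},

where ``e_x`` is model minus observation on observed boxes, bulk model
DOC is the sum of the three modelled DOC pools, and ``W_x`` is a
diagonal precision matrix proportional to grid-box volume (so every
cubic metre of ocean counts equally) and inversely proportional to the
tracer's error variance.  Priors beyond parameter bounds are flat in
the log of each (positive) parameter.

Optimization is a bounded quasi-Newton search with finite differences
in log-parameter space — adequate at desk scale, where a forward solve
is a few sparse factorizations.  Failed forward solves return a large
penalty rather than raising, so the search is robust to excursions
into infeasible corners of parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize

from .element_cycles import (
    CycleParameters,
    ParameterDomainError,
    SolverDiagnosticError,
    solve_equilibrium,
)
from .grid_transport import Grid
from .synthetic_ocean import ForcingFields, ObservationSet, OBSERVED_TRACERS

__all__ = [
    "ObjectiveBreakdown",
    "OptimizationResult",
    "precision_weights",
    "objective",
    "make_objective",
    "optimize",
    "goodness_of_fit",
    "PENALTY_VALUE",
]

PENALTY_VALUE = 1.0e12


@dataclass
class ObjectiveBreakdown:
    """Objective value with per-tracer terms and solver diagnostics."""

    total: float
    terms: dict[str, float]
    params: CycleParameters
    failed: bool = False
    failure_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.failed:
            assert all(v >= 0 for v in self.terms.values())


@dataclass
class OptimizationResult:
    """Outcome of a parameter search."""

    best_params: CycleParameters
    best_f: float
    trace: pd.DataFrame          # columns: iteration, f, one per free parameter
    converged: bool
    n_evaluations: int
    seed: int | None = None
    free_names: tuple[str, ...] = ()

    def best_values(self) -> dict[str, float]:
        return {k: float(getattr(self.best_params, k)) for k in self.free_names}


def precision_weights(
    grid: Grid,
    obs: ObservationSet,
    per_tracer_variance: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Diagonal precision weights per tracer.

    ``W_x[i] = V_i / (sigma_x^2 * V_obs)`` on observed boxes and zero
    exactly where the observation is missing; ``V_obs`` is the total
    observed volume for the tracer, making each term a volume-weighted
    mean squared misfit over the observed ocean.  The default variance
    is the volume-weighted variance of the observations themselves
    (config-exposed through ``per_tracer_variance``).
    """
    weights: dict[str, np.ndarray] = {}
    v = grid.box_volume
    for x in obs.tracers():
        mask = obs.observed[x]
        if per_tracer_variance and x in per_tracer_variance:
            var = float(per_tracer_variance[x])
        else:
            vals = obs.values[x][mask]
            w = v[mask]
            mean = float(np.average(vals, weights=w))
            var = float(np.average((vals - mean) ** 2, weights=w))
            if var == 0.0:
                var = max(mean**2, 1.0)
        if var <= 0:
            raise ValueError(f"variance for tracer {x!r} must be positive")
        v_obs = float(v[mask].sum())
        w_x = np.zeros(grid.n_boxes)
        w_x[mask] = v[mask] / (var * v_obs)
        weights[x] = w_x
    return weights


def objective(
    params: CycleParameters,
    A: sp.spmatrix,
    forcing: ForcingFields,
    obs: ObservationSet,
    grid: Grid,
    weights: dict[str, np.ndarray] | None = None,
    tracers: tuple[str, ...] = OBSERVED_TRACERS,
) -> ObjectiveBreakdown:
    """Evaluate the misfit objective at ``params``.

    Runs the phosphorus then carbon steady-state solves and accumulates
    ``1/2 e' W e`` per tracer.  ``tracers`` can restrict the sum (e.g.
    to the phosphorus tracers for a P-only inversion).  A failed solve
    returns ``PENALTY_VALUE`` with a failure flag instead of raising.
    """
    if weights is None:
        weights = precision_weights(grid, obs)
    try:
        params.validate()
        state = solve_equilibrium(params, A, forcing, grid)
    except (ParameterDomainError, SolverDiagnosticError, RuntimeError) as exc:
        return ObjectiveBreakdown(
            total=PENALTY_VALUE,
            terms={},
            params=params,
            failed=True,
            failure_reason=str(exc),
        )
    terms: dict[str, float] = {}
    for x in tracers:
        model = state.bulk_doc() if x == "DOC" else state.concentrations[x]
        e = model - obs.values[x]
        terms[x] = 0.5 * float(e @ (weights[x] * e))
    return ObjectiveBreakdown(total=sum(terms.values()), terms=terms, params=params)


def make_objective(A, forcing, obs, grid, tracers=OBSERVED_TRACERS):
    """Bind data into a callable ``params -> ObjectiveBreakdown``."""
    weights = precision_weights(grid, obs)

    def fn(params: CycleParameters) -> ObjectiveBreakdown:
        return objective(params, A, forcing, obs, grid, weights, tracers)

    return fn


def optimize(
    objective_fn,
    initial: CycleParameters,
    free_names: tuple[str, ...],
    bounds: dict[str, tuple[float, float]] | None = None,
    budget: int = 500,
    seed: int | None = None,
    f_tol: float = 1.0e-12,
) -> OptimizationResult:
    """Minimize the objective over a subset of parameters.

    Searches in log-transformed parameter space (all optimizable
    parameters are positive) with L-BFGS-B and finite-difference
    gradients, within ``bounds`` (defaulting to the registry bounds on
    ``initial``) and an evaluation ``budget``.  Exhausting the budget
    without convergence flags the result rather than raising.
    Deterministic; ``seed`` is recorded for provenance.
    """
    bounds = bounds or initial.bounds
    missing = [n for n in free_names if n not in bounds]
    if missing:
        raise ValueError(f"no bounds registered for parameters {missing}")
    x0 = np.array([float(getattr(initial, n)) for n in free_names])
    lo = np.array([bounds[n][0] for n in free_names])
    hi = np.array([bounds[n][1] for n in free_names])
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("initial parameters outside bounds")
    lo = np.maximum(lo, 1e-30)  # log-space search needs positive bounds
    x0 = np.maximum(x0, lo)

    trace_rows: list[dict] = []
    n_eval = 0

    class _BudgetExhausted(Exception):
        pass

    def f_log(z: np.ndarray) -> float:
        nonlocal n_eval
        if n_eval >= budget:
            raise _BudgetExhausted
        vals = np.exp(z)
        params = initial.replace(**{n: float(val) for n, val in zip(free_names, vals)})
        bd = objective_fn(params)
        n_eval += 1
        row = {"iteration": n_eval, "f": bd.total}
        row.update({n: float(val) for n, val in zip(free_names, vals)})
        trace_rows.append(row)
        return bd.total

    f0 = f_log(np.log(x0))
    if f0 <= f_tol:
        trace = pd.DataFrame(trace_rows)
        return OptimizationResult(
            best_params=initial, best_f=f0, trace=trace, converged=True,
            n_evaluations=n_eval, seed=seed, free_names=tuple(free_names),
        )

    exhausted = False
    try:
        res = minimize(
            f_log,
            np.log(x0),
            method="L-BFGS-B",
            bounds=list(zip(np.log(lo), np.log(hi))),
            options={"maxfun": max(budget - 1, 1), "ftol": 1e-14, "gtol": 1e-12},
        )
    except _BudgetExhausted:
        exhausted = True
        res = None
    trace = pd.DataFrame(trace_rows)
    i_best = int(trace["f"].idxmin())
    best_row = trace.loc[i_best]
    best_params = initial.replace(
        **{n: float(best_row[n]) for n in free_names}
    )
    converged = (res is not None and bool(res.success) and not exhausted) or (
        float(best_row["f"]) <= f_tol
    )
    return OptimizationResult(
        best_params=best_params,
        best_f=float(best_row["f"]),
        trace=trace,
        converged=converged,
        n_evaluations=n_eval,
        seed=seed,
        free_names=tuple(free_names),
    )


def goodness_of_fit(
    model_field: np.ndarray, obs_field: np.ndarray, weights: np.ndarray
) -> float:
    """Volume-weighted coefficient of determination R^2.

    ``1 - sum(w e^2) / sum(w (obs - mean_w(obs))^2)`` over boxes with
    positive weight; requires at least two observed boxes and nonzero
    observation variance.
    """
    w = np.asarray(weights, float)
    mask = w > 0
    if mask.sum() < 2:
        raise ValueError("need at least two observed boxes")
    w = w[mask]
    y = np.asarray(obs_field, float)[mask]
    m = np.asarray(model_field, float)[mask]
    ybar = float(np.average(y, weights=w))
    ss_tot = float(w @ (y - ybar) ** 2)
    if ss_tot == 0:
        raise ValueError("observations have zero variance")
    ss_err = float(w @ (m - y) ** 2)
    return 1.0 - ss_err / ss_tot
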