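"""Constrained performance optimization by projected gradient descent.

The planner optimizes an action/plan vector ``u`` of length m by
minimizing ``J(u) = -P(u) + beta * R(u)``, trading a scalar performance
score P (to be maximized) against a predicted injury-risk score R,
subject to biomechanical feasibility constraints: elementwise box bounds
``u_min <= u <= u_max``, an optional smoothness budget on the update
step ``||u - u_prev||_2 <= delta``, and differentiable inequality
penalties ``g_j(u) <= 0`` (squared hinge).  Each iteration takes a
gradient step (gradients via the package's reverse-mode automatic
differentiation) and projects back onto the feasible set, box first and
smoothness ball second.  That composition is exact whenever only one of
the two constraints is active, which is how the packaged test problems
are constructed; it is documented as a composition, not an exact
projection onto the intersection.

This module is a conceptual extension: it formalizes a reproducible
solver for future datasets with controllable action variables and is
not validated against any empirical athletic-performance outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .exceptions import ConfigurationError, ContractError, SolverError

Scalar = Callable[[Tensor], Tensor]


@dataclass
class ConstraintSet:
    u_min: np.ndarray | None = None
    u_max: np.ndarray | None = None
    smoothness_delta: float | None = None     # ||u_t+1 - u_t||_2 budget
    inequalities: list[Scalar] = field(default_factory=list)

    def __post_init__(self):
        if self.u_min is not None and self.u_max is not None:
            lo = np.asarray(self.u_min, dtype=np.float64)
            hi = np.asarray(self.u_max, dtype=np.float64)
            if np.any(lo > hi):
                raise ConfigurationError("u_min must be <= u_max elementwise")
        if self.smoothness_delta is not None and self.smoothness_delta < 0:
            raise ConfigurationError("smoothness budget must be >= 0")


@dataclass
class PomObjective:
    performance: Scalar                       # P(u), maximized
    risk: Scalar                              # R(u), penalized
    beta: float = 1.0
    step_size: float = 0.05
    max_iterations: int = 500
    tolerance: float = 1e-10
    backtracking: bool = False                # halve the step on J increase

    def __post_init__(self):
        if self.beta <= 0:
            raise ConfigurationError("beta must be > 0")
        if self.step_size <= 0:
            raise ConfigurationError("step_size must be > 0")


def objective(u, obj: PomObjective) -> float:
    """J(u) = -P(u) + beta * R(u)."""
    t = u if isinstance(u, Tensor) else Tensor(np.asarray(u, dtype=np.float64))
    value = (-obj.performance(t) + obj.beta * obj.risk(t)).item()
    if not np.isfinite(value):
        raise SolverError(f"objective non-finite at u = {t.data}")
    return value


def project_box(u: np.ndarray, u_min=None, u_max=None) -> np.ndarray:
    """Elementwise clamp onto the box; idempotent."""
    return np.clip(u, -np.inf if u_min is None else u_min,
                   np.inf if u_max is None else u_max)


def project_smoothness(u: np.ndarray, u_prev: np.ndarray,
                       delta: float) -> np.ndarray:
    """Scale the step back onto the radius-delta ball around u_prev."""
    if delta < 0:
        raise ConfigurationError("delta must be >= 0")
    step = u - u_prev
    norm = float(np.linalg.norm(step))
    if norm <= delta:
        return u
    if norm == 0.0:
        return u_prev.copy()
    return u_prev + delta * step / norm


@dataclass
class SolveTrace:
    u: np.ndarray
    objective_trace: list[float]
    iterates: list[np.ndarray]
    converged: bool
    feasible_box: bool
    feasible_inequalities: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": range(len(self.objective_trace)),
                             "objective": self.objective_trace})


def _grad(obj: PomObjective, u_val: np.ndarray) -> tuple[float, np.ndarray]:
    u = Tensor(u_val.copy(), requires_grad=True)
    J = -obj.performance(u) + obj.beta * obj.risk(u)
    if not np.isfinite(J.data).all():
        raise SolverError(f"objective non-finite at u = {u_val}")
    J.backward()
    return float(J.data), u.grad.astype(np.float64)


def pgd_solve(obj: PomObjective, constraints: ConstraintSet,
              u0: np.ndarray) -> SolveTrace:
    """Iterate u <- Pi_C(u - eta * grad J(u)) until the objective change
    drops below tolerance or the iteration budget is spent."""
    u = np.asarray(u0, dtype=np.float64).copy()
    if not np.isfinite(u).all():
        raise ContractError("u0 must be finite")
    u = project_box(u, constraints.u_min, constraints.u_max)
    eta = obj.step_size
    J_prev, _ = _grad(obj, u)
    trace = [J_prev]
    iterates = [u.copy()]
    converged = False
    for _ in range(obj.max_iterations):
        _, g = _grad(obj, u)
        candidate = u - eta * g
        candidate = project_box(candidate, constraints.u_min,
                                constraints.u_max)
        if constraints.smoothness_delta is not None:
            candidate = project_smoothness(candidate, u,
                                           constraints.smoothness_delta)
        J_new, _ = _grad(obj, candidate)
        if obj.backtracking and J_new > J_prev:
            eta *= 0.5
            continue
        u = candidate
        trace.append(J_new)
        iterates.append(u.copy())
        if abs(J_new - J_prev) < obj.tolerance:
            converged = True
            J_prev = J_new
            break
        J_prev = J_new
    feasible_box = bool(
        (constraints.u_min is None or np.all(u >= np.asarray(constraints.u_min) - 1e-12))
        and (constraints.u_max is None or np.all(u <= np.asarray(constraints.u_max) + 1e-12)))
    feasible_ineq = all(float(g(Tensor(u.copy())).data) <= 1e-9
                        for g in constraints.inequalities)
    return SolveTrace(u=u, objective_trace=trace, iterates=iterates,
                      converged=converged, feasible_box=feasible_box,
                      feasible_inequalities=feasible_ineq)


# -- penalty and auxiliary losses -------------------------------------------

def constraint_penalty(values) -> float:
    """Sum of squared hinge penalties: sum_i max(0, c_i)^2."""
    c = np.asarray(values, dtype=np.float64)
    return float(np.sum(np.maximum(0.0, c) ** 2))


def torque_violation(predicted_torque: float, torque_limit: float) -> float:
    """c = tau - tau_max; positive values feed constraint_penalty."""
    return float(predicted_torque - torque_limit)


def symmetry_loss(force_left, force_right) -> float:
    """Squared Euclidean distance between bilateral force vectors."""
    left = np.asarray(force_left, dtype=np.float64)
    right = np.asarray(force_right, dtype=np.float64)
    if left.shape != right.shape:
        raise ContractError(f"force vectors must match: {left.shape} vs "
                            f"{right.shape}")
    return float(np.sum((left - right) ** 2))


def total_loss(l_risk: float, l_performance: float, l_constraints: float,
               lam: float, mu: float) -> float:
    """L_total = L_risk + lambda * L_performance + mu * L_constraints."""
    if lam < 0 or mu < 0:
        raise ConfigurationError("lambda and mu must be >= 0")
    return float(l_risk + lam * l_performance + mu * l_constraints)


def iterative_refine(values: np.ndarray, gradient_fn, eta: float,
                     steps: int) -> np.ndarray:
    """Generic value-refinement: v <- v - eta * dL/dv for a fixed number
    of steps (gradient descent applied directly to prediction values)."""
    if eta <= 0:
        raise ConfigurationError("eta must be > 0")
    v = np.asarray(values, dtype=np.float64).copy()
    for _ in range(steps):
        g = np.asarray(gradient_fn(v), dtype=np.float64)
        if not np.isfinite(g).all():
            raise SolverError(f"non-finite gradient at v = {v}")
        v = v - eta * g
    return v


# -- named test functions for problem files ---------------------------------

def _as_vec(x, m: int) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    return np.full(m, float(arr)) if arr.ndim == 0 else arr


def make_named_function(spec: dict, m: int) -> Scalar:
    """Build a P or R callable from a problem-file entry.

    Supported names: ``neg_quadratic`` (P = -sum a*(u-c)^2),
    ``quadratic`` (sum a*(u-c)^2), ``linear`` (sum w*u), ``zero``.
    """
    name = spec.get("name")
    if name == "zero":
        return lambda u: (u * 0.0).sum()
    if name == "linear":
        w = Tensor(_as_vec(spec.get("weights", 1.0), m))
        return lambda u: (u * w).sum()
    if name in ("quadratic", "neg_quadratic"):
        a = Tensor(_as_vec(spec.get("scale", 1.0), m))
        c = Tensor(_as_vec(spec.get("center", 0.0), m))
        sign = -1.0 if name == "neg_quadratic" else 1.0
        return lambda u: (((u - c) ** 2) * a).sum() * sign
    raise ConfigurationError(f"unknown function name {name!r}")


def solve_problem_dict(problem: dict) -> SolveTrace:
    """Solve a problem described by a parsed YAML/JSON mapping."""
    try:
        m = int(problem["dimension"])
        u0 = _as_vec(problem.get("u0", 0.0), m)
        obj = PomObjective(
            performance=make_named_function(problem["performance"], m),
            risk=make_named_function(problem.get("risk", {"name": "zero"}), m),
            beta=float(problem.get("beta", 1.0)),
            step_size=float(problem.get("step_size", 0.05)),
            max_iterations=int(problem.get("max_iterations", 500)),
            tolerance=float(problem.get("tolerance", 1e-12)),
            backtracking=bool(problem.get("backtracking", False)))
        constraints = ConstraintSet(
            u_min=_as_vec(problem["bounds"][0], m) if "bounds" in problem else None,
            u_max=_as_vec(problem["bounds"][1], m) if "bounds" in problem else None,
            smoothness_delta=problem.get("smoothness_delta"))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed problem description: {exc}") \
            from exc
    return pgd_solve(obj, constraints, u0)
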