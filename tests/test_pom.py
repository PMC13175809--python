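"""Constrained-optimizer correctness against analytic KKT solutions."""

import numpy as np
import pytest

from kneemil.autodiff import Tensor
from kneemil.exceptions import ConfigurationError, ContractError, SolverError
from kneemil.pom import (ConstraintSet, PomObjective, constraint_penalty,
                         iterative_refine, objective, pgd_solve, project_box,
                         project_smoothness, solve_problem_dict,
                         symmetry_loss, torque_violation, total_loss)


def quad_obj(performance, risk, **kwargs):
    defaults = dict(beta=1.0, step_size=0.05, max_iterations=2000,
                    tolerance=1e-14)
    defaults.update(kwargs)
    return PomObjective(performance=performance, risk=risk, **defaults)


# -- objective ---------------------------------------------------------------

def test_objective_arithmetic_and_beta_monotonicity():
    obj = quad_obj(lambda u: u.sum(), lambda u: (u ** 2.0).sum(), beta=1.0)
    assert objective(np.array([2.0]), obj) == pytest.approx(-2.0 + 4.0)
    zero = quad_obj(lambda u: u.sum() * 0.0, lambda u: u.sum() * 0.0)
    assert objective(np.array([5.0]), zero) == 0.0
    doubled = quad_obj(lambda u: u.sum(), lambda u: (u ** 2.0).sum(), beta=2.0)
    assert objective(np.array([2.0]), doubled) > objective(np.array([2.0]), obj)


def test_objective_validates_hyperparameters():
    with pytest.raises(ConfigurationError):
        quad_obj(lambda u: u.sum(), lambda u: u.sum(), beta=0.0)
    with pytest.raises(ConfigurationError):
        quad_obj(lambda u: u.sum(), lambda u: u.sum(), step_size=-1.0)


# -- projections -------------------------------------------------------------

def test_box_projection_clamps_and_is_idempotent():
    u = np.array([1.5, -0.2, 0.7])
    out = project_box(u, 0.0, 1.0)
    np.testing.assert_array_equal(out, [1.0, 0.0, 0.7])
    np.testing.assert_array_equal(project_box(out, 0.0, 1.0), out)


def test_smoothness_projection_scales_345_vector():
    out = project_smoothness(np.array([3.0, 4.0]), np.zeros(2), 1.0)
    np.testing.assert_allclose(out, [0.6, 0.8])
    within = project_smoothness(np.array([0.1, 0.1]), np.zeros(2), 1.0)
    np.testing.assert_array_equal(within, [0.1, 0.1])


@pytest.mark.parametrize("seed", range(5))
def test_smoothness_projection_never_exceeds_budget(seed):
    rng = np.random.default_rng(seed)
    u_prev = rng.normal(size=4)
    u = rng.normal(size=4, scale=5)
    delta = float(rng.uniform(0, 2))
    out = project_smoothness(u, u_prev, delta)
    assert np.linalg.norm(out - u_prev) <= delta + 1e-12


def test_inconsistent_bounds_rejected():
    with pytest.raises(ConfigurationError):
        ConstraintSet(u_min=np.array([1.0]), u_max=np.array([0.0]))


# -- PGD against analytic optima ---------------------------------------------

def test_boundary_active_quadratic_reaches_upper_bound():
    # maximize -(u-2)^2 over [0, 1]: the optimum sits at the boundary u = 1
    obj = quad_obj(lambda u: -((u - 2.0) ** 2.0).sum(),
                   lambda u: u.sum() * 0.0, step_size=0.1, max_iterations=500)
    trace = pgd_solve(obj, ConstraintSet(u_min=np.zeros(1), u_max=np.ones(1)),
                      np.array([0.5]))
    assert abs(trace.u[0] - 1.0) < 1e-6
    assert trace.feasible_box


def test_interior_stationary_point_with_risk_term():
    # minimize (u-0.5)^2 + 0.1 u: stationary at u = 0.45, interior of [0, 1]
    obj = quad_obj(lambda u: -((u - 0.5) ** 2.0).sum(), lambda u: u.sum(),
                   beta=0.1, step_size=0.1, max_iterations=2000)
    trace = pgd_solve(obj, ConstraintSet(u_min=np.zeros(1), u_max=np.ones(1)),
                      np.array([0.0]))
    assert abs(trace.u[0] - 0.45) < 1e-6


@pytest.mark.parametrize("center, scale, lo, hi", [
    (np.array([0.3, 0.8]), np.array([1.0, 2.0]), 0.0, 1.0),
    (np.array([-1.0, 2.0]), np.array([0.5, 1.5]), 0.0, 1.0),
    (np.array([5.0, -3.0]), np.array([2.0, 1.0]), -1.0, 1.0),
])
def test_2d_quadratics_match_kkt_clamped_solution(center, scale, lo, hi):
    # minimize sum_i scale_i (u_i - center_i)^2 over a box: the KKT point
    # clamps each coordinate of the unconstrained optimum to the box
    obj = quad_obj(lambda u: -(((u - Tensor(center)) ** 2.0)
                               * Tensor(scale)).sum(),
                   lambda u: u.sum() * 0.0, step_size=0.05,
                   max_iterations=3000)
    constraints = ConstraintSet(u_min=np.full(2, lo), u_max=np.full(2, hi))
    trace = pgd_solve(obj, constraints, np.zeros(2))
    np.testing.assert_allclose(trace.u, np.clip(center, lo, hi), atol=1e-6)


def test_objective_trace_non_increasing_for_small_steps():
    obj = quad_obj(lambda u: -((u - 0.7) ** 2.0).sum(),
                   lambda u: u.sum() * 0.0, step_size=0.02,
                   max_iterations=300)
    trace = pgd_solve(obj, ConstraintSet(u_min=np.zeros(3), u_max=np.ones(3)),
                      np.array([0.0, 0.5, 1.0]))
    diffs = np.diff(trace.objective_trace)
    assert np.all(diffs <= 1e-12)


def test_smoothness_constraint_limits_each_step():
    obj = quad_obj(lambda u: -((u - 10.0) ** 2.0).sum(),
                   lambda u: u.sum() * 0.0, step_size=0.4, max_iterations=50,
                   tolerance=0.0)
    trace = pgd_solve(obj, ConstraintSet(smoothness_delta=0.25),
                      np.array([0.0]))
    steps = np.abs(np.diff([it[0] for it in trace.iterates]))
    assert np.all(steps <= 0.25 + 1e-12)


def test_divergent_objective_raises_solver_error():
    obj = quad_obj(lambda u: (u ** 2.0).sum() * 1e30,
                   lambda u: u.sum() * 0.0,
                   step_size=10.0, max_iterations=500)
    with pytest.raises(SolverError):
        pgd_solve(obj, ConstraintSet(), np.array([1e30]))


# -- penalties and auxiliary losses ------------------------------------------

def test_constraint_penalty_squared_hinge():
    assert constraint_penalty([-1.0, -0.5]) == 0.0
    assert constraint_penalty([1.0, -2.0, 0.5]) == pytest.approx(1.25)
    assert constraint_penalty(np.random.default_rng(0).normal(size=10)) >= 0


def test_torque_violation_values():
    assert torque_violation(10.0, 12.0) == -2.0
    assert torque_violation(15.0, 12.0) == 3.0
    assert constraint_penalty([torque_violation(15.0, 12.0)]) == 9.0
    assert torque_violation(12.0, 12.0) == 0.0


def test_symmetry_loss_is_squared_distance_and_symmetric():
    assert symmetry_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert symmetry_loss([1.0, 0.0], [0.0, 1.0]) == 2.0
    assert symmetry_loss([1.0, 3.0], [2.0, 0.0]) == \
        symmetry_loss([2.0, 0.0], [1.0, 3.0])
    with pytest.raises(ContractError):
        symmetry_loss([1.0], [1.0, 2.0])


def test_total_loss_weighted_sum():
    assert total_loss(1.0, 2.0, 3.0, lam=0.5, mu=0.1) == pytest.approx(2.3)
    assert total_loss(1.0, 2.0, 3.0, lam=0.0, mu=0.0) == 1.0


def test_iterative_refine_descends_quadratic():
    out = iterative_refine(np.array([1.0]), lambda v: 2.0 * v, eta=0.1,
                           steps=1)
    np.testing.assert_allclose(out, [0.8])
    unchanged = iterative_refine(np.array([3.0]), lambda v: 0.0 * v, eta=0.1,
                                 steps=10)
    np.testing.assert_allclose(unchanged, [3.0])
    values = [np.array([1.0])]
    for _ in range(20):
        values.append(iterative_refine(values[-1], lambda v: 2.0 * v,
                                       eta=0.1, steps=1))
    losses = [float(v[0] ** 2) for v in values]
    assert all(a > b for a, b in zip(losses, losses[1:]))


# -- problem files -----------------------------------------------------------

def test_problem_dict_solves_bundled_quadratic():
    trace = solve_problem_dict({
        "dimension": 1,
        "performance": {"name": "neg_quadratic", "center": 0.5},
        "risk": {"name": "linear", "weights": 1.0},
        "beta": 0.1, "bounds": [0.0, 1.0], "u0": 0.0,
        "step_size": 0.1, "max_iterations": 2000, "tolerance": 1e-14})
    assert abs(trace.u[0] - 0.45) < 1e-6
    assert len(trace.objective_trace) == len(trace.iterates)


def test_malformed_problem_dict_raises_configuration_error():
    with pytest.raises(ConfigurationError):
        solve_problem_dict({"performance": {"name": "neg_quadratic"}})
    with pytest.raises(ConfigurationError):
        solve_problem_dict({"dimension": 1,
                            "performance": {"name": "nope"}})
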