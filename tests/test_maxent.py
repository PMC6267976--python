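import numpy as np
import pytest

import cwmcats as cc
from cwmcats.errors import ConvergenceError, InfeasibleConstraintError, ValidationError

from conftest import grid_entropy_oracle


@pytest.mark.parametrize(
    "p, expected",
    [
        ([1.0, 0.0, 0.0], 0.0),
        ([0.5, 0.5], np.log(2)),
        ([0.2] * 5, np.log(5)),
    ],
)
def test_entropy_closed_forms(p, expected):
    assert cc.entropy(p) == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_negative():
    with pytest.raises(ValidationError):
        cc.entropy([-0.1, 1.1])


def test_uniform_at_centroid(grass_traits):
    t = grass_traits.data.to_numpy()
    sol = cc.solve_maxent(cc.MaxEntProblem(traits=t, constraints=t.mean(axis=0)))
    np.testing.assert_allclose(sol.p, np.full(5, 0.2), atol=1e-8)
    assert sol.entropy == pytest.approx(np.log(5), abs=1e-8)


def test_two_species_single_constraint_determined():
    sol = cc.solve_maxent(cc.MaxEntProblem(traits=[[0.0], [1.0]], constraints=[0.7]))
    np.testing.assert_allclose(sol.p, [0.3, 0.7], atol=1e-8)


def test_three_species_grid_oracle():
    traits = np.array([[0.0], [1.0], [2.0]])
    sol = cc.solve_maxent(cc.MaxEntProblem(traits=traits, constraints=[0.5]))
    oracle = grid_entropy_oracle(traits, np.array([0.5]), step=1e-3)
    assert sol.entropy >= oracle - 1e-6
    assert sol.residuals.max() <= 1e-8
    # forced by the constraint: p1 + 2 p2 = 0.5 and exponential-family form
    assert sol.p[0] > sol.p[1] > sol.p[2]


def test_random_problems_beat_grid_oracle():
    """Solver entropy >= exhaustive-grid entropy on random small problems."""
    rng = np.random.default_rng(2024)
    for _ in range(25):
        s = rng.integers(2, 5)
        j = rng.integers(1, 3)
        traits = rng.normal(0, 1, (s, j))
        target = traits.T @ rng.dirichlet(np.ones(s))
        sol = cc.solve_maxent(cc.MaxEntProblem(traits=traits, constraints=target))
        oracle = grid_entropy_oracle(traits, target, step=4e-3)
        assert oracle is not None
        assert sol.entropy >= oracle - 1e-6
        assert sol.residuals.max() <= 1e-6


@pytest.mark.parametrize(
    "target, feasible, proj, dist",
    [
        (0.5, True, 0.5, 0.0),
        (1.5, False, 1.0, 0.5),
        (-0.25, False, 0.0, 0.25),
    ],
)
def test_feasibility_interval(target, feasible, proj, dist):
    problem = cc.MaxEntProblem(
        traits=[[0.0], [1.0]], constraints=[target], standardize=False
    )
    rep = cc.check_feasibility(problem)
    assert rep.feasible == feasible
    assert rep.projected_constraints[0] == pytest.approx(proj, abs=1e-6)
    assert rep.distance == pytest.approx(dist, abs=1e-6)


def test_centroid_always_feasible(grass_traits):
    t = grass_traits.data.to_numpy()
    rep = cc.check_feasibility(cc.MaxEntProblem(traits=t, constraints=t.mean(axis=0)))
    assert rep.feasible


def test_infeasible_error_carries_projection_report(grass_traits):
    t = grass_traits.data.to_numpy()
    bad = t.max(axis=0) * 2.0
    with pytest.raises(InfeasibleConstraintError) as exc:
        cc.solve_maxent(cc.MaxEntProblem(traits=t, constraints=bad))
    assert exc.value.report.distance > 0
    sol = cc.solve_maxent(
        cc.MaxEntProblem(traits=t, constraints=bad), on_infeasible="project"
    )
    assert sol.projection is not None
    np.testing.assert_allclose(
        t.T @ sol.p, sol.projection.projected_constraints, atol=1e-6
    )


def test_affine_rescaling_invariance(grass_traits):
    """Rescaling a trait column (and its target) leaves p unchanged."""
    t = grass_traits.data.to_numpy().copy()
    rng = np.random.default_rng(5)
    target = t.T @ rng.dirichlet(np.ones(5))
    sol = cc.solve_maxent(cc.MaxEntProblem(traits=t, constraints=target))
    t2 = t.copy()
    target2 = target.copy()
    t2[:, 1] = 3.5 * t2[:, 1] + 40.0
    target2[1] = 3.5 * target2[1] + 40.0
    sol2 = cc.solve_maxent(cc.MaxEntProblem(traits=t2, constraints=target2))
    np.testing.assert_allclose(sol.p, sol2.p, atol=1e-8)


def test_monotone_constraint_tradeoff():
    """Pushing the target toward one species' trait raises that species' p."""
    traits = np.array([[0.0], [0.4], [1.0]])
    last = 0.0
    for target in np.linspace(0.47, 0.95, 12):
        sol = cc.solve_maxent(cc.MaxEntProblem(traits=traits, constraints=[target]))
        assert sol.p[2] > last
        last = sol.p[2]


def test_duplicate_trait_vectors_share_abundance():
    traits = np.array([[1.0, 5.0], [1.0, 5.0], [3.0, 2.0]])
    target = traits.T @ np.array([0.25, 0.25, 0.5])
    sol = cc.solve_maxent(cc.MaxEntProblem(traits=traits, constraints=target))
    assert sol.p[0] == pytest.approx(sol.p[1], abs=1e-10)


def test_fully_constrained_matches_linear_algebra():
    """With J = S-1 independent constraints the simplex point is unique."""
    rng = np.random.default_rng(9)
    traits = rng.normal(0, 1, (3, 2))
    p_true = rng.dirichlet(np.ones(3))
    target = traits.T @ p_true
    sol = cc.solve_maxent(cc.MaxEntProblem(traits=traits, constraints=target))
    a = np.vstack([np.ones(3), traits.T])
    p_lin = np.linalg.solve(a, np.concatenate([[1.0], target]))
    np.testing.assert_allclose(sol.p, p_lin, atol=1e-7)
    np.testing.assert_allclose(sol.p, p_true, atol=1e-7)


def test_nonuniform_prior_recovered_without_constraints_pull():
    """At the prior's own CWM target, maxent returns the prior."""
    traits = np.array([[0.0], [1.0], [2.0]])
    prior = np.array([0.5, 0.3, 0.2])
    target = traits.T @ prior
    sol = cc.solve_maxent(
        cc.MaxEntProblem(traits=traits, constraints=target, prior=prior)
    )
    np.testing.assert_allclose(sol.p, prior, atol=1e-8)


def test_solution_invariants(grass_traits):
    rng = np.random.default_rng(13)
    t = grass_traits.data.to_numpy()
    target = t.T @ rng.dirichlet(np.ones(5))
    sol = cc.solve_maxent(cc.MaxEntProblem(traits=t, constraints=target))
    assert sol.p.min() >= 0
    assert sol.p.sum() == pytest.approx(1.0, abs=1e-9)
    assert sol.entropy == pytest.approx(cc.entropy(sol.p), abs=1e-10)
    assert sol.converged


def test_nonconvergence_raises():
    with pytest.raises(ConvergenceError):
        cc.solve_maxent(
            cc.MaxEntProblem(traits=[[0.0], [1.0]], constraints=[0.99999]),
            tol=1e-14,
            max_iter=2,
        )
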