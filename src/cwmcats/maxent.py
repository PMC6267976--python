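"""Maximum-entropy prediction of species relative abundances (the CATS core).

Given a species pool with trait vectors :math:`t_i` and target
community-weighted means :math:`\\bar T_j`, find the relative-abundance
distribution :math:`p` that maximizes the Shannon entropy
:math:`H(p) = -\\sum_i p_i \\ln p_i` subject to

    sum_i p_i t_{ij} = Tbar_j   (j = 1..J),   sum_i p_i = 1,   p_i >= 0.

The maximizer has exponential-family form
``p_i ∝ prior_i * exp(sum_j lambda_j t~_ij)`` and is found by minimizing the
convex dual in the Lagrange multipliers ``lambda`` with damped Newton steps
(log-sum-exp stabilized). Trait columns are z-standardized over the species
pool before solving — the solution is provably invariant to affine
rescaling of any trait, but standardization makes a single convergence
tolerance meaningful across traits measured in mg, m g^-1 and Julian days.

A constraint vector is attainable only if it lies in the convex hull of the
pool's trait vectors; :func:`check_feasibility` tests this exactly (linear
program) and, when infeasible, reports the Euclidean projection onto the
hull and its distance so callers can diagnose — or deliberately adopt —
the nearest attainable constraints (``on_infeasible="project"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize
from scipy.special import logsumexp

from .errors import (
    ConvergenceError,
    InfeasibleConstraintError,
    ValidationError,
)

_SIMPLEX_ATOL = 1e-9


def entropy(p) -> float:
    """Shannon entropy -sum p ln p in nats, with 0 ln 0 := 0."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError("entropy requires nonnegative probabilities")
    if not np.isclose(p.sum(), 1.0, atol=1e-6, rtol=0):
        raise ValidationError(f"probabilities sum to {p.sum()}, not 1")
    pz = p[p > 0]
    return float(-(pz * np.log(pz)).sum())


@dataclass(frozen=True)
class MaxEntProblem:
    """Trait matrix, CWM constraint targets, and an optional prior.

    ``traits`` is S x J (species by trait), ``constraints`` length J in the
    same units. ``prior`` defaults to uniform — the classical unweighted
    maxent; a metacommunity-abundance prior can be supplied but is off by
    default. ``standardize`` controls whether columns are z-scored before
    solving (recommended; the solution is invariant to it).
    """

    traits: np.ndarray
    constraints: np.ndarray
    prior: np.ndarray = None
    species: tuple = None
    trait_names: tuple = None
    standardize: bool = True

    def __post_init__(self):
        traits = np.atleast_2d(np.asarray(self.traits, dtype=float))
        constraints = np.atleast_1d(np.asarray(self.constraints, dtype=float))
        object.__setattr__(self, "traits", traits)
        object.__setattr__(self, "constraints", constraints)
        s, j = traits.shape
        if s < 2:
            raise ValidationError("need at least 2 species")
        if j < 1 or constraints.shape != (j,):
            raise ValidationError(
                f"constraints shape {constraints.shape} does not match {j} trait(s)"
            )
        if not (np.isfinite(traits).all() and np.isfinite(constraints).all()):
            raise ValidationError("traits and constraints must be finite")
        if self.prior is None:
            object.__setattr__(self, "prior", np.full(s, 1.0 / s))
        else:
            prior = np.asarray(self.prior, dtype=float)
            if prior.shape != (s,) or (prior < 0).any() or not np.isclose(
                prior.sum(), 1.0, atol=_SIMPLEX_ATOL, rtol=0
            ):
                raise ValidationError("prior must be a length-S simplex vector")
            object.__setattr__(self, "prior", prior)
        if self.species is not None:
            object.__setattr__(self, "species", tuple(self.species))
        if self.trait_names is not None:
            object.__setattr__(self, "trait_names", tuple(self.trait_names))

    @property
    def n_species(self) -> int:
        return self.traits.shape[0]

    @property
    def n_constraints(self) -> int:
        return self.traits.shape[1]

    def _standardized(self):
        """(Z, zbar, scale): working trait matrix and targets.

        Constant trait columns carry no usable constraint direction and are
        dropped here; their targets are reconciled in feasibility checking.
        """
        t = self.traits
        tbar = self.constraints
        if not self.standardize:
            keep = np.ptp(t, axis=0) > 0
            return t[:, keep], tbar[keep], np.ones(keep.sum()), keep
        mu = t.mean(axis=0)
        sd = t.std(axis=0, ddof=1) if t.shape[0] > 1 else np.ones(t.shape[1])
        keep = sd > 0
        z = (t[:, keep] - mu[keep]) / sd[keep]
        zbar = (tbar[keep] - mu[keep]) / sd[keep]
        return z, zbar, sd[keep], keep


@dataclass(frozen=True)
class FeasibilityReport:
    feasible: bool
    projected_constraints: np.ndarray  # raw trait units, length J
    distance: float  # Euclidean distance in the working (standardized) space
    projection_weights: np.ndarray = field(default=None, repr=False)


@dataclass(frozen=True)
class MaxEntSolution:
    """Solver output: the predicted simplex vector plus diagnostics."""

    p: np.ndarray
    lambdas: np.ndarray  # duals per standardized trait column
    log_partition: float
    entropy: float
    residuals: np.ndarray  # |Z^T p - zbar| per constraint, standardized units
    raw_residuals: np.ndarray  # |T^T p - Tbar| per constraint, trait units
    converged: bool
    iterations: int
    projection: FeasibilityReport = None
    species: tuple = None


def check_feasibility(problem: MaxEntProblem, tol: float = 1e-8) -> FeasibilityReport:
    """Is the constraint vector inside the convex hull of the trait vectors?

    Exact membership is decided by a linear program; when infeasible the
    report carries the Euclidean projection of the target onto the hull
    (computed in the working trait space) and the projection distance.
    """
    z, zbar, scale, keep = problem._standardized()
    s = problem.n_species
    # constant trait columns: target must equal the constant
    dropped = ~keep
    drop_miss = 0.0
    if dropped.any():
        consts = problem.traits[0, dropped]
        drop_miss = float(
            np.abs(problem.constraints[dropped] - consts).max(initial=0.0)
        )

    if z.shape[1] == 0:
        feasible = drop_miss <= tol
        return FeasibilityReport(
            feasible,
            problem.traits[0, :].copy() if dropped.all() else problem.constraints.copy(),
            drop_miss,
            np.full(s, 1.0 / s),
        )

    a_eq = np.vstack([np.ones((1, s)), z.T])
    b_eq = np.concatenate([[1.0], zbar])
    lp = linprog(
        c=np.zeros(s),
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=[(0, None)] * s,
        method="highs",
    )
    if lp.status == 0 and drop_miss <= tol:
        return FeasibilityReport(True, problem.constraints.copy(), 0.0, lp.x)

    # Euclidean projection of zbar onto the hull: min ||Z^T w - zbar||^2 on the simplex
    def obj(w):
        r = z.T @ w - zbar
        return r @ r

    def grad(w):
        return 2.0 * z @ (z.T @ w - zbar)

    res = minimize(
        obj,
        np.full(s, 1.0 / s),
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * s,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()
    proj_raw = problem.traits.T @ w
    dist = float(np.hypot(np.sqrt(obj(w)), drop_miss))
    feasible = dist <= tol
    return FeasibilityReport(feasible, proj_raw, dist, w)


def _dual_newton(z, zbar, log_prior, tol, max_iter):
    """Minimize logZ(lam) - lam.zbar by damped Newton with log-sum-exp."""
    j = z.shape[1]
    lam = np.zeros(j)

    def value_state(lam):
        logits = log_prior + z @ lam
        lz = logsumexp(logits)
        p = np.exp(logits - lz)
        return lz - lam @ zbar, p

    f, p = value_state(lam)
    it = 0
    for it in range(1, max_iter + 1):
        g = z.T @ p - zbar
        if np.abs(g).max() <= tol:
            return lam, p, True, it - 1
        m1 = z.T @ p
        h = (z.T * p) @ z - np.outer(m1, m1)
        # ridge keeps the step defined when constraints push p to a face
        ridge = 1e-12 * max(1.0, np.trace(h) / j)
        try:
            step = np.linalg.solve(h + ridge * np.eye(j), -g)
        except np.linalg.LinAlgError:
            step = -g
        # backtracking line search on the dual objective
        t = 1.0
        for _ in range(60):
            f_new, p_new = value_state(lam + t * step)
            if f_new <= f + 1e-4 * t * (g @ step):
                break
            t *= 0.5
        lam = lam + t * step
        f, p = f_new, p_new
    g = z.T @ p - zbar
    return lam, p, bool(np.abs(g).max() <= tol), it


def solve_maxent(
    problem: MaxEntProblem,
    tol: float = 1e-8,
    max_iter: int = 10000,
    on_infeasible: str = "error",
) -> MaxEntSolution:
    """Solve the CATS maximum-entropy problem.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the maximum constraint residual, in
        standardized trait units.
    on_infeasible : {"error", "project"}
        What to do when the target CWM vector lies outside the convex
        hull of the species traits: raise (default, with the projection
        report attached) or substitute the hull projection and record
        the projection distance in the solution.
    """
    if on_infeasible not in ("error", "project"):
        raise ValidationError("on_infeasible must be 'error' or 'project'")
    report = check_feasibility(problem, tol=max(tol, 1e-8))
    working = problem
    if not report.feasible:
        if on_infeasible == "error":
            raise InfeasibleConstraintError(report)
        working = MaxEntProblem(
            traits=problem.traits,
            constraints=report.projected_constraints,
            prior=problem.prior,
            species=problem.species,
            trait_names=problem.trait_names,
            standardize=problem.standardize,
        )

    z, zbar, _, _ = working._standardized()
    with np.errstate(divide="ignore"):
        log_prior = np.log(working.prior)

    if z.shape[1] == 0:
        p = working.prior.copy()
        lam = np.zeros(0)
        converged, iters, lz = True, 0, 0.0
    else:
        lam, p, converged, iters = _dual_newton(z, zbar, log_prior, tol, max_iter)
        lz = float(logsumexp(log_prior + z @ lam))

    residuals = np.abs(z.T @ p - zbar) if z.shape[1] else np.zeros(0)
    raw_residuals = np.abs(problem.traits.T @ p - working.constraints)
    if not converged:
        raise ConvergenceError(
            f"maxent solver did not reach tol={tol:g} in {max_iter} iterations "
            f"(max residual {residuals.max():.3g})",
            residuals=residuals,
            iterations=iters,
        )
    return MaxEntSolution(
        p=p,
        lambdas=lam,
        log_partition=lz,
        entropy=entropy(p),
        residuals=residuals,
        raw_residuals=raw_residuals,
        converged=converged,
        iterations=iters,
        projection=None if report.feasible else report,
        species=problem.species,
    )
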