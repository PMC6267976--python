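import numpy as np
import pandas as pd
import pytest

import cwmcats as cc


@pytest.fixture()
def grass_traits():
    """Five-species synthetic trait table spanning the grass trait space."""
    return cc.TraitTable(
        pd.DataFrame(
            {
                "seed_mass": [0.21, 1.10, 0.50, 0.39, 1.31],
                "srl": [190.0, 55.0, 116.0, 78.0, 149.0],
                "flowering_date": [220.0, 160.0, 197.0, 185.0, 178.0],
            },
            index=pd.Index([f"sp{i + 1:03d}" for i in range(5)], name="species_id"),
        )
    )


@pytest.fixture(scope="session")
def landscape():
    """One default synthetic landscape shared across read-only tests."""
    return cc.generate_landscape(cc.LandscapeConfig(seed=11))


@pytest.fixture(scope="session")
def experiment(landscape):
    return cc.generate_experiment(
        landscape.traits, cc.ExperimentConfig(kernel=landscape.truth.kernel, seed=12)
    )


def _entropy_rows(p):
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * lg).sum(axis=1)


def grid_entropy_oracle(traits, constraints, step=2e-3, n_refine=2):
    """Brute-force constrained-entropy optimum by exhaustive grid search.

    Exactly-feasible points are enumerated by gridding S-(J+1) free
    simplex coordinates and solving the remaining coordinates from the
    normalization + CWM constraint system, so every candidate satisfies
    the constraints to machine precision. The best cell is refined twice
    on a shrinking local grid. Independent of the dual-Newton solver.
    Returns None when no feasible grid point exists (infeasible target).
    """
    from itertools import combinations

    traits = np.asarray(traits, dtype=float)
    constraints = np.asarray(constraints, dtype=float)
    s, j = traits.shape
    a = np.vstack([np.ones(s), traits.T])  # (J+1) x S
    b = np.concatenate([[1.0], constraints])
    n_pinned = j + 1
    if n_pinned > s:
        # overdetermined: the feasible set is (at most) a single point
        p, *_ = np.linalg.lstsq(a, b, rcond=None)
        if (p < -1e-9).any() or np.abs(a @ p - b).max() > 1e-9:
            return None
        return float(_entropy_rows(np.clip(p, 0, None)[None, :])[0])

    # pick an invertible pinned-column set
    for pinned in combinations(range(s), n_pinned):
        sub = a[:, pinned]
        if abs(np.linalg.det(sub)) > 1e-8:
            break
    else:
        raise ValueError("constraint system is rank deficient")
    free = [i for i in range(s) if i not in pinned]
    inv = np.linalg.inv(sub)

    def best_on(qgrid):
        # qgrid: (n_pts, n_free) free coordinates
        rem = (inv @ (b[:, None] - a[:, free] @ qgrid.T)).T
        p = np.empty((len(qgrid), s))
        p[:, free] = qgrid
        p[:, list(pinned)] = rem
        ok = (p >= -1e-12).all(axis=1)
        if not ok.any():
            return None, None
        p = np.clip(p[ok], 0.0, None)
        h = _entropy_rows(p)
        i = np.argmax(h)
        return float(h[i]), p[i]

    if not free:
        h, p = best_on(np.zeros((1, 0)))
        return h

    # seed the search from an LP-found feasible point so thin feasible
    # regions (targets near the hull boundary) are never missed
    from scipy.optimize import linprog

    lp = linprog(
        c=np.zeros(s), A_eq=a, b_eq=b, bounds=[(0, None)] * s, method="highs"
    )
    if lp.status != 0:
        return None
    h_best = float(_entropy_rows(np.clip(lp.x, 0, None)[None, :])[0])
    p_best = np.clip(lp.x, 0, None)

    width = 0.5
    center = p_best[free]
    cur_step = step
    for level in range(n_refine + 1):
        axes = [
            np.arange(
                max(0.0, c - width), min(1.0, c + width) + cur_step / 2, cur_step
            )
            for c in center
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        qgrid = np.vstack(
            [np.column_stack([m.ravel() for m in mesh]), p_best[None, free]]
        )
        h, p = best_on(qgrid)
        if h is not None and h > h_best:
            h_best, p_best = h, p
        center = p_best[free]
        width = 2 * cur_step
        cur_step = cur_step / 25
    return h_best
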