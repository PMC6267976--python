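"""Two-way factorial PerMANOVA on distance matrices.

Partitions the total sum of squared dissimilarities among the terms of a
two-factor crossed design (A, B, A:B, residual) using the Gower-centered
inner-product matrix G = -1/2 C D^2 C and sequential (Type I) projection
matrices, so balance is not required. The pseudo-F for each term is

    F = (SS_term / df_term) / (SS_residual / df_residual)

and its p-value comes from free permutation of the samples (rows and
columns of D permuted together), recomputing every term's pseudo-F. With
Euclidean distances on a univariate response this reproduces classical
two-way ANOVA exactly (the McArdle-Anderson identity), which is the oracle
used in the test suite; scikit-bio's one-way permanova provides an
independent cross-check of the one-factor reduction.

Community distances are Bray-Curtis, d(x,y) = sum|x_k - y_k| / sum(x_k + y_k);
univariate responses (single species, per-pot CWM traits) use Euclidean
distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .community import CommunityMatrix
from .errors import DegenerateDesignError, ValidationError


def bray_curtis(m) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix of a community matrix.

    Rejects all-zero rows: the dissimilarity is undefined for empty
    communities (drop them first via ``drop_zero_rows``).
    """
    if isinstance(m, CommunityMatrix):
        df = m.data
    else:
        df = pd.DataFrame(m)
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("Bray-Curtis requires nonnegative abundances")
    zero = x.sum(axis=1) == 0
    if zero.any():
        raise ValidationError(
            f"Bray-Curtis undefined for all-zero rows: {df.index[zero].tolist()}"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in df.index])


def euclidean_distance(y, ids=None) -> DistanceMatrix:
    """Euclidean distance matrix of a univariate (or multivariate) response."""
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if ids is None:
        ids = getattr(y, "index", range(len(arr)))
    d = squareform(pdist(arr, metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in ids])


@dataclass
class PermanovaResult:
    """Sequential two-way PerMANOVA term table plus permutation metadata."""

    table: pd.DataFrame  # index: term; columns: df, ss, pseudo_f, r2, p
    n_perm: int
    seed: int

    def __str__(self):
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")


def _dummies(labels: pd.Series) -> np.ndarray:
    levels = pd.unique(labels)
    return (labels.to_numpy()[:, None] == levels[None, :]).astype(float)


def _proj(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova_2way(
    d: DistanceMatrix,
    factor_a,
    factor_b,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Two-way crossed PerMANOVA with interaction on a distance matrix.

    ``factor_a`` and ``factor_b`` are per-sample label sequences in the
    order of ``d.ids`` (pandas Series are aligned by position; their
    ``name`` attributes label the output terms). Sums of squares are
    sequential with A entered before B before A:B; for balanced designs
    the order is immaterial.
    """
    dm = np.asarray(d.data if isinstance(d, DistanceMatrix) else d, dtype=float)
    n = dm.shape[0]
    a = pd.Series(list(factor_a))
    b = pd.Series(list(factor_b))
    name_a = getattr(factor_a, "name", None) or "A"
    name_b = getattr(factor_b, "name", None) or "B"
    if len(a) != n or len(b) != n:
        raise ValidationError("factor length does not match distance matrix size")
    if a.nunique() < 2 or b.nunique() < 2:
        raise ValidationError("each factor needs at least 2 levels")
    cells = pd.crosstab(a, b)
    if (cells.to_numpy() == 0).any():
        raise DegenerateDesignError("empty cell in the two-way design")
    if (cells.to_numpy() < 2).any():
        warnings.warn("some cells have a single replicate", UserWarning, stacklevel=2)

    n_a, n_b = a.nunique(), b.nunique()
    df_terms = {
        name_a: n_a - 1,
        name_b: n_b - 1,
        f"{name_a}:{name_b}": (n_a - 1) * (n_b - 1),
    }
    df_res = n - n_a * n_b
    if df_res <= 0:
        raise DegenerateDesignError("no residual degrees of freedom")

    # Gower-centered inner-product matrix
    c = np.eye(n) - np.full((n, n), 1.0 / n)
    g = -0.5 * c @ (dm**2) @ c
    ss_total = float(np.trace(g))
    if ss_total <= 1e-12 * n:
        raise DegenerateDesignError("zero total sum of squares (constant response)")

    ones = np.ones((n, 1))
    xa = _dummies(a)
    xb = _dummies(b)
    xab = (xa[:, :, None] * xb[:, None, :]).reshape(n, -1)
    h0 = _proj(ones)
    h1 = _proj(np.hstack([ones, xa]))
    h2 = _proj(np.hstack([ones, xa, xb]))
    h3 = _proj(np.hstack([ones, xa, xb, xab]))
    diffs = {
        name_a: h1 - h0,
        name_b: h2 - h1,
        f"{name_a}:{name_b}": h3 - h2,
    }
    m_res = np.eye(n) - h3

    def partition(gmat):
        ss = {t: float(np.sum(m * gmat)) for t, m in diffs.items()}
        ss_res = float(np.sum(m_res * gmat))
        return ss, ss_res

    ss, ss_res = partition(g)
    f_obs = {t: (ss[t] / df_terms[t]) / (ss_res / df_res) for t in diffs}

    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in diffs}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ssp, ssp_res = partition(gp)
        for t in diffs:
            fp = (ssp[t] / df_terms[t]) / (ssp_res / df_res)
            if fp >= f_obs[t] - 1e-12:
                exceed[t] += 1

    rows = []
    for t in diffs:
        rows.append(
            {
                "term": t,
                "df": df_terms[t],
                "ss": ss[t],
                "pseudo_f": f_obs[t],
                "r2": ss[t] / ss_total,
                "p": (1 + exceed[t]) / (1 + n_perm),
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "ss": ss_res,
            "pseudo_f": np.nan,
            "r2": ss_res / ss_total,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "ss": ss_total,
            "pseudo_f": np.nan,
            "r2": 1.0,
            "p": np.nan,
        }
    )
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_perm, seed)


def permanova_univariate(
    y,
    factor_a,
    factor_b,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Two-way PerMANOVA of a single response via Euclidean distances.

    Equivalent to classical two-way ANOVA on the raw values, but with
    permutation p-values.
    """
    d = euclidean_distance(y)
    return permanova_2way(d, factor_a, factor_b, n_perm=n_perm, seed=seed)
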