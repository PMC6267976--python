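"""Goodness-of-fit between predicted and observed communities.

Two headline statistics compare a treatment x species matrix of observed
mean relative abundances with the matrix predicted by the maxent model:

* ``r2`` — squared Pearson correlation over all flattened cells of the
  untransformed relative abundances ("degree of correlation");
* ``rmse_sqrt`` — root-mean-square error of square-root-transformed
  relative abundances, bounded in [0, 1] on simplex rows.

Significance comes from a permutation null: species entries of the
observed matrix are shuffled (by default independently within each
treatment row, keeping each treatment's abundance profile while destroying
species identity; permuting whole rows is available as an alternative
scheme) and the statistic recomputed, with the observed value included in
the null set: p = (1 + #{null at least as extreme}) / (1 + n_perm).

Also here: per-trait Pearson concordance of observed vs predicted CWM
traits, and top-species accuracy (did the model name the right dominant
species per treatment, and in what fraction of individual pots?).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

SCHEMES = ("within_row", "rows")


def _as_matrix(x) -> np.ndarray:
    a = np.asarray(x, dtype=float) if not isinstance(x, pd.DataFrame) else x.to_numpy(dtype=float)
    if a.ndim != 2:
        raise ValidationError("expected a 2-D treatment x species matrix")
    return a


def _check_pair(observed, predicted):
    obs, pred = _as_matrix(observed), _as_matrix(predicted)
    if obs.shape != pred.shape:
        raise ValidationError(f"shape mismatch: {obs.shape} vs {pred.shape}")
    if (obs < 0).any() or (pred < 0).any():
        raise ValidationError("relative abundances must be nonnegative")
    return obs, pred


def fit_r2(observed, predicted) -> float:
    """Squared Pearson correlation over all flattened cells, untransformed."""
    obs, pred = _check_pair(observed, predicted)
    a, b = obs.ravel(), pred.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("correlation undefined: zero variance in a matrix")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def rmse_sqrt(observed, predicted) -> float:
    """RMSE of square-root-transformed relative abundances."""
    obs, pred = _check_pair(observed, predicted)
    d = np.sqrt(obs) - np.sqrt(pred)
    return float(np.sqrt(np.mean(d * d)))


@dataclass
class FitAssessment:
    """Fit statistics with their permutation null distributions."""

    r2: float
    rmse_sqrt: float
    p_r2: float
    p_rmse: float
    n_perm: int
    seed: int
    scheme: str
    null_r2: np.ndarray = field(repr=False)
    null_rmse: np.ndarray = field(repr=False)


def permutation_test(
    observed,
    predicted,
    statistic: str = "r2",
    n_perm: int = 999,
    seed: int = 0,
    scheme: str = "within_row",
) -> FitAssessment:
    """Permutation null for the observed-vs-predicted fit statistics.

    ``statistic`` names the primary statistic ("r2" or "rmse_sqrt") but
    both are computed on every permutation, so the assessment carries
    both p-values. "Extreme" means >= the observed value for r2 and
    <= for rmse_sqrt.
    """
    if statistic not in ("r2", "rmse_sqrt"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    obs, pred = _check_pair(observed, predicted)
    t, s = obs.shape
    obs_r2 = fit_r2(obs, pred)
    obs_rmse = rmse_sqrt(obs, pred)

    rng = np.random.default_rng(seed)
    null_r2 = np.empty(n_perm)
    null_rmse = np.empty(n_perm)
    for k in range(n_perm):
        if scheme == "within_row":
            perm = np.empty_like(obs)
            for i in range(t):
                perm[i] = obs[i, rng.permutation(s)]
        else:
            perm = obs[rng.permutation(t)]
        a = perm.ravel()
        if np.ptp(a) == 0:
            null_r2[k] = 0.0
        else:
            r = np.corrcoef(a, pred.ravel())[0, 1]
            null_r2[k] = r * r
        d = np.sqrt(perm) - np.sqrt(pred)
        null_rmse[k] = np.sqrt(np.mean(d * d))

    p_r2 = (1 + int((null_r2 >= obs_r2 - 1e-12).sum())) / (1 + n_perm)
    p_rmse = (1 + int((null_rmse <= obs_rmse + 1e-12).sum())) / (1 + n_perm)
    return FitAssessment(
        r2=obs_r2,
        rmse_sqrt=obs_rmse,
        p_r2=p_r2,
        p_rmse=p_rmse,
        n_perm=n_perm,
        seed=seed,
        scheme=scheme,
        null_r2=null_r2,
        null_rmse=null_rmse,
    )


def cwm_concordance(observed_cwm, predicted_cwm) -> pd.DataFrame:
    """Per-trait Pearson correlation of observed vs predicted CWM values.

    Returns a DataFrame indexed by trait with columns ``r`` and
    ``p_value`` (classical two-sided t test). Requires >= 3 units.
    """
    if isinstance(observed_cwm, pd.DataFrame) and isinstance(predicted_cwm, pd.DataFrame):
        common = [c for c in observed_cwm.columns if c in predicted_cwm.columns]
        obs = observed_cwm[common]
        pred = predicted_cwm.loc[obs.index, common]
        names = common
    else:
        obs = pd.DataFrame(_as_matrix(observed_cwm))
        pred = pd.DataFrame(_as_matrix(predicted_cwm))
        names = obs.columns.tolist()
    if obs.shape != pred.shape:
        raise ValidationError("observed and predicted CWM shapes differ")
    if len(obs) < 3:
        raise ValidationError("need at least 3 units per trait for a correlation")
    rows = []
    for c in names:
        a = obs[c].to_numpy(dtype=float)
        b = pred[c].to_numpy(dtype=float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValidationError(f"correlation undefined for trait {c!r}: zero variance")
        r, p = stats.pearsonr(a, b)
        rows.append({"trait": c, "r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows).set_index("trait")


def _argmax_set(row: np.ndarray, rtol: float = 0.0) -> set:
    m = row.max()
    return set(np.flatnonzero(row >= m - rtol))


def top_species_accuracy(
    observed_pots: pd.DataFrame,
    treatments: pd.Series,
    predicted: pd.DataFrame,
) -> dict:
    """Dominant-species agreement between predictions and observations.

    Parameters
    ----------
    observed_pots : DataFrame
        Pot x species relative abundances (rows on the simplex or all
        zero; all-zero pots are excluded, mirroring the removal of pots
        without any emergence).
    treatments : Series
        Treatment label per pot (same index as ``observed_pots``).
    predicted : DataFrame
        Treatment x species predicted relative abundances.

    Returns
    -------
    dict with ``per_treatment_hit`` (treatment -> bool: predicted argmax
    matches the argmax of the observed treatment mean), ``pot_fraction``
    (share of non-empty pots whose own dominant species is the predicted
    one), and ``predicted_dominant`` (treatment -> species label). Ties
    in observed maxima count as hits when the predicted dominant is
    among the tied species.
    """
    if not observed_pots.index.equals(treatments.index):
        treatments = treatments.reindex(observed_pots.index)
        if treatments.isna().any():
            raise ValidationError("every pot needs a treatment label")
    unknown = set(treatments.unique()) - set(predicted.index)
    if unknown:
        raise ValidationError(f"unknown treatment label(s): {sorted(unknown)}")
    obs = observed_pots.reindex(columns=predicted.columns)
    if obs.isna().any().any():
        raise ValidationError("observed and predicted species columns differ")

    per_treatment_hit = {}
    predicted_dominant = {}
    hits = 0
    total = 0
    for tr in predicted.index:
        pred_row = predicted.loc[tr].to_numpy(dtype=float)
        pred_top = int(np.argmax(pred_row))
        predicted_dominant[tr] = predicted.columns[pred_top]
        pots = obs.loc[treatments[treatments == tr].index]
        nonzero = pots.sum(axis=1) > 0
        pots = pots.loc[nonzero]
        if len(pots):
            mean_row = pots.mean(axis=0).to_numpy()
            per_treatment_hit[tr] = pred_top in _argmax_set(mean_row)
        else:
            per_treatment_hit[tr] = False
        for _, pot in pots.iterrows():
            total += 1
            if pred_top in _argmax_set(pot.to_numpy(dtype=float)):
                hits += 1
    return {
        "per_treatment_hit": per_treatment_hit,
        "pot_fraction": hits / total if total else float("nan"),
        "predicted_dominant": predicted_dominant,
    }
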