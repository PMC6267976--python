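"""Smooth additive trait-environment models.

Each community-weighted mean (CWM) trait is modelled as an additive sum of
penalized cubic regression splines in soil pH and pine basal area, with
Gaussian errors:

    CWM(trait) ~ s(soil_ph, k=10) + s(pine_ba, k=10)

The per-term smoothing parameters are chosen by generalized cross-validation
(GCV). ``k`` caps the basis dimension of each smooth; the effective degrees
of freedom after penalization are typically far smaller.

Fitted models predict the expected CWM trait at new environments — in
particular at treatment-level (pH, basal area) combinations — supplying the
constraint vectors for the maximum-entropy abundance model. Predictions
outside the calibration range are clamped to the nearest range edge and
flagged, since a penalized spline says nothing beyond its data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines, GLMGam

from .community import CWMTable, EnvironmentTable
from .errors import DegenerateDesignError, ExtrapolationWarning, ValidationError

PREDICTORS = ("soil_ph", "pine_ba")

_MIN_SAMPLES = 20


@dataclass
class CWMPrediction:
    """A predicted CWM value together with its extrapolation flag."""

    value: float
    extrapolated: bool

    def __float__(self):
        return float(self.value)


@dataclass
class SmoothAdditiveFit:
    """A fitted additive spline model for one CWM trait.

    Attributes
    ----------
    trait_name : str
        Which CWM trait this model predicts.
    basis_dim : int
        Basis dimension (k) per smooth term; the upper bound on each
        term's flexibility.
    smoothing_params : ndarray, shape (2,)
        GCV-selected penalty weight per smooth term.
    coefficients : ndarray
        Intercept followed by spline basis weights.
    adj_r2 : float
        Adjusted R^2 computed from residual variance at the effective
        degrees of freedom.
    term_tests : dict
        Per-predictor approximate Wald tests of the smooth term
        (statistic, p_value). Approximate: they condition on the
        selected smoothing parameters.
    training_ranges : dict
        Observed (min, max) per predictor; the support of the fit.
    degenerate : bool
        True when the response was constant and no model was estimated.
    """

    trait_name: str
    basis_dim: int
    smoothing_params: np.ndarray
    coefficients: np.ndarray
    adj_r2: float
    term_tests: dict
    training_ranges: dict
    degenerate: bool = False
    training_x: np.ndarray = field(default=None, repr=False)
    _basis: BSplines = field(default=None, repr=False, compare=False)

    def _design(self, x: np.ndarray) -> np.ndarray:
        if self._basis is None:
            self._basis = BSplines(
                self.training_x,
                df=[self.basis_dim, self.basis_dim],
                degree=[3, 3],
            )
        return np.column_stack([np.ones(len(x)), self._basis.transform(x)])

    def predict(self, ph, ba) -> CWMPrediction:
        """Predict the CWM trait at one (soil pH, pine basal area) point.

        Inputs outside the calibration range are clamped to the nearest
        edge; the result is flagged and an :class:`ExtrapolationWarning`
        is emitted.
        """
        ph = float(ph)
        ba = float(ba)
        if not (np.isfinite(ph) and np.isfinite(ba)):
            raise ValidationError("predict requires finite (ph, ba)")
        if self.degenerate:
            return CWMPrediction(float(self.coefficients[0]), False)
        x = np.array([[ph, ba]])
        lo = np.array([self.training_ranges[p][0] for p in PREDICTORS])
        hi = np.array([self.training_ranges[p][1] for p in PREDICTORS])
        clamped = np.clip(x, lo, hi)
        extrapolated = bool((clamped != x).any())
        if extrapolated:
            warnings.warn(
                f"({ph:g}, {ba:g}) outside calibration range for "
                f"{self.trait_name}; clamped to range edge",
                ExtrapolationWarning,
                stacklevel=2,
            )
        value = float((self._design(clamped) @ self.coefficients)[0])
        return CWMPrediction(value, extrapolated)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "trait_name": self.trait_name,
            "basis_dim": self.basis_dim,
            "smoothing_params": np.asarray(self.smoothing_params).tolist(),
            "coefficients": np.asarray(self.coefficients).tolist(),
            "adj_r2": self.adj_r2,
            "term_tests": self.term_tests,
            "training_ranges": {k: list(v) for k, v in self.training_ranges.items()},
            "degenerate": self.degenerate,
            "training_x": self.training_x.tolist() if self.training_x is not None else None,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SmoothAdditiveFit":
        doc = json.loads(text)
        return cls(
            trait_name=doc["trait_name"],
            basis_dim=doc["basis_dim"],
            smoothing_params=np.asarray(doc["smoothing_params"], dtype=float),
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            adj_r2=doc["adj_r2"],
            term_tests=doc["term_tests"],
            training_ranges={k: tuple(v) for k, v in doc["training_ranges"].items()},
            degenerate=doc["degenerate"],
            training_x=(
                np.asarray(doc["training_x"], dtype=float)
                if doc["training_x"] is not None
                else None
            ),
        )


def _select_alpha(y, exog, basis) -> np.ndarray:
    gam = GLMGam(y, exog=exog, smoother=basis)
    # select_penweight reads model.scale before any fit has set it;
    # prime the attribute so the selector can save/restore it.
    if not hasattr(gam, "scale"):
        gam.scale = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # the GCV surface over the two log-penalties is smooth and nearly
        # unimodal; 150 simplex evaluations locate its optimum to well
        # below the criterion's noise floor
        alpha, _, _ = gam.select_penweight(
            criterion="gcv", method="nm", disp=False, maxiter=150, maxfun=150
        )
    return np.asarray(alpha, dtype=float)


def fit_cwm_model(
    cwm: CWMTable,
    env: EnvironmentTable,
    trait_name: str,
    basis_dim: int = 10,
    alpha=None,
) -> SmoothAdditiveFit:
    """Calibrate CWM(trait) ~ s(soil_ph) + s(pine_ba) on quadrat data.

    Samples are matched by id; rows with missing CWM (empty communities)
    are dropped. Requires at least 20 usable samples and non-constant
    predictors. A constant response yields a flagged degenerate fit that
    predicts the constant. ``alpha`` fixes the per-term smoothing
    penalties instead of selecting them by GCV (diagnostics only; in the
    infinite-penalty limit the fit approaches the least-squares plane).
    """
    if trait_name not in cwm.data.columns:
        raise ValidationError(f"trait {trait_name!r} not in CWM table")
    joined = cwm.data[[trait_name]].join(env.data[list(PREDICTORS)], how="inner")
    joined = joined.dropna()
    n = len(joined)
    if n < _MIN_SAMPLES:
        raise ValidationError(
            f"need >= {_MIN_SAMPLES} samples with non-missing CWM, got {n}"
        )
    y = joined[trait_name].to_numpy(dtype=float)
    x = joined[list(PREDICTORS)].to_numpy(dtype=float)

    ranges = {p: (float(x[:, i].min()), float(x[:, i].max())) for i, p in enumerate(PREDICTORS)}
    for i, p in enumerate(PREDICTORS):
        if np.ptp(x[:, i]) == 0:
            raise DegenerateDesignError(f"predictor {p} has zero variance")
    if n <= 2 * (basis_dim - 1) + 1:
        raise DegenerateDesignError(
            f"{n} samples cannot support two smooths of basis dimension {basis_dim}"
        )

    if np.ptp(y) == 0:
        return SmoothAdditiveFit(
            trait_name=trait_name,
            basis_dim=basis_dim,
            smoothing_params=np.array([np.inf, np.inf]),
            coefficients=np.array([y[0]]),
            adj_r2=0.0,
            term_tests={p: {"statistic": 0.0, "p_value": 1.0} for p in PREDICTORS},
            training_ranges=ranges,
            degenerate=True,
            training_x=x,
        )

    basis = BSplines(x, df=[basis_dim, basis_dim], degree=[3, 3])
    exog = np.ones((n, 1))
    if alpha is None:
        alpha = _select_alpha(y, exog, basis)
    else:
        alpha = np.asarray(alpha, dtype=float)
    res = GLMGam(y, exog=exog, smoother=basis, alpha=alpha).fit()

    resid = y - res.fittedvalues
    edf = float(res.edf.sum())
    rss = float(resid @ resid)
    tss = float(np.var(y, ddof=1)) * (n - 1)
    adj_r2 = 1.0 - (rss / max(n - edf, 1.0)) / (tss / (n - 1))

    term_tests = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, p in enumerate(PREDICTORS):
            t = res.test_significance(i)
            term_tests[p] = {
                "statistic": float(np.squeeze(t.statistic)),
                "p_value": float(np.squeeze(t.pvalue)),
            }

    return SmoothAdditiveFit(
        trait_name=trait_name,
        basis_dim=basis_dim,
        smoothing_params=alpha,
        coefficients=np.asarray(res.params, dtype=float),
        adj_r2=float(adj_r2),
        term_tests=term_tests,
        training_ranges=ranges,
        training_x=x,
        _basis=basis,
    )


def predict_cwm(fit: SmoothAdditiveFit, ph, ba) -> CWMPrediction:
    """Functional alias for :meth:`SmoothAdditiveFit.predict`."""
    return fit.predict(ph, ba)


def predict_cwm_table(fits: dict, treatments: pd.DataFrame) -> CWMTable:
    """Predict a CWM constraint table for a set of treatments.

    ``treatments`` must have columns ``soil_ph`` and ``pine_ba`` and be
    indexed by treatment label; ``fits`` maps trait name to a
    :class:`SmoothAdditiveFit`.
    """
    out = {}
    for trait, fit in fits.items():
        out[trait] = [
            fit.predict(row["soil_ph"], row["pine_ba"]).value
            for _, row in treatments.iterrows()
        ]
    return CWMTable(pd.DataFrame(out, index=treatments.index))
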