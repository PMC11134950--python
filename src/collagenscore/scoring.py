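"""The collagen Feature-score: published weights and ridge-Cox refitting.

The Feature-score is a linear combination of the eight collagen features.
The published weight vector (obtained in the original training cohort by
ridge regression with cross-validation, applied to raw feature values) is

    score = -7.7656606*fea1 - 44.6439289*fea2 + 0.309178*fea3
            + 0.8884292*fea4 - 1.1665562*fea5 + 10.1583025*fea6
            - 0.1356464*fea7 + 0.6020531*fea8

and is shipped as a frozen constant.  A higher score corresponds to worse
prognosis.

Refitting on a new cohort uses a ridge-penalised Cox partial likelihood on
z-scored features (overall survival being the only outcome analysed); the
penalty is chosen to maximise the mean cross-validated partial
log-likelihood over a logarithmic grid.

The statsmodels-style entry point is :class:`FeatureScoreModel`: build it
from a cohort DataFrame, then ``.fit()`` (ridge-Cox CV) or
``.fit_published()`` returns a :class:`FeatureScoreResults` carrying the
coefficients, the CV path and score prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector

__all__ = ["PUBLISHED_COEFFICIENTS", "ScoreCoefficients",
           "published_coefficients", "compute_feature_score",
           "fit_ridge_cv", "FeatureScoreModel", "FeatureScoreResults"]

#: Published Feature-score weights for fea1..fea8, applied to raw features.
PUBLISHED_COEFFICIENTS = np.array([
    -7.7656606, -44.6439289, 0.309178, 0.8884292,
    -1.1665562, 10.1583025, -0.1356464, 0.6020531,
])


@dataclass
class ScoreCoefficients:
    """Eight linear weights defining a Feature-score.

    ``provenance`` is ``"published"`` (weights applied to raw features) or
    ``"refit"`` (weights applied to z-scored features using the stored
    ``center``/``scale``).
    """
    weights: np.ndarray
    intercept: float = 0.0
    provenance: str = "published"
    penalty: float | None = None
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (8,):
            raise ValueError("exactly 8 weights are required")

    def to_json(self) -> str:
        return json.dumps({
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "provenance": self.provenance,
            "penalty": self.penalty,
            "center": None if self.center is None else self.center.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
        })


def published_coefficients() -> ScoreCoefficients:
    return ScoreCoefficients(PUBLISHED_COEFFICIENTS.copy(),
                             provenance="published")


def _features_to_array(features) -> np.ndarray:
    if isinstance(features, FeatureVector):
        return features.to_array()
    if isinstance(features, pd.Series):
        return features[FEATURE_NAMES].to_numpy(dtype=float)
    arr = np.asarray(features, dtype=float)
    if arr.shape[-1] != 8:
        raise ValueError("expected 8 features")
    return arr


def compute_feature_score(features, coeffs: ScoreCoefficients) -> float:
    """Evaluate the Feature-score for one feature vector.

    Any missing (NaN) feature is an error naming the feature: the score is
    undefined without all eight inputs.
    """
    x = _features_to_array(features)
    if x.ndim != 1:
        raise ValueError("compute_feature_score takes a single vector; use "
                         "FeatureScoreResults.predict for a table")
    missing = np.where(np.isnan(x))[0]
    if missing.size:
        names = ", ".join(FEATURE_NAMES[i] for i in missing)
        raise ValueError(f"missing feature(s): {names}")
    if coeffs.provenance == "refit" and coeffs.center is not None:
        x = (x - coeffs.center) / coeffs.scale
    return float(coeffs.weights @ x + coeffs.intercept)


DEFAULT_PENALTY_GRID = np.logspace(-3, 3, 13)


def fit_ridge_cv(cohort: pd.DataFrame, penalty_grid=None, k_folds: int = 5,
                 seed: int = 0, feature_cols=None,
                 duration_col: str = "os_months",
                 event_col: str = "event") -> ScoreCoefficients:
    """Ridge-penalised Cox refit of the Feature-score weights.

    Features are z-scored with the cohort mean/SD (stored on the returned
    coefficients); the ridge penalty is chosen by k-fold cross-validation
    maximising the mean held-out partial log-likelihood.  Fold assignment
    is a deterministic function of ``seed``.
    """
    from lifelines import CoxPHFitter
    from sklearn.model_selection import KFold

    feature_cols = list(feature_cols or FEATURE_NAMES)
    if len(feature_cols) != 8:
        raise ValueError("exactly 8 feature columns are required")
    if len(cohort) < 2 * k_folds:
        raise ValueError(f"need at least {2 * k_folds} patients for "
                         f"{k_folds}-fold cross-validation")
    X = cohort[feature_cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("cohort contains missing features")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    degenerate = np.where(scale == 0)[0]
    if degenerate.size:
        names = ", ".join(feature_cols[i] for i in degenerate)
        raise ValueError(f"constant feature(s): {names}")
    Z = (X - center) / scale
    df = pd.DataFrame(Z, columns=feature_cols)
    df["_T"] = cohort[duration_col].to_numpy(dtype=float)
    df["_E"] = cohort[event_col].to_numpy(dtype=int)

    grid = np.asarray(penalty_grid if penalty_grid is not None
                      else DEFAULT_PENALTY_GRID, dtype=float)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(df))
    cv_ll = np.full((grid.size, k_folds), -np.inf)
    for gi, lam in enumerate(grid):
        for fi, (tr, te) in enumerate(folds):
            cph = CoxPHFitter(penalizer=lam, l1_ratio=0.0)
            cph.fit(df.iloc[tr], duration_col="_T", event_col="_E")
            cv_ll[gi, fi] = cph.score(df.iloc[te],
                                      scoring_method="log_likelihood")
    mean_ll = cv_ll.mean(axis=1)
    best = int(np.argmax(mean_ll))
    cph = CoxPHFitter(penalizer=grid[best], l1_ratio=0.0)
    cph.fit(df, duration_col="_T", event_col="_E")
    weights = cph.params_[feature_cols].to_numpy()
    coeffs = ScoreCoefficients(weights, provenance="refit",
                               penalty=float(grid[best]),
                               center=center, scale=scale)
    coeffs.cv_path_ = pd.DataFrame({"penalty": grid, "mean_cv_ll": mean_ll})
    return coeffs


class FeatureScoreModel:
    """Feature-score model over a patient-level cohort DataFrame.

    Parameters
    ----------
    data : DataFrame with the eight feature columns and, for refitting,
        overall-survival time and event columns.
    """

    def __init__(self, data: pd.DataFrame, feature_cols=None,
                 duration_col: str = "os_months", event_col: str = "event"):
        self.data = data
        self.feature_cols = list(feature_cols or FEATURE_NAMES)
        self.duration_col = duration_col
        self.event_col = event_col

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs):
        return cls(data, **kwargs)

    def fit(self, penalty_grid=None, k_folds: int = 5,
            seed: int = 0) -> "FeatureScoreResults":
        """Refit the weights by cross-validated ridge-Cox."""
        coeffs = fit_ridge_cv(
            self.data, penalty_grid=penalty_grid, k_folds=k_folds, seed=seed,
            feature_cols=self.feature_cols, duration_col=self.duration_col,
            event_col=self.event_col)
        return FeatureScoreResults(self, coeffs)

    def fit_published(self) -> "FeatureScoreResults":
        """Use the published weight vector (no fitting)."""
        return FeatureScoreResults(self, published_coefficients())


class FeatureScoreResults:
    """Fitted Feature-score: coefficients, CV path and prediction."""

    def __init__(self, model: FeatureScoreModel, coeffs: ScoreCoefficients):
        self.model = model
        self.coefficients = coeffs
        self.params = pd.Series(coeffs.weights, index=model.feature_cols)
        self.penalty_ = coeffs.penalty
        self.cv_path_ = getattr(coeffs, "cv_path_", None)

    def predict(self, data: pd.DataFrame | None = None) -> pd.Series:
        """Feature-score for every row of ``data`` (default: model data)."""
        df = self.model.data if data is None else data
        scores = [compute_feature_score(row[self.model.feature_cols],
                                        self.coefficients)
                  for _, row in df.iterrows()]
        return pd.Series(scores, index=df.index, name="feature_score")

    def summary(self) -> str:
        c = self.coefficients
        lines = ["Feature-score coefficients",
                 "=" * 42,
                 f"provenance: {c.provenance}"]
        if c.penalty is not None:
            lines.append(f"ridge penalty (CV-selected): {c.penalty:g}")
        lines.append("-" * 42)
        lines.append(f"{'feature':<10}{'weight':>12}")
        for name, w in self.params.items():
            lines.append(f"{name:<10}{w:>12.5f}")
        lines.append("=" * 42)
        return "\n".join(lines)

    def __repr__(self):
        return (f"<FeatureScoreResults provenance="
                f"{self.coefficients.provenance!r} n={len(self.model.data)}>")
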