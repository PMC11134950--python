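"""Prognostic evaluation: Cox regression, Kaplan-Meier stratification,
ROC/Youden cutoffs, nomogram point scales, calibration and correlations.

All survival machinery (partial-likelihood fitting with Efron ties,
product-limit estimation, the log-rank test) comes from lifelines; this
module adds the study design around it: reference-level encoding of the
clinical covariates, the DeLong AUC confidence interval, the Youden-index
cutoff rule (ties broken toward higher specificity), the 0-100 nomogram
point scales, and quantile-binned calibration against Kaplan-Meier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CoxResult", "KMCurve", "ROCResult", "NomogramModel",
           "cox_fit", "km_logrank", "roc_youden", "build_nomogram",
           "calibration_curve", "feature_os_correlation",
           "assign_risk_groups", "CLINICAL_TERMS"]

#: Dummy encoding of the clinical covariates (reference level first).
CLINICAL_TERMS = {
    "age_group": {"reference": "<=50", "levels": ["<=50", ">50"]},
    "sex": {"reference": "female", "levels": ["female", "male"]},
    "tnm": {"reference": "<=IIA", "levels": ["<=IIA", ">=IIB"]},
    "differentiation": {"reference": "I", "levels": ["I", "II", "III"]},
    "pni": {"reference": "no", "levels": ["no", "yes"]},
    "lvi": {"reference": "no", "levels": ["no", "yes"]},
    "location": {"reference": "head",
                 "levels": ["head", "body-tail", "other"]},
}


def _encode_design(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design matrix: categorical covariates become 0/1 indicator
    columns named ``var[level]`` against the reference level; numeric
    covariates pass through unchanged."""
    cols = {}
    for cov in covariates:
        if cov not in cohort.columns:
            raise ValueError(f"covariate {cov!r} not in cohort")
        series = cohort[cov]
        if cov in CLINICAL_TERMS:
            spec = CLINICAL_TERMS[cov]
            bad = set(series.unique()) - set(spec["levels"])
            if bad:
                raise ValueError(f"unknown level(s) {sorted(bad)} for {cov!r}")
            for level in spec["levels"][1:]:
                ind = (series == level).astype(float)
                if ind.any():  # skip levels unobserved in this cohort
                    cols[f"{cov}[{level}]"] = ind
        elif series.dtype == object:
            for level in sorted(series.unique())[1:]:
                cols[f"{cov}[{level}]"] = (series == level).astype(float)
        else:
            cols[cov] = series.astype(float)
    return pd.DataFrame(cols, index=cohort.index)


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs and p-values.

    ``table`` is indexed by design column; for multivariate fits the
    lifelines model is kept on ``fitter`` (needed for the nomogram and
    survival prediction).
    """
    table: pd.DataFrame
    mode: str
    fitter: object = None
    design: pd.DataFrame = None


def _check_events(events: np.ndarray, minimum: int = 10):
    n_events = int(np.asarray(events).sum())
    if n_events == 0:
        raise ValueError("no events in cohort; Cox model is undefined")
    if n_events < minimum:
        raise ValueError(f"need >= {minimum} events, got {n_events}")


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str):
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError
    design_cols = [c for c in df.columns if c not in (duration_col, event_col)]
    X = df[design_cols].to_numpy(dtype=float)
    if X.shape[1] > 1:
        centered = X - X.mean(axis=0)
        if np.linalg.matrix_rank(centered) < X.shape[1]:
            raise ValueError(
                "singular design: linearly dependent covariates among "
                f"{design_cols}")
    cph = CoxPHFitter()  # lifelines uses Efron tie handling
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise ValueError(
            f"Cox fit failed (possible complete separation) for covariates "
            f"{design_cols}: {err}") from None
    return cph


def cox_fit(cohort: pd.DataFrame, covariates, mode: str = "multivariate",
            duration_col: str = "os_months",
            event_col: str = "event") -> CoxResult:
    """Univariate or multivariate Cox proportional-hazards regression.

    Univariate mode fits each covariate alone; multivariate fits them
    jointly.  Requires >= 10 events.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_events(cohort[event_col].to_numpy())
    rows = []
    fitter = None
    design_all = _encode_design(cohort, covariates)

    def _collect(cph, cols):
        summ = cph.summary
        for col in cols:
            rows.append({
                "covariate": col,
                "HR": float(summ.loc[col, "exp(coef)"]),
                "CI_lower": float(summ.loc[col, "exp(coef) lower 95%"]),
                "CI_upper": float(summ.loc[col, "exp(coef) upper 95%"]),
                "p": float(summ.loc[col, "p"]),
            })

    if mode == "univariate":
        for cov in covariates:
            design = _encode_design(cohort, [cov])
            df = design.assign(**{duration_col: cohort[duration_col],
                                  event_col: cohort[event_col]})
            cph = _fit_cox(df, duration_col, event_col)
            _collect(cph, design.columns)
    else:
        df = design_all.assign(**{duration_col: cohort[duration_col],
                                  event_col: cohort[event_col]})
        fitter = _fit_cox(df, duration_col, event_col)
        _collect(fitter, design_all.columns)

    table = pd.DataFrame(rows).set_index("covariate")
    return CoxResult(table=table, mode=mode, fitter=fitter,
                     design=design_all)


@dataclass
class KMCurve:
    times: np.ndarray
    survival: dict            # group label -> survival estimates on `times`
    logrank_p: float
    hazard_ratio: float
    group_sizes: dict


def km_logrank(cohort: pd.DataFrame, group_labels,
               duration_col: str = "os_months", event_col: str = "event",
               reference=None) -> KMCurve:
    """Kaplan-Meier curves for two groups, two-sided log-rank p, and the
    between-group hazard ratio from a single-indicator Cox model.

    ``hazard_ratio`` is the non-reference group relative to ``reference``
    (default: the alphabetically first label).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    groups = pd.Series(np.asarray(group_labels), index=cohort.index)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    if reference is not None:
        if reference not in labels:
            raise ValueError(f"reference {reference!r} not among {labels}")
        labels = [reference] + [l for l in labels if l != reference]
    T = cohort[duration_col].to_numpy(dtype=float)
    E = cohort[event_col].to_numpy(dtype=int)
    for lab in labels:
        if (groups == lab).sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
    if E.sum() == 0:
        raise ValueError("no events in either group")

    times = np.unique(T)
    survival = {}
    sizes = {}
    for lab in labels:
        sel = (groups == lab).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(T[sel], E[sel])
        survival[lab] = kmf.survival_function_at_times(times).to_numpy()
        sizes[lab] = int(sel.sum())

    sel = (groups == labels[1]).to_numpy()
    res = logrank_test(T[sel], T[~sel], E[sel], E[~sel])
    cox = _fit_cox(pd.DataFrame({"g": sel.astype(float), "_T": T, "_E": E}),
                   "_T", "_E")
    hr = float(np.exp(cox.params_["g"]))
    return KMCurve(times=times, survival=survival,
                   logrank_p=float(res.p_value), hazard_ratio=hr,
                   group_sizes=sizes)


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple
    cutoff: float
    youden_j: float


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC (single-classifier case)."""
    m, n = len(pos), len(neg)
    # placement values via mid-rank comparison
    psi = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_youden(scores, outcome) -> ROCResult:
    """Empirical ROC with trapezoidal AUC, DeLong 95% CI, and the
    Youden-optimal cutoff (ties broken toward higher specificity).

    Scores above the cutoff are called positive (high risk).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")

    from sklearn.metrics import roc_auc_score
    auc = float(roc_auc_score(y, s))
    var = _delong_auc_variance(s[y == 1], s[y == 0])
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    # candidate cutoffs: midpoints between consecutive distinct scores,
    # plus sentinels below/above the observed range
    uniq = np.unique(s)
    cand = np.concatenate([[uniq[0] - 1.0],
                           (uniq[:-1] + uniq[1:]) / 2.0,
                           [uniq[-1] + 1.0]])
    pos, neg = s[y == 1], s[y == 0]
    sens = np.array([(pos > c).mean() for c in cand])
    spec = np.array([(neg <= c).mean() for c in cand])
    j = sens + spec - 1.0
    best_j = j.max()
    ties = np.where(np.isclose(j, best_j))[0]
    best = ties[np.argmax(spec[ties])]
    return ROCResult(thresholds=cand, sensitivity=sens, specificity=spec,
                     auc=auc, auc_ci=ci, cutoff=float(cand[best]),
                     youden_j=float(j[best]))


def assign_risk_groups(scores, cutoff: float) -> np.ndarray:
    """High risk when score > cutoff (higher score = worse prognosis)."""
    s = np.asarray(scores, dtype=float)
    return np.where(s > cutoff, "high", "low")


# ---------------------------------------------------------------------------
# nomogram
# ---------------------------------------------------------------------------

@dataclass
class NomogramModel:
    """0-100 point scales per covariate plus a total-points -> survival map.

    Each design column's points are ``100 * (beta*x - min_level beta*x) /
    max_range`` where ``max_range`` is the widest per-covariate linear-
    predictor span, so the most influential covariate spans exactly 0-100
    and total points increase strictly with the Cox linear predictor.
    """
    point_scales: dict        # column -> {"per_unit": slope, "x_min": anchor}
    scale: float              # linear predictor per point
    lp_at_zero_points: float  # linear predictor when all points are 0
    baseline_times: np.ndarray
    baseline_survival: np.ndarray  # survival of the zero-point profile
    lp_center: float

    def points_for(self, design_row: pd.Series) -> float:
        total = 0.0
        for col, sc in self.point_scales.items():
            total += sc["per_unit"] * (float(design_row[col]) - sc["x_min"])
        return total

    def predict_survival(self, total_points: float, horizon: float) -> float:
        """Survival probability at ``horizon`` for a given point total."""
        if horizon > self.baseline_times.max():
            raise ValueError(
                f"horizon {horizon} beyond last observed time "
                f"{self.baseline_times.max():g}")
        lp = self.lp_at_zero_points + total_points * self.scale
        idx = np.searchsorted(self.baseline_times, horizon, side="right") - 1
        s0 = self.baseline_survival[max(idx, 0)]
        return float(s0 ** np.exp(lp - self.lp_center))


def build_nomogram(cox: CoxResult, cohort: pd.DataFrame,
                   duration_col: str = "os_months",
                   event_col: str = "event") -> NomogramModel:
    """Nomogram point scales from a fitted multivariate Cox model.

    Covariate levels observed in the cohort define each scale's span; the
    covariate with the widest linear-predictor range spans exactly 0-100
    points.  Total points map to survival through the model's baseline
    survival function (Cox identity: the profile at zero total points has
    survival ``S_ref``; a profile with points P has ``S_ref**exp(P*scale)``
    relative to the centred baseline).
    """
    if cox.mode != "multivariate" or cox.fitter is None:
        raise ValueError("nomogram requires a fitted multivariate Cox model")
    cph = cox.fitter
    design = cox.design
    betas = cph.params_

    spans = {}
    for col in design.columns:
        vals = design[col].to_numpy(dtype=float)
        bx = betas[col] * vals
        spans[col] = (bx.min(), bx.max())
    max_range = max((hi - lo) for lo, hi in spans.values())

    point_scales = {}
    lp_min = 0.0
    for col in design.columns:
        lo, hi = spans[col]
        lp_min += lo
        if max_range > 0:
            per_unit = 100.0 * betas[col] / max_range
            # anchor at the level minimising beta*x so points are >= 0
            x_min = (design[col].min() if betas[col] >= 0
                     else design[col].max())
        else:
            per_unit, x_min = 0.0, 0.0
        point_scales[col] = {"per_unit": float(per_unit),
                             "x_min": float(x_min)}
    scale = max_range / 100.0 if max_range > 0 else 0.0

    base = cph.baseline_survival_
    lp_center = float(np.dot(betas.to_numpy(),
                             cph._norm_mean.reindex(betas.index).to_numpy()))
    return NomogramModel(
        point_scales=point_scales,
        scale=scale,
        lp_at_zero_points=lp_min,
        baseline_times=base.index.to_numpy(dtype=float),
        baseline_survival=base.iloc[:, 0].to_numpy(dtype=float),
        lp_center=lp_center,
    )


# ---------------------------------------------------------------------------
# calibration and correlations
# ---------------------------------------------------------------------------

def calibration_curve(predicted, cohort: pd.DataFrame, horizon: float,
                      n_bins: int = 4, duration_col: str = "os_months",
                      event_col: str = "event") -> pd.DataFrame:
    """Predicted vs observed survival at ``horizon``.

    Patients are split into ``n_bins`` quantile bins of predicted survival
    probability (bins with identical predictions collapse); the observed
    value is the within-bin Kaplan-Meier estimate at the horizon.
    """
    from lifelines import KaplanMeierFitter
    p = np.asarray(predicted, dtype=float)
    T = cohort[duration_col].to_numpy(dtype=float)
    E = cohort[event_col].to_numpy(dtype=int)
    if not E.any() or horizon > T[E == 1].max():
        raise ValueError(f"horizon {horizon} beyond last event time")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins == 1 or np.unique(p).size == 1:
        bins = np.zeros(len(p), dtype=int)
    else:
        bins = pd.qcut(p, q=n_bins, labels=False, duplicates="drop")
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        kmf = KaplanMeierFitter()
        kmf.fit(T[sel], E[sel])
        rows.append({
            "bin": int(b),
            "n": int(sel.sum()),
            "predicted": float(p[sel].mean()),
            "observed": float(kmf.survival_function_at_times(horizon).iloc[0]),
        })
    return pd.DataFrame(rows)


def feature_os_correlation(cohort: pd.DataFrame, columns,
                           method: str = "spearman",
                           duration_col: str = "os_months") -> pd.DataFrame:
    """Spearman or Pearson correlation of each column with survival time."""
    from scipy import stats
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if len(cohort) < 3:
        raise ValueError("need at least 3 patients")
    t = cohort[duration_col].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("survival times have zero variance")
    fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for col in columns:
        x = cohort[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"column {col!r} has zero variance")
        r, p = fn(x, t)
        rows.append({"variable": col, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("variable")
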