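"""Downstream demographic analyses of a segmentation.

Given per-vertex labels (from the reference parcellation or from a trained
model) and per-vertex attributes, this module aggregates region means,
correlates them with demographics (age, MMSE, education) under Bonferroni
control, compares two label sources via a paired Wilcoxon signed-rank test
on region-wise p-values, and evaluates cross-validated age-prediction RMSE
against the trivial mean-age baseline (whose out-of-fold RMSE approximates
the age standard deviation — the utility bar any regressor must clear).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import Subject

logger = logging.getLogger(__name__)

__all__ = [
    "region_means",
    "build_region_table",
    "table_to_matrix",
    "correlate",
    "bonferroni_threshold",
    "compare_sources",
    "age_prediction_rmse",
    "REGRESSOR_KINDS",
]


def region_means(
    subject: Subject,
    attribute: str = "thickness",
    labels: np.ndarray | None = None,
    n_regions: int = 35,
) -> np.ndarray:
    """Mean attribute value per region; absent regions are NaN (not zero).

    ``attribute`` is ``"thickness"``, ``"curvature"``, or ``"conductance"``
    (the vertex-wise mean conductance over the connectivity row).  ``labels``
    defaults to the subject's own (reference) labels; pass model predictions
    to aggregate over the predicted parcellation instead.
    """
    if attribute == "conductance":
        if subject.connectivity is None:
            raise ValueError(f"subject {subject.id} has no connectivity map")
        values = subject.connectivity.matrix.mean(axis=1)
    else:
        values = np.asarray(getattr(subject, attribute), dtype=np.float64)
    labels = subject.labels if labels is None else np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("attribute and labels must have equal length")
    out = np.full(n_regions, np.nan)
    for r in range(n_regions):
        mask = labels == r
        if mask.any():
            out[r] = values[mask].mean()
    return out


def build_region_table(
    subjects: list[Subject],
    attribute: str = "thickness",
    labels_by_subject: dict[tuple[str, str], np.ndarray] | None = None,
    n_regions: int = 35,
) -> pd.DataFrame:
    """Long-format region feature table: subject_id, hemisphere, region, value.

    ``labels_by_subject`` maps (subject_id, hemisphere) to predicted labels;
    omitted entries fall back to the reference labels.
    """
    rows = []
    for s in subjects:
        labels = None
        if labels_by_subject is not None:
            labels = labels_by_subject.get((s.id, s.hemisphere))
        means = region_means(s, attribute, labels=labels, n_regions=n_regions)
        for r in range(n_regions):
            if np.isnan(means[r]):
                continue  # absent region: recorded as absent, not zero
            rows.append({"subject_id": s.id, "hemisphere": s.hemisphere,
                         "region": r, "value": means[r]})
    return pd.DataFrame(rows)


def table_to_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Pivot to one row per subject, one column per (hemisphere, region).

    With 35 regions in each of two hemispheres the row length is 70.
    Missing regions become NaN (imputed downstream).
    """
    wide = table.pivot_table(index="subject_id", columns=["hemisphere", "region"],
                             values="value")
    wide = wide.sort_index(axis=1)
    return wide.to_numpy(), list(wide.index)


def correlate(
    table: pd.DataFrame,
    covariate: dict[str, float] | pd.Series,
    covariate_name: str = "age",
    attribute: str = "thickness",
    source: str = "reference",
) -> pd.DataFrame:
    """Pearson correlation of each region's mean attribute with a covariate.

    Returns one row per (hemisphere, region) with r and the two-sided p from
    the t-transform with n−2 df, plus one cohort-level row per hemisphere
    (region = -1) correlating the across-region average (equal region
    weights) with the covariate.  Zero-variance inputs are skipped with a
    warning rather than reported with an undefined r.
    """
    cov = pd.Series(covariate, dtype=float)
    rows = []

    def _corr(values: pd.Series, region: int, hemi: str) -> None:
        merged = values.dropna()
        ages = cov.reindex(merged.index).dropna()
        merged = merged.reindex(ages.index)
        if len(merged) < 3:
            return
        if merged.std() == 0 or ages.std() == 0:
            logger.warning("zero-variance input for region %s/%s; skipping", hemi, region)
            return
        r, p = stats.pearsonr(merged.to_numpy(), ages.to_numpy())
        rows.append({"hemisphere": hemi, "region": region, "r": float(r),
                     "p": float(p), "attribute": attribute,
                     "covariate": covariate_name, "source": source})

    for hemi, sub in table.groupby("hemisphere"):
        for region, grp in sub.groupby("region"):
            _corr(grp.set_index("subject_id")["value"], int(region), str(hemi))
        cohort_mean = sub.groupby("subject_id")["value"].mean()
        _corr(cohort_mean, -1, str(hemi))
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha / m."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def compare_sources(p_a: np.ndarray, p_b: np.ndarray) -> float:
    """Paired Wilcoxon signed-rank two-sided p comparing region-wise p-values.

    Zero-difference pairs are dropped; the exact null distribution is used
    for n ≤ 25 untied pairs, the normal approximation with continuity
    correction otherwise.  All pairs tied → p = 1.0 by convention.
    """
    p_a = np.asarray(p_a, dtype=np.float64)
    p_b = np.asarray(p_b, dtype=np.float64)
    if p_a.shape != p_b.shape:
        raise ValueError("p-value arrays must be paired (equal shape)")
    d = p_a - p_b
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    ranks_tied = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                         method=method)
    return float(res.pvalue)


REGRESSOR_KINDS = ("mean-baseline", "linear-ridge", "decision-tree",
                   "k-nearest", "mlp")


def _make_regressor(kind: str, seed: int):
    from sklearn.dummy import DummyRegressor
    from sklearn.impute import SimpleImputer
    from sklearn.linear_model import RidgeCV
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.neural_network import MLPRegressor
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.tree import DecisionTreeRegressor

    if kind == "mean-baseline":
        core = DummyRegressor(strategy="mean")
    elif kind == "linear-ridge":
        # p ~ n here, so the penalty is tuned by internal cross-validation
        core = RidgeCV(alphas=np.logspace(-3, 5, 17))
    elif kind == "decision-tree":
        core = DecisionTreeRegressor(max_depth=4, random_state=seed)
    elif kind == "k-nearest":
        core = KNeighborsRegressor(n_neighbors=5)
    elif kind == "mlp":
        core = MLPRegressor(hidden_layer_sizes=(32,), max_iter=3000,
                            random_state=seed)
    else:
        raise ValueError(f"unknown regressor kind {kind!r}; "
                         f"choose from {REGRESSOR_KINDS}")
    # Absent regions are imputed with the training-fold column mean.
    return make_pipeline(SimpleImputer(strategy="mean"), StandardScaler(), core)


def age_prediction_rmse(
    table: pd.DataFrame,
    ages: dict[str, float] | pd.Series,
    regressor_kind: str = "linear-ridge",
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Cross-validated out-of-fold age-prediction RMSE from region means.

    Returns ``(rmse, baseline_rmse)`` where the baseline is the out-of-fold
    mean-age predictor — its RMSE approximates the sample age sd, the
    reference any useful regressor must beat.
    """
    from sklearn.model_selection import KFold

    x, subject_ids = table_to_matrix(table)
    y = pd.Series(ages, dtype=float).reindex(subject_ids).to_numpy()
    if np.isnan(y).any():
        raise ValueError("ages missing for some subjects in the table")
    if len(y) < 2 * cv_folds:
        raise ValueError(f"need at least {2 * cv_folds} subjects for {cv_folds}-fold CV")

    def _oof_rmse(kind: str) -> float:
        preds = np.empty_like(y)
        for train, test in KFold(n_splits=cv_folds, shuffle=True,
                                 random_state=seed).split(x):
            model = _make_regressor(kind, seed)
            model.fit(x[train], y[train])
            preds[test] = model.predict(x[test])
        return float(np.sqrt(np.mean((preds - y) ** 2)))

    return _oof_rmse(regressor_kind), _oof_rmse("mean-baseline")
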