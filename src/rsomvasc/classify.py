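"""Per-minute disease classification: leave-one-subject-out (LOSO)
feature-selected random forests producing a scalar disease index.

For every post-baseline minute of the PORH test the percentage changes of the
18 features (raw features at baseline) feed a top-k univariate F-statistic
selection followed by a random-forest classifier.  Selection and fitting run
strictly inside each LOSO fold so no information about the held-out subject
leaks into feature ranking.  The out-of-fold class-1 probability is the
subject's feature-based index; AUC (Mann-Whitney form), plus threshold-based
confusion metrics, summarise per-minute performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif

from .core import CohortTable, ValidationError, logger
from .dynamics import percent_change

#: ``class_weight="balanced"`` compensates the one-subject class imbalance
#: every LOSO training fold has, and ``min_samples_leaf=5`` keeps trees from
#: memorising single subjects; both counter the pessimistic bias of
#: leave-one-out probabilities at cohort sizes of a few dozen.
DEFAULT_RF_PARAMS: dict = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "class_weight": "balanced",
    "min_samples_leaf": 5,
}


# ---------------------------------------------------------------------------
# Univariate selection
# ---------------------------------------------------------------------------

def select_top_k(train_features: pd.DataFrame, train_labels, k: int) -> list[str]:
    """Top-k features by the one-way between-group F statistic.

    Computed on training data only.  Constant features have an undefined F
    and rank last; ties break deterministically by column order.
    """
    p = train_features.shape[1]
    if not 1 <= k <= p:
        raise ValidationError(f"k must be in [1, {p}], got {k}")
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")
    X = train_features.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(X, y)
    F = np.where(np.isfinite(F), F, -np.inf)
    order = np.lexsort((np.arange(p), -F))
    return [train_features.columns[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# AUC and confusion metrics
# ---------------------------------------------------------------------------

def auc(index_values, labels) -> float:
    """Probability a random diseased index exceeds a random healthy one
    (Mann-Whitney form; ties count one half)."""
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(labels)
    pos = x[y == 1]
    neg = x[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("AUC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV and NPV from confusion counts.

    Undefined cells (e.g. PPV with no positive calls) are NaN.
    """
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0 or int(v) != v:
            raise ValidationError(f"{name} must be a non-negative integer, got {v}")
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("both classes must be represented")
    return {
        "accuracy": (tp + tn) / (tp + fn + tn + fp),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }


def counts_from_rates(sensitivity: float, specificity: float,
                      n_pos: int, n_neg: int) -> tuple[int, int, int, int]:
    """Reconstruct integer confusion counts (tp, fn, tn, fp) from rounded
    sensitivity/specificity and the per-class sizes."""
    tp = int(round(sensitivity * n_pos))
    tn = int(round(specificity * n_neg))
    return tp, n_pos - tp, tn, n_neg - tn


# ---------------------------------------------------------------------------
# LOSO index
# ---------------------------------------------------------------------------

@dataclass
class IndexResult:
    timepoint: str
    classifiable: bool
    index: pd.Series | None = None          # out-of-fold P(disease) per subject
    k: int | None = None
    auc: float | None = None
    threshold: float = 0.5
    metrics: dict = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)
    selection_frequency: dict = field(default_factory=dict)
    importances: pd.Series | None = None


def _feature_matrix(cohort: CohortTable, timepoint: str,
                    delta: pd.DataFrame | None) -> pd.DataFrame:
    if timepoint == "baseline":
        return cohort.at_timepoint("baseline")
    if delta is None:
        delta = percent_change(cohort)
    return delta.xs(timepoint, level=1).loc[cohort.subjects]


def loso_index(
    cohort: CohortTable,
    timepoint: str = "hyp1",
    k: int | str = "auto",
    rf_params: dict | None = None,
    seed: int = 0,
    threshold: float = 0.5,
    delta: pd.DataFrame | None = None,
) -> IndexResult:
    """Leave-one-subject-out feature-selected random-forest index.

    For each fold, the top-k F-ranked features are chosen and a random forest
    fitted on the remaining subjects; the held-out subject's class-1
    probability is its index.  With ``k="auto"`` an outer scan over
    k = 1..18 repeats the full LOSO and keeps the AUC-maximising k (smallest
    on ties; note this optimises k in-sample).  The selected-feature report
    lists features chosen in at least half the folds; importances come from a
    final refit on all subjects restricted to those features.

    A timepoint whose percentage changes are entirely missing is flagged
    "not classifiable" rather than raising.
    """
    X = _feature_matrix(cohort, timepoint, delta)
    y = cohort.groups.loc[X.index].to_numpy()
    if (y == 0).sum() < 3 or (y == 1).sum() < 3:
        raise ValidationError("need at least 3 subjects per group for LOSO")
    X = X.loc[:, X.notna().any()]
    if X.shape[1] == 0:
        logger.warning("timepoint %s: all features missing; not classifiable", timepoint)
        return IndexResult(timepoint=timepoint, classifiable=False)
    rf_params = {**DEFAULT_RF_PARAMS, **(rf_params or {})}
    if "min_samples_leaf" in rf_params:
        # keep trees able to split on very small cohorts
        cap = max(1, (len(X) - 1) // 5)
        rf_params["min_samples_leaf"] = min(rf_params["min_samples_leaf"], cap)

    if k == "auto":
        best = None
        for kk in range(1, X.shape[1] + 1):
            res = _run_loso(X, y, kk, rf_params, seed)
            a = auc(res[0], y)
            if best is None or a > best[1] + 1e-12:
                best = (kk, a)
        k = best[0]
    k = int(k)
    index_values, per_fold_selected = _run_loso(X, y, k, rf_params, seed)
    a = auc(index_values, y)

    freq = pd.Series(
        {f: sum(f in s for s in per_fold_selected) / len(per_fold_selected)
         for f in X.columns}
    )
    selected = [f for f in X.columns if freq[f] >= 0.5]
    importances = None
    if selected:
        rf = RandomForestClassifier(random_state=_rf_seed(seed), **rf_params)
        med = _impute(X[selected])
        rf.fit(med, y)
        imp = rf.feature_importances_
        total = imp.sum()
        importances = pd.Series(
            imp / total if total > 0 else imp, index=selected
        ).sort_values(ascending=False)

    pred = (index_values >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    metrics = confusion_metrics(tp, fn, tn, fp)
    metrics["auc"] = a
    return IndexResult(
        timepoint=timepoint,
        classifiable=True,
        index=pd.Series(index_values, index=X.index, name="index"),
        k=k,
        auc=a,
        threshold=threshold,
        metrics=metrics,
        selected=selected,
        selection_frequency=freq.to_dict(),
        importances=importances,
    )


def _rf_seed(seed: int) -> int:
    return int(np.random.default_rng(seed).integers(2**31))


def _impute(X: pd.DataFrame, reference: pd.DataFrame | None = None) -> pd.DataFrame:
    ref = reference if reference is not None else X
    return X.fillna(ref.median())


def _run_loso(X: pd.DataFrame, y: np.ndarray, k: int, rf_params: dict, seed: int):
    """One full LOSO pass; returns (out-of-fold indices, per-fold selections)."""
    n = len(X)
    out = np.empty(n)
    per_fold_selected = []
    rf_seed = _rf_seed(seed)
    for i in range(n):
        train_mask = np.ones(n, dtype=bool)
        train_mask[i] = False
        X_tr = _impute(X.iloc[train_mask])
        y_tr = y[train_mask]
        feats = select_top_k(X_tr, y_tr, min(k, X_tr.shape[1]))
        per_fold_selected.append(feats)
        rf = RandomForestClassifier(random_state=rf_seed, **rf_params)
        rf.fit(X_tr[feats], y_tr)
        X_te = _impute(X.iloc[[i]][feats], reference=X_tr[feats])
        out[i] = rf.predict_proba(X_te)[0, list(rf.classes_).index(1)]
    return out, per_fold_selected


def classify_timeline(
    cohort: CohortTable,
    k: int | str = "auto",
    rf_params: dict | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-minute classification summary across all five post-baseline
    timepoints (index metrics per column, one column per minute)."""
    delta = percent_change(cohort)
    cols = {}
    for tp in ("occl1", "occl2", "occl3", "hyp1", "hyp2"):
        res = loso_index(cohort, tp, k=k, rf_params=rf_params, seed=seed,
                         threshold=threshold, delta=delta)
        if not res.classifiable:
            cols[tp] = {"n_selected": np.nan, "auc": np.nan}
            continue
        cols[tp] = {
            "n_selected": len(res.selected),
            "auc": res.auc,
            **{m: res.metrics[m] for m in
               ("accuracy", "sensitivity", "specificity", "ppv", "npv")},
        }
    return pd.DataFrame(cols)
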