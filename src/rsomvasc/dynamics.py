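"""Percentage-change dynamics over the PORH timeline and group statistics.

For every feature, five values describe its dynamics: the percentage change
at each post-baseline minute relative to the subject's own baseline.  Group
differences use the classic equal-variance two-sided Student's t-test
(Welch optional), with boxplot summaries (median, quartiles, whiskers at
1.5 IQR).  The multiscale analysis aggregates features within each scale of
detail: min-max normalised values at baseline, percentage changes at
hyperemia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DEFAULT_SCALE_MAP,
    FEATURE_NAMES,
    POST_TIMEPOINTS,
    SCALES,
    CohortTable,
    ValidationError,
    logger,
)


# ---------------------------------------------------------------------------
# Percentage changes
# ---------------------------------------------------------------------------

def percent_change(cohort: CohortTable) -> pd.DataFrame:
    """Delta table: 100 * (f_t - f_baseline) / f_baseline per subject x feature.

    Indexed by (subject, timepoint) over the five post-baseline timepoints.
    Entries with a zero or missing baseline are NaN (missing data, not
    failure); their count is logged.
    """
    feats = cohort.features
    baseline = feats.xs("baseline", level=1)
    rows = []
    index = []
    for tp in POST_TIMEPOINTS:
        ft = feats.xs(tp, level=1)
        base = baseline.reindex(ft.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 100.0 * (ft - base) / base
        delta = delta.where(base != 0)
        for subject in ft.index:
            rows.append(delta.loc[subject])
            index.append((subject, tp))
    out = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["subject", "timepoint"])
    )
    n_missing = int(out.isna().sum().sum())
    if n_missing:
        logger.info("percent_change: %d missing entries (zero or missing baseline)", n_missing)
    return out


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class BoxplotStats:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


@dataclass
class GroupComparison:
    mean_0: float
    mean_1: float
    t: float
    p: float
    n_0: int
    n_1: int
    box_0: BoxplotStats
    box_1: BoxplotStats
    degenerate: bool = False


def boxplot_stats(values: np.ndarray) -> BoxplotStats:
    """Median, quartiles and 1.5-IQR whiskers (clipped to observed data)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr].min()
    hi = v[v <= q3 + 1.5 * iqr].max()
    return BoxplotStats(float(med), float(q1), float(q3), float(lo), float(hi))


def group_compare(values, labels, equal_var: bool = True) -> GroupComparison:
    """Unpaired two-sided Student's t-test plus per-group boxplot summary.

    ``labels`` are binary (0 healthy, 1 patient).  NaN values are dropped
    pairwise.  If both groups have zero variance: identical means give
    t = 0, p = 1; distinct means are flagged degenerate.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    g0, g1 = values[labels == 0], values[labels == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValidationError("need at least 2 subjects per group")
    degenerate = False
    if g0.std(ddof=1) == 0 and g1.std(ddof=1) == 0:
        if g0.mean() == g1.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf if g1.mean() > g0.mean() else -np.inf, 0.0
            degenerate = True
    else:
        t, p = stats.ttest_ind(g1, g0, equal_var=equal_var)
        t, p = float(t), float(p)
    return GroupComparison(
        mean_0=float(g0.mean()), mean_1=float(g1.mean()), t=t, p=p,
        n_0=len(g0), n_1=len(g1),
        box_0=boxplot_stats(g0), box_1=boxplot_stats(g1),
        degenerate=degenerate,
    )


def compare_features(
    cohort: CohortTable,
    delta: pd.DataFrame | None = None,
    timepoint: str = "hyp1",
    baseline: bool = False,
    equal_var: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-feature group comparison table at one timepoint.

    With ``baseline=True``, compares raw baseline values; otherwise compares
    percentage changes at ``timepoint``.  Returns one row per feature with
    group means, t, p (optionally Benjamini-Hochberg adjusted in an extra
    column; off by default to match per-feature presentation).
    """
    groups = cohort.groups
    if baseline:
        data = cohort.at_timepoint("baseline")
    else:
        if delta is None:
            delta = percent_change(cohort)
        data = delta.xs(timepoint, level=1).loc[cohort.subjects]
    rows = {}
    for f in FEATURE_NAMES:
        try:
            c = group_compare(data[f].to_numpy(), groups.to_numpy(), equal_var=equal_var)
        except ValidationError:
            continue
        rows[f] = {
            "mean_healthy": c.mean_0, "mean_patient": c.mean_1,
            "t": c.t, "p": c.p, "degenerate": c.degenerate,
        }
    out = pd.DataFrame(rows).T
    if fdr and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_fdr"] = multipletests(out["p"].to_numpy(dtype=float), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Multiscale aggregation
# ---------------------------------------------------------------------------

def scale_aggregate(
    cohort: CohortTable,
    delta: pd.DataFrame | None = None,
    scale_map: dict[str, str] | None = None,
    timepoint: str = "hyp1",
    equal_var: bool = True,
):
    """Per-scale per-subject aggregates at baseline and at one hyperemic minute.

    Baseline: each feature is min-max normalised across the cohort, then
    averaged within its scale per subject.  Hyperemic: percentage changes are
    averaged within scale.  Features constant across the cohort at baseline
    cannot be normalised and are dropped with a warning.  Returns
    ``(baseline_df, delta_df, comparisons)`` where the DataFrames are
    subjects x scales and ``comparisons`` maps (scale, "baseline"|"delta") to
    a :class:`GroupComparison`.
    """
    scale_map = scale_map or DEFAULT_SCALE_MAP
    missing = [f for f in FEATURE_NAMES if f not in scale_map]
    if missing:
        raise ValidationError(f"scale_map does not cover features: {missing}")
    if delta is None:
        delta = percent_change(cohort)
    base = cohort.at_timepoint("baseline")
    spans = base.max() - base.min()
    dropped = [f for f in FEATURE_NAMES if not spans[f] > 0]
    if dropped:
        logger.warning("scale_aggregate: dropping constant feature(s) %s", dropped)
    kept = [f for f in FEATURE_NAMES if f not in dropped]
    if not kept:
        raise ValidationError("all features constant across the cohort")
    norm = (base[kept] - base[kept].min()) / spans[kept]
    d_tp = delta.xs(timepoint, level=1).loc[cohort.subjects]

    base_out = {}
    delta_out = {}
    for scale in SCALES:
        members = [f for f in kept if scale_map[f] == scale]
        if not members:
            raise ValidationError(f"scale {scale!r} has no usable features")
        base_out[scale] = norm[members].mean(axis=1)
        delta_out[scale] = d_tp[members].mean(axis=1)
    base_df = pd.DataFrame(base_out)
    delta_df = pd.DataFrame(delta_out)
    comparisons = {}
    labels = cohort.groups.loc[base_df.index].to_numpy()
    for scale in SCALES:
        comparisons[(scale, "baseline")] = group_compare(
            base_df[scale].to_numpy(), labels, equal_var=equal_var
        )
        comparisons[(scale, "delta")] = group_compare(
            delta_df[scale].to_numpy(), labels, equal_var=equal_var
        )
    return base_df, delta_df, comparisons
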