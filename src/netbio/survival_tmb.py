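"""Survival stratification and tumor mutational burden (TMB).

Predicted responder / non-responder groups are compared with Kaplan–Meier
product-limit curves and the two-group log-rank test (lifelines).  TMB is a
weighted mutation count, TMB = 2·T + 1·NT, where T counts truncating
variants (nonsense, frame-shift ins/del, splice site) and NT non-truncating
ones (missense, in-frame ins/del, nonstop).  The combined model appends
z-scored TMB as one extra feature next to the z-scored NetBio pathway
activities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .pathway_activity import PathwayActivity, zscore_standardize
from .response_model import ModelSpec, MetricReport, PredictionResult, loocv

logger = logging.getLogger("netbio")

__all__ = [
    "TRUNCATING_CLASSES",
    "NON_TRUNCATING_CLASSES",
    "KMCurve",
    "LogRankResult",
    "compute_tmb",
    "classify_variant",
    "tmb_from_maf",
    "tmb_from_counts",
    "km_estimate",
    "logrank_test",
    "survival_stratify",
    "combined_tmb_netbio",
    "reclassification_sets",
]

TRUNCATING_CLASSES = frozenset(
    {"Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site"}
)
NON_TRUNCATING_CLASSES = frozenset(
    {"Missense_Mutation", "In_Frame_Del", "In_Frame_Ins", "Nonstop_Mutation"}
)


def compute_tmb(truncating: int, non_truncating: int) -> float:
    """TMB = 2.0 × truncating + 1.0 × non-truncating mutation counts."""
    if truncating < 0 or non_truncating < 0:
        raise ValueError("mutation counts must be non-negative")
    return truncating * 2.0 + non_truncating * 1.0


def classify_variant(variant_classification: str) -> str:
    """Map a MAF Variant_Classification to truncating / non_truncating / excluded."""
    if variant_classification in TRUNCATING_CLASSES:
        return "truncating"
    if variant_classification in NON_TRUNCATING_CLASSES:
        return "non_truncating"
    return "excluded"


def tmb_from_maf(
    maf: pd.DataFrame,
    sample_col: str = "Tumor_Sample_Barcode",
    class_col: str = "Variant_Classification",
) -> pd.Series:
    """Per-sample TMB from a MAF-like variant table."""
    kinds = maf[class_col].map(classify_variant)
    n_excluded = int((kinds == "excluded").sum())
    if n_excluded:
        logger.info("excluded %d variants outside the TMB classes", n_excluded)
    t = maf.loc[kinds == "truncating", sample_col].value_counts()
    nt = maf.loc[kinds == "non_truncating", sample_col].value_counts()
    samples = maf[sample_col].unique()
    tmb = pd.Series(
        {
            s: compute_tmb(int(t.get(s, 0)), int(nt.get(s, 0)))
            for s in samples
        },
        name="tmb",
    )
    return tmb.sort_index()


def tmb_from_counts(counts: pd.DataFrame, t_col: str = "T", nt_col: str = "NT") -> pd.Series:
    """Per-sample TMB from a pre-counted (sample, T, NT) table (sample = index)."""
    return pd.Series(
        [compute_tmb(int(t), int(nt)) for t, nt in zip(counts[t_col], counts[nt_col])],
        index=counts.index,
        name="tmb",
    )


@dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood-type 95% CI."""

    timeline: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Left-continuous step value of S at time t (the last step <= t)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    p: float


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate with 95% confidence interval."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no survival records")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    timeline = sf.index.to_numpy(dtype=float)
    event_table = kmf.event_table
    return KMCurve(
        timeline=timeline,
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
        n_at_risk=event_table["at_risk"].reindex(timeline).to_numpy(dtype=float),
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test; groups are (time, event) DataFrames or tuples."""
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events observed in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(chi_square=float(res.test_statistic), p=float(res.p_value))


def _times_events(g) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(g, pd.DataFrame):
        return g["os_time"].to_numpy(dtype=float), g["os_event"].to_numpy(dtype=int)
    t, e = g
    return np.asarray(t, dtype=float), np.asarray(e, dtype=int)


def survival_stratify(
    predictions: PredictionResult,
    survival: pd.DataFrame,
    year_days: float = 365.0,
) -> dict:
    """Compare overall survival between predicted responders and non-responders.

    ``survival`` is indexed by sample with ``os_time``/``os_event`` columns.
    Returns KM curves per group, the log-rank result, and the 1-year percent
    survival per group and its difference (responders − non-responders).
    """
    labels = predictions.labels
    common = labels.index.intersection(survival.index)
    labels = labels.loc[common]
    surv = survival.loc[common]
    groups = {}
    for name, flag in (("responder", 1), ("non_responder", 0)):
        sub = surv.loc[labels == flag]
        if len(sub) < 2:
            raise ValueError(f"predicted {name} group has fewer than 2 samples")
        groups[name] = sub
    km = {
        name: km_estimate(g["os_time"], g["os_event"]) for name, g in groups.items()
    }
    lr = logrank_test(groups["responder"], groups["non_responder"])
    s1 = {name: curve.survival_at(year_days) for name, curve in km.items()}
    return {
        "km": km,
        "logrank": lr,
        "survival_at_1yr": s1,
        "survival_at_1yr_difference": s1["responder"] - s1["non_responder"],
        "n": {name: len(g) for name, g in groups.items()},
    }


def combined_tmb_netbio(
    activity: PathwayActivity | pd.DataFrame,
    tmb: pd.Series,
    y,
    spec: ModelSpec | None = None,
) -> tuple[PredictionResult, MetricReport]:
    """LOOCV of the combined model: z-scored pathway activities + z-scored TMB.

    Samples without a TMB value are dropped (logged).  ``y`` is aligned to the
    activity sample order.
    """
    values = activity.values if isinstance(activity, PathwayActivity) else activity
    y = pd.Series(np.asarray(y, dtype=int), index=values.columns)
    have_tmb = values.columns.intersection(tmb.dropna().index)
    n_dropped = values.shape[1] - len(have_tmb)
    if n_dropped:
        logger.info("dropped %d samples without TMB", n_dropped)
    values = values[have_tmb]
    X = zscore_standardize(values).T
    tmb_row = zscore_standardize(tmb.loc[have_tmb].to_frame().T)
    X["TMB"] = tmb_row.iloc[0]
    return loocv(X, y.loc[have_tmb], spec)


def reclassification_sets(
    pred_tmb_only: PredictionResult, pred_combined: PredictionResult
) -> dict[str, set[str]]:
    """Samples whose predicted label flips between the TMB-only and combined
    models: R2NR (responder -> non-responder) and NR2R (the converse)."""
    a, b = pred_tmb_only.labels, pred_combined.labels
    if set(a.index) != set(b.index):
        raise ValueError("prediction results cover different samples")
    b = b.loc[a.index]
    return {
        "R2NR": set(a.index[(a == 1) & (b == 0)]),
        "NR2R": set(a.index[(a == 0) & (b == 1)]),
    }
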