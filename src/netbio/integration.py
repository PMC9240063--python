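"""Combining NetBio predictions with an external score; cohort similarity.

The combined score is a linear blend, w·netbio + (1 − w)·external, with w
swept over {0.0, 0.1, ..., 1.0} and evaluated by ROC AUC.  Cross-cohort
transcriptome similarity restricts both expression matrices to a gene subset
(by default the direct PPI neighbors of the ICI targets) and reports, for
each patient, the maximum Spearman correlation to any patient of the other
cohort.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .response_model import compute_metrics

logger = logging.getLogger("netbio")

__all__ = [
    "W_GRID",
    "rescale_minmax",
    "combine_scores",
    "combination_sweep",
    "score_correlation",
    "transcriptome_similarity",
]

W_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


def rescale_minmax(scores: pd.Series) -> pd.Series:
    """Min-max rescale to [0, 1]; constant input is an error."""
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        raise ValueError("cannot min-max rescale a constant score vector")
    return (scores - lo) / (hi - lo)


def _align(netbio: pd.Series, external: pd.Series) -> tuple[pd.Series, pd.Series]:
    if set(netbio.index) != set(external.index):
        raise ValueError("netbio and external scores cover different samples")
    return netbio, external.loc[netbio.index]


def combine_scores(
    netbio_score: pd.Series,
    external_score: pd.Series,
    w: float,
    rescale_external: bool = True,
) -> pd.Series:
    """Linear weighted combination w·netbio + (1 − w)·external.

    The external score is min-max rescaled to [0, 1] by default so that w is
    comparable across score families.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    netbio_score, external_score = _align(netbio_score, external_score)
    if rescale_external:
        external_score = rescale_minmax(external_score)
    return w * netbio_score + (1.0 - w) * external_score


def combination_sweep(
    netbio_score: pd.Series,
    external_score: pd.Series,
    y,
    grid: Sequence[float] = W_GRID,
    rescale_external: bool = True,
) -> dict:
    """ROC AUC of the combined score at each grid weight; reports the argmax."""
    y = np.asarray(y, dtype=int)
    aucs = {}
    for w in grid:
        combined = combine_scores(
            netbio_score, external_score, w, rescale_external=rescale_external
        )
        aucs[float(w)] = compute_metrics(y, combined.to_numpy()).auc_roc
    best_w = max(aucs, key=lambda w: (aucs[w], w))
    return {"auc_by_w": aucs, "best_w": best_w, "best_auc": aucs[best_w]}


def score_correlation(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties get average ranks.  For n <= 9 the p-value is exact (enumeration of
    the permutation null); larger n uses the t approximation.
    """
    a, b = _align(a, b)
    x = a.to_numpy(dtype=float)
    z = b.to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.unique(x).size == 1 or np.unique(z).size == 1:
        raise ValueError("constant score vector")
    rho, p_t = stats.spearmanr(x, z)
    if n <= 9:
        rx = stats.rankdata(x)
        rz = stats.rankdata(z)
        perms = np.array(list(itertools.permutations(rz)), dtype=float)
        cx = rx - rx.mean()
        cp = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((cx**2).sum() * (cp**2).sum(axis=1))
        rhos = cp @ cx / denom
        p_exact = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return float(rho), p_exact
    return float(rho), float(p_t)


def transcriptome_similarity(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    gene_subset: Iterable[str],
) -> dict:
    """Max-Spearman cross-cohort similarity over a gene subset.

    For every patient of cohort A, the maximum Spearman correlation (over the
    shared subset genes) to any patient of cohort B — and vice versa.  Returns
    both per-patient value series and their medians.
    """
    genes = sorted(set(gene_subset) & set(expr_a.index) & set(expr_b.index))
    if len(genes) < 3:
        raise ValueError("fewer than 3 subset genes shared by both cohorts")
    logger.info("transcriptome similarity over %d shared genes", len(genes))
    ra = _rank_columns(expr_a.loc[genes])
    rb = _rank_columns(expr_b.loc[genes])
    # Pearson on ranks == Spearman
    ra_c = (ra - ra.mean(axis=0)) / ra.std(axis=0, ddof=0)
    rb_c = (rb - rb.mean(axis=0)) / rb.std(axis=0, ddof=0)
    corr = (ra_c.T @ rb_c) / len(genes)  # patients_a × patients_b
    a_to_b = pd.Series(corr.max(axis=1), index=expr_a.columns, name="similarity")
    b_to_a = pd.Series(corr.max(axis=0), index=expr_b.columns, name="similarity")
    return {
        "a_to_b": a_to_b,
        "b_to_a": b_to_a,
        "median_a_to_b": float(a_to_b.median()),
        "median_b_to_a": float(b_to_a.median()),
    }


def _rank_columns(df: pd.DataFrame) -> np.ndarray:
    arr = df.to_numpy(dtype=float)
    return np.apply_along_axis(stats.rankdata, 0, arr)
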