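"""Per-sample pathway activity via single-sample GSEA (ssGSEA).

Gene expression (genes × samples, already normalized) is converted to a
pathways × samples matrix of enrichment scores.  For each sample, genes are
ranked by descending expression; the enrichment score of a gene set is the
sum over all ranks of the difference between the weighted in-set cumulative
rank statistic and the uniform out-of-set cumulative count:

    ES(S) = Σ_i [ P_hit(i) − P_miss(i) ],
    P_hit(i)  = Σ_{g∈S, pos(g)≤i} r_g^α / Σ_{g∈S} r_g^α,
    P_miss(i) = |{g∉S : pos(g)≤i}| / (N − |S|),

with rank statistic r_g = N − pos(g) + 1 and weight α (default 0.25).  ES
matrices are normalized to NES by the global ES range, and features are
z-standardized across samples of one cohort before model training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .netbio_selection import GeneSetCollection

logger = logging.getLogger("netbio")

__all__ = [
    "PathwayActivity",
    "read_expression",
    "write_matrix",
    "ssgsea_es",
    "normalize_es",
    "zscore_standardize",
    "zscore_activity",
]


@dataclass
class PathwayActivity:
    """Pathways × samples activity matrix with a processing-stage tag.

    ``stage`` moves only forward: raw_es -> nes -> zscored.
    """

    values: pd.DataFrame  # pathways × samples
    stage: str = "raw_es"

    _STAGES = ("raw_es", "nes", "zscored")

    def __post_init__(self) -> None:
        if self.stage not in self._STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("activity matrix contains non-finite values")

    @property
    def pathways(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _validate_expression(df)
    return df


def _validate_expression(df: pd.DataFrame) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


def ssgsea_es(
    expr: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.25,
) -> PathwayActivity:
    """Raw ssGSEA enrichment scores for every usable gene set and sample.

    Gene sets are intersected with the expression gene universe first; sets
    left with zero genes, or with every gene (P_miss undefined), are dropped
    with a log message.  Ranking ties are resolved by ascending gene symbol
    after a stable sort on expression value, so results are deterministic.
    """
    _validate_expression(expr)
    genes = expr.index.to_numpy()
    N = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    usable: list[tuple[str, np.ndarray]] = []
    for name, members in collection:
        idx = np.array(sorted(gene_pos[g] for g in members if g in gene_pos), dtype=int)
        n_dropped = len(members) - idx.size
        if n_dropped:
            logger.debug("set %s: %d genes absent from expression", name, n_dropped)
        if idx.size == 0:
            logger.info("dropping set %s: no overlap with expression genes", name)
            continue
        if idx.size == N:
            logger.info("dropping set %s: covers every expressed gene", name)
            continue
        usable.append((name, idx))
    if not usable:
        raise ValueError("no gene set overlaps the expression matrix")

    membership = np.zeros((N, len(usable)), dtype=float)
    set_sizes = np.empty(len(usable))
    for j, (_, idx) in enumerate(usable):
        membership[idx, j] = 1.0
        set_sizes[j] = idx.size

    values = expr.to_numpy(dtype=float)
    # pre-sort gene symbols once: secondary key for expression ties
    symbol_order = np.argsort(genes, kind="stable")
    es = np.empty((len(usable), expr.shape[1]))
    r_full = (N - np.arange(N)).astype(float)  # rank statistic in sorted order
    weights_sorted = r_full**alpha
    for s in range(expr.shape[1]):
        col = values[:, s]
        # descending value, ties by ascending symbol: sort symbols first
        # (stable), then by descending value.
        order = symbol_order[np.argsort(-col[symbol_order], kind="stable")]
        M = membership[order, :]  # N × n_sets in ranked order
        hit_w = M * weights_sorted[:, None]
        p_hit = np.cumsum(hit_w, axis=0) / hit_w.sum(axis=0)
        p_miss = np.cumsum(1.0 - M, axis=0) / (N - set_sizes)[None, :]
        es[:, s] = (p_hit - p_miss).sum(axis=0)

    df = pd.DataFrame(es, index=[name for name, _ in usable], columns=expr.columns)
    return PathwayActivity(df, stage="raw_es")


def normalize_es(esm: PathwayActivity) -> PathwayActivity:
    """Normalized enrichment scores: ES divided by the global ES range."""
    if esm.stage != "raw_es":
        raise ValueError(f"normalize_es expects stage raw_es, got {esm.stage}")
    arr = esm.values.to_numpy()
    rng = arr.max() - arr.min()
    if rng == 0:
        raise ValueError("constant ES matrix: range normalization undefined")
    return PathwayActivity(esm.values / rng, stage="nes")


def zscore_standardize(m: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score across samples (population SD, ddof=0).

    Zero-variance rows map to all-zeros with a warning; fewer than two
    samples is an error.
    """
    if m.shape[1] < 2:
        raise ValueError("z-score standardization needs >= 2 samples")
    arr = m.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    std = arr.std(axis=1, ddof=0, keepdims=True)
    flat = (std == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance rows standardized to zeros", stacklevel=2
        )
    std[std == 0] = 1.0
    out = (arr - mean) / std
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def zscore_activity(pa: PathwayActivity) -> PathwayActivity:
    """z-standardize an NES matrix across samples (stage nes -> zscored)."""
    if pa.stage != "nes":
        raise ValueError(f"zscore_activity expects stage nes, got {pa.stage}")
    return PathwayActivity(zscore_standardize(pa.values), stage="zscored")


def write_matrix(df: pd.DataFrame | PathwayActivity, path: str | Path) -> None:
    """Write a matrix in the expression TSV dialect (rows labelled, header of samples)."""
    if isinstance(df, PathwayActivity):
        df = df.values
    df.to_csv(path, sep="\t")
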