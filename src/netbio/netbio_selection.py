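"""Selection of NetBio pathways.

A pathway is a NetBio biomarker when it is significantly enriched with
target-proximal genes under a one-sided hypergeometric (over-representation)
test, after step-down Šidák (Holm-Šidák) multiple-testing correction at
adjusted P < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .ppi_network import PPINetwork

logger = logging.getLogger("netbio")

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "GMTParseError",
    "read_gmt",
    "write_gmt",
    "hypergeometric_pvalue",
    "holm_sidak_adjust",
    "build_universe",
    "select_netbio_pathways",
]


class GMTParseError(ValueError):
    """Raised on a malformed GMT line or duplicate pathway name."""


@dataclass
class GeneSetCollection:
    """Named gene sets (pathway name -> member gene symbols)."""

    sets: dict[str, frozenset[str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        return GeneSetCollection(
            {n: self.sets[n] for n in names}, source_label=self.source_label
        )


@dataclass
class EnrichmentRecord:
    """Hypergeometric over-representation result for one pathway.

    N genes in the universe, K of them in the pathway, n drawn (proximal),
    k in the overlap.
    """

    pathway: str
    universe_size: int
    pathway_in_universe: int
    proximal_in_universe: int
    overlap: int
    p_raw: float
    p_adjusted: float
    selected: bool
    overlap_genes: frozenset[str] = field(default_factory=frozenset)


def read_gmt(gmt_file: str | Path, source_label: str | None = None) -> GeneSetCollection:
    """Read MSigDB GMT: ``name<TAB>description<TAB>gene...`` per line.

    The description column is discarded; duplicate genes within a set are
    deduplicated; a duplicate pathway name is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(gmt_file) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{gmt_file}: line {lineno}: expected >=3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise GMTParseError(f"{gmt_file}: line {lineno}: duplicate set {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise GMTParseError(f"{gmt_file}: line {lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets, source_label=source_label or str(gmt_file))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, collection.source_label or "na", *sorted(genes)]) + "\n")


def hypergeometric_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size; K: pathway genes in the universe; n: proximal genes
    drawn; k: observed overlap.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent hypergeometric counts N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def holm_sidak_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Šidák adjusted p-values, returned in the input order.

    Sort ascending; the i-th smallest (1-based) becomes
    ``1 - (1 - p)^(m - i + 1)``; a running maximum enforces monotonicity and
    values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out


def build_universe(
    net: PPINetwork | Iterable[str],
    collection: GeneSetCollection,
    mode: str = "network_and_collection",
) -> frozenset[str]:
    """Gene universe for the enrichment test.

    ``network_and_collection`` (default): network nodes that appear in at
    least one pathway — both the drawn genes and the urn live in one
    population.  ``network``: all network nodes.  ``collection``: the union of
    all pathway genes.
    """
    nodes = frozenset(net.nodes()) if hasattr(net, "nodes") else frozenset(net)
    if mode == "network_and_collection":
        return nodes & collection.all_genes()
    if mode == "network":
        return nodes
    if mode == "collection":
        return collection.all_genes()
    raise ValueError(f"unknown universe mode {mode!r}")


def select_netbio_pathways(
    proximal: Sequence[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.01,
    min_set_size: int = 1,
    max_set_size: int | None = None,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of proximal genes in each pathway.

    All pathways with a nonzero intersection with the universe (and within the
    optional size band) are tested jointly; Holm-Šidák adjustment is applied
    over the whole family and a pathway is ``selected`` when its adjusted p is
    below ``alpha``.  Records come back sorted by (p_adjusted, pathway name).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    universe = frozenset(universe)
    proximal_set = frozenset(proximal)
    if not proximal_set:
        raise ValueError("proximal gene set is empty")
    drawn = proximal_set & universe
    if not drawn:
        raise ValueError("no proximal gene lies in the universe")
    if drawn != proximal_set:
        logger.info(
            "%d of %d proximal genes outside the universe were ignored",
            len(proximal_set) - len(drawn),
            len(proximal_set),
        )
    N, n = len(universe), len(drawn)

    tested: list[tuple[str, int, int, frozenset[str]]] = []
    n_skipped = 0
    for name, genes in collection:
        in_universe = genes & universe
        K = len(in_universe)
        if K == 0 or K < min_set_size or (max_set_size is not None and K > max_set_size):
            n_skipped += 1
            continue
        overlap = in_universe & drawn
        tested.append((name, K, len(overlap), overlap))
    if n_skipped:
        logger.info("skipped %d untestable pathways (no/filtered universe overlap)", n_skipped)
    if not tested:
        return []

    p_raw = [hypergeometric_pvalue(N, K, n, k) for _, K, k, _ in tested]
    p_adj = holm_sidak_adjust(p_raw)
    records = [
        EnrichmentRecord(
            pathway=name,
            universe_size=N,
            pathway_in_universe=K,
            proximal_in_universe=n,
            overlap=k,
            p_raw=pr,
            p_adjusted=float(pa),
            selected=bool(pa < alpha),
            overlap_genes=ov,
        )
        for (name, K, k, ov), pr, pa in zip(tested, p_raw, p_adj)
    ]
    records.sort(key=lambda r: (r.p_adjusted, r.pathway))
    return records


def write_enrichment_table(records: Sequence[EnrichmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\tN\tK\tn\tk\tp_raw\tp_adjusted\tselected\n")
        for r in records:
            fh.write(
                f"{r.pathway}\t{r.universe_size}\t{r.pathway_in_universe}\t"
                f"{r.proximal_in_universe}\t{r.overlap}\t{r.p_raw:.6g}\t"
                f"{r.p_adjusted:.6g}\t{r.selected}\n"
            )
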