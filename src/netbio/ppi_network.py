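"""Scored protein–protein interaction networks and network propagation.

The immunotherapy-biomarker pipeline starts from a high-confidence PPI
network (STRING-style scored edge list), restricted to its largest
connected component.  Influence of the drug targets (e.g. PDCD1, CD274,
CTLA4) is spread over the graph with personalized PageRank; the top-k
genes by stationary probability mass are the "target-proximal" genes fed
to pathway enrichment.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger("netbio")

__all__ = [
    "PPINetwork",
    "SeedSet",
    "PropagationResult",
    "NetworkParseError",
    "EmptyNetworkError",
    "load_string_network",
    "read_alias_map",
    "largest_connected_component",
    "propagate",
    "select_proximal_genes",
    "direct_neighbors",
    "write_network",
    "read_network",
]

#: The in-memory network container is an undirected :class:`networkx.Graph`
#: with an integer ``score`` attribute (0–1000) on every edge.
PPINetwork = nx.Graph


class NetworkParseError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


class EmptyNetworkError(ValueError):
    """Raised when filtering leaves no edges, or an operation needs a non-empty graph."""


@dataclass(frozen=True)
class SeedSet:
    """Non-empty set of seed genes (the ICI drug targets)."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("seed set must be non-empty")

    @classmethod
    def of(cls, genes: Iterable[str]) -> "SeedSet":
        return cls(frozenset(genes))

    def present_in(self, net: PPINetwork) -> frozenset[str]:
        return frozenset(g for g in self.genes if g in net)

    def missing_from(self, net: PPINetwork) -> frozenset[str]:
        return self.genes - self.present_in(net)


@dataclass
class PropagationResult:
    """Stationary distribution of a personalized PageRank run.

    ``scores`` is a probability mass over every node of the network
    (non-negative, sums to 1).  ``converged`` is False when the power
    iteration hit ``max_iter`` before the L1 change dropped below ``tol``.
    """

    scores: dict[str, float]
    damping: float
    seeds: SeedSet
    converged: bool = True
    n_iter: int | None = None
    missing_seeds: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        total = sum(self.scores.values())
        if self.converged and abs(total - 1.0) > 1e-9:
            raise ValueError(f"propagation scores sum to {total}, not 1")


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping protein identifiers to gene symbols."""
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            mapping[fields[0]] = fields[1]
    return mapping


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_string_network(
    edge_file: str | Path,
    score_threshold: int = 700,
    aliases: Mapping[str, str] | str | Path | None = None,
    inclusive: bool = False,
) -> PPINetwork:
    """Load a STRING-dialect scored edge list, keeping high-confidence links.

    The file is whitespace/tab delimited with two identifier columns and one
    integer combined-score column (0–1000); a header row is tolerated.  Edges
    are kept when ``score > score_threshold`` (``>=`` with ``inclusive=True``),
    deduplicated as undirected pairs, and self-loops are dropped.

    ``aliases`` optionally maps raw identifiers (e.g. ``9606.ENSP…``) to gene
    symbols; edges with an unmapped endpoint are dropped and counted.
    """
    if aliases is not None and not isinstance(aliases, Mapping):
        aliases = read_alias_map(aliases)

    net = nx.Graph()
    n_unmapped = 0
    with _open_text(edge_file) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise NetworkParseError(
                    f"{edge_file}: line {lineno}: expected 3 columns, got {len(fields)}"
                )
            a, b, raw_score = fields[0], fields[1], fields[2]
            try:
                score = int(raw_score)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise NetworkParseError(
                    f"{edge_file}: line {lineno}: non-integer score {raw_score!r}"
                ) from None
            if aliases is not None:
                if a not in aliases or b not in aliases:
                    n_unmapped += 1
                    continue
                a, b = aliases[a], aliases[b]
            if a == b:
                continue
            keep = score >= score_threshold if inclusive else score > score_threshold
            if keep:
                net.add_edge(a, b, score=score)
    if n_unmapped:
        logger.info("dropped %d edges with unmapped identifiers", n_unmapped)
    if net.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"no edges pass score threshold {score_threshold} in {edge_file}"
        )
    return net


def largest_connected_component(net: PPINetwork) -> PPINetwork:
    """Induced subgraph on the largest connected component.

    Ties between equally sized components are broken in favour of the one
    containing the lexicographically smallest node, so the result is
    deterministic.
    """
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("cannot take the largest component of an empty network")
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    best = comps[0]
    return net.subgraph(best).copy()


def propagate(
    net: PPINetwork,
    seeds: SeedSet,
    damping: float = 0.85,
    tol: float = 1e-6,
    max_iter: int = 100,
    weighted: bool = False,
) -> PropagationResult:
    """Personalized PageRank from the seed genes.

    The restart vector is uniform over the seeds present in the network
    (personalization 1 per seed, normalized), restart probability
    ``1 - damping``.  Each undirected edge acts as two directed edges with
    degree-normalized transition probability; by default the walk ignores the
    STRING scores (``weighted=True`` uses them as edge weights).

    Non-convergence within ``max_iter`` is flagged on the result rather than
    raised.
    """
    if not 0 < damping < 1:
        raise ValueError("damping must be in (0, 1)")
    present = seeds.present_in(net)
    if not present:
        raise ValueError("no seed gene is present in the network")
    missing = seeds.missing_from(net)
    if missing:
        logger.warning("seeds absent from network: %s", ", ".join(sorted(missing)))

    personalization = {g: 1.0 for g in present}
    weight = "score" if weighted else None
    try:
        scores = nx.pagerank(
            net,
            alpha=damping,
            personalization=personalization,
            tol=tol,
            max_iter=max_iter,
            weight=weight,
        )
        converged = True
        n_iter = None
    except nx.PowerIterationFailedConvergence:
        warnings.warn(
            f"personalized PageRank did not converge in {max_iter} iterations",
            stacklevel=2,
        )
        scores, n_iter = _power_iteration(
            net, present, damping, tol, max_iter, weighted=weighted
        )
        converged = False
    return PropagationResult(
        scores=dict(scores),
        damping=damping,
        seeds=seeds,
        converged=converged,
        n_iter=n_iter,
        missing_seeds=missing,
    )


def _power_iteration(
    net: PPINetwork,
    seed_genes: frozenset[str],
    damping: float,
    tol: float,
    max_iter: int,
    weighted: bool = False,
) -> tuple[dict[str, float], int]:
    """Dense power iteration; used only when the sparse solver fails to converge."""
    nodes = list(net.nodes())
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    weight = "score" if weighted else None
    A = nx.to_numpy_array(net, nodelist=nodes, weight=weight)
    out = A.sum(axis=1)
    dangling = out == 0
    out[dangling] = 1.0
    P = A / out[:, None]  # row-stochastic
    v = np.zeros(n)
    for g in seed_genes:
        v[index[g]] = 1.0 / len(seed_genes)
    x = v.copy()
    it = 0
    for it in range(1, max_iter + 1):
        x_new = damping * (x @ P + x[dangling].sum() * v) + (1 - damping) * v
        if np.abs(x_new - x).sum() < n * tol:
            x = x_new
            break
        x = x_new
    return {g: float(x[index[g]]) for g in nodes}, it


def select_proximal_genes(prop: PropagationResult, k: int = 200) -> list[str]:
    """Top-k genes by influence score (descending); ties broken by gene symbol."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(prop.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ordered[:k]]


def direct_neighbors(net: PPINetwork, targets: SeedSet) -> set[str]:
    """Union of first-degree neighbors of the targets, excluding the targets."""
    present = targets.present_in(net)
    if not present:
        raise ValueError("no target gene is present in the network")
    neigh: set[str] = set()
    for t in present:
        neigh.update(net.neighbors(t))
    neigh -= set(targets.genes)
    if not neigh:
        warnings.warn("targets have no neighbors in the network", stacklevel=2)
    return neigh


def write_network(net: PPINetwork, path: str | Path) -> None:
    """Write the graph as a 3-column TSV (geneA, geneB, score)."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, d in sorted(net.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = sorted((a, b))
            fh.write(f"{a}\t{b}\t{d.get('score', 0)}\n")


def read_network(path: str | Path) -> PPINetwork:
    """Read a graph written by :func:`write_network` (no score filtering)."""
    return load_string_network(path, score_threshold=-1)
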