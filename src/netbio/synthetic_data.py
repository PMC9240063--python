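"""Self-contained synthetic cohorts for testing the whole pipeline.

The generator emulates the statistical structure the method assumes:

* a scale-free (preferential-attachment) PPI graph with a couple of
  designated drug-target genes placed at mid-degree nodes;
* a gene-set collection in which a few "planted" pathways are drawn mostly
  from the targets' two-hop network neighborhood while the rest are drawn
  from elsewhere in the graph;
* expression matrices in which planted-pathway genes are mean-shifted in
  responders (a configurable fraction of planted pathways shifts downward,
  emulating negatively associated programs);
* RECIST labels, exponential overall-survival times with a responder hazard
  ratio, independent censoring, and Poisson mutation counts whose log-mean
  is shifted in responders (a TMB signal).

Everything is deterministic given ``rng_seed``; cohort pairs share the
network, collection and planted truth but have independent samples, a
globally attenuated effect in the second cohort, and independent per-cohort
"confounded" pathways (response-linked in one cohort only) emulating
cohort-specific biology.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .netbio_selection import GeneSetCollection, write_gmt
from .ppi_network import PPINetwork, SeedSet, write_network

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_network",
    "generate_genesets",
    "generate_cohort",
    "generate_cohort_pair",
    "write_fixtures",
]


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG: SeedSequence(root, crc32(stage))."""
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    )


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    ``effect_size`` is the responder mean shift of planted-pathway genes in
    units of the expression SD; ``survival_hazard_ratio`` multiplies the
    event hazard for responders; ``tmb_effect`` is the log-scale shift of
    responder mutation-count means.
    """

    rng_seed: int = 0
    n_genes: int = 1000
    attachment: int = 3  # preferential-attachment edges per new node
    n_targets: int = 2
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (15, 60)
    n_planted: int = 5
    negative_planted_fraction: float = 0.2
    n_samples: int = 100
    responder_fraction: float = 0.35
    effect_size: float = 1.0
    tmb_effect: float = 1.0
    base_truncating_mean: float = 5.0
    base_non_truncating_mean: float = 50.0
    survival_hazard_ratio: float = 0.4
    median_survival_nonresponder: float = 300.0  # days
    censor_fraction: float = 0.2
    cohort_shift: float = 0.8  # global delta attenuation in cohort B
    n_confounded: int = 5  # cohort-specific response-linked non-planted pathways

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_pathways, self.n_planted, self.n_samples) <= 0:
            raise ValueError("all counts must be positive")
        for f in (self.responder_fraction, self.censor_fraction):
            if not 0 < f < 1:
                raise ValueError("fractions must lie in (0, 1)")
        if self.pathway_size_range[1] >= self.n_genes:
            raise ValueError("pathway sizes must be smaller than n_genes")


@dataclass
class SyntheticCohort:
    """One simulated cohort plus its generating ground truth."""

    expression: pd.DataFrame  # genes × samples
    clinical: pd.DataFrame  # sample-indexed: recist, response, os_time, os_event
    mutations: pd.DataFrame  # sample-indexed: T, NT
    ground_truth: dict = field(default_factory=dict)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_network(cfg: SyntheticConfig) -> tuple[PPINetwork, SeedSet]:
    """Scale-free scored PPI graph with mid-degree target genes.

    Targets are sampled among nodes whose degree lies between the 40th and
    80th percentile so that planted-pathway recovery exercises propagation
    rather than hub dominance.
    """
    rng = stage_rng(cfg.rng_seed, "network")
    g = nx.barabasi_albert_graph(
        cfg.n_genes, cfg.attachment, seed=int(rng.integers(2**31))
    )
    net = nx.Graph()
    for u, v in g.edges():
        net.add_edge(
            _gene_name(u), _gene_name(v), score=int(rng.integers(701, 1001))
        )
    degrees = dict(net.degree())
    vals = np.array(list(degrees.values()))
    lo, hi = np.percentile(vals, [40, 80])
    mid = sorted(n for n, d in degrees.items() if lo <= d <= hi)
    targets = rng.choice(mid, size=cfg.n_targets, replace=False)
    return net, SeedSet.of(targets.tolist())


def generate_genesets(
    cfg: SyntheticConfig, net: PPINetwork, seeds: SeedSet
) -> tuple[GeneSetCollection, list[str]]:
    """Pathway collection with planted target-proximal sets.

    Planted sets draw at least 80% of their members from the targets'
    two-hop neighborhood (three hops if the neighborhood is too small);
    non-planted sets draw uniformly from genes outside it.
    """
    rng = stage_rng(cfg.rng_seed, "genesets")
    hood: set[str] = set()
    for t in seeds.genes:
        hood |= set(nx.single_source_shortest_path_length(net, t, cutoff=2))
    max_size = cfg.pathway_size_range[1]
    if len(hood) < max_size:
        import warnings

        warnings.warn("2-hop neighborhood too small; enlarging to 3 hops", stacklevel=2)
        for t in seeds.genes:
            hood |= set(nx.single_source_shortest_path_length(net, t, cutoff=3))
    hood_genes = np.array(sorted(hood))
    outside = np.array(sorted(set(net.nodes()) - hood))

    sets: dict[str, frozenset[str]] = {}
    planted: list[str] = []
    lo, hi = cfg.pathway_size_range
    for i in range(cfg.n_pathways):
        name = f"PATHWAY_{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        if i < cfg.n_planted:
            n_in = int(np.ceil(0.8 * size))
            n_in = min(n_in, len(hood_genes))
            members = set(rng.choice(hood_genes, size=n_in, replace=False))
            if size - n_in > 0:
                members |= set(rng.choice(outside, size=size - n_in, replace=False))
            planted.append(name)
        else:
            members = set(rng.choice(outside, size=min(size, len(outside)), replace=False))
        sets[name] = frozenset(members)
    return GeneSetCollection(sets, source_label="synthetic"), planted


def generate_cohort(
    cfg: SyntheticConfig,
    collection: GeneSetCollection,
    planted: list[str],
    cohort_seed: int | None = None,
    delta: float | None = None,
    confounded: list[str] | None = None,
    genes: list[str] | None = None,
) -> SyntheticCohort:
    """Simulate one cohort tied to the planted truth.

    Baseline expression is i.i.d. standard normal per gene and sample; genes
    of each planted pathway gain ``±delta`` in responders (the sign is fixed
    per pathway: the first ``negative_planted_fraction`` of the planted list
    shifts downward).  ``confounded`` pathways — cohort-specific,
    response-linked programs that do not generalize — receive the same
    responder shift in this cohort only.  Survival is exponential with the
    responder hazard ratio and independent censoring; mutation counts are
    Poisson with a responder log-mean shift.
    """
    seed = cfg.rng_seed if cohort_seed is None else cohort_seed
    rng = stage_rng(seed, "cohort")
    delta = cfg.effect_size if delta is None else delta
    n = cfg.n_samples
    samples = [f"S{seed % 997:03d}_{j:03d}" for j in range(n)]
    all_genes = genes if genes is not None else sorted({g for _, gs in collection for g in gs})

    # responder labels + RECIST classes
    n_resp = int(round(cfg.responder_fraction * n))
    response = np.zeros(n, dtype=int)
    response[rng.choice(n, size=n_resp, replace=False)] = 1
    recist = np.where(
        response == 1,
        rng.choice(["CR", "PR"], size=n),
        rng.choice(["SD", "PD"], size=n),
    )

    expr = pd.DataFrame(
        rng.standard_normal((len(all_genes), n)),
        index=all_genes,
        columns=samples,
    )
    n_negative = int(round(cfg.negative_planted_fraction * len(planted)))
    effect_flags: dict[str, float] = {}
    shifted = [
        (name, (-1.0 if i < n_negative else 1.0) * delta)
        for i, name in enumerate(planted)
    ] + [(name, delta) for name in (confounded or [])]
    for name, shift in shifted:
        for g in collection.sets[name]:
            # overlapping pathways: keep the largest-magnitude shift
            if abs(shift) > abs(effect_flags.get(g, 0.0)):
                effect_flags[g] = shift
    resp_cols = np.array(samples)[response == 1]
    for g, shift in effect_flags.items():
        expr.loc[g, resp_cols] += shift

    # exponential survival with responder hazard ratio, independent censoring
    base_rate = np.log(2.0) / cfg.median_survival_nonresponder
    rate = np.where(response == 1, base_rate * cfg.survival_hazard_ratio, base_rate)
    os_time = rng.exponential(1.0 / rate)
    censored = rng.random(n) < cfg.censor_fraction
    os_event = (~censored).astype(int)
    os_time = np.where(censored, os_time * rng.random(n), os_time)

    # mutation counts: responders have exp(tmb_effect)-fold higher means
    mult = np.where(response == 1, np.exp(cfg.tmb_effect), 1.0)
    t_counts = rng.poisson(cfg.base_truncating_mean * mult)
    nt_counts = rng.poisson(cfg.base_non_truncating_mean * mult)

    clinical = pd.DataFrame(
        {
            "recist": recist,
            "response": response,
            "os_time": np.round(os_time, 2),
            "os_event": os_event,
        },
        index=pd.Index(samples, name="sample"),
    )
    mutations = pd.DataFrame(
        {"T": t_counts, "NT": nt_counts}, index=pd.Index(samples, name="sample")
    )
    return SyntheticCohort(
        expression=expr,
        clinical=clinical,
        mutations=mutations,
        ground_truth={
            "planted_pathways": list(planted),
            "confounded_pathways": list(confounded or []),
            "gene_effects": effect_flags,
            "delta": delta,
        },
    )


def generate_cohort_pair(
    cfg: SyntheticConfig,
) -> tuple[SyntheticCohort, SyntheticCohort, PPINetwork, SeedSet, GeneSetCollection, list[str]]:
    """Two cohorts sharing network/collection/planted truth, independent samples.

    Cohort B's effect size is attenuated globally by ``cohort_shift``, and
    each cohort independently draws ``n_confounded`` non-planted pathways
    that are response-shifted in that cohort only — cohort-specific biology
    that makes purely data-driven feature selection overfit its training
    cohort while the network-selected planted pathways transfer.
    """
    net, seeds = generate_network(cfg)
    collection, planted = generate_genesets(cfg, net, seeds)
    non_planted = sorted(set(collection.sets) - set(planted))
    rng_a = stage_rng(cfg.rng_seed, "confound_a")
    rng_b = stage_rng(cfg.rng_seed, "confound_b")
    conf_a = sorted(rng_a.choice(non_planted, size=cfg.n_confounded, replace=False))
    conf_b = sorted(rng_b.choice(non_planted, size=cfg.n_confounded, replace=False))
    all_genes = sorted(net.nodes())
    cohort_a = generate_cohort(
        cfg,
        collection,
        planted,
        cohort_seed=cfg.rng_seed * 2 + 1,
        confounded=conf_a,
        genes=all_genes,
    )
    cohort_b = generate_cohort(
        cfg,
        collection,
        planted,
        cohort_seed=cfg.rng_seed * 2 + 2,
        delta=cfg.effect_size * cfg.cohort_shift,
        confounded=conf_b,
        genes=all_genes,
    )
    return cohort_a, cohort_b, net, seeds, collection, planted


def write_fixtures(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write all fixture files (graph TSV, GMT, expression/clinical/mutation
    TSVs for both cohorts, ground-truth JSON).  Byte-identical across runs
    with the same config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a, b, net, seeds, collection, planted = generate_cohort_pair(cfg)
    paths: dict[str, Path] = {}

    paths["network"] = outdir / "network.tsv"
    write_network(net, paths["network"])
    paths["genesets"] = outdir / "pathways.gmt"
    write_gmt(collection, paths["genesets"])
    for label, cohort in (("a", a), ("b", b)):
        paths[f"expression_{label}"] = outdir / f"expression_{label}.tsv"
        cohort.expression.to_csv(paths[f"expression_{label}"], sep="\t")
        paths[f"clinical_{label}"] = outdir / f"clinical_{label}.tsv"
        cohort.clinical.to_csv(paths[f"clinical_{label}"], sep="\t")
        paths[f"mutations_{label}"] = outdir / f"mutations_{label}.tsv"
        cohort.mutations.to_csv(paths[f"mutations_{label}"], sep="\t")
    paths["ground_truth"] = outdir / "ground_truth.json"
    truth = {
        "seed_genes": sorted(seeds.genes),
        "planted_pathways": planted,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
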