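"""Shared fixtures: small graphs and the default synthetic benchmark.

The benchmark bundle is session-scoped because LOOCV with the inner grid
search is the expensive part of the suite; tests share one realization of
the default study conditions (fixed seed) rather than regenerating it.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netbio import (
    ModelSpec,
    SeedSet,
    build_universe,
    loocv,
    propagate,
    select_netbio_pathways,
    select_proximal_genes,
)
from netbio.synthetic_data import SyntheticConfig, generate_cohort, generate_cohort_pair
from netbio.workflow import _score_cohort

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark: cohort pair + network pipeline outputs."""
    cfg = SyntheticConfig(rng_seed=BENCHMARK_SEED)
    cohort_a, cohort_b, net, seeds, collection, planted = generate_cohort_pair(cfg)
    prop = propagate(net, seeds)
    proximal = select_proximal_genes(prop, k=200)
    universe = build_universe(net, collection)
    records = select_netbio_pathways(proximal, collection, universe, alpha=0.01)
    selected = [r.pathway for r in records if r.selected]
    return {
        "cfg": cfg,
        "cohort_a": cohort_a,
        "cohort_b": cohort_b,
        "net": net,
        "seeds": seeds,
        "collection": collection,
        "planted": planted,
        "proximal": proximal,
        "universe": universe,
        "records": records,
        "selected": selected,
    }


@pytest.fixture(scope="session")
def benchmark_single(benchmark):
    """One clean single cohort (no confounding) on the shared truth, with its
    z-scored NetBio feature matrix and LOOCV result."""
    cfg = benchmark["cfg"]
    cohort = generate_cohort(
        cfg,
        benchmark["collection"],
        benchmark["planted"],
        genes=sorted(benchmark["net"].nodes()),
    )
    features = _score_cohort(
        cohort.expression, benchmark["collection"].subset(benchmark["selected"]), 0.25
    )
    y = cohort.clinical["response"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred, report = loocv(features, y, ModelSpec(rng_seed=BENCHMARK_SEED))
    return {"cohort": cohort, "features": features, "y": y, "pred": pred, "report": report}


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edge("A", "B", score=900)
    return g


@pytest.fixture
def two_component_graph():
    g = nx.Graph()
    for a, b in [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")]:  # 5 nodes
        g.add_edge(a, b, score=800)
    for a, b in [("X", "Y"), ("Y", "Z")]:  # 3 nodes
        g.add_edge(a, b, score=800)
    return g


@pytest.fixture
def tiny_expression():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(10)]
    samples = [f"s{j}" for j in range(4)]
    return pd.DataFrame(rng.standard_normal((10, 4)), index=genes, columns=samples)
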