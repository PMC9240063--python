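"""End-to-end pipeline orchestration.

One YAML config drives the stage chain
network -> propagation -> pathway selection -> ssGSEA scoring -> evaluation
(-> survival / combination), writing every intermediate artifact plus a
machine-readable run manifest (config, seed, content hash and row count per
artifact).  All randomness derives from a single root seed expanded per
stage by name hashing, so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    integration,
    netbio_selection,
    pathway_activity,
    ppi_network,
    response_model,
    survival_tmb,
)
from .synthetic_data import stage_rng

logger = logging.getLogger("netbio")

__all__ = ["PipelineConfig", "run_end_to_end"]

MODES = ("loocv", "mccv", "across_study", "survival", "combine")


@dataclasses.dataclass
class PipelineConfig:
    """File paths and thresholds for one pipeline run."""

    links_file: str
    gmt_file: str
    expression_file: str
    clinical_file: str
    out_dir: str
    seed_genes: list[str] = dataclasses.field(default_factory=list)
    aliases_file: str | None = None
    expression_file_test: str | None = None
    clinical_file_test: str | None = None
    mutations_file: str | None = None
    external_score_file: str | None = None
    score_threshold: int = 700
    damping: float = 0.85
    pagerank_tol: float = 1e-6
    pagerank_max_iter: int = 100
    top_k: int = 200
    alpha: float = 0.01
    universe: str = "network_and_collection"
    ssgsea_alpha: float = 0.25
    n_iter: int = 100
    train_frac: float = 0.8
    year_days: float = 365.0
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _count_rows(path: Path) -> int:
    try:
        with open(path) as fh:
            return sum(1 for _ in fh)
    except UnicodeDecodeError:
        return -1


class _Manifest:
    def __init__(self, cfg: PipelineConfig, mode: str):
        self.data = {
            "config": cfg.to_dict(),
            "mode": mode,
            "rng_seed": cfg.rng_seed,
            "artifacts": {},
            "stages": {},
        }

    def add(self, stage: str, path: Path) -> None:
        self.data["artifacts"][path.name] = {
            "stage": stage,
            "sha256": _sha256(path),
            "rows": _count_rows(path),
        }

    def time_stage(self, stage: str, seconds: float) -> None:
        self.data["stages"][stage] = {"seconds": round(seconds, 3)}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _load_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "response" not in df.columns:
        df["response"] = response_model.binarize_recist(df["recist"])
    return df


def _score_cohort(
    expr: pd.DataFrame, collection, ssgsea_alpha: float
) -> pd.DataFrame:
    """ssGSEA -> NES -> z-scored features as a samples × pathways frame."""
    es = pathway_activity.ssgsea_es(expr, collection, alpha=ssgsea_alpha)
    nes = pathway_activity.normalize_es(es)
    z = pathway_activity.zscore_activity(nes)
    return z.values.T


def run_end_to_end(cfg: PipelineConfig, mode: str = "loocv") -> dict:
    """Run the configured stage chain; returns the manifest dictionary."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(cfg, mode)
    spec = response_model.ModelSpec(
        rng_seed=int(stage_rng(cfg.rng_seed, "model").integers(2**31))
    )

    current_stage = "setup"

    def staged(stage):
        nonlocal current_stage
        current_stage = stage
        t0 = time.perf_counter()

        def done(*paths: Path):
            manifest.time_stage(stage, time.perf_counter() - t0)
            for p in paths:
                manifest.add(stage, p)

        return done

    try:
        # --- network + propagation -------------------------------------
        done = staged("network")
        net = ppi_network.load_string_network(
            cfg.links_file, cfg.score_threshold, aliases=cfg.aliases_file
        )
        net = ppi_network.largest_connected_component(net)
        graph_path = out / "network_lcc.tsv"
        ppi_network.write_network(net, graph_path)
        done(graph_path)

        done = staged("propagation")
        seeds = ppi_network.SeedSet.of(cfg.seed_genes)
        prop = ppi_network.propagate(
            net,
            seeds,
            damping=cfg.damping,
            tol=cfg.pagerank_tol,
            max_iter=cfg.pagerank_max_iter,
        )
        proximal = ppi_network.select_proximal_genes(prop, k=cfg.top_k)
        proximal_path = out / "proximal_genes.txt"
        proximal_path.write_text("\n".join(proximal) + "\n")
        done(proximal_path)

        # --- pathway selection ------------------------------------------
        done = staged("selection")
        collection = netbio_selection.read_gmt(cfg.gmt_file)
        universe = netbio_selection.build_universe(net, collection, mode=cfg.universe)
        records = netbio_selection.select_netbio_pathways(
            proximal, collection, universe, alpha=cfg.alpha
        )
        enrich_path = out / "netbio_pathways.tsv"
        netbio_selection.write_enrichment_table(records, enrich_path)
        selected = [r.pathway for r in records if r.selected]
        if not selected:
            raise RuntimeError("no NetBio pathway selected at the configured alpha")
        done(enrich_path)

        # --- scoring ----------------------------------------------------
        done = staged("scoring")
        expr = pathway_activity.read_expression(cfg.expression_file)
        features = _score_cohort(expr, collection.subset(selected), cfg.ssgsea_alpha)
        activity_path = out / "activity.tsv"
        pathway_activity.write_matrix(features.T, activity_path)
        done(activity_path)

        clinical = _load_clinical(cfg.clinical_file)
        y = clinical.loc[features.index, "response"].to_numpy(dtype=int)

        # --- evaluation --------------------------------------------------
        done = staged(mode)
        metrics_path = out / "metrics.json"
        pred_path = out / "predictions.tsv"
        if mode == "loocv":
            pred, report = response_model.loocv(features, y, spec)
            pred.to_frame().to_csv(pred_path, sep="\t")
            metrics_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
            done(pred_path, metrics_path)
        elif mode == "mccv":
            reports = response_model.monte_carlo_cv(
                features, y, spec, n_iter=cfg.n_iter, train_frac=cfg.train_frac
            )
            aucs = [r.auc_roc for r in reports]
            summary = {
                "iterations": [r.to_dict() for r in reports],
                "mean_auc": float(np.mean(aucs)),
                "sd_auc": float(np.std(aucs, ddof=1)),
            }
            metrics_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
            done(metrics_path)
        elif mode == "across_study":
            if not (cfg.expression_file_test and cfg.clinical_file_test):
                raise ValueError("across_study mode needs test expression+clinical files")
            expr_b = pathway_activity.read_expression(cfg.expression_file_test)
            features_b = _score_cohort(
                expr_b, collection.subset(selected), cfg.ssgsea_alpha
            )
            pred = response_model.across_study_predict(features, y, features_b, spec)
            clin_b = _load_clinical(cfg.clinical_file_test)
            y_b = clin_b.loc[pred.probabilities.index, "response"].to_numpy(dtype=int)
            report = response_model.compute_metrics(y_b, pred.probabilities.to_numpy())
            pred.to_frame().to_csv(pred_path, sep="\t")
            metrics_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
            done(pred_path, metrics_path)
        elif mode == "survival":
            pred, report = response_model.loocv(features, y, spec)
            pred.to_frame().to_csv(pred_path, sep="\t")
            strat = survival_tmb.survival_stratify(
                pred, clinical, year_days=cfg.year_days
            )
            survival_path = out / "survival_report.json"
            survival_path.write_text(
                json.dumps(
                    {
                        "logrank_chi_square": strat["logrank"].chi_square,
                        "logrank_p": strat["logrank"].p,
                        "survival_at_1yr": strat["survival_at_1yr"],
                        "survival_at_1yr_difference": strat["survival_at_1yr_difference"],
                        "n": strat["n"],
                        "loocv_metrics": report.to_dict(),
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            metrics_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
            done(pred_path, metrics_path, survival_path)
        elif mode == "combine":
            pred_netbio, _ = response_model.loocv(features, y, spec)
            if cfg.external_score_file:
                ext = pd.read_csv(cfg.external_score_file, sep="\t", index_col=0).iloc[:, 0]
                sweep = integration.combination_sweep(
                    pred_netbio.probabilities, ext.loc[pred_netbio.probabilities.index], y
                )
                metrics_path.write_text(json.dumps(sweep, indent=2, sort_keys=True))
            elif cfg.mutations_file:
                counts = pd.read_csv(cfg.mutations_file, sep="\t", index_col=0)
                tmb = survival_tmb.tmb_from_counts(counts)
                activity = pathway_activity.PathwayActivity(features.T, stage="zscored")
                pred_comb, report = survival_tmb.combined_tmb_netbio(
                    activity.values, tmb, y, spec
                )
                pred_comb.to_frame().to_csv(pred_path, sep="\t")
                metrics_path.write_text(
                    json.dumps(report.to_dict(), indent=2, sort_keys=True)
                )
            else:
                raise ValueError("combine mode needs external_score_file or mutations_file")
            done(metrics_path)
    except Exception as e:
        raise RuntimeError(
            f"pipeline failed in stage {current_stage!r}; partial outputs under {out}"
        ) from e

    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    logger.info("run complete; manifest at %s", manifest_path)
    return manifest.data
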