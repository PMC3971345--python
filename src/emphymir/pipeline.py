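"""End-to-end pipeline driver: simulate -> preprocess -> screen ->
network -> enrichment -> knockdown, with a machine-readable run report
recording counts at every filter step.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as emio
from .enrichment import enrichment_matrix
from .knockdown import (
    cross_dataset_enrichment,
    ks_target_shift,
    moderated_t,
    top_upregulated_targets,
)
from .lmm import lrt_screen, position_screen
from .network import (
    build_network,
    connectivity,
    edge_screen_all,
    summarize_edges,
    to_graphml,
    to_sif,
)
from .preprocess import preprocess_probe_table
from .synthetic import (
    CohortConfig,
    generate_cohort,
    generate_knockdown_experiment,
    generate_prediction_table,
    make_gene_sets,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Thresholds, sizes, and output paths for one reproducible run.

    Thresholds default to the analysis conventions: severity screen at
    P < 0.05, network and enrichment at FDR < 0.25, features present
    in at least 80% of samples, hubs above 50 targets, the top 100
    derepressed targets carried across datasets.
    """

    outdir: str = "run_out"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    p_screen: float = 0.05
    fdr_network: float = 0.25
    fdr_gsea: float = 0.25
    min_present: float = 0.8
    pca_sd: float = 3.0
    hub_threshold: int = 50
    top_n_targets: int = 100
    gsea_n_perm: int = 200
    run_enrichment_matrix: bool = True
    fdr_family: str = "joint"

    def validate(self) -> None:
        for name in ("p_screen", "fdr_network", "fdr_gsea", "min_present"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.hub_threshold < 1 or self.top_n_targets < 1:
            raise ValueError("count thresholds must be >= 1")
        self.cohort.validate()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order on a synthetic cohort.

    Returns the run report (also written to ``outdir/report.json``)
    with in/out counts at each filter step, headline statistics, and
    the seed, so a rerun with the same config is byte-identical modulo
    the timestamp.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    # -- simulate ------------------------------------------------------
    cohort_cfg = config.cohort
    cohort_cfg.seed = config.seed
    cohort = generate_cohort(cohort_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    predictions = generate_prediction_table(
        cohort.truth, list(cohort.mirna.index), list(cohort.gene.index), rng=rng
    )
    kd_expr, kd_groups = generate_knockdown_experiment(
        list(cohort.gene.index),
        cohort.truth.knockdown_targets,
        fold_range=cohort_cfg.knockdown_fold_range,
        rng=np.random.default_rng(np.random.SeedSequence([config.seed, 2])),
    )
    gene_sets = make_gene_sets(
        cohort.truth, list(cohort.gene.index),
        rng=np.random.default_rng(np.random.SeedSequence([config.seed, 3])),
    )
    emio.write_cohort(cohort, outdir / "inputs", predictions,
                      (kd_expr, kd_groups), gene_sets)
    report["simulate"] = {
        "n_samples": len(cohort.metadata),
        "n_patients": cohort.metadata["patient_id"].nunique(),
        "n_mirna": len(cohort.mirna),
        "n_gene": len(cohort.gene),
        "n_predicted_pairs": len(predictions),
        "hub_mirna": cohort.truth.hub_mirna,
    }

    # -- preprocess ----------------------------------------------------
    prep = preprocess_probe_table(
        cohort.probe_table, min_present=config.min_present, pca_sd=config.pca_sd
    )
    mirna = prep.matrix
    kept_samples = list(mirna.columns)
    meta = cohort.metadata.loc[kept_samples]
    gene = cohort.gene[kept_samples]
    report["preprocess"] = {
        "n_features_in": prep.qc["n_features_initial"],
        "n_features_out": prep.qc["n_features_kept"],
        "n_features_dropped": len(prep.dropped_features),
        "n_samples_in": prep.qc["n_samples"],
        "n_samples_out": prep.qc["n_kept"],
        "samples_excluded": sorted(
            set(prep.qc["excluded_pca"]) | set(prep.qc["excluded_present_frac"])
        ),
    }
    emio.write_expression_tsv(mirna, outdir / "mirna_matrix.tsv")

    # -- severity and position screens ---------------------------------
    screen = lrt_screen(mirna, meta)
    screen_pos = position_screen(mirna, meta)
    screen.to_csv(outdir / "screen_lm.tsv", sep="\t", index_label="feature_id")
    screen_pos.to_csv(outdir / "screen_position.tsv", sep="\t", index_label="feature_id")
    sig = screen.loc[screen["ok"] & (screen["p"] < config.p_screen)]
    report["screen"] = {
        "n_screened": int(screen["ok"].sum()),
        "n_significant": len(sig),
        "expected_by_chance": round(float(screen["ok"].sum()) * config.p_screen, 2),
        "n_position_significant": int(
            (screen_pos["ok"] & (screen_pos["p"] < config.p_screen)).sum()
        ),
    }

    # -- network -------------------------------------------------------
    edge_stats = edge_screen_all(gene, mirna.loc[sig.index], meta,
                                 fdr_family=config.fdr_family)
    edges = build_network(edge_stats, predictions, fdr_cutoff=config.fdr_network)
    conn = connectivity(edges, screen, hub_threshold=config.hub_threshold)
    edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    conn.to_csv(outdir / "connectivity.tsv", sep="\t", index_label="mirna_id")
    to_graphml(edges, outdir / "network.graphml", screen)
    to_sif(edges, outdir / "network.sif")
    report["network"] = {
        "n_pairs_tested": len(edge_stats),
        **summarize_edges(edges),
        "hubs": list(conn.index[conn["hub"]]),
    }

    # -- per-miRNA rankings and the pathway matrix ---------------------
    rankings = {
        m: pd.Series(
            sub["t"].to_numpy(), index=sub["gene_id"].to_numpy(), name=m
        ).dropna()
        for m, sub in edge_stats.groupby("mirna_id")
    }
    if config.run_enrichment_matrix and rankings:
        up = [m for m in rankings if float(screen.loc[m, "direction"]) > 0]
        mat = enrichment_matrix(
            {m: rankings[m] for m in up},
            gene_sets,
            fdr=config.fdr_gsea,
            n_perm=config.gsea_n_perm,
            seed=config.seed,
        )
        mat.to_csv(outdir / "enrichment_matrix.tsv", sep="\t", index_label="mirna_id")
        report["enrichment"] = {
            "n_mirnas_up": len(up),
            "n_sets": mat.shape[1],
            "n_negative_entries": int((mat.to_numpy() == -1).sum()),
            "n_positive_entries": int((mat.to_numpy() == 1).sum()),
        }

    # -- knockdown integration -----------------------------------------
    hub = cohort.truth.hub_mirna
    if hub is not None and hub in rankings:
        mod = moderated_t(kd_expr, kd_groups)
        mod.table.to_csv(outdir / "moderated_t.tsv", sep="\t", index_label="gene_id")
        hub_predicted = predictions.loc[
            predictions["mirna_id"] == hub, "gene_id"
        ].unique()
        ks = ks_target_shift(mod.table["t"], hub_predicted)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            top = top_upregulated_targets(mod, predictions, hub, n=config.top_n_targets)
        emio.write_gmt({f"{hub}_top_derepressed": top}, outdir / "derepressed.gmt")
        cross = cross_dataset_enrichment(
            rankings[hub], top, all_predicted=list(hub_predicted),
            n_perm=1000, seed=config.seed,
        )
        report["knockdown"] = {
            "hub": hub,
            "d0": mod.d0,
            "n_predicted_targets": len(hub_predicted),
            "ks_d": ks.d,
            "ks_p": ks.p,
            "ks_direction": ks.direction,
            "top_set_size": len(top),
            "cross_nes": cross["nes"],
            "cross_q": cross["q_gsea"],
            "cross_ks_p": cross["ks"].p,
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
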