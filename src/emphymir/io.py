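"""Readers and writers for the pipeline's plain-text formats.

Conventions: features are rows and samples are columns everywhere;
all matrices are tab separated with the feature id in the first
column; GMT files follow the MSigDB layout (name, description, then
one gene per field). Every reader validates ids and raises on
duplicates or sample mismatches; read(write(x)) is the identity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CohortData, GroundTruth

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_probe_table",
    "write_probe_table",
    "read_predictions",
    "write_predictions",
    "read_gmt",
    "write_gmt",
    "read_truth",
    "write_truth",
    "check_samples_match",
    "write_cohort",
]


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated feature id {dup!r} in {path}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicated sample id in {path}")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path, index_label="feature_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    required = {"patient_id", "group", "slice", "lm_um"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta.index.has_duplicates:
        raise ValueError("duplicated sample id in metadata")
    if (meta["lm_um"] <= 0).any():
        raise ValueError("lm_um must be positive")
    return meta


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    for col in ("probe_id", "feature_id", "replicate", "is_background"):
        if col not in df.columns:
            raise ValueError(f"probe table missing column {col!r}")
    if df["probe_id"].duplicated().any():
        raise ValueError("duplicated probe id")
    df["is_background"] = df["is_background"].astype(str).str.lower().isin(
        ["true", "1"]
    ) | (df["is_background"] == True)  # noqa: E712 - tolerate bool dtype
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_probe_table(probe_table: pd.DataFrame, path) -> None:
    probe_table.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"mirna_id", "gene_id"} <= set(df.columns):
        raise ValueError("prediction table needs mirna_id and gene_id columns")
    if df.duplicated(["mirna_id", "gene_id"]).any():
        raise ValueError("duplicated (mirna, gene) pair in predictions")
    source_cols = [c for c in df.columns if c.startswith("source_")]
    if "n_sources" not in df.columns:
        if not source_cols:
            raise ValueError("predictions need source_* flags or n_sources")
        df["n_sources"] = df[source_cols].sum(axis=1)
    return df


def write_predictions(predictions: pd.DataFrame, path) -> None:
    predictions.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, genes")
            name, desc, *genes = parts
            if name in sets:
                raise ValueError(f"duplicated gene set name {name!r}")
            sets[name] = [g for g in genes if g]
            descriptions[name] = desc
    read_gmt.descriptions = descriptions  # type: ignore[attr-defined]
    return sets


def write_gmt(collection: dict[str, list[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "lm_mirnas": truth.lm_mirnas,
        "slice_mirnas": truth.slice_mirnas,
        "circuits": [list(c) for c in truth.circuits],
        "hub_mirna": truth.hub_mirna,
        "knockdown_targets": truth.knockdown_targets,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        lm_mirnas=payload["lm_mirnas"],
        slice_mirnas=payload["slice_mirnas"],
        circuits=[tuple(c) for c in payload["circuits"]],
        hub_mirna=payload["hub_mirna"],
        knockdown_targets=payload["knockdown_targets"],
    )


def check_samples_match(matrix: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Hard error naming any matrix sample missing from the metadata."""
    missing = [s for s in matrix.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")


def write_cohort(cohort: CohortData, outdir, predictions=None,
                 knockdown=None, gene_sets=None) -> dict[str, str]:
    """Write a synthetic cohort's files into ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": str(outdir / "probes.tsv"),
        "genes": str(outdir / "genes.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_probe_table(cohort.probe_table, paths["probes"])
    write_expression_tsv(cohort.gene, paths["genes"], index_label="gene_id")
    write_metadata_tsv(cohort.metadata, paths["metadata"])
    write_truth(cohort.truth, paths["truth"])
    if predictions is not None:
        paths["predictions"] = str(outdir / "predictions.tsv")
        write_predictions(predictions, paths["predictions"])
    if knockdown is not None:
        expr, groups = knockdown
        paths["knockdown"] = str(outdir / "knockdown.tsv")
        write_expression_tsv(expr, paths["knockdown"], index_label="gene_id")
        paths["knockdown_groups"] = str(outdir / "knockdown_groups.tsv")
        groups.rename("group").to_csv(paths["knockdown_groups"], sep="\t",
                                      index_label="sample_id")
    if gene_sets is not None:
        paths["gmt"] = str(outdir / "gene_sets.gmt")
        write_gmt(gene_sets, paths["gmt"])
    return paths
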