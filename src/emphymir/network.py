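"""miRNA-mRNA co-expression network construction.

For each screened miRNA, every gene is regressed on the miRNA's
expression with the same random-intercept machinery used for the
severity screen (gene as response; intercept + slice fixed effects +
patient random intercept; the miRNA's expression as the tested fixed
effect). Pairs passing a lenient FDR cutoff (default 0.25) are
intersected with a multi-source target-prediction table to form signed
edges; per-miRNA connectivity identifies hub regulators.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .lmm import _fit_many, bh_fdr, lrt_pvalue

__all__ = [
    "edge_screen",
    "edge_screen_all",
    "build_network",
    "connectivity",
    "summarize_edges",
    "collapse_duplicate_genes",
    "to_graphml",
    "to_sif",
]


def collapse_duplicate_genes(gene_matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated gene symbol, the highest-variance row."""
    if gene_matrix.index.is_unique:
        return gene_matrix
    var = gene_matrix.var(axis=1)
    order = np.argsort(-var.to_numpy(), kind="stable")
    dedup = gene_matrix.iloc[order]
    dedup = dedup[~dedup.index.duplicated(keep="first")]
    return dedup.loc[pd.unique(gene_matrix.index)]


def _screen_designs(metadata: pd.DataFrame, samples: list[str]):
    meta = metadata.loc[samples]
    codes = pd.factorize(meta["patient_id"].to_numpy())[0]
    n = len(samples)
    X0 = np.column_stack([np.ones(n), meta["slice"].to_numpy(float)])
    return codes, X0


def edge_screen(
    gene_matrix: pd.DataFrame,
    mirna_vector: pd.Series,
    metadata: pd.DataFrame,
    _null_fit: dict | None = None,
) -> pd.DataFrame:
    """Association of every gene with one miRNA's expression.

    Returns per-gene beta (of the miRNA term), Wald t, LRT statistic
    and its p-value.  No q-values here: BH is applied jointly over
    the full (miRNA x gene) family by :func:`edge_screen_all`.
    """
    samples = list(gene_matrix.columns)
    codes, X0 = _screen_designs(metadata, samples)
    Y = gene_matrix.to_numpy(float)
    fit0 = _null_fit if _null_fit is not None else _fit_many(Y, X0, codes)
    m = mirna_vector.loc[samples].to_numpy(float)
    X1 = np.column_stack([X0, m])
    fit1 = _fit_many(Y, X1, codes)
    lrt = np.maximum(2.0 * (fit1["loglik"] - fit0["loglik"]), 0.0)
    beta = fit1["beta"][:, -1]
    se = fit1["se"][:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.nan)
    return pd.DataFrame(
        {
            "mirna_id": mirna_vector.name,
            "gene_id": gene_matrix.index,
            "beta": beta,
            "t": t,
            "lrt": lrt,
            "p": lrt_pvalue(lrt, len(samples), X1.shape[1]),
        }
    )


def edge_screen_all(
    gene_matrix: pd.DataFrame,
    mirna_matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    fdr_family: str = "joint",
) -> pd.DataFrame:
    """Edge statistics for every (screened miRNA, gene) pair.

    The null model (no miRNA term) is identical for every miRNA and is
    fitted once. ``fdr_family`` selects the BH family: ``"joint"``
    corrects over all pairs at once (the stricter reading);
    ``"per_mirna"`` corrects each miRNA's gene family separately.
    """
    if fdr_family not in ("joint", "per_mirna"):
        raise ValueError("fdr_family must be 'joint' or 'per_mirna'")
    gene_matrix = collapse_duplicate_genes(gene_matrix)
    samples = list(gene_matrix.columns)
    codes, X0 = _screen_designs(metadata, samples)
    null_fit = _fit_many(gene_matrix.to_numpy(float), X0, codes)
    frames = [
        edge_screen(gene_matrix, mirna_matrix.loc[m], metadata, _null_fit=null_fit)
        for m in mirna_matrix.index
    ]
    out = pd.concat(frames, ignore_index=True)
    if fdr_family == "joint":
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = out.groupby("mirna_id")["p"].transform(
            lambda p: bh_fdr(p.to_numpy())
        )
    return out


def build_network(
    edge_stats: pd.DataFrame,
    predictions: pd.DataFrame,
    fdr_cutoff: float = 0.25,
) -> pd.DataFrame:
    """Intersect FDR-passing pairs with predicted target pairs.

    Retains pairs with q < ``fdr_cutoff`` that appear in the
    prediction table with at least one supporting source; annotates
    the correlation sign and the number of sources (edge weight in
    exports).
    """
    if predictions.empty:
        warnings.warn("prediction table is empty: returning an empty network")
        cols = ["mirna_id", "gene_id", "beta", "t", "p", "q", "sign", "n_sources"]
        return pd.DataFrame(columns=cols)
    sig = edge_stats.loc[edge_stats["q"] < fdr_cutoff]
    pred = predictions.loc[predictions["n_sources"] >= 1, ["mirna_id", "gene_id", "n_sources"]]
    edges = sig.merge(pred, on=["mirna_id", "gene_id"], how="inner")
    edges["sign"] = np.where(edges["beta"] >= 0, "+", "-")
    return edges.reset_index(drop=True)


def connectivity(
    edge_table: pd.DataFrame,
    screen_result: pd.DataFrame | None = None,
    hub_threshold: int = 50,
) -> pd.DataFrame:
    """Per-miRNA target counts and hub flags.

    ``screen_result`` (the severity screen) supplies each miRNA's
    direction of change with emphysema when available.
    """
    if edge_table.empty:
        return pd.DataFrame(
            columns=["mirna_id", "n_targets", "n_pos", "n_neg", "hub", "direction"]
        ).set_index("mirna_id")
    grp = edge_table.groupby("mirna_id")
    summary = pd.DataFrame(
        {
            "n_targets": grp.size(),
            "n_pos": grp["sign"].apply(lambda s: int((s == "+").sum())),
            "n_neg": grp["sign"].apply(lambda s: int((s == "-").sum())),
        }
    )
    summary["hub"] = summary["n_targets"] > hub_threshold
    if screen_result is not None:
        summary["direction"] = screen_result["direction"].reindex(summary.index)
    else:
        summary["direction"] = np.nan
    return summary.sort_values("n_targets", ascending=False)


def summarize_edges(edge_table: pd.DataFrame) -> dict:
    """Headline network counts, including the positive-edge percentage
    (reported to the nearest whole percent)."""
    n = len(edge_table)
    n_pos = int((edge_table["sign"] == "+").sum()) if n else 0
    return {
        "n_edges": n,
        "n_pos": n_pos,
        "n_neg": n - n_pos,
        "pct_positive": int(round(100.0 * n_pos / n)) if n else 0,
        "n_mirnas_with_edges": int(edge_table["mirna_id"].nunique()) if n else 0,
    }


def _graph(edge_table: pd.DataFrame, screen_result: pd.DataFrame | None = None):
    g = nx.Graph()
    directions = {}
    if screen_result is not None:
        directions = screen_result["direction"].to_dict()
    for _, row in edge_table.iterrows():
        m, gn = row["mirna_id"], row["gene_id"]
        g.add_node(m, type="mirna", direction=float(directions.get(m, 0.0)))
        g.add_node(gn, type="gene")
        g.add_edge(m, gn, sign=row["sign"], n_sources=int(row["n_sources"]), q=float(row["q"]))
    return g


def to_graphml(edge_table: pd.DataFrame, path, screen_result=None) -> None:
    nx.write_graphml(_graph(edge_table, screen_result), path)


def to_sif(edge_table: pd.DataFrame, path) -> None:
    """Simple interaction format: mirna <sign> gene per line."""
    with open(path, "w") as fh:
        for _, row in edge_table.iterrows():
            rel = "pos" if row["sign"] == "+" else "neg"
            fh.write(f"{row['mirna_id']}\t{rel}\t{row['gene_id']}\n")
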