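"""Two-group inhibitor (knockdown) experiment analysis.

A miRNA inhibitor derepresses its direct targets, typically by modest
amounts (1.15-1.4 fold), so per-gene evidence is weak at n = 3 vs 3
and two complementary tests are used: empirical-Bayes moderated
t-tests (gene-wise variances shrunk toward a prior estimated from all
genes, adding prior degrees of freedom) and a two-sample
Kolmogorov-Smirnov test for a distributional shift of the predicted
targets' statistics relative to all other genes. The most derepressed
predicted targets form a gene set that is carried back into the tissue
data by pre-ranked enrichment against the miRNA's correlation ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats

from .enrichment import gsea_preranked

__all__ = [
    "ModeratedTResult",
    "moderated_t",
    "ks_target_shift",
    "KSShift",
    "top_upregulated_targets",
    "cross_dataset_enrichment",
]


@dataclass
class ModeratedTResult:
    table: pd.DataFrame  # per gene: logfc, fold, s2, t_ordinary, t, df, p
    d0: float            # prior degrees of freedom
    s0_2: float          # prior variance


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log sample variances to a scaled F distribution.

    Returns (d0, s0^2): prior df (inf when the log-variances are no
    more dispersed than chi-square sampling alone) and prior variance.
    """
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    return d0, s0_2


def moderated_t(
    expr_matrix: pd.DataFrame,
    group_labels,
    group_order: tuple[str, str] = ("control", "inhibitor"),
    d0_override: float | None = None,
) -> ModeratedTResult:
    """Empirical-Bayes moderated t-tests, inhibitor minus control.

    The per-gene pooled variance s_g^2 (d_g = n1 + n2 - 2 df) is shrunk
    toward a prior s0^2 with d0 prior df estimated by matching moments
    of log s_g^2 to a scaled log-F distribution; the moderated t uses
    the posterior variance (d0 s0^2 + d_g s_g^2)/(d0 + d_g) and is
    referred to a t distribution with d0 + d_g df.

    ``d0_override`` forces the prior df (0 recovers the ordinary t;
    inf gives complete shrinkage to s0^2).
    """
    groups = pd.Series(group_labels, index=expr_matrix.columns)
    g1, g2 = group_order
    X1 = expr_matrix.loc[:, groups == g1].to_numpy(float)
    X2 = expr_matrix.loc[:, groups == g2].to_numpy(float)
    n1, n2 = X1.shape[1], X2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 arrays")
    logfc = X2.mean(axis=1) - X1.mean(axis=1)
    dg = n1 + n2 - 2
    s2 = (X1.var(axis=1, ddof=1) * (n1 - 1) + X2.var(axis=1, ddof=1) * (n2 - 1)) / dg
    if np.all(s2 == 0):
        raise ValueError("zero variance across all genes")
    d0, s0_2 = _fit_f_dist(s2, dg) if d0_override is None else (d0_override, None)
    if d0_override is not None and s0_2 is None:
        s0_2 = _fit_f_dist(s2, dg)[1]
    stderr_scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = logfc / (np.sqrt(s2) * stderr_scale)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = logfc / (np.sqrt(s2_post) * stderr_scale)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    table = pd.DataFrame(
        {
            "logfc": logfc,
            "fold": 2.0**logfc,
            "s2": s2,
            "t_ordinary": t_ord,
            "t": t_mod,
            "df": df_total,
            "p": p,
        },
        index=expr_matrix.index,
    )
    return ModeratedTResult(table=table, d0=float(d0), s0_2=float(s0_2))


@dataclass
class KSShift:
    d: float
    p: float
    direction: str  # 'right' if targets sit right of the complement
    n_targets: int
    n_others: int
    exact: bool


def _ks_d(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Signed sups of ECDF_x - ECDF_y over the pooled points."""
    pooled = np.union1d(x, y)
    fx = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    fy = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    diff = fx - fy
    return float(diff.max()), float(-diff.min())


def ks_target_shift(
    statistics: pd.Series, target_set, exact_max_n: int = 10
) -> KSShift:
    """Two-sided KS test of target statistics vs all other genes.

    Uses the asymptotic Kolmogorov distribution; when both samples
    have at most ``exact_max_n`` members the p-value is computed by
    exact enumeration over all label assignments instead.
    """
    targets = [g for g in target_set if g in statistics.index]
    if not targets:
        raise ValueError("target set does not overlap the statistic universe")
    mask = statistics.index.isin(targets)
    x = statistics.to_numpy(float)[mask]
    y = statistics.to_numpy(float)[~mask]
    if y.size == 0:
        raise ValueError("complement is empty")
    d_xy, d_yx = _ks_d(x, y)
    d = max(d_xy, d_yx)
    direction = "right" if d_yx >= d_xy else "left"
    if x.size <= exact_max_n and y.size <= exact_max_n:
        pooled = np.concatenate([x, y])
        n = x.size
        count = total = 0
        for idx in combinations(range(pooled.size), n):
            sel = np.zeros(pooled.size, dtype=bool)
            sel[list(idx)] = True
            a, b = _ks_d(pooled[sel], pooled[~sel])
            if max(a, b) >= d - 1e-12:
                count += 1
            total += 1
        return KSShift(d, count / total, direction, x.size, y.size, True)
    p = float(stats.ks_2samp(x, y, method="asymp").pvalue)
    return KSShift(d, p, direction, x.size, y.size, False)


def top_upregulated_targets(
    mod_result: pd.DataFrame | ModeratedTResult,
    prediction_table: pd.DataFrame,
    mirna: str,
    n: int = 100,
) -> list[str]:
    """The n predicted targets most upregulated on inhibition.

    Ranked by log fold change (inhibitor minus control), ties broken
    by moderated t then gene id. With fewer than n predicted targets
    on the array, all are returned with a warning.
    """
    table = mod_result.table if isinstance(mod_result, ModeratedTResult) else mod_result
    predicted = prediction_table.loc[
        prediction_table["mirna_id"] == mirna, "gene_id"
    ].unique()
    avail = table.loc[table.index.isin(predicted)].copy()
    if avail.empty:
        raise ValueError(f"no predicted targets of {mirna} on the array")
    avail["_gene"] = avail.index
    avail = avail.sort_values(
        ["logfc", "t", "_gene"], ascending=[False, False, True]
    )
    if len(avail) < n:
        warnings.warn(
            f"only {len(avail)} predicted targets of {mirna} available "
            f"(requested {n}); returning all"
        )
        return list(avail.index)
    return list(avail.index[:n])


def cross_dataset_enrichment(
    tissue_ranking: pd.Series,
    derepressed_set: list[str],
    all_predicted: list[str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict:
    """Carry the in-vitro derepressed set back into the tissue network.

    GSEA of the set against the gene ranking by correlation with the
    miRNA in tissue (negative enrichment means the derepressed targets
    concentrate at the anti-correlated end), plus a KS comparison of
    the set's tissue statistics against all predicted targets of the
    miRNA (or against all genes when predictions are not given).
    """
    res = gsea_preranked(
        tissue_ranking,
        {"derepressed_targets": list(derepressed_set)},
        n_perm=n_perm,
        seed=seed,
        min_size=1,
        max_size=len(tissue_ranking),
    )
    uni = tissue_ranking
    if all_predicted is not None:
        sub = tissue_ranking.loc[tissue_ranking.index.isin(all_predicted)]
        # the KS complement needs genes outside the set; when the set
        # covers (almost) the whole predicted universe, compare against
        # all genes instead
        if len(sub) - len(set(derepressed_set) & set(sub.index)) >= 5:
            uni = sub
    ks = ks_target_shift(uni, derepressed_set)
    row = res.iloc[0]
    return {
        "es": float(row["es"]),
        "nes": float(row["nes"]),
        "p_gsea": float(row["p"]),
        "q_gsea": float(row["q"]),
        "ks": ks,
    }
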