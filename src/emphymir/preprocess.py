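"""Probe-level microarray preprocessing: normalization, detection
calls, replicate collapsing, feature/sample filtering, and the qPCR
comparative-CT validation transform.

The processing order is: quantile-normalize probe intensities on the
linear scale across samples, log2-transform, call each probe present
when its normalized linear intensity exceeds the per-sample background
threshold (mean of background probes + 2 SD), collapse triplicate
probes to the median of the present replicates, drop features not
present in at least 80% of samples, then screen samples by PCA
outlier and present-call-fraction rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "quantile_normalize",
    "detection_call",
    "collapse_replicates",
    "filter_features",
    "qc_samples",
    "preprocess_probe_table",
    "comparative_ct",
    "correlate_with_array",
    "PreprocessResult",
]

META_COLS = ["probe_id", "feature_id", "replicate", "is_background"]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean distribution.

    Each column's values are replaced by the across-sample mean of the
    order statistics at their within-column rank; ranks are preserved
    and ties share the average of the order statistics they span.
    """
    if matrix.size == 0:
        raise ValueError("empty matrix")
    arr = matrix.to_numpy(float)
    n = arr.shape[0]
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, target)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def detection_call(probe_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Present/absent call per probe against per-sample background.

    The threshold for a sample is mean(background) + 2 * SD(background)
    (sample SD), on the same scale as the probe intensities; a probe is
    present iff its intensity strictly exceeds the threshold.

    Returns the boolean call matrix for non-background probes (indexed
    by probe_id) and the per-sample thresholds.
    """
    sample_cols = [c for c in probe_table.columns if c not in META_COLS]
    bg = probe_table.loc[probe_table["is_background"].astype(bool), sample_cols]
    if len(bg) < 2:
        raise ValueError("need at least 2 background probes per sample")
    thr = bg.mean(axis=0) + 2.0 * bg.std(axis=0, ddof=1)
    fg = probe_table.loc[~probe_table["is_background"].astype(bool)]
    present = fg[sample_cols].gt(thr, axis=1)
    present.index = fg["probe_id"].to_numpy()
    return present, thr


def collapse_replicates(
    probe_table: pd.DataFrame, calls: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse replicate probes to one log2 value per (feature, sample).

    If two or more replicates are present the value is the median of
    the present replicates' log2 intensities and the feature is called
    present in that sample; with zero or one present replicate the
    sample-level call is absent and the value is imputed as the median
    of all replicates (complete vectors are needed downstream).

    Returns (log2 value matrix, sample-level present calls), both
    feature x sample.
    """
    sample_cols = [c for c in probe_table.columns if c not in META_COLS]
    fg = probe_table.loc[~probe_table["is_background"].astype(bool)]
    log2 = np.log2(fg[sample_cols].to_numpy(float))
    pres = calls.loc[fg["probe_id"]].to_numpy()
    features = fg["feature_id"].to_numpy()
    uniq = pd.unique(features)
    values = np.empty((uniq.size, len(sample_cols)))
    present = np.empty((uniq.size, len(sample_cols)), dtype=bool)
    for i, f in enumerate(uniq):
        rows = features == f
        v = log2[rows]
        p = pres[rows]
        n_pres = p.sum(axis=0)
        present[i] = n_pres >= 2
        masked = np.where(p, v, np.nan)
        with np.errstate(invalid="ignore"):
            med_present = np.nanmedian(
                np.where(n_pres[None, :] >= 2, masked, v), axis=0
            )
        values[i] = med_present
    values_df = pd.DataFrame(values, index=uniq, columns=sample_cols)
    present_df = pd.DataFrame(present, index=uniq, columns=sample_cols)
    return values_df, present_df


def filter_features(
    values: pd.DataFrame, present: pd.DataFrame, min_present: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Retain features present in at least ``min_present`` of samples."""
    frac = present.mean(axis=1)
    keep = frac >= min_present
    dropped = list(values.index[~keep])
    return values.loc[keep], present.loc[keep], dropped


def qc_samples(
    feature_matrix: pd.DataFrame,
    present: pd.DataFrame,
    pca_sd: float = 3.0,
    min_present_frac: float = 0.5,
) -> tuple[list[str], dict]:
    """Flag outlier samples by PCA and by present-call fraction.

    A sample is excluded if its score on PC1 or PC2 of the feature
    matrix lies more than ``pca_sd`` standard deviations from zero
    (single pass), or if fewer than ``min_present_frac`` of all
    features are called present in it.
    """
    samples = list(feature_matrix.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for QC")
    X = feature_matrix.to_numpy(float).T  # samples x features
    scores = PCA(n_components=2).fit_transform(X - X.mean(axis=0))
    sds = scores.std(axis=0, ddof=1)
    pca_out = (np.abs(scores) > pca_sd * sds).any(axis=1)
    frac = present.reindex(columns=samples).mean(axis=0).to_numpy()
    pa_out = frac < min_present_frac
    excluded = pca_out | pa_out
    kept = [s for s, e in zip(samples, excluded) if not e]
    if not kept:
        raise ValueError("sample QC excluded every sample")
    report = {
        "n_samples": len(samples),
        "n_kept": len(kept),
        "excluded_pca": [s for s, e in zip(samples, pca_out) if e],
        "excluded_present_frac": [s for s, e in zip(samples, pa_out) if e],
        "pc_sd": [float(v) for v in sds],
        "present_fraction": {s: float(f) for s, f in zip(samples, frac)},
    }
    return kept, report


@dataclass
class PreprocessResult:
    matrix: pd.DataFrame          # filtered, QC'd feature x sample log2
    present: pd.DataFrame         # sample-level calls for kept features
    thresholds: pd.Series         # per-sample detection thresholds
    dropped_features: list[str]
    qc: dict

    @property
    def present_fraction(self) -> pd.Series:
        return self.present.mean(axis=1)


def preprocess_probe_table(
    probe_table: pd.DataFrame,
    min_present: float = 0.8,
    pca_sd: float = 3.0,
    min_present_frac: float = 0.5,
) -> PreprocessResult:
    """Full probe-level pipeline: normalize, call, collapse, filter, QC."""
    sample_cols = [c for c in probe_table.columns if c not in META_COLS]
    norm = probe_table.copy()
    norm[sample_cols] = quantile_normalize(probe_table[sample_cols]).to_numpy()
    calls, thr = detection_call(norm)
    values, present = collapse_replicates(norm, calls)
    n_initial = len(values)
    values_f, present_f, dropped = filter_features(values, present, min_present)
    if values_f.empty:
        return PreprocessResult(values_f, present_f, thr, dropped,
                                {"n_features_initial": n_initial, "n_features_kept": 0})
    kept, qc = qc_samples(values_f, present, pca_sd, min_present_frac)
    qc["n_features_initial"] = n_initial
    qc["n_features_kept"] = len(values_f)
    return PreprocessResult(
        matrix=values_f[kept],
        present=present_f[kept],
        thresholds=thr,
        dropped_features=dropped,
        qc=qc,
    )


def comparative_ct(
    ct_table: pd.DataFrame,
    reference_feature: str = "U6",
    calibrator_sample: str | None = None,
) -> pd.DataFrame:
    """Comparative-CT relative expression from replicate Ct values.

    ``ct_table`` is long format with columns ``feature_id``,
    ``sample_id``, ``ct`` (replicates as repeated rows). Per sample,
    dCt = mean Ct(target) - mean Ct(reference); ddCt subtracts the
    calibrator sample's dCt; relative expression is 2^(-ddCt).
    """
    mean_ct = ct_table.groupby(["feature_id", "sample_id"])["ct"].mean().unstack()
    if reference_feature not in mean_ct.index:
        raise ValueError(f"reference feature {reference_feature!r} missing")
    ref = mean_ct.loc[reference_feature]
    if ref.isna().any():
        raise ValueError("reference feature missing in some samples")
    dct = mean_ct.drop(index=reference_feature).sub(ref, axis=1)
    if calibrator_sample is None:
        calibrator_sample = dct.columns[0]
    ddct = dct.sub(dct[calibrator_sample], axis=0)
    return 2.0 ** (-ddct)


def correlate_with_array(
    rel_expr: pd.Series, array_values: pd.Series
) -> tuple[float, float]:
    """Pearson correlation between log2 relative expression (qPCR) and
    array log2 values over shared samples."""
    common = rel_expr.index.intersection(array_values.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    r, p = stats.pearsonr(np.log2(rel_expr.loc[common]), array_values.loc[common])
    return float(r), float(p)
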