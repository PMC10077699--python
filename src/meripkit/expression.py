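"""Expression filtering, normalization, differential expression, PCA screen.

Differential expression here is deliberately lightweight: size-factor
(median-of-ratios) normalization followed by a two-sample t-test on
log2(normalized + 1), applying the study thresholds raw P < 0.05 and
|log2FC| > log2(1.5). It is a documented stand-in for a full
negative-binomial GLM framework — the analysis contract is the
thresholds, not the test engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "filter_low_expression",
    "tpm_normalize",
    "size_factor_normalize",
    "size_factors",
    "differential_expression",
    "pca_outlier_screen",
    "DEOptions",
]


def filter_low_expression(
    counts: pd.DataFrame, min_count: int = 10, min_samples: int = 4
) -> pd.DataFrame:
    """Keep genes with counts >= ``min_count`` in >= ``min_samples`` samples.

    This is the conventional MeRIP-input low-expression filter
    ("counts > 9 in fewer than 4 samples are dropped"). Row order is
    preserved; idempotent.
    """
    if min_count < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    return counts.loc[keep]


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized, column sums = 1e6."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"genes missing lengths: {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths / 1e3, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Only genes with no zero count enter the reference. When no such
    gene exists, falls back to library-size factors (scaled to
    geometric mean 1) with a warning.
    """
    positive = (counts > 0).all(axis=1)
    if positive.sum() == 0:
        warnings.warn(
            "no zero-free gene for median-of-ratios; using library-size factors",
            RuntimeWarning,
            stacklevel=2,
        )
        libs = counts.sum(axis=0).astype(float)
        return libs / np.exp(np.log(libs).mean())
    sub = counts.loc[positive].to_numpy(float)
    log_ref = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


def size_factor_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts divided by their sample's median-of-ratios size factor."""
    return counts.div(size_factors(counts), axis=1)


@dataclass(frozen=True)
class DEOptions:
    p_thresh: float = 0.05
    fc_thresh: float = 1.5
    pseudocount: float = 1.0
    welch: bool = True


def differential_expression(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    options: DEOptions | None = None,
    normalized: bool = False,
) -> pd.DataFrame:
    """High-vs-Low differential expression on (size-factor) normalized counts.

    log2FC = log2(mean_high + c) - log2(mean_low + c) with pseudocount
    ``c``; the t-test runs on log2(normalized + c) per gene. Pass
    ``normalized=True`` when ``counts`` are already normalized.
    """
    opt = options or DEOptions()
    groups = pd.Series(groups)
    norm = counts if normalized else size_factor_normalize(counts)
    high = [s for s in norm.columns if groups.get(s) == "High"]
    low = [s for s in norm.columns if groups.get(s) == "Low"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs at least 2 samples")
    logm = np.log2(norm.to_numpy(float) + opt.pseudocount)
    cols = list(norm.columns)
    hi_idx = [cols.index(s) for s in high]
    lo_idx = [cols.index(s) for s in low]
    xh, xl = logm[:, hi_idx], logm[:, lo_idx]
    mean_h = norm[high].mean(axis=1).to_numpy()
    mean_l = norm[low].mean(axis=1).to_numpy()
    lfc = np.log2(mean_h + opt.pseudocount) - np.log2(mean_l + opt.pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xh, xl, axis=1, equal_var=not opt.welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = np.isnan(p)
    t[bad] = 0.0
    p[bad] = 1.0
    sig = (p < opt.p_thresh) & (np.abs(lfc) > np.log2(opt.fc_thresh))
    return pd.DataFrame(
        {
            "mean_high": mean_h,
            "mean_low": mean_l,
            "log2fc": lfc,
            "t_stat": t,
            "p_value": p,
            "significant": sig,
        },
        index=norm.index,
    )


def pca_outlier_screen(
    counts: pd.DataFrame,
    k: float = 3.0,
    normalized: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """PCA-based sample screen on log2(normalized + 1) expression.

    Genes are centered; samples are projected on PCs 1-2 and flagged as
    outliers when their Euclidean distance from the score centroid
    exceeds ``median + k * 1.4826 * MAD`` of the distances (a robust
    analogue of visual PCA screening).

    Returns a per-sample table: ``pc1, pc2, distance, outlier``.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    norm = counts if normalized else size_factor_normalize(counts)
    x = np.log2(norm.to_numpy(float).T + pseudocount)  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    n_comp = min(2, min(x.shape) - 0)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(x)
    if scores.shape[1] < 2:
        scores = np.column_stack([scores, np.zeros(len(scores))])
    centroid = scores.mean(axis=0)
    dist = np.linalg.norm(scores - centroid, axis=1)
    mad = stats.median_abs_deviation(dist)
    cutoff = np.median(dist) + k * 1.4826 * mad
    return pd.DataFrame(
        {
            "pc1": scores[:, 0],
            "pc2": scores[:, 1],
            "distance": dist,
            "outlier": dist > cutoff,
        },
        index=counts.columns,
    )
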