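"""Normalized-depth m6A quantification and High-vs-Low differential methylation.

The per-peak, per-sample statistic is the IP-over-input normalized depth

    ((SRN_IP / ITR_IP) - (SRN_input / ITR_input)) / peak length,

where SRN is the summed per-base read depth over the peak region and ITR
the library's total read count. Differential peaks are called by a
two-sample t-test on normalized depth between the High and Low groups,
with significance at raw P < 0.05 and |log2FC| > log2(1.5) (both
configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from meripkit.intervals import PeakPanel

__all__ = [
    "normalized_read_count",
    "normalized_depth",
    "depth_matrix",
    "differential_methylation",
    "aggregate_to_genes",
    "DMOptions",
]

LOG2_FC_DEFAULT = np.log2(1.5)
EPS_DEPTH = 1e-9  # pseudo-depth added to floored means before log-ratio


def normalized_read_count(srn: float, itr: float) -> float:
    """SRN/ITR: per-region read depth as a fraction of the library total."""
    if itr <= 0:
        raise ValueError("library total (ITR) must be positive")
    return srn / itr


def normalized_depth(
    ip_depth: np.ndarray | pd.Series,
    ip_total: float,
    input_depth: np.ndarray | pd.Series,
    input_total: float,
    lengths: np.ndarray | pd.Series,
) -> np.ndarray:
    """Per-peak normalized depth for one paired IP/input library.

    ``((ip/ip_total) - (input/input_total)) / length``; may be negative
    when input coverage exceeds IP coverage.
    """
    if ip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    ip = np.asarray(ip_depth, dtype=float)
    inp = np.asarray(input_depth, dtype=float)
    ln = np.asarray(lengths, dtype=float)
    if ip.shape != inp.shape or ip.shape != ln.shape:
        raise ValueError("ip, input and length vectors must align")
    return (ip / ip_total - inp / input_total) / ln


def depth_matrix(
    ip_counts: pd.DataFrame,
    input_counts: pd.DataFrame,
    panel: PeakPanel | pd.Series | None = None,
    ip_totals: pd.Series | None = None,
    input_totals: pd.Series | None = None,
    lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Build the peaks x samples normalized-depth matrix.

    ``ip_counts`` and ``input_counts`` are peak x sample depth tables
    with identical indexes and columns (samples paired by name). Peak
    lengths come from ``panel`` or an explicit ``lengths`` series;
    library totals default to column sums (flagstat-style totals may be
    passed instead).
    """
    if not ip_counts.index.equals(input_counts.index):
        raise ValueError("IP and input tables index different peak panels")
    if list(ip_counts.columns) != list(input_counts.columns):
        raise ValueError("IP and input tables cover different samples")
    if lengths is None:
        if isinstance(panel, PeakPanel):
            lengths = pd.Series(panel.lengths(), index=panel.ids)
        elif isinstance(panel, pd.Series):
            lengths = panel
        else:
            raise ValueError("peak lengths required (panel or lengths)")
    lengths = lengths.reindex(ip_counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"peaks missing from panel lengths: {missing} ...")
    ip_t = ip_totals if ip_totals is not None else ip_counts.sum(axis=0)
    in_t = input_totals if input_totals is not None else input_counts.sum(axis=0)
    if (ip_t <= 0).any() or (in_t <= 0).any():
        raise ValueError("zero-total library encountered")
    values = (
        ip_counts.to_numpy(float) / ip_t.to_numpy(float)[None, :]
        - input_counts.to_numpy(float) / in_t.to_numpy(float)[None, :]
    ) / lengths.to_numpy(float)[:, None]
    return pd.DataFrame(values, index=ip_counts.index, columns=ip_counts.columns)


@dataclass(frozen=True)
class DMOptions:
    """Thresholds and test variant for the differential-methylation call."""

    p_thresh: float = 0.05
    fc_thresh: float = 1.5
    welch: bool = True  # False = Student's pooled-variance t
    eps: float = EPS_DEPTH


def _log2_ratio(mean_high: np.ndarray, mean_low: np.ndarray, eps: float) -> np.ndarray:
    """log2(mean_high / mean_low) with means floored at 0 plus ``eps``.

    Normalized depth can be negative; both means non-positive yields 0.
    """
    h = np.maximum(mean_high, 0.0) + eps
    l = np.maximum(mean_low, 0.0) + eps
    lfc = np.log2(h / l)
    lfc[(mean_high <= 0) & (mean_low <= 0)] = 0.0
    return lfc


def differential_methylation(
    depth: pd.DataFrame,
    groups: pd.Series | dict,
    options: DMOptions | None = None,
) -> pd.DataFrame:
    """Per-peak High-vs-Low t-test on normalized depth.

    Returns a table with columns ``mean_high, mean_low, log2fc, t_stat,
    p_value, significant``. Peaks whose values are identical in both
    groups get ``p = 1`` (no evidence, by convention); peaks whose
    floored means are both zero get ``log2fc = 0``.
    """
    opt = options or DMOptions()
    groups = pd.Series(groups)
    high = [s for s in depth.columns if groups.get(s) == "High"]
    low = [s for s in depth.columns if groups.get(s) == "Low"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs at least 2 samples")
    xh = depth[high].to_numpy(float)
    xl = depth[low].to_numpy(float)
    mean_h = xh.mean(axis=1)
    mean_l = xl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xh, xl, axis=1, equal_var=not opt.welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    lfc = _log2_ratio(mean_h, mean_l, opt.eps)
    zero_both = (mean_h <= 0) & (mean_l <= 0)
    sig = (p < opt.p_thresh) & (np.abs(lfc) > np.log2(opt.fc_thresh)) & ~zero_both
    return pd.DataFrame(
        {
            "mean_high": mean_h,
            "mean_low": mean_l,
            "log2fc": lfc,
            "t_stat": t,
            "p_value": p,
            "significant": sig,
        },
        index=depth.index,
    )


def aggregate_to_genes(
    dm_peaks: pd.DataFrame, peak_to_gene: pd.Series | dict
) -> pd.DataFrame:
    """Collapse peak-level calls to genes.

    A gene is differentially methylated when any of its peaks is
    significant; the representative log2FC and P come from the
    minimum-P peak. Peaks without a gene assignment are dropped (they
    can be counted by the caller).
    """
    mapping = pd.Series(peak_to_gene)
    tab = dm_peaks.copy()
    tab["gene"] = mapping.reindex(tab.index)
    tab = tab.dropna(subset=["gene"])
    if tab.empty:
        return pd.DataFrame(
            columns=["gene", "n_peaks", "log2fc", "p_value", "significant"]
        ).set_index("gene")
    rows = []
    for gene, sub in tab.groupby("gene", sort=True):
        best = sub.loc[sub["p_value"].idxmin()]
        rows.append(
            {
                "gene": gene,
                "n_peaks": len(sub),
                "log2fc": float(best["log2fc"]),
                "p_value": float(best["p_value"]),
                "significant": bool(sub["significant"].any()),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
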