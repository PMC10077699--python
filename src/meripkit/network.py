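"""Weighted co-expression network, modules, eigengenes and hub genes.

Re-implements the standard weighted-network workflow: unsigned
adjacency ``|cor|^beta`` with the soft power chosen by scale-free fit,
topological overlap similarity, average-linkage clustering of
``1 - TOM`` with a static cut, module eigengenes (first principal
component), module-trait Pearson correlation, and per-gene module
membership (MM) / gene significance (GS) hub screening with the
conventional thresholds |MM| > 0.8 and GS > 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "SoftThresholdScan",
    "ModuleResult",
    "adjacency",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "refine_modules_by_kme",
    "module_eigengene",
    "module_trait_correlation",
    "corr_pvalue",
    "gene_module_stats",
    "screen_hub_genes",
]


def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1)
    return expr.loc[sd > 0]


def adjacency(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned adjacency ``a_ij = |pearson(x_i, x_j)|^beta`` (genes as rows)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = expr.to_numpy(float)
    if (x.std(axis=1) == 0).any():
        raise ValueError("zero-variance gene rows; filter before adjacency")
    cor = np.corrcoef(x)
    a = np.abs(np.clip(cor, -1, 1)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


@dataclass
class SoftThresholdScan:
    """Scale-free fit per candidate power and the chosen soft threshold."""

    candidates: list[int]
    fit_r2: list[float]  # signed scale-free fit (-sign(slope) * R^2)
    slopes: list[float]
    mean_connectivity: list[float]
    chosen: int
    fit_thresh: float = 0.85

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.candidates, "signed_r2": self.fit_r2,
             "slope": self.slopes, "mean_k": self.mean_connectivity}
        )


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free fit of a connectivity vector.

    Connectivities are discretized into ``n_bins`` equal-width bins;
    p(k) is the fraction of genes per occupied bin and k-bar the bin
    mean. Returns ``(signed_r2, slope)`` of the log10 p(k) ~ log10
    k-bar regression; the sign is ``-sign(slope)`` so a declining
    degree distribution (scale-free-like) scores positive.
    """
    k = k[k > 0]
    if len(k) < n_bins or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xk, pk = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            xk.append(k[mask].mean())
            pk.append(mask.sum())
    xk = np.asarray(xk)
    pk = np.asarray(pk, dtype=float) / len(k)
    if len(xk) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(np.log10(xk), np.log10(pk))
    if np.isnan(r):
        return 0.0, 0.0
    return float(-np.sign(slope) * r ** 2), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidates: list[int] | None = None,
    fit_thresh: float = 0.85,
    min_mean_connectivity: float = 5.0,
    slope_range: tuple[float, float] = (-2.0, 0.0),
) -> SoftThresholdScan:
    """Choose the soft power: smallest candidate whose signed scale-free
    fit R^2 reaches ``fit_thresh``, else the argmax-R^2 candidate.

    Two practitioner guards restrict eligibility: the power must keep
    mean connectivity at or above ``min_mean_connectivity`` (raising it
    further disconnects the network faster than it improves the fit),
    and the log-log regression slope must lie in ``slope_range`` — a
    scale-free degree distribution has slope around -1 to -2, and a
    steeper fit at low powers is an artifact of background correlation
    rather than network topology. Guards are waived when they would
    exclude every candidate.

    When no eligible candidate reaches ``fit_thresh`` the scan falls
    back to the conventional sample-size default for unsigned networks
    (9 below 20 samples, 8 below 30, 7 below 40, else 6), clipped into
    the eligible candidate range — the standard recommendation when a
    small cohort never shows a clean scale-free plateau.
    """
    candidates = list(candidates) if candidates is not None else list(range(1, 21))
    expr = _drop_constant(expr)
    x = expr.to_numpy(float)
    cor = np.abs(np.clip(np.corrcoef(x), -1, 1))
    np.fill_diagonal(cor, 0.0)
    r2s, slopes, ks = [], [], []
    for b in candidates:
        a = cor ** b
        k = a.sum(axis=1)
        r2, slope = _scale_free_fit(k)
        r2s.append(r2)
        slopes.append(slope)
        ks.append(float(k.mean()))
    eligible = [
        i for i in range(len(candidates))
        if ks[i] >= min_mean_connectivity
        and slope_range[0] <= slopes[i] < slope_range[1]
    ]
    if not eligible:
        eligible = [i for i, k in enumerate(ks) if k >= min_mean_connectivity]
    if not eligible:
        eligible = list(range(len(candidates)))
    chosen = None
    for i in eligible:
        if r2s[i] >= fit_thresh:
            chosen = candidates[i]
            break
    if chosen is None:
        n = expr.shape[1]
        default = 9 if n < 20 else 8 if n < 30 else 7 if n < 40 else 6
        pool = [candidates[i] for i in eligible]
        chosen = min(pool, key=lambda b: abs(b - default))
    return SoftThresholdScan(
        candidates=candidates, fit_r2=r2s, slopes=slopes, mean_connectivity=ks,
        chosen=chosen, fit_thresh=fit_thresh,
    )


def tom_similarity(adj: pd.DataFrame | np.ndarray, atol: float = 1e-8) -> pd.DataFrame | np.ndarray:
    """Topological overlap similarity of an adjacency matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` where
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{j != i} a_ij``;
    diagonal is 1. Values lie in [0, 1] for adjacencies in [0, 1].
    """
    a = adj.to_numpy(float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    if not np.allclose(a, a.T, atol=atol):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=0) - 1.0
    # (A @ A)_ij counts u = i and u = j; with unit diagonal both add a_ij
    l = a @ a - 2.0 * a
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom[denom <= 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height_frac: float | None = None,
) -> pd.Series:
    """Average-linkage clustering of ``1 - TOM`` with a static tree cut.

    The dendrogram is cut at ``cut_height_frac`` of its maximum merge
    height; clusters smaller than ``min_module_size`` become label 0
    ("grey" / unassigned). Remaining modules are relabelled 1..K in
    decreasing size order.

    With the default ``cut_height_frac=None`` the cut height is chosen
    adaptively: heights from 0.80 to 0.98 of the maximum are scanned
    and the lowest height yielding the largest number of minimum-size
    clusters is kept. A fixed fraction is brittle — too high and
    distinct-but-related modules merge, too low and modules shatter
    below the size threshold; maximizing resolved structure is a simple
    stand-in for dynamic tree cutting. Peripheral genes the low cut
    leaves unassigned can be recovered with
    :func:`refine_modules_by_kme`.
    """
    diss = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(diss, 0.0)
    z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    hmax = z[:, 2].max()
    fracs = (
        [cut_height_frac] if cut_height_frac is not None
        else list(np.arange(0.80, 0.985, 0.02))
    )
    best_key, best = None, None
    for frac in fracs:
        raw = hierarchy.fcluster(z, t=frac * hmax, criterion="distance")
        labels = pd.Series(raw, index=tom.index, name="module")
        sizes = labels.value_counts()
        keep = sizes[sizes >= min_module_size].index
        key = (len(keep), -frac)
        if best_key is None or key > best_key:
            best_key, best = key, (labels, sizes, keep)
    labels, sizes, keep = best
    relabel = {old: new + 1 for new, old in enumerate(
        sorted(keep, key=lambda c: (-sizes[c], c))
    )}
    return labels.map(lambda c: relabel.get(c, 0)).astype(int)


def refine_modules_by_kme(
    expr: pd.DataFrame,
    labels: pd.Series,
    kme_thresh: float = 0.6,
    n_iter: int = 2,
) -> pd.Series:
    """Reassign genes to the module whose eigengene they track best.

    A light analogue of eigengene-based module membership cleanup:
    after the static cut, each gene (including unassigned ones) moves
    to the module with the largest |kME| = |cor(gene, eigengene)|,
    provided that exceeds ``kme_thresh``; otherwise it becomes
    unassigned. Eigengenes are recomputed between iterations.
    """
    labels = labels.copy()
    for _ in range(n_iter):
        eig = module_eigengene(expr, labels)
        if eig.empty:
            return labels
        x = expr.to_numpy(float)
        sd = x.std(axis=1)
        sd[sd == 0] = 1.0
        xz = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        e = eig.to_numpy(float)
        ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, keepdims=True)
        kme = xz @ ez.T / x.shape[1]
        best = np.abs(kme).argmax(axis=1)
        best_val = np.abs(kme).max(axis=1)
        mods = np.array([int(name[2:]) for name in eig.index])
        new = np.where(best_val >= kme_thresh, mods[best], 0)
        if (new == labels.to_numpy()).all():
            break
        labels = pd.Series(new, index=labels.index, name="module")
    return labels.astype(int)


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First-PC eigengene per module (samples as columns, unit norm).

    Genes are z-scored across samples before the SVD; each eigengene's
    sign is oriented so its correlation with the module's mean
    expression profile is non-negative. Module 0 (unassigned) is
    skipped.
    """
    out = {}
    for mod in sorted(set(labels)):
        if mod == 0:
            continue
        sub = expr.loc[labels.index[labels == mod]].to_numpy(float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        # first right-singular vector = PC scores over samples
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        ref = sub.mean(axis=0)
        if np.std(ref) > 0 and np.corrcoef(eig, ref)[0, 1] < 0:
            eig = -eig
        out[f"ME{mod}"] = eig / np.linalg.norm(eig)
    return pd.DataFrame(out, index=expr.columns).T


def corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson r via the t distribution (n-2 df)."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and p between each eigengene and each trait column."""
    n = eigengenes.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if list(traits.index) != list(eigengenes.columns):
        traits = traits.loc[list(eigengenes.columns)]
    if (traits.std(axis=0) == 0).any():
        raise ValueError("zero-variance trait")
    r = np.zeros((len(eigengenes), traits.shape[1]))
    for i, (_, eig) in enumerate(eigengenes.iterrows()):
        for j, col in enumerate(traits.columns):
            r[i, j] = np.corrcoef(eig.to_numpy(float), traits[col].to_numpy(float))[0, 1]
    p = corr_pvalue(r, n)
    return (
        pd.DataFrame(r, index=eigengenes.index, columns=traits.columns),
        pd.DataFrame(p, index=eigengenes.index, columns=traits.columns),
    )


@dataclass
class ModuleResult:
    """Full network-analysis output for one expression matrix."""

    labels: pd.Series
    eigengenes: pd.DataFrame
    trait_r: pd.DataFrame
    trait_p: pd.DataFrame
    gene_stats: pd.DataFrame  # gene, module, MM, GS
    hubs: dict[int, list[str]] = field(default_factory=dict)


def gene_module_stats(
    expr: pd.DataFrame,
    eigengenes: pd.DataFrame,
    labels: pd.Series,
    trait: pd.Series,
) -> pd.DataFrame:
    """Per-gene module membership and gene significance.

    MM is the (signed) Pearson correlation of the gene with its own
    module's eigengene; GS is the absolute correlation with the trait.
    Unassigned genes get MM = NaN.
    """
    trait_v = trait.loc[expr.columns].to_numpy(float)
    mm = np.full(len(expr), np.nan)
    gs = np.full(len(expr), np.nan)
    x = expr.to_numpy(float)
    for i, g in enumerate(expr.index):
        xi = x[i]
        if np.std(xi) == 0:
            continue
        gs[i] = abs(np.corrcoef(xi, trait_v)[0, 1])
        mod = int(labels.get(g, 0))
        me = f"ME{mod}"
        if mod != 0 and me in eigengenes.index:
            mm[i] = np.corrcoef(xi, eigengenes.loc[me].to_numpy(float))[0, 1]
    return pd.DataFrame(
        {"module": labels.reindex(expr.index).fillna(0).astype(int), "MM": mm, "GS": gs},
        index=expr.index,
    )


def screen_hub_genes(
    stats_table: pd.DataFrame,
    module: int | None = None,
    mm_thresh: float = 0.8,
    gs_thresh: float = 0.2,
) -> pd.DataFrame:
    """Hub genes: |MM| > ``mm_thresh`` and GS > ``gs_thresh``.

    Restricted to one module when given; sorted by GS descending.
    """
    tab = stats_table
    if module is not None:
        tab = tab[tab["module"] == module]
    hubs = tab[(tab["MM"].abs() > mm_thresh) & (tab["GS"] > gs_thresh)]
    return hubs.sort_values("GS", ascending=False)
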