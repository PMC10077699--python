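"""Co-differential gene integration and gene-set over-representation.

Genes significant in both the differential-methylation and the
differential-expression analyses are classified into four quadrants by
the signs of their fold changes (hyper/hypo-methylated x up/down
regulated). Over-representation uses the upper-tail hypergeometric test
with Holm ("Bonferroni step-down") correction across terms.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "co_differential",
    "read_gmt",
    "ora_enrichment",
    "build_report",
]

QUADRANTS = {
    (1, 1): "hyper-up",
    (1, -1): "hyper-down",
    (-1, 1): "hypo-up",
    (-1, -1): "hypo-down",
}


def co_differential(dm_genes: pd.DataFrame, de_genes: pd.DataFrame) -> pd.DataFrame:
    """Intersect significant DM and DE gene sets and assign quadrants.

    Both inputs are gene-indexed with ``log2fc``, ``p_value`` and
    ``significant`` columns. Genes with a zero fold change in either
    table stay in the output but get quadrant ``"unclassified"``.
    """
    dm_sig = dm_genes[dm_genes["significant"].astype(bool)]
    de_sig = de_genes[de_genes["significant"].astype(bool)]
    shared = dm_sig.index.intersection(de_sig.index)
    rows = []
    for g in shared:
        dm_fc = float(dm_sig.loc[g, "log2fc"])
        de_fc = float(de_sig.loc[g, "log2fc"])
        key = (int(np.sign(dm_fc)), int(np.sign(de_fc)))
        rows.append(
            {
                "gene": g,
                "dm_log2fc": dm_fc,
                "dm_p": float(dm_sig.loc[g, "p_value"]),
                "de_log2fc": de_fc,
                "de_p": float(de_sig.loc[g, "p_value"]),
                "quadrant": QUADRANTS.get(key, "unclassified"),
            }
        )
    cols = ["gene", "dm_log2fc", "dm_p", "de_log2fc", "de_p", "quadrant"]
    return pd.DataFrame(rows, columns=cols).set_index("gene")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: term -> gene set (description column ignored)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def ora_enrichment(
    query: set[str] | list[str],
    universe: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    alpha: float = 0.05,
    method: str = "holm",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Gene sets are intersected with the universe first. Raw
    ``p = P(X >= overlap)`` under sampling ``|query|`` genes from the
    universe; adjustment is Holm by default (``method="bonferroni"``
    for the single-step variant). Terms with adjusted p <= ``alpha``
    are flagged.
    """
    universe = set(universe)
    query = set(query)
    if not universe or not query:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    m = len(universe)
    n_q = len(query)
    rows = []
    for term, genes in gene_sets.items():
        term_genes = genes & universe
        k_t = len(term_genes)
        if k_t == 0:
            continue
        ov = len(term_genes & query)
        p = float(stats.hypergeom.sf(ov - 1, m, k_t, n_q))
        rows.append(
            {"term": term, "overlap": ov, "term_size": k_t,
             "query_size": n_q, "universe_size": m, "p_raw": min(p, 1.0)}
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "overlap", "term_size", "query_size",
                     "universe_size", "p_raw", "p_adj", "significant"]
        ).set_index("term")
    tab = pd.DataFrame(rows).set_index("term")
    _, p_adj, _, _ = multipletests(tab["p_raw"].to_numpy(), method=method)
    tab["p_adj"] = p_adj
    tab["significant"] = tab["p_adj"] <= alpha
    return tab.sort_values("p_raw")


def build_report(
    outdir: str | Path,
    *,
    parameters: dict | None = None,
    seed: int | None = None,
    panel=None,
    dm_peaks: pd.DataFrame | None = None,
    dm_genes: pd.DataFrame | None = None,
    de_genes: pd.DataFrame | None = None,
    codiff: pd.DataFrame | None = None,
    module_labels: pd.Series | None = None,
    hubs: pd.DataFrame | None = None,
) -> dict:
    """Summarize a run into ``report.json`` (missing stages become gaps)."""
    from meripkit import __version__

    report: dict = {"version": __version__, "seed": seed,
                    "parameters": parameters or {}, "missing_stages": []}

    def _put(name: str, value) -> None:
        if value is None:
            report["missing_stages"].append(name)
        else:
            report[name] = value

    _put("n_panel_peaks", len(panel) if panel is not None else None)
    _put("n_dm_peaks", int(dm_peaks["significant"].sum()) if dm_peaks is not None else None)
    _put("n_dm_genes", int(dm_genes["significant"].sum()) if dm_genes is not None else None)
    _put("n_de_genes", int(de_genes["significant"].sum()) if de_genes is not None else None)
    if codiff is not None:
        report["n_codifferential"] = int(len(codiff))
        report["quadrants"] = codiff["quadrant"].value_counts().to_dict()
    else:
        report["missing_stages"].append("codifferential")
    if module_labels is not None:
        report["n_modules"] = int((pd.Series(module_labels).value_counts().index != 0).sum())
        report["n_grey_genes"] = int((pd.Series(module_labels) == 0).sum())
    else:
        report["missing_stages"].append("modules")
    _put("n_hub_genes", len(hubs) if hubs is not None else None)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
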