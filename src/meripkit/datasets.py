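"""Small bundled reference tables.

``load_ldm_hub_candidates`` returns published module-membership (MM)
and gene-significance (GS) values for the IMF-associated dark-turquoise
co-expression module of porcine *longissimus dorsi* muscle — the worked
example for the hub-gene screening rule (|MM| > 0.8, GS > 0.2).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_ldm_hub_candidates"]


def load_ldm_hub_candidates() -> pd.DataFrame:
    """MM/GS table for the porcine LDM adipogenic module, gene-indexed."""
    ref = resources.files("meripkit.data") / "ldm_hub_candidates.tsv"
    with resources.as_file(ref) as path:
        tab = pd.read_csv(path, sep="\t")
    return tab.set_index("gene")
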