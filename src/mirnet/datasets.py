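"""Bundled reference data.

``load_opll_de_table`` returns the published list of the 50 most
up- and 50 most down-regulated miRNAs in ossified vs normal posterior
longitudinal ligament (OPLL vs PLL) primary cells, with the reported
fold change, raw p-value, FDR and regulation calls in two contrasts
(OPLL vs PLL, and osteo-differentiated vs undifferentiated mesenchymal
stem cells). Fold changes are printed to two decimals, as published.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_opll_de_table", "opll_status_maps"]


def load_opll_de_table() -> pd.DataFrame:
    """The published OPLL/PLL differentially expressed miRNA table."""
    ref = resources.files("mirnet.data").joinpath("opll_de_mirnas.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def opll_status_maps() -> tuple[dict[str, str], dict[str, str]]:
    """Feature -> printed status label for the two published contrasts
    (primary OPLL vs PLL, comparison MSC-osteo vs MSC)."""
    df = load_opll_de_table()
    primary = dict(zip(df["mirna"], df["status_opll_vs_pll"]))
    comparison = dict(zip(df["mirna"], df["status_msc_osteo_vs_msc"]))
    return primary, comparison
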