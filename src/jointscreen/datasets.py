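"""Bundled reference datasets.

Published joint-read percentages and plating fractions from the pooled
screens of known toxic/non-toxic control genes and of the 32 hypothetical-
protein (HPUF) genes of coliphage fHy-Eco03.  The percentage columns are
measured inputs; the ``published_*`` columns are the ratios as printed in
the original reports, kept for cross-checking the ratio statistic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files(__package__).joinpath("data", name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_control_screen() -> pd.DataFrame:
    """Control-gene screen: 9 known toxic/non-toxic phage genes.

    Columns: gene_id, ligation_pct, plasmid_pct, published_ratio.  A tenth
    control (regB) yielded no joint-reads in any sample — a pool dropout —
    and therefore has no row.
    """
    return _load("control_screen.tsv")


def load_hpuf_screen() -> pd.DataFrame:
    """fHy-Eco03 HPUF screen: 32 genes, replicate-averaged NGS columns.

    Columns: gene_id, ligation_pct, plasmid_pct, published_ratio,
    published_sd (SD over replicate transformations).
    """
    return _load("hpuf_screen.tsv")


def load_hpuf_plating() -> pd.DataFrame:
    """Plating-efficiency fractions (vs the non-toxic control g178) for the
    23 HPUF genes also tested by plating.  Columns: gene_id, fraction,
    fraction_sd."""
    return _load("hpuf_plating.tsv")
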