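"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_caco2_tf_table() -> pd.DataFrame:
    """Transcription factors enriched in Caco-2 cells whose promoters change
    methylation under indicaxanthin treatment.

    Columns: gene symbol, Entrez id, affected promoters, direction
    (hyper/hypo) and the promoter methylation difference at the 50 uM dose,
    in percent points.
    """
    ref = resources.files("dmrkit").joinpath("data/caco2_tf_promoters.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def count_tf_directions(table: pd.DataFrame | None = None) -> tuple[int, int]:
    """Distinct TFs with increased vs decreased promoter methylation."""
    if table is None:
        table = load_caco2_tf_table()
    hyper = table.loc[table["direction"] == "hyper", "gene"].nunique()
    hypo = table.loc[table["direction"] == "hypo", "gene"].nunique()
    return int(hyper), int(hypo)
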