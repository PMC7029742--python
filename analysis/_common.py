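"""Shared loading/preprocessing for the numbered analysis scripts.

Reads the landscape written by ``01_simulate.py`` and applies the study
preprocessing: drop OTUs with fewer than 5 reads overall, rarefy every
lake to 25,000 reads (fixed seed, so all scripts see the same table),
and drop OTUs left without reads.
"""

from pathlib import Path

import pandas as pd

from lakescape.io_prep import (filter_low_abundance, metadata_to_frame,
                               rarefy, read_metadata, read_otu_table)

SEED = 2020
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"


def load_prepared():
    """Return (rarefied OtuTable, metadata frame, metadata list)."""
    table = read_otu_table(DATA / "otu_table.tsv")
    metadata = read_metadata(DATA / "metadata.tsv")
    table = filter_low_abundance(table, 5)
    table = rarefy(table, 25000, seed=SEED)
    table = table.select_otus(table.otu_totals() > 0)
    meta_df = metadata_to_frame(metadata).loc[list(table.sample_ids)]
    return table, meta_df, metadata


def write_tsv(df: pd.DataFrame, name: str, index: bool = True) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    df.to_csv(RESULTS / name, sep="\t", index=index)
    print(f"wrote results/{name}")
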