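import numpy as np
import pandas as pd
import pytest

from lakescape.io_prep import OtuTable


@pytest.fixture
def tiny_table() -> OtuTable:
    """4 OTUs x 3 samples with mixed lineages; totals 9/12/4/5 per OTU."""
    counts = np.array([
        [3, 4, 1, 0],
        [3, 4, 0, 5],
        [3, 4, 3, 0],
    ])
    lineages = (
        ("Bacteria", "Cyanobacteria", "", "", "", "", ""),
        ("Bacteria", "Actinobacteria", "Actinomycetia", "", "", "", ""),
        ("Bacteria", "Cyanobacteria", "", "", "", "", ""),
        ("", "", "", "", "", "", ""),
    )
    return OtuTable(
        sample_ids=("s1", "s2", "s3"),
        otu_ids=("otu1", "otu2", "otu3", "otu4"),
        counts=counts,
        lineages=lineages,
    )


@pytest.fixture
def qiime_tsv(tmp_path):
    """QIIME-classic on-disk fixture (OTUs x samples + taxonomy column)."""
    text = (
        "# Constructed from a community survey\n"
        "#OTU ID\ts1\ts2\ts3\ttaxonomy\n"
        "otu1\t3\t3\t3\tk__Bacteria; p__Cyanobacteria; c__; o__; f__; g__; s__\n"
        "otu2\t4\t4\t4\tk__Bacteria; p__Actinobacteria; c__Actinomycetia\n"
        "otu3\t1\t0\t3\tk__Bacteria; p__Cyanobacteria\n"
        "otu4\t0\t5\t0\t\n"
    )
    p = tmp_path / "otus.tsv"
    p.write_text(text)
    return p


@pytest.fixture
def coords_cloud():
    """A 60-point standard-normal cloud in the ordination plane."""
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(60, 2))
    return pd.DataFrame(pts, index=[f"o{i}" for i in range(60)],
                        columns=["CCA1", "CCA2"])
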