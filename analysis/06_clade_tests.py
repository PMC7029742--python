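#!/usr/bin/env python
"""Step 6 — clade clustering and chemistry association on the CCA plane.

For each clade (phylum down to family, at least 5 OTUs) on the first
two CCA axes: (i) a permutation test of whether the clade's OTU scores
are more tightly clustered than random OTU sets of the same size, and
(ii) a projection test of whether the clade sits unusually far along
each chemistry biplot vector, with BH correction and a signed verdict.
"""

from lakescape.clade_test import run_clade_tests
from lakescape.io_prep import ENV_COLUMNS
from lakescape.ordination import cca

from _common import SEED, load_prepared, write_tsv


def main() -> None:
    table, meta_df, _ = load_prepared()
    ordn = cca(table.to_frame(), meta_df[list(ENV_COLUMNS)].astype(float))
    res = run_clade_tests(ordn, table,
                          ranks=("phylum", "class", "order", "family"),
                          n_clustering=1000, n_association=1000, seed=SEED)
    write_tsv(res, "06_clade_tests.tsv", index=False)

    clustered = res.loc[res["q_clust"] <= 0.05, ["rank", "clade"]]
    clustered = clustered.drop_duplicates()
    print(f"clustered clades (BH q <= 0.05): {len(clustered)}")
    for _, row in clustered.iterrows():
        print(f"  {row['rank']:7s} {row['clade']}")
    assoc = res[res["direction"] != "none"]
    print(f"signed chemistry associations: {len(assoc)}")
    for _, row in assoc.iterrows():
        print(f"  {row['rank']:7s} {row['clade']:24s} {row['vector']:12s} "
              f"{row['direction']}")


if __name__ == "__main__":
    main()
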