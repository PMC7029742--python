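#!/usr/bin/env python
"""Step 2 — alpha diversity and occupancy structure.

Shannon diversity per lake and the occupancy-based classification of
OTUs (core / cosmopolitan / common / intermediate / rare / unique),
with each category's share of OTUs and of reads.
"""

import pandas as pd

from lakescape.community import alpha_diversity, prevalence_categories

from _common import load_prepared, write_tsv


def main() -> None:
    table, meta_df, _ = load_prepared()
    print(f"prepared table: {table.n_samples} lakes x {table.n_otus} OTUs")

    alpha = alpha_diversity(table)
    write_tsv(alpha.to_frame(), "02_alpha_diversity.tsv")
    print(f"Shannon range: {alpha.min():.2f} - {alpha.max():.2f} "
          f"(median {alpha.median():.2f})")

    prev = prevalence_categories(table)
    summary = pd.DataFrame({"otu_fraction": prev.otu_fraction,
                            "read_fraction": prev.read_fraction})
    write_tsv(summary, "02_prevalence_summary.tsv")
    print(f"rare+unique OTUs: {100 * prev.rare_unique_otu_fraction:.1f}% of "
          f"OTUs, {100 * prev.rare_unique_read_fraction:.1f}% of reads")


if __name__ == "__main__":
    main()
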