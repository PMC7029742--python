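#!/usr/bin/env python
"""Step 3 — distance decay of community similarity.

Spearman correlation of Bray-Curtis dissimilarity against great-circle
distance, overall and split into within- and between-basin lake pairs,
with Mantel-style permutation p-values.
"""

import pandas as pd

from lakescape.community import (dissimilarity, distance_decay,
                                 geographic_distances)

from _common import SEED, load_prepared, write_tsv


def main() -> None:
    table, meta_df, metadata = load_prepared()
    bc = dissimilarity(table, "bray_curtis")
    kept = set(table.sample_ids)
    geo = geographic_distances([m for m in metadata if m.sample_id in kept])
    basins = meta_df["basin"].astype(str).to_dict()

    rows = []
    for scope in ("all", "within_basin", "between_basin"):
        d = distance_decay(geo, bc, scope=scope, basins=basins,
                           n_perm=999, seed=SEED)
        rows.append({"scope": scope, "n_pairs": len(d.pairs), "rho": d.rho,
                     "p_spearman": d.p_spearman, "p_mantel": d.p_mantel})
        print(f"{scope:14s} rho={d.rho:+.3f}  p_mantel={d.p_mantel:.3f} "
              f"({len(d.pairs)} pairs)")
    write_tsv(pd.DataFrame(rows), "03_distance_decay.tsv", index=False)


if __name__ == "__main__":
    main()
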