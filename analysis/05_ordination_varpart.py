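#!/usr/bin/env python
"""Step 5 — constrained ordination and variation partitioning.

CCA of the rarefied community on the seven chemistry variables, with a
whole-model permutation test and marginal tests per constraint, then a
three-way partition of log-abundance variance between basin land use,
local land use and chemistry.
"""

import json

import pandas as pd

from lakescape.io_prep import ENV_COLUMNS, LANDUSE_CATEGORIES, log_transform
from lakescape.ordination import cca, permutation_anova, varpart3

from _common import RESULTS, SEED, load_prepared, write_tsv


def main() -> None:
    table, meta_df, _ = load_prepared()
    Y = table.to_frame()
    Xc = meta_df[list(ENV_COLUMNS)].astype(float)

    ordn = cca(Y, Xc)
    print(f"CCA: constraints explain "
          f"{100 * ordn.proportion_explained:.1f}% of total inertia "
          f"({ordn.constrained_inertia:.3f} / {ordn.total_inertia:.3f})")
    whole = permutation_anova(Y, Xc, term="model", n_perm=999, seed=SEED)
    print(f"whole model: pseudo-F={whole.pseudo_f:.2f}  p={whole.p_value:.3f}")
    margins = {}
    for name in ENV_COLUMNS:
        r = permutation_anova(Y, Xc, term=f"margin:{name}", n_perm=199,
                              seed=SEED)
        margins[name] = {"pseudo_f": r.pseudo_f, "p": r.p_value}
    write_tsv(ordn.biplot_scores, "05_cca_biplot_scores.tsv")
    write_tsv(ordn.site_scores, "05_cca_site_scores.tsv")

    basin = meta_df[[f"basin_{c}" for c in LANDUSE_CATEGORIES]].astype(float)
    local = meta_df[[f"local_{c}" for c in LANDUSE_CATEGORIES]].astype(float)
    vp = varpart3(log_transform(table), basin, local, Xc,
                  names=("landuse_basin", "landuse_local", "chemistry"))
    total = vp.subset_r2[("landuse_basin", "landuse_local", "chemistry")]
    print(f"varpart: total explained {100 * total:.1f}%, chemistry unique "
          f"{100 * vp.unique['chemistry']:.1f}%")

    summary = {
        "eigenvalues": [float(e) for e in ordn.eigenvalues],
        "explained_inertia_pct": 100 * ordn.proportion_explained,
        "model_pseudo_f": whole.pseudo_f,
        "model_p": whole.p_value,
        "margins": margins,
        "varpart_unique": vp.unique,
        "varpart_shared_all": vp.shared_all,
        "varpart_residual": vp.residual,
        "varpart_total_explained": total,
    }
    with open(RESULTS / "05_ordination_varpart.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print("wrote results/05_ordination_varpart.json")


if __name__ == "__main__":
    main()
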