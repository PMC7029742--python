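#!/usr/bin/env python
"""Step 4 — land use as a predictor of lake chemistry.

For every chemistry variable, fits all subsets of the six basin-scale
land-use fractions, weights them by AIC, and reports per-predictor
importance (summed Akaike weights), shrinkage model-averaged
coefficients and hierarchical-partitioning independent R^2.
"""

import pandas as pd

from lakescape import model_ensemble
from lakescape.io_prep import ENV_COLUMNS, LANDUSE_CATEGORIES

from _common import load_prepared, write_tsv


def main() -> None:
    _, meta_df, _ = load_prepared()
    X = meta_df[[f"basin_{c}" for c in LANDUSE_CATEGORIES]].astype(float)

    rows = []
    for resp in ENV_COLUMNS:
        ens = model_ensemble(meta_df[resp].astype(float), X, response=resp)
        top = ens.importance.idxmax()
        print(f"{resp:12s} full-model R2={ens.full_model_r2:.2f}  "
              f"top predictor: {top} (importance "
              f"{ens.importance[top]:.2f})")
        for pred in ens.importance.index:
            rows.append({"response": resp, "predictor": pred,
                         "importance": ens.importance[pred],
                         "avg_coef": ens.averaged_coef[pred],
                         "independent_r2": ens.independent[pred],
                         "full_model_r2": ens.full_model_r2})
    write_tsv(pd.DataFrame(rows), "04_landuse_glm.tsv", index=False)


if __name__ == "__main__":
    main()
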