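"""Validation experiments: oracles, null calibrations and recovery rates.

These routines quantify whether the pipeline behaves as advertised:
the CCA decomposition agrees with an independent generalized-eigenproblem
oracle, all four permutation tests produce uniform p-values under their
nulls, and the planted structure of the synthetic landscape (land-use
driver, clustered/associated clades, chemistry as the community driver)
is recovered. They back both the test suite and the results scripts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from . import landuse_models
from .clade_test import CladeMap, association_test, clustering_test, run_clade_tests
from .community import DistanceMatrix, dissimilarity, distance_decay
from .io_prep import ENV_COLUMNS, LANDUSE_CATEGORIES, filter_low_abundance, \
    log_transform, metadata_to_frame
from .ordination import cca, permutation_anova, varpart3
from .synthetic import SimulationConfig, simulate


def cca_eigen_oracle(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Canonical eigenvalues via the weighted cross-product matrices.

    Builds S_qx' S_xx^-1 S_xq explicitly (normal equations + symmetric
    eigensolver), independent of the SVD-projection route used by
    :func:`lakescape.ordination.cca`.
    """
    Y = np.asarray(Y, dtype=float)
    P = Y / Y.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X - r @ X
    Xc = Xc / np.sqrt(r @ (Xc ** 2))
    Xw = Xc * np.sqrt(r)[:, None]
    M = Q.T @ Xw @ np.linalg.inv(Xw.T @ Xw) @ Xw.T @ Q
    ev = np.linalg.eigvalsh(M)[::-1]
    return ev[ev > 1e-12]


def cca_oracle_error(n_tables: int = 10, seed: int = 0) -> dict:
    """Worst-case disagreement between cca() and its independent oracles.

    Returns the maximum |eigenvalue difference| against the generalized-
    eigenproblem oracle over random 8x12 tables, and the maximum relative
    error of CA total inertia against the Pearson chi-square / N identity.
    """
    rng = np.random.default_rng(seed)
    eig_err, inertia_err = 0.0, 0.0
    for _ in range(n_tables):
        Y = rng.integers(1, 50, size=(8, 12)).astype(float)
        X = rng.normal(size=(8, 2))
        res = cca(Y, X)
        oracle = cca_eigen_oracle(Y, X)
        k = len(res.eigenvalues)
        eig_err = max(eig_err, float(np.abs(res.eigenvalues - oracle[:k]).max()))
        chi2 = stats.chi2_contingency(Y, correction=False)[0]
        ca = cca(Y)
        inertia_err = max(inertia_err,
                          abs(ca.total_inertia - chi2 / Y.sum()) / (chi2 / Y.sum()))
    return {"max_eigenvalue_abs_err": eig_err,
            "max_ca_inertia_rel_err": inertia_err,
            "n_tables": n_tables}


def null_pvalues(kind: str, n_rep: int = 300, seed: int = 0,
                 n_perm: int = 199) -> np.ndarray:
    """P-values of one permutation test under its independence null.

    kind in {'clustering', 'association', 'cca_anova', 'mantel'}. Each
    replicate simulates data with no signal and runs the test once.
    """
    rng = np.random.default_rng(seed)
    ps = np.empty(n_rep)
    if kind == "clustering":
        for t in range(n_rep):
            pts = rng.normal(size=(120, 2))
            coords = pd.DataFrame(pts, index=[f"o{i}" for i in range(120)],
                                  columns=["CCA1", "CCA2"])
            members = tuple(rng.choice(coords.index, 8, replace=False))
            cm = CladeMap(rank="phylum", clades={"A": members})
            df = clustering_test(coords, cm, n=n_perm, seed=rng,
                                 pool=tuple(coords.index))
            ps[t] = df["p_clust"].iloc[0]
    elif kind == "association":
        eig = pd.DataFrame([[1.0, 0.0]], index=["TP"], columns=["CCA1", "CCA2"])
        for t in range(n_rep):
            pts = rng.normal(size=(15, 2))
            coords = pd.DataFrame(pts, index=[f"o{i}" for i in range(15)],
                                  columns=["CCA1", "CCA2"])
            cm = CladeMap(rank="phylum", clades={"A": tuple(coords.index)})
            df = association_test(coords, cm, eig, n=n_perm, seed=rng)
            ps[t] = df["p_assoc"].iloc[0]
    elif kind == "cca_anova":
        for t in range(n_rep):
            Y = rng.integers(1, 30, size=(20, 30))
            X = rng.normal(size=(20, 3))
            r = permutation_anova(Y, X, n_perm=99,
                                  seed=int(rng.integers(2 ** 31)))
            ps[t] = r.p_value
    elif kind == "mantel":
        n = 15
        ids = tuple(f"s{i}" for i in range(n))
        for t in range(n_rep):
            geo = DistanceMatrix(
                ids=ids, values=squareform(pdist(rng.normal(size=(n, 2)))),
                metric="geographic_km")
            com = dissimilarity(rng.uniform(0.1, 1, size=(n, 40)),
                                "bray_curtis", ids=ids)
            d = distance_decay(geo, com, n_perm=99,
                               seed=int(rng.integers(2 ** 31)))
            ps[t] = d.p_mantel
    else:
        raise ValueError(f"unknown calibration kind {kind!r}")
    return ps


def calibration_ks(kind: str, n_rep: int = 300, seed: int = 0) -> dict:
    """KS test of the null p-value distribution against uniform."""
    ps = null_pvalues(kind, n_rep=n_rep, seed=seed)
    ks = stats.kstest(ps, "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue),
            "n_rep": n_rep}


def recovery_experiment(n_rep: int = 50, seed: int = 0,
                        config: SimulationConfig | None = None,
                        n_clade_perm: int = 1000) -> dict:
    """Ground-truth recovery rates over repeated synthetic landscapes.

    Per replicate: (i) is the urban fraction the top-importance land-use
    predictor of NO2+NO3; (ii) is the planted clustered phylum flagged
    (BH-adjusted clustering p <= 0.05) and the planted associated phylum
    flagged with positive TP direction; (iii) does variation partitioning
    award chemistry the largest unique fraction.
    """
    ss = np.random.SeedSequence(seed)
    hits = {"urban_top": 0, "clustered": 0, "associated_sign": 0,
            "varpart_chem": 0}
    basin_cols = [f"basin_{c}" for c in LANDUSE_CATEGORIES]
    local_cols = [f"local_{c}" for c in LANDUSE_CATEGORIES]
    for child in ss.spawn(n_rep):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        ds = simulate(config, seed=rep_seed)
        md = metadata_to_frame(ds.metadata)
        # (i) land-use -> chemistry importance
        fits, subs = [], []
        X = md[basin_cols].astype(float)
        for sub in landuse_models.enumerate_models(basin_cols):
            try:
                fits.append(landuse_models.fit_gaussian_glm(md["NO23"], X, sub))
            except landuse_models.ModelSetError:
                continue
        w = landuse_models.akaike_weights([f.aic for f in fits])
        ens = landuse_models.importance_and_average(fits, w, response="NO23")
        hits["urban_top"] += ens.importance.idxmax() == "basin_urban"
        # (ii) clade tests on the CCA plane
        table = filter_low_abundance(ds.table, 5)
        ordn = cca(table.to_frame(), md[list(ENV_COLUMNS)])
        clades = run_clade_tests(ordn, table, ranks=("phylum",),
                                 n_clustering=n_clade_perm,
                                 n_association=n_clade_perm,
                                 seed=rep_seed)
        planted_c = ds.truth["planted_clustered"]
        planted_a = ds.truth["planted_associated"]
        qc = clades.loc[clades["clade"] == planted_c, "q_clust"]
        hits["clustered"] += bool(len(qc)) and float(qc.iloc[0]) <= 0.05
        row = clades[(clades["clade"] == planted_a) & (clades["vector"] == "TP")]
        hits["associated_sign"] += bool(len(row)) and \
            row["direction"].iloc[0] == "positive"
        # (iii) chemistry as the sole community driver
        vp = varpart3(log_transform(table), md[basin_cols].astype(float),
                      md[local_cols].astype(float),
                      md[list(ENV_COLUMNS)].astype(float),
                      names=("basin", "local", "chem"))
        hits["varpart_chem"] += max(vp.unique, key=vp.unique.get) == "chem"
    return {k: v / n_rep for k, v in hits.items()} | {"n_rep": n_rep}


def closed_form_checks() -> dict:
    """Instant identities: Shannon, Bray–Curtis, Akaike ratio, model count,
    and agreement of hierarchical partitioning with the all-orderings
    oracle at k=3."""
    from .community import shannon
    out = {}
    out["shannon_uniform4"] = shannon([10, 10, 10, 10])
    out["bray_curtis_22_20"] = float(
        dissimilarity(np.array([[2.0, 2.0], [2.0, 0.0]])).values[0, 1])
    w = landuse_models.akaike_weights([0.0, 2.0])
    out["akaike_ratio_delta2"] = float(w[0] / w[1])
    out["n_models_6_predictors"] = len(landuse_models.enumerate_models(
        list("abcdef")))
    # hierarchical partitioning vs exhaustive orderings
    import itertools
    rng = np.random.default_rng(12)
    X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
    y = X @ [1.0, 0.5, 0.0] + rng.normal(size=25)
    indep, _ = landuse_models.independent_contribution(y, X)
    contrib = {p: 0.0 for p in "abc"}
    orders = list(itertools.permutations("abc"))
    for order in orders:
        seen = []
        for p in order:
            before = landuse_models.projection_r2(y, X, tuple(sorted(seen)))
            seen.append(p)
            after = landuse_models.projection_r2(y, X, tuple(sorted(seen)))
            contrib[p] += (after - before) / len(orders)
    out["hierpart_oracle_max_abs_err"] = float(
        max(abs(indep[p] - contrib[p]) for p in "abc"))
    return out
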