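"""Clade coherence tests in the ordination plane.

Beyond asking how single OTUs relate to the canonical axes, these tests
ask whether a whole lineage (phylum, class, order or family) behaves
coherently. Two permutation scores are computed for a clade *p* from the
first two canonical axes:

* clustering score ``d_p`` — the sum of Euclidean distances between all
  pairs of member OTUs; the null redraws ``s_p`` OTUs from the pool of
  all tested clades, and a small upper-tail count (observed rarely
  exceeds random) means the clade is tighter than chance;
* association score ``d_p,v`` — the sum of scalar projections of member
  OTUs onto a unit environmental eigenvector ``v``; the null redraws
  ``s_p`` points from an axis-aligned bivariate normal centred at the
  ordination origin with the clade's own per-axis variances. The
  upper-tail proportion u yields a two-sided p = 2*min(u, 1-u) and a
  sign: u in the high tail marks positive association with ``v``, the
  low tail negative.

P-values are Benjamini–Hochberg adjusted within each taxonomy rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io_prep import OtuTable
from .ordination import OrdinationResult

logger = logging.getLogger(__name__)


class CladeTestError(ValueError):
    pass


@dataclass(frozen=True)
class CladeMap:
    """Clade label -> member OTU ids, at one taxonomy rank."""

    rank: str
    clades: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for label, members in self.clades.items():
            if not members:
                raise CladeTestError(f"clade {label!r} is empty")
            for otu in members:
                if otu in seen:
                    raise CladeTestError(
                        f"OTU {otu!r} assigned to both {seen[otu]!r} and {label!r} "
                        f"at rank {self.rank!r}"
                    )
                seen[otu] = label

    @property
    def pool(self) -> tuple[str, ...]:
        out: list[str] = []
        for members in self.clades.values():
            out.extend(members)
        return tuple(out)


def clade_map_from_lineages(table: OtuTable, rank: str,
                            min_size: int = 1) -> CladeMap:
    """Group OTUs by their taxon at ``rank``; unassigned OTUs are skipped."""
    names = table.lineage_at_rank(rank)
    clades: dict[str, list[str]] = {}
    for otu, name in zip(table.otu_ids, names):
        if name:
            clades.setdefault(name, []).append(otu)
    kept = {k: tuple(v) for k, v in clades.items() if len(v) >= min_size}
    return CladeMap(rank=rank, clades=kept)


def _coords_array(coords, members) -> np.ndarray:
    if isinstance(coords, pd.DataFrame):
        missing = [m for m in members if m not in coords.index]
        if missing:
            raise CladeTestError(f"member OTU(s) missing from ordination: {missing}")
        pts = coords.loc[list(members)].to_numpy(dtype=float)
    else:
        pts = np.asarray(coords, dtype=float)[list(members)]
    if pts.shape[1] < 2:
        raise CladeTestError("need 2-D ordination coordinates")
    pts = pts[:, :2]
    if not np.isfinite(pts).all():
        raise CladeTestError("non-finite ordination coordinates")
    return pts


def clustering_score(coords, members) -> float:
    """Sum of Euclidean distances over all unordered member pairs (d_p)."""
    pts = _coords_array(coords, members)
    if pts.shape[0] < 2:
        raise CladeTestError("clustering score undefined for a singleton clade")
    return float(pdist(pts).sum())


def projection_score(coords, members, v) -> float:
    """Sum of scalar projections of members on the unit direction of v (d_p,v)."""
    v = np.asarray(v, dtype=float)[:2]
    norm = np.linalg.norm(v)
    if norm == 0:
        raise CladeTestError("projection direction must be a nonzero vector")
    pts = _coords_array(coords, members)
    return float((pts @ (v / norm)).sum())


def _sum_pdist_subsets(pool_pts: np.ndarray, size: int, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """d_p of `n` random size-`size` subsets of the pool, without replacement."""
    out = np.empty(n)
    npool = pool_pts.shape[0]
    for t in range(n):
        idx = rng.choice(npool, size=size, replace=False)
        out[t] = pdist(pool_pts[idx]).sum()
    return out


def clustering_test(coords, clade_map: CladeMap, n: int = 1000,
                    seed: int | None = None,
                    pool: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-clade clustering p-values against random draws from the pool.

    p = #{d_p >= d_random}/n; small p marks a clade more tightly
    clustered than random same-size draws. BH adjustment across the
    clades of the rank.
    """
    if n < 100:
        raise CladeTestError("need at least 100 permutations")
    if pool is None:
        if len(clade_map.clades) < 2:
            raise CladeTestError(
                "clustering null needs >= 2 clades or an explicit pool")
        pool = clade_map.pool
    rng = np.random.default_rng(seed)
    pool_pts = _coords_array(coords, pool)
    rows = []
    for label, members in sorted(clade_map.clades.items()):
        s_p = len(members)
        if s_p < 2:
            logger.warning("clustering_test: skipping singleton clade %r", label)
            continue
        if s_p > len(pool):
            raise CladeTestError(
                f"clade {label!r} has {s_p} members but the pool holds {len(pool)}"
            )
        d_p = clustering_score(coords, members)
        d_rand = _sum_pdist_subsets(pool_pts, s_p, n, rng)
        p = float(np.mean(d_p >= d_rand - 1e-12))
        rows.append({"clade": label, "rank": clade_map.rank, "s_p": s_p,
                     "d_p": d_p, "p_clust": p, "n_clustering": n})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_clust"] = multipletests(df["p_clust"], method="fdr_bh")[1]
    return df


def association_test(coords, clade_map: CladeMap, eigenvectors: pd.DataFrame,
                     n: int = 100, seed: int | None = None,
                     null_mean: str = "origin",
                     lower: float = 0.025, upper: float = 0.975) -> pd.DataFrame:
    """Per-clade, per-eigenvector signed association test.

    ``eigenvectors`` is a DataFrame of constraint arrows (rows named by
    the environmental variable, two columns for the plane). The Gaussian
    null is centred at the ordination origin by default
    (``null_mean='clade'`` recentres it at the clade centroid for
    sensitivity analysis). Direction is called from the upper-tail
    proportion u after BH adjustment of the two-sided p across the
    clade x eigenvector family of the rank.
    """
    if n < 100:
        logger.warning("association_test: n=%d gives tail granularity coarser "
                       "than the %.3f threshold", n, lower)
    if null_mean not in ("origin", "clade"):
        raise CladeTestError(f"unknown null_mean {null_mean!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for label, members in sorted(clade_map.clades.items()):
        s_p = len(members)
        if s_p < 2:
            logger.warning("association_test: skipping singleton clade %r", label)
            continue
        pts = _coords_array(coords, members)
        var = pts.var(axis=0, ddof=0)
        if (var == 0).all():
            raise CladeTestError(f"clade {label!r} has zero variance on both axes")
        mean = pts.mean(axis=0) if null_mean == "clade" else np.zeros(2)
        sd = np.sqrt(var)
        # one set of null clouds per clade, reused across eigenvectors so a
        # clade's tests share the same random panel
        nulls = rng.normal(loc=mean, scale=sd, size=(n, s_p, 2))
        for vec_name, v in eigenvectors.iterrows():
            v = v.to_numpy(dtype=float)[:2]
            norm = np.linalg.norm(v)
            if norm == 0:
                raise CladeTestError(f"eigenvector {vec_name!r} is the zero vector")
            vhat = v / norm
            d_pv = float((pts @ vhat).sum())
            d_rand = (nulls @ vhat).sum(axis=1)
            u = float(np.mean(d_pv >= d_rand - 1e-12))
            p_two = 2.0 * min(u, 1.0 - u)
            rows.append({"clade": label, "rank": clade_map.rank, "s_p": s_p,
                         "vector": str(vec_name), "d_pv": d_pv, "u": u,
                         "p_assoc": min(1.0, p_two), "n_association": n})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_assoc"] = multipletests(df["p_assoc"], method="fdr_bh")[1]
        alpha = 2.0 * min(lower, 1.0 - upper)
        sig = df["q_assoc"] <= alpha
        df["direction"] = np.where(
            sig & (df["u"] >= upper), "positive",
            np.where(sig & (df["u"] <= lower), "negative", "none"),
        )
    return df


def run_clade_tests(ordination: OrdinationResult, table: OtuTable,
                    ranks=("phylum", "class", "order", "family"),
                    n_clustering: int = 1000, n_association: int = 1000,
                    min_clade_size: int = 5, seed: int | None = None,
                    null_mean: str = "origin") -> pd.DataFrame:
    """Both clade tests at every requested rank, as one tidy table.

    Coordinates are the first two canonical axes; association runs
    against every constraint eigenvector of the ordination. Clades with
    fewer than ``min_clade_size`` OTUs are skipped.
    """
    coords = ordination.otu_scores.iloc[:, :2]
    eig = ordination.biplot_scores.iloc[:, :2]
    ss = np.random.SeedSequence(seed)
    out = []
    for rank, child in zip(ranks, ss.spawn(len(ranks))):
        cmap = clade_map_from_lineages(table, rank, min_size=min_clade_size)
        if len(cmap.clades) < 2:
            logger.warning("run_clade_tests: fewer than 2 clades of size >= %d "
                           "at rank %r; skipping", min_clade_size, rank)
            continue
        s1, s2 = child.spawn(2)
        clust = clustering_test(coords, cmap, n=n_clustering,
                                seed=np.random.default_rng(s1))
        assoc = association_test(coords, cmap, eig, n=n_association,
                                 seed=np.random.default_rng(s2),
                                 null_mean=null_mean)
        merged = assoc.merge(
            clust[["clade", "d_p", "p_clust", "q_clust", "n_clustering"]],
            on="clade", how="left",
        )
        out.append(merged)
    if not out:
        logger.warning("run_clade_tests: no rank produced results")
        return pd.DataFrame()
    df = pd.concat(out, ignore_index=True)
    df["seed"] = seed
    return df
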