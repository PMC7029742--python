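"""Alpha diversity, dissimilarities, prevalence classes and distance decay.

Implements the descriptive community layer: Shannon diversity per sample,
Bray–Curtis and Jaccard dissimilarity matrices, occupancy-based
gamma-diversity categories (core / cosmopolitan / common / intermediate /
rare / unique), per-sample phylum composition, environment correlations,
great-circle distances and a Mantel-style distance-decay test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import shannon as _skbio_shannon

from .io_prep import OtuTable, SiteMetadata

EARTH_RADIUS_KM = 6371.0

#: occupancy categories in precedence order (highest occupancy first)
CATEGORIES = ("core", "cosmopolitan", "common", "intermediate", "rare", "unique")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample ids and a metric tag."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match id count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        object.__setattr__(self, "values", v)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids),
                            columns=list(self.ids))


@dataclass(frozen=True)
class PrevalenceSummary:
    """Per-OTU occupancy categories and per-category shares."""

    occupancy: pd.Series           # OTU id -> number of sites with count > 0
    category: pd.Series            # OTU id -> category label
    otu_fraction: pd.Series        # category -> fraction of OTUs
    read_fraction: pd.Series       # category -> fraction of reads
    phylum_composition: pd.DataFrame  # category x phylum, fraction of OTUs
    rare_unique_otu_fraction: float
    rare_unique_read_fraction: float


@dataclass(frozen=True)
class DecayResult:
    """Distance-decay relationship between geography and community distance."""

    pairs: pd.DataFrame     # pair_a, pair_b, geo_km, dissimilarity, same_basin
    rho: float
    p_spearman: float       # analytic Spearman p (pairs treated independent)
    p_mantel: float         # permutation p, sample labels permuted jointly
    n_perm: int
    scope: str


def shannon(counts, base: float = np.e) -> float:
    """Shannon diversity H = -sum p_i log p_i of one sample (nats by default)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("shannon expects a single sample's count vector")
    if counts.sum() <= 0:
        raise ValueError("shannon is undefined for an all-zero sample")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return float(_skbio_shannon(counts, base=base))


def alpha_diversity(table: OtuTable, base: float = np.e) -> pd.Series:
    """Shannon index per sample."""
    vals = [shannon(table.counts[i], base=base) for i in range(table.n_samples)]
    return pd.Series(vals, index=list(table.sample_ids), name="shannon")


def dissimilarity(abundance, metric: str = "bray_curtis",
                  ids: tuple[str, ...] | None = None) -> DistanceMatrix:
    """Pairwise Bray–Curtis or Jaccard dissimilarity (samples are rows).

    Bray–Curtis is abundance-weighted (sum |x-y| / sum (x+y)); Jaccard is
    computed on presence/absence.
    """
    if isinstance(abundance, OtuTable):
        if ids is None:
            ids = abundance.sample_ids
        abundance = abundance.counts
    x = np.asarray(abundance, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a matrix with at least two samples")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = np.flatnonzero(x.sum(axis=1) == 0)
    if zero.size:
        bad = [ids[i] if ids else str(i) for i in zero]
        raise ValueError(f"sample(s) with zero total abundance: {', '.join(bad)}")
    if ids is None:
        ids = tuple(str(i) for i in range(x.shape[0]))
    if metric == "bray_curtis":
        d = pdist(x, metric="braycurtis")
    elif metric == "jaccard":
        d = pdist(x > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(ids=tuple(ids), values=squareform(d), metric=metric)


def _categorize(occ: int, n: int) -> str:
    # precedence: core > cosmopolitan > common > intermediate > rare > unique
    if occ == n:
        return "core"
    frac = occ / n
    if frac > 0.9:
        return "cosmopolitan"
    if frac > 0.5:
        return "common"
    if occ == 1:
        return "unique"
    if frac < 0.1:
        return "rare"
    return "intermediate"


def prevalence_categories(table: OtuTable,
                          rare_threshold: float = 0.1,
                          common_threshold: float = 0.5,
                          cosmopolitan_threshold: float = 0.9) -> PrevalenceSummary:
    """Occupancy-based gamma-diversity classification of OTUs.

    Default bins: core = all sites; cosmopolitan = >90% of sites;
    common = >50%; intermediate = 10–50%; rare = <10% (more than one
    site); unique = exactly one site.
    """
    if not (0 < rare_threshold < common_threshold < cosmopolitan_threshold < 1):
        raise ValueError("prevalence thresholds must be strictly increasing in (0,1)")
    if table.n_samples < 2:
        raise ValueError("prevalence classification needs at least two samples")
    n = table.n_samples
    occ = (table.counts > 0).sum(axis=0)
    occupancy = pd.Series(occ, index=list(table.otu_ids), name="occupancy")
    category = pd.Series([_categorize(o, n) for o in occ],
                         index=list(table.otu_ids), name="category")
    totals = table.otu_totals().astype(float)
    grand = totals.sum()
    otu_fraction = category.value_counts(normalize=True).reindex(
        CATEGORIES, fill_value=0.0
    )
    read_fraction = pd.Series(
        {c: totals[(category == c).to_numpy()].sum() / grand for c in CATEGORIES}
    )
    phyla = pd.Series(table.lineage_at_rank("phylum"),
                      index=list(table.otu_ids)).replace("", "Unassigned")
    comp = (
        pd.crosstab(category, phyla, normalize="index")
        .reindex(CATEGORIES, fill_value=0.0)
    )
    ru = category.isin(["rare", "unique"]).to_numpy()
    return PrevalenceSummary(
        occupancy=occupancy,
        category=category,
        otu_fraction=otu_fraction,
        read_fraction=read_fraction,
        phylum_composition=comp,
        rare_unique_otu_fraction=float(ru.mean()),
        rare_unique_read_fraction=float(totals[ru].sum() / grand),
    )


def phylum_relative_abundance(table: OtuTable, rank: str = "phylum") -> pd.DataFrame:
    """Per-sample relative read abundance of taxa at ``rank``.

    OTUs unassigned at the rank are pooled into ``Unassigned``. Rows
    (samples) sum to 1.
    """
    names = table.lineage_at_rank(rank)
    if not any(names):
        raise ValueError(f"no OTU has a taxon assigned at rank {rank!r}")
    taxa = pd.Series([t if t else "Unassigned" for t in names])
    df = pd.DataFrame(table.counts, index=list(table.sample_ids))
    grouped = df.T.groupby(taxa.values).sum().T
    totals = grouped.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero reads cannot be normalized")
    return grouped.div(totals, axis=0)


def env_correlation(x, y, method: str = "pearson") -> tuple[float, float, float]:
    """Correlation between two per-sample vectors.

    Returns ``(r, r_squared, p)``; Spearman uses average ranks for ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(r * r), float(p)


def geographic_distances(metadata: list[SiteMetadata]) -> DistanceMatrix:
    """Haversine great-circle distances (km) between sites."""
    ids = tuple(m.sample_id for m in metadata)
    lat = np.radians([m.lat for m in metadata])
    lon = np.radians([m.lon for m in metadata])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against rounding
    return DistanceMatrix(ids=ids, values=d, metric="geographic_km")


def distance_decay(geo: DistanceMatrix, community: DistanceMatrix,
                   scope: str = "all", basins: dict[str, str] | None = None,
                   n_perm: int = 9999, seed: int | None = None) -> DecayResult:
    """Spearman correlation of geographic vs community distance.

    The permutation p-value is Mantel-style: sample labels of the
    community matrix are permuted jointly, preserving the within-matrix
    dependence between pairs that share a site. ``scope`` restricts the
    pair set to within-basin or between-basin pairs.
    """
    if geo.ids != community.ids:
        raise ValueError("distance matrices must share the same sample ids")
    if scope not in ("all", "within_basin", "between_basin"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope != "all" and basins is None:
        raise ValueError("basin labels required for basin-scoped decay")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    n = len(geo.ids)
    iu = np.triu_indices(n, k=1)
    same = np.ones(len(iu[0]), dtype=bool)
    if basins is not None:
        lab = np.array([basins[s] for s in geo.ids])
        same = lab[iu[0]] == lab[iu[1]]
    if scope == "within_basin":
        mask = same
    elif scope == "between_basin":
        mask = ~same
    else:
        mask = np.ones_like(same)
    if mask.sum() < 3:
        raise ValueError(f"scope {scope!r} leaves fewer than 3 pairs")
    g = geo.values[iu]
    c = community.values[iu]
    rho, p_sp = stats.spearmanr(g[mask], c[mask])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        cp = community.values[np.ix_(perm, perm)][iu]
        r_perm = stats.spearmanr(g[mask], cp[mask]).statistic
        if abs(r_perm) >= abs(rho) - 1e-12:
            hits += 1
    p_mantel = (hits + 1) / (n_perm + 1)
    pairs = pd.DataFrame({
        "site_a": np.asarray(geo.ids)[iu[0]][mask],
        "site_b": np.asarray(geo.ids)[iu[1]][mask],
        "geo_km": g[mask],
        "dissimilarity": c[mask],
        "same_basin": same[mask],
    })
    return DecayResult(pairs=pairs, rho=float(rho), p_spearman=float(p_sp),
                       p_mantel=float(p_mantel), n_perm=n_perm, scope=scope)
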