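"""Reading, writing and preprocessing of OTU tables and site metadata.

The community matrix is held as an :class:`OtuTable` (samples x OTUs).
Preprocessing follows the standard amplicon workflow for lake surveys:
drop OTUs with fewer than ``min_total`` reads over all samples, rarefy
every sample to a common depth without replacement, and log10-transform
abundances for the linear-model stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical rank order used for lineage strings
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Greengenes-style rank prefixes, stripped on read
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

ENV_COLUMNS = ("temperature", "pH", "DO", "turbidity", "chl_a", "TP", "NO23")
LANDUSE_CATEGORIES = (
    "urban",
    "hetero_agri",
    "pasture",
    "arable",
    "forest",
    "water_wetland",
)


class OtuTableError(ValueError):
    """Malformed OTU table input or an operation contract violation."""


@dataclass(frozen=True)
class OtuTable:
    """Integer community matrix with per-OTU taxonomy.

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers (rows of ``counts``).
    otu_ids : list of str
        Ordered, unique OTU identifiers (columns of ``counts``).
    counts : ndarray of int, shape (n_samples, n_otus)
        Non-negative read counts.
    lineages : list of tuple of str
        Per-OTU ranked taxonomy (kingdom..species); ranks may be empty
        strings; an all-empty tuple marks an unannotated OTU.
    """

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray
    lineages: tuple[tuple[str, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix (samples x OTUs)")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise OtuTableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise OtuTableError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise OtuTableError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise OtuTableError("sample_ids must be unique")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise OtuTableError("otu_ids must be unique")
        lineages = self.lineages
        if not lineages:
            lineages = tuple(("",) * len(RANKS) for _ in self.otu_ids)
        if len(lineages) != len(self.otu_ids):
            raise OtuTableError("one lineage per OTU required")
        object.__setattr__(self, "lineages", tuple(tuple(l) for l in lineages))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def lineage_at_rank(self, rank: str) -> tuple[str, ...]:
        """Taxon name of every OTU at ``rank`` ('' where unassigned)."""
        if rank not in RANKS:
            raise OtuTableError(f"unknown rank {rank!r}; expected one of {RANKS}")
        i = RANKS.index(rank)
        return tuple(l[i] if i < len(l) else "" for l in self.lineages)

    def select_otus(self, mask: np.ndarray) -> "OtuTable":
        mask = np.asarray(mask, dtype=bool)
        return OtuTable(
            sample_ids=self.sample_ids,
            otu_ids=tuple(np.asarray(self.otu_ids)[mask]),
            counts=self.counts[:, mask],
            lineages=tuple(l for l, m in zip(self.lineages, mask) if m),
        )

    def select_samples(self, mask: np.ndarray) -> "OtuTable":
        mask = np.asarray(mask, dtype=bool)
        return OtuTable(
            sample_ids=tuple(np.asarray(self.sample_ids)[mask]),
            otu_ids=self.otu_ids,
            counts=self.counts[mask, :],
            lineages=self.lineages,
        )

    def to_frame(self) -> pd.DataFrame:
        """Counts as a samples x OTUs DataFrame."""
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.otu_ids)
        )


@dataclass(frozen=True)
class SiteMetadata:
    """Per-site environment, location and land-use composition.

    ``landuse_basin`` and ``landuse_local`` are fraction vectors over the
    six land-use categories (urban, heterogeneous agriculture, pasture,
    arable, forest, water/wetland); each sums to 1.
    """

    sample_id: str
    env: dict[str, float]
    lat: float
    lon: float
    basin: str
    landuse_basin: dict[str, float]
    landuse_local: dict[str, float]

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(
                f"sample {self.sample_id}: coordinates ({self.lat}, {self.lon}) "
                "outside valid WGS84 ranges"
            )
        for name, vec in (("landuse_basin", self.landuse_basin),
                          ("landuse_local", self.landuse_local)):
            vals = np.array(list(vec.values()), dtype=float)
            if vals.size:
                if (vals < -1e-9).any() or (vals > 1 + 1e-9).any():
                    raise ValueError(
                        f"sample {self.sample_id}: {name} fractions outside [0,1]"
                    )
                if abs(vals.sum() - 1.0) > 1e-6:
                    raise ValueError(
                        f"sample {self.sample_id}: {name} fractions sum to "
                        f"{vals.sum():.6f}, expected 1"
                    )


def metadata_to_frame(metadata: list[SiteMetadata]) -> pd.DataFrame:
    """Flatten a metadata list into a per-sample DataFrame.

    Environment columns keep their names; land-use columns are prefixed
    ``basin_``/``local_``.
    """
    rows = []
    for m in metadata:
        row: dict[str, object] = {"sample_id": m.sample_id, "lat": m.lat,
                                  "lon": m.lon, "basin": m.basin}
        row.update(m.env)
        row.update({f"basin_{k}": v for k, v in m.landuse_basin.items()})
        row.update({f"local_{k}": v for k, v in m.landuse_local.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def _split_lineage(raw: str) -> tuple[str, ...]:
    parts = [p.strip() for p in str(raw).split(";")]
    cleaned = []
    for p in parts:
        for pref in _RANK_PREFIXES:
            if p.startswith(pref):
                p = p[len(pref):]
                break
        cleaned.append(p.strip())
    # pad/truncate to the canonical 7 ranks
    cleaned = (cleaned + [""] * len(RANKS))[: len(RANKS)]
    return tuple(cleaned)


_TAXONOMY_HEADERS = {"taxonomy", "consensus lineage", "consensuslineage", "lineage"}


def read_otu_table(path, dialect: str = "qiime_classic_tsv") -> OtuTable:
    """Read a QIIME-classic TSV OTU table.

    On disk the table is OTUs x samples with a leading ``#OTU ID`` column
    and an optional trailing taxonomy column; the returned
    :class:`OtuTable` is oriented samples x OTUs.
    """
    if dialect != "qiime_classic_tsv":
        raise OtuTableError(f"unsupported dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.readlines()
    header_idx = None
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("#"):
            if "OTU ID" in line:
                header_idx = i
                break
            continue  # provenance comment
        header_idx = i  # headerless '#' but first data-ish line is the header
        break
    if header_idx is None:
        raise OtuTableError(f"{path}: no header row found (expected '#OTU ID ...')")
    header = lines[header_idx].lstrip("#").rstrip("\n").split("\t")
    header = [h.strip() for h in header]
    if len(header) < 2:
        raise OtuTableError(
            f"{path}: malformed header at line {header_idx + 1}: {lines[header_idx]!r}"
        )
    has_tax = header[-1].strip().lower() in _TAXONOMY_HEADERS
    sample_cols = header[1: -1 if has_tax else len(header)]
    otu_ids, lineages, rows = [], [], []
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise OtuTableError(
                f"{path}: line {lineno} has {len(fields)} fields, expected "
                f"{len(header)}"
            )
        otu_ids.append(fields[0].strip())
        raw_counts = fields[1: 1 + len(sample_cols)]
        try:
            vals = [float(v) for v in raw_counts]
        except ValueError as exc:
            raise OtuTableError(f"{path}: non-numeric count at line {lineno}") from exc
        if any(v < 0 for v in vals):
            raise OtuTableError(f"{path}: negative count at line {lineno}")
        if any(abs(v - round(v)) > 1e-9 for v in vals):
            raise OtuTableError(f"{path}: non-integral count at line {lineno}")
        rows.append([int(round(v)) for v in vals])
        lineages.append(_split_lineage(fields[-1]) if has_tax else ("",) * len(RANKS))
    counts = np.asarray(rows, dtype=np.int64).T if rows else np.zeros(
        (len(sample_cols), 0), dtype=np.int64
    )
    return OtuTable(
        sample_ids=tuple(sample_cols),
        otu_ids=tuple(otu_ids),
        counts=counts,
        lineages=tuple(lineages),
    )


def write_otu_table(table: OtuTable, path, provenance: str | None = None) -> None:
    """Write a QIIME-classic TSV (OTUs x samples, trailing taxonomy column)."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\ttaxonomy\n")
        for j, otu in enumerate(table.otu_ids):
            lineage = ";".join(table.lineages[j]).rstrip(";")
            row = "\t".join(str(int(v)) for v in table.counts[:, j])
            fh.write(f"{otu}\t{row}\t{lineage}\n")


def read_metadata(path, column_map: dict[str, str] | None = None) -> list[SiteMetadata]:
    """Read per-site metadata TSV into :class:`SiteMetadata` records.

    ``column_map`` translates on-disk column names to the canonical names
    (``sample_id``, ``lat``, ``lon``, ``basin``, the seven environment
    variables, and ``basin_<cat>``/``local_<cat>`` land-use fractions).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    required = {"sample_id", "lat", "lon", "basin"}
    missing = required - set(df.columns)
    if missing:
        raise OtuTableError(f"{path}: missing metadata columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        env = {k: float(row[k]) for k in ENV_COLUMNS if k in df.columns}
        lb = {k: float(row[f"basin_{k}"]) for k in LANDUSE_CATEGORIES
              if f"basin_{k}" in df.columns}
        ll = {k: float(row[f"local_{k}"]) for k in LANDUSE_CATEGORIES
              if f"local_{k}" in df.columns}
        records.append(
            SiteMetadata(
                sample_id=str(row["sample_id"]),
                env=env,
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                basin=str(row["basin"]),
                landuse_basin=lb,
                landuse_local=ll,
            )
        )
    return records


def write_metadata(metadata: list[SiteMetadata], path,
                   provenance: str | None = None) -> None:
    df = metadata_to_frame(metadata)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.reset_index().to_csv(fh, sep="\t", index=False)


def filter_low_abundance(table: OtuTable, min_total: int = 5) -> OtuTable:
    """Drop OTUs with fewer than ``min_total`` reads summed over all samples."""
    if min_total < 1:
        raise OtuTableError("min_total must be >= 1")
    keep = table.otu_totals() >= min_total
    if not keep.any():
        logger.warning("filter_low_abundance: no OTU reaches min_total=%d", min_total)
    return table.select_otus(keep)


def rarefy(table: OtuTable, depth: int = 25000, seed: int | None = None) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Per-sample draws follow the multivariate hypergeometric distribution.
    Samples with fewer than ``depth`` reads are dropped with a warning.
    """
    if depth <= 0:
        raise OtuTableError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(dropped),
        )
    sub = table.select_samples(keep)
    new_counts = np.empty_like(sub.counts)
    for i in range(sub.n_samples):
        row = sub.counts[i]
        if row.sum() == depth:
            new_counts[i] = row
        else:
            new_counts[i] = rng.multivariate_hypergeometric(
                row, depth, method="marginals"
            )
    return replace(sub, counts=new_counts)


def log_transform(table_or_counts, pseudocount: float = 1.0) -> np.ndarray:
    """Elementwise ``log10(pseudocount + x)`` abundance transform.

    With the default pseudocount of 1, zeros map to zero and the transform
    is monotone; counts of 9 and 99 map to 1 and 2.
    """
    x = table_or_counts.counts if isinstance(table_or_counts, OtuTable) \
        else np.asarray(table_or_counts, dtype=float)
    if np.min(x) < 0:
        raise OtuTableError("log_transform requires non-negative abundances")
    if pseudocount <= 0:
        raise OtuTableError("pseudocount must be positive")
    return np.log10(pseudocount + x.astype(float))
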