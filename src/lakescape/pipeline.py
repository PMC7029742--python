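"""End-to-end orchestration of the lake-microbiome analysis.

``run_pipeline`` executes the full stage sequence — preprocessing,
diversity/prevalence, distance decay, per-response land-use GLM
ensembles, CCA with permutation inference, three-way variation
partitioning and the clade tests — writes every stage's TSV/JSON
artifacts under an output directory, and returns a single report dict
with the headline numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, io_prep, landuse_models, ordination
from .clade_test import run_clade_tests
from .io_prep import ENV_COLUMNS, LANDUSE_CATEGORIES

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, loadable from a YAML mapping.

    Defaults follow the study conventions: low-abundance filter at 5
    reads, rarefaction to 25,000, 1000 clustering / 1000 association
    permutations, BH-corrected 0.025/0.975 two-tail rule, six land-use
    predictors.
    """

    otu_table: str = ""
    metadata: str = ""
    outdir: str = "results"
    seed: int = 0
    min_total: int = 5
    rarefaction_depth: int = 25000
    cca_constraints: list[str] = field(
        default_factory=lambda: list(ENV_COLUMNS))
    glm_responses: list[str] = field(default_factory=lambda: list(ENV_COLUMNS))
    glm_predictors: list[str] = field(
        default_factory=lambda: [f"basin_{c}" for c in LANDUSE_CATEGORIES])
    clade_ranks: list[str] = field(
        default_factory=lambda: ["phylum", "class", "order", "family"])
    n_clustering: int = 1000
    n_association: int = 1000
    min_clade_size: int = 5
    n_perm_anova: int = 999
    n_perm_decay: int = 999
    prevalence_on_rarefied: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError("config", f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t")


def run_pipeline(config: PipelineConfig,
                 table: io_prep.OtuTable | None = None,
                 metadata: list[io_prep.SiteMetadata] | None = None) -> dict:
    """Run every stage; returns the report dict (also written as JSON).

    ``table``/``metadata`` may be passed directly (e.g. fresh from the
    synthetic generator); otherwise they are read from the configured
    paths.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = f"lakescape run seed={config.seed}"
    report: dict = {"seed": config.seed, "stages": {}}

    # ---- load & validate -------------------------------------------------
    stage = "load"
    try:
        if table is None:
            table = io_prep.read_otu_table(config.otu_table)
        if metadata is None:
            metadata = io_prep.read_metadata(config.metadata)
        meta_df = io_prep.metadata_to_frame(metadata)
        needed = (set(config.cca_constraints) | set(config.glm_responses)
                  | set(config.glm_predictors))
        missing = needed - set(meta_df.columns)
        if missing:
            raise PipelineError(stage, f"missing metadata column(s) "
                                f"{sorted(missing)}")
        common = [s for s in table.sample_ids if s in meta_df.index]
        if len(common) < 3:
            raise PipelineError(stage, "fewer than 3 samples shared between "
                                "OTU table and metadata")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- prep ------------------------------------------------------------
    stage = "prep"
    try:
        filtered = io_prep.filter_low_abundance(table, config.min_total)
        rarefied = io_prep.rarefy(filtered, config.rarefaction_depth,
                                  seed=config.seed)
        keep = [s in rarefied.sample_ids for s in common]
        samples = [s for s, k in zip(common, keep) if k]
        meta_df = meta_df.loc[samples]
        order = [rarefied.sample_ids.index(s) for s in samples]
        rarefied = rarefied.select_samples(
            np.isin(np.arange(rarefied.n_samples), order))
        rarefied = rarefied.select_otus(rarefied.otu_totals() > 0)
        logab = io_prep.log_transform(rarefied)
        io_prep.write_otu_table(rarefied, out / "rarefied_otu_table.tsv",
                                provenance=prov)
        report["stages"]["prep"] = {
            "n_samples": rarefied.n_samples,
            "n_otus": rarefied.n_otus,
            "depth": config.rarefaction_depth,
            "seed": config.seed,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- diversity & prevalence -----------------------------------------
    stage = "diversity"
    try:
        alpha = community.alpha_diversity(rarefied)
        prev_tab = rarefied if config.prevalence_on_rarefied else filtered
        prev = community.prevalence_categories(prev_tab)
        bc = community.dissimilarity(rarefied, "bray_curtis")
        _write_tsv(alpha.to_frame(), out / "alpha_diversity.tsv", prov)
        _write_tsv(bc.to_frame(), out / "bray_curtis.tsv", prov)
        _write_tsv(prev.category.to_frame(), out / "prevalence_categories.tsv",
                   prov)
        report["stages"]["diversity"] = {
            "shannon_range": [float(alpha.min()), float(alpha.max())],
            "prevalence_otu_fraction": prev.otu_fraction.to_dict(),
            "rare_unique_otu_fraction": prev.rare_unique_otu_fraction,
            "rare_unique_read_fraction": prev.rare_unique_read_fraction,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- distance decay --------------------------------------------------
    stage = "decay"
    try:
        geo = community.geographic_distances(
            [m for m in metadata if m.sample_id in set(samples)])
        idx = [geo.ids.index(s) for s in samples]
        geo = community.DistanceMatrix(
            ids=tuple(samples), values=geo.values[np.ix_(idx, idx)],
            metric="geographic_km")
        basins = dict(zip(samples, meta_df["basin"].astype(str)))
        decay = community.distance_decay(geo, bc, scope="all", basins=basins,
                                         n_perm=config.n_perm_decay,
                                         seed=config.seed + 1)
        _write_tsv(decay.pairs, out / "distance_decay_pairs.tsv", prov)
        report["stages"]["decay"] = {
            "rho": decay.rho, "p_spearman": decay.p_spearman,
            "p_mantel": decay.p_mantel, "n_perm": decay.n_perm,
            "seed": config.seed + 1,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- land-use GLM ensembles ------------------------------------------
    stage = "glm"
    try:
        glm_report = {}
        rows = []
        X = meta_df[config.glm_predictors].astype(float)
        for resp in config.glm_responses:
            ens = landuse_models.model_ensemble(
                meta_df[resp].astype(float), X, response=resp)
            glm_report[resp] = {
                "importance": ens.importance.to_dict(),
                "best_model": list(ens.best_model.predictors),
                "best_model_r2": ens.best_model.r2,
                "full_model_r2": ens.full_model_r2,
                "independent": ens.independent.to_dict(),
            }
            for pred in ens.importance.index:
                rows.append({"response": resp, "predictor": pred,
                             "importance": ens.importance[pred],
                             "avg_coef": ens.averaged_coef[pred],
                             "independent_r2": ens.independent[pred]})
        _write_tsv(pd.DataFrame(rows), out / "landuse_glm.tsv", prov)
        report["stages"]["glm"] = glm_report
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- CCA + permutation anova -----------------------------------------
    stage = "ordination"
    try:
        Xc = meta_df[config.cca_constraints].astype(float)
        ord_res = ordination.cca(rarefied.to_frame(), Xc)
        whole = ordination.permutation_anova(
            rarefied.to_frame(), Xc, term="model",
            n_perm=config.n_perm_anova, seed=config.seed + 2)
        margins = {}
        for name in config.cca_constraints:
            r = ordination.permutation_anova(
                rarefied.to_frame(), Xc, term=f"margin:{name}",
                n_perm=config.n_perm_anova, seed=config.seed + 3)
            margins[name] = {"pseudo_f": r.pseudo_f, "p": r.p_value}
        _write_tsv(ord_res.site_scores, out / "cca_site_scores.tsv", prov)
        _write_tsv(ord_res.otu_scores, out / "cca_otu_scores.tsv", prov)
        _write_tsv(ord_res.biplot_scores, out / "cca_biplot_scores.tsv", prov)
        report["stages"]["ordination"] = {
            "eigenvalues": [float(e) for e in ord_res.eigenvalues],
            "total_inertia": ord_res.total_inertia,
            "constrained_inertia": ord_res.constrained_inertia,
            "explained_inertia_pct": 100.0 * ord_res.proportion_explained,
            "model_pseudo_f": whole.pseudo_f,
            "model_p": whole.p_value,
            "margins": margins,
            "seed": config.seed + 2,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- variation partitioning ------------------------------------------
    stage = "varpart"
    try:
        vp = ordination.varpart3(
            logab,
            meta_df[[f"basin_{c}" for c in LANDUSE_CATEGORIES]].astype(float),
            meta_df[[f"local_{c}" for c in LANDUSE_CATEGORIES]].astype(float),
            meta_df[config.cca_constraints].astype(float),
            names=("landuse_basin", "landuse_local", "chemistry"),
        )
        report["stages"]["varpart"] = {
            "unique": vp.unique, "shared_all": vp.shared_all,
            "residual": vp.residual,
            "total_explained": vp.subset_r2[
                ("landuse_basin", "landuse_local", "chemistry")],
            "chemistry_total": vp.subset_r2[("chemistry",)],
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- clade tests -------------------------------------------------------
    stage = "cladetest"
    try:
        clades = run_clade_tests(
            ord_res, rarefied, ranks=config.clade_ranks,
            n_clustering=config.n_clustering,
            n_association=config.n_association,
            min_clade_size=config.min_clade_size, seed=config.seed + 4)
        if len(clades):
            _write_tsv(clades, out / "clade_tests.tsv", prov)
            sig_clust = clades.loc[clades["q_clust"] <= 0.05, "clade"].unique()
            sig_assoc = clades.loc[clades["direction"] != "none",
                                   ["clade", "vector", "direction"]]
            report["stages"]["cladetest"] = {
                "significant_clustered": sorted(map(str, sig_clust)),
                "significant_associations": sig_assoc.to_dict("records"),
                "seed": config.seed + 4,
            }
        else:
            report["stages"]["cladetest"] = {"significant_clustered": [],
                                             "significant_associations": [],
                                             "seed": config.seed + 4}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


#: minimal structural schema of the report (stage -> required keys)
REPORT_SCHEMA = {
    "seed": int,
    "stages": {
        "prep": ["n_samples", "n_otus", "depth", "seed"],
        "diversity": ["shannon_range", "prevalence_otu_fraction"],
        "decay": ["rho", "p_mantel", "seed"],
        "glm": [],
        "ordination": ["eigenvalues", "explained_inertia_pct", "model_p", "seed"],
        "varpart": ["unique", "residual"],
        "cladetest": ["significant_clustered", "seed"],
    },
}


def validate_report(report: dict) -> None:
    """Raise if the report lacks the documented structure or stage seeds."""
    if "seed" not in report or "stages" not in report:
        raise PipelineError("report", "missing top-level 'seed'/'stages'")
    for stage, keys in REPORT_SCHEMA["stages"].items():
        if stage not in report["stages"]:
            raise PipelineError("report", f"missing stage section {stage!r}")
        for k in keys:
            if k not in report["stages"][stage]:
                raise PipelineError("report", f"stage {stage!r} lacks key {k!r}")
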