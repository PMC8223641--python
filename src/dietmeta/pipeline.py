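"""End-to-end orchestration: data -> FFQ -> QC -> clustering ->
per-cohort associations -> meta-analysis -> descriptives.

A single :class:`PipelineConfig` governs every stage; every value used
is echoed into the run manifest together with stage row counts and
output checksums, so a rerun with the same config and inputs is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import COHORTS, __version__, association, cluster, descriptives, ffq
from . import meta as meta_mod
from . import qc, simulate

logger = logging.getLogger(__name__)

_TSV_FLOAT = "%.10g"

#: Covariate sets of the three model families. Individual food/nutrient
#: models adjust for age, sex and log10 read depth; cluster-centroid and
#: inflammation-marker models additionally adjust for total kcal because
#: their exposures are built from unadjusted g/day intakes.
BASE_COVARIATES = {
    "taxa": ("age", "sex", "log_depth"),
    "pathway": ("age", "sex", "log_depth"),
    "species_cluster": ("age", "sex", "log_depth", "kcal"),
    "pathway_cluster": ("age", "sex", "log_depth", "kcal"),
    "fcal": ("age", "sex", "log_depth", "kcal"),
    "cga": ("age", "sex", "log_depth", "kcal"),
}

SENSITIVITY_COVARIATES = ("bmi", "smoking", "antihypertensives",
                          "antidiabetics", "statins")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a pipeline run (see docs/methods.md for rationale)."""

    simulation: simulate.SimulationConfig | None = None
    input_dir: str | None = None
    min_depth: float = qc.MIN_DEPTH_READS
    min_prevalence: float = qc.MIN_PREVALENCE
    min_mean_abundance: float = qc.MIN_MEAN_ABUNDANCE
    grubbs_alpha: float = 0.05
    grubbs_max_iter: int = 5
    linkage: str = "complete"
    # z-score foods before the squared-Euclidean food tree (scale-free,
    # co-consumption-driven); False keeps raw g/day distances.
    standardize_food_distance: bool = False
    # None -> cut at half the root merge height (data-driven default);
    # for the original FFQ/MetaPhlAn data the documented cuts are 53
    # (food tree) and 0.8 (species tree).
    food_cut_height: float | None = None
    species_cut_height: float | None = None
    pathway_cut_height: float | None = None
    standardize_exposure: bool = True
    min_complete_cases: int = association.MIN_COMPLETE_CASES
    fdr_family: str = "per_exposure_kind"
    fdr_max: float = meta_mod.FDR_MAX
    qp_min: float = meta_mod.QP_MIN
    log_markers: bool = True
    run_sensitivity: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.simulation is None and self.input_dir is None:
            raise ValueError("need either a simulation block or an input_dir")
        for name, value in (("min_prevalence", self.min_prevalence),
                            ("grubbs_alpha", self.grubbs_alpha),
                            ("fdr_max", self.fdr_max),
                            ("qp_min", self.qp_min)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _half_root(model: cluster.ClusterModel) -> float:
    return float(model.merge_heights[-1]) / 2.0


@dataclass
class PipelineResult:
    """In-memory results of a full run."""

    dataset: simulate.SyntheticDataset
    intake: ffq.IntakeMatrix
    taxa: qc.AbundanceTable
    pathways: qc.AbundanceTable
    qc_reports: dict
    cluster_models: dict
    associations: pd.DataFrame
    meta: pd.DataFrame
    significant: pd.DataFrame
    descriptives: pd.DataFrame
    cohort_data: dict = field(default_factory=dict)
    sensitivity: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _load_dataset(config: PipelineConfig) -> simulate.SyntheticDataset:
    if config.simulation is not None:
        return simulate.simulate_cohorts(config.simulation)
    return simulate.read_dataset(config.input_dir)


def run_pipeline(config: PipelineConfig,
                 outdir: str | pathlib.Path | None = None) -> PipelineResult:
    """Execute every stage; optionally write all stage TSVs + manifest."""
    stages_done = []

    def stage(name):
        logger.info("stage %s", name)
        stages_done.append(name)

    try:
        stage("data")
        ds = _load_dataset(config)

        stage("ffq")
        intake = ffq.intake_from_matrix(ds.intake, ds.metadata["kcal"])
        intake = ffq.energy_adjust(intake)

        stage("qc")
        depth = ds.metadata["read_depth"]
        reports = {}
        taxa = qc.AbundanceTable(ds.taxa, kind="taxa").with_depth(depth)
        taxa, reports["taxa"] = qc.filter_samples(taxa, config.min_depth)
        taxa, reports["taxa"] = qc.filter_features(
            taxa, config.min_prevalence, config.min_mean_abundance,
            reports["taxa"])
        taxa = qc.transform_taxa(taxa)
        taxa, reports["taxa"] = qc.mask_outliers(
            taxa, config.grubbs_alpha, config.grubbs_max_iter,
            reports["taxa"])
        paths = qc.AbundanceTable(ds.pathways, kind="pathway").with_depth(depth)
        paths, reports["pathway"] = qc.filter_samples(paths, config.min_depth)
        paths, reports["pathway"] = qc.filter_features(
            paths, config.min_prevalence, np.nan, reports["pathway"])
        paths = qc.transform_pathways(paths)
        paths, reports["pathway"] = qc.mask_outliers(
            paths, config.grubbs_alpha, config.grubbs_max_iter,
            reports["pathway"])
        retained = taxa.values.index

        stage("clustering")
        raw_taxa = ds.taxa.loc[retained, taxa.values.columns]
        models = {}
        models["food"] = cluster.hierarchical_cluster(
            cluster.variable_distances(
                ds.intake.loc[retained], "sqeuclidean",
                standardize=config.standardize_food_distance),
            linkage=config.linkage)
        models["species"] = cluster.hierarchical_cluster(
            cluster.variable_distances(raw_taxa, "braycurtis"),
            linkage=config.linkage)
        models["pathway"] = cluster.hierarchical_cluster(
            cluster.variable_distances(paths.values, "sqeuclidean"),
            linkage=config.linkage)
        cuts = {"food": config.food_cut_height,
                "species": config.species_cut_height,
                "pathway": config.pathway_cut_height}
        data_for = {"food": ds.intake.loc[retained],
                    "species": taxa.masked_values(),
                    "pathway": paths.masked_values()}
        for name, model in models.items():
            h = cuts[name] if cuts[name] is not None else _half_root(model)
            cut = cluster.cut_model(model, h, data_for[name])
            # domain-prefixed centroid names keep responses unambiguous
            cut.centroids.columns = [f"{name}_{c}"
                                     for c in cut.centroids.columns]
            models[name] = cut

        stage("association")
        cohort_of = ds.metadata.loc[retained, "cohort"]
        covs = pd.DataFrame({
            "age": ds.metadata.loc[retained, "age"],
            "sex": ds.metadata.loc[retained, "sex"].astype(float),
            "log_depth": np.log10(depth.loc[retained]),
            "bmi": ds.metadata.loc[retained, "bmi"],
            "smoking": ds.metadata.loc[retained, "smoking"].astype(float),
            "antihypertensives":
                ds.metadata.loc[retained, "antihypertensives"].astype(float),
            "antidiabetics":
                ds.metadata.loc[retained, "antidiabetics"].astype(float),
            "statins": ds.metadata.loc[retained, "statins"].astype(float),
        })
        kcal = ds.metadata.loc[retained, "kcal"]
        markers = ds.metadata.loc[retained, ["fcal", "cga"]]
        if config.log_markers:
            markers = np.log(markers.where(markers > 0))
        food_exposures = intake.items_density.loc[retained]
        food_centroids = models["food"].centroids

        feature_cohorts = {}
        cluster_cohorts = {}
        for c in COHORTS:
            members = cohort_of.index[cohort_of == c]
            if len(members) == 0:
                continue
            feature_cohorts[c] = association.CohortData(
                cohort=c,
                exposures=food_exposures.loc[members],
                features={"taxa": taxa.masked_values().loc[members],
                          "pathway": paths.masked_values().loc[members]},
                covariates=covs.loc[members], kcal=kcal.loc[members])
            cluster_cohorts[c] = association.CohortData(
                cohort=c,
                exposures=food_centroids.loc[members],
                features={
                    "species_cluster": models["species"].centroids.loc[members],
                    "pathway_cluster": models["pathway"].centroids.loc[members],
                    "fcal": markers[["fcal"]].loc[members],
                    "cga": markers[["cga"]].loc[members]},
                covariates=covs.loc[members], kcal=kcal.loc[members])
        plan_features = [(k, BASE_COVARIATES[k]) for k in ("taxa", "pathway")]
        plan_clusters = [(k, BASE_COVARIATES[k])
                         for k in ("species_cluster", "pathway_cluster",
                                   "fcal", "cga")]
        assoc = pd.concat([
            association.associate_all(
                feature_cohorts, plan_features,
                min_n=config.min_complete_cases,
                standardize_exposure=config.standardize_exposure),
            association.associate_all(
                cluster_cohorts, plan_clusters,
                min_n=config.min_complete_cases,
                standardize_exposure=config.standardize_exposure),
        ], ignore_index=True)

        stage("meta")
        pooled = meta_mod.meta_analyze(assoc, family=config.fdr_family)
        gated = meta_mod.significance_gate(pooled, config.fdr_max,
                                           config.qp_min)

        stage("descriptives")
        food_plan = tuple(descriptives.DEFAULT_PLAN) + tuple(
            descriptives.ComparisonPlan(f, "continuous", "vs_hc")
            for f in ds.intake.columns)
        desc = descriptives.compare_cohorts(
            ds.metadata, intake=ds.intake, plan=food_plan,
            fdr_max=config.fdr_max)

        sensitivity = None
        if config.run_sensitivity:
            stage("sensitivity")
            sens_pairs = gated.loc[gated["response_kind"].isin(
                ("taxa", "pathway"))]
            sensitivity = association.sensitivity_refit(
                sens_pairs, feature_cohorts, BASE_COVARIATES,
                SENSITIVITY_COVARIATES, fdr_max=config.fdr_max,
                min_n=config.min_complete_cases,
                standardize_exposure=config.standardize_exposure)
    except PipelineError:
        raise
    except Exception as exc:
        failed = stages_done[-1] if stages_done else "setup"
        raise PipelineError(failed, str(exc)) from exc

    result = PipelineResult(
        dataset=ds, intake=intake, taxa=taxa, pathways=paths,
        qc_reports=reports, cluster_models=models, associations=assoc,
        meta=pooled, significant=gated, descriptives=desc,
        cohort_data=feature_cohorts, sensitivity=sensitivity)
    result.manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _asdict(config),
        "config_hash": config_hash(config),
        "stages": stages_done,
        "row_counts": {
            "subjects_in": int(len(ds.metadata)),
            "subjects_retained": int(len(retained)),
            "taxa_retained": int(taxa.n_features),
            "pathways_retained": int(paths.n_features),
            "food_clusters": int(models["food"].n_clusters),
            "species_clusters": int(models["species"].n_clusters),
            "pathway_clusters": int(models["pathway"].n_clusters),
            "associations": int(len(assoc)),
            "associations_usable": int(assoc["usable"].sum()),
            "meta_rows": int(len(pooled)),
            "meta_significant": int(len(gated)),
            "descriptive_rows": int(len(desc)),
        },
        "cluster_cut_heights": {n: models[n].cut_height for n in models},
        "linkage": config.linkage,
    }
    if outdir is not None:
        _write_outputs(result, pathlib.Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: pathlib.Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    def save(df: pd.DataFrame, name: str, index=False):
        path = outdir / name
        df.to_csv(path, sep="\t", index=index, float_format=_TSV_FLOAT)
        written[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    save(result.associations, "associations.tsv")
    save(result.meta, "meta.tsv")
    save(result.significant, "meta_significant.tsv")
    save(result.descriptives, "descriptives.tsv")
    for kind, report in result.qc_reports.items():
        save(report.to_frame(), f"qc_report_{kind}.tsv")
    for name, model in result.cluster_models.items():
        save(model.memberships.rename("cluster").rename_axis("variable")
             .reset_index(), f"clusters_{name}.tsv")
        (outdir / f"dendrogram_{name}.nwk").write_text(
            cluster.to_newick(model) + "\n")
        written[f"dendrogram_{name}.nwk"] = hashlib.sha256(
            (outdir / f"dendrogram_{name}.nwk").read_bytes()).hexdigest()
    if result.sensitivity is not None:
        save(result.sensitivity, "sensitivity_refit.tsv")
    result.manifest["outputs"] = written
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str)
        + "\n")


def report(result: PipelineResult) -> dict:
    """Summary counts of the gated meta-analysis (tabular analogue of
    the headline association counting)."""
    return report_tables(result.meta, result.significant)


def report_tables(meta: pd.DataFrame, gated: pd.DataFrame) -> dict:
    by_kind = gated.groupby("response_kind").size().to_dict() if len(gated) \
        else {}
    consistent = (float(gated["direction_consistent"].mean())
                  if len(gated) else float("nan"))
    top = {}
    if len(gated):
        top = gated.groupby("exposure").size().sort_values(
            ascending=False).head(10).to_dict()
    return {
        "n_meta_tested": int(len(meta)),
        "n_significant": int(len(gated)),
        "n_unique_exposures": int(gated["exposure"].nunique()) if len(gated)
        else 0,
        "n_unique_responses": int(gated["response"].nunique()) if len(gated)
        else 0,
        "significant_by_kind": {str(k): int(v) for k, v in by_kind.items()},
        "direction_consistent_fraction": consistent,
        "top_exposures": {str(k): int(v) for k, v in top.items()},
    }


def confusion_against_truth(result: PipelineResult,
                            kinds=("taxa", "pathway")) -> dict:
    """Truth-vs-detected confusion matrix for planted food effects.

    A planted (food, feature) pair counts as detected when it appears in
    the gated significant set with the same sign as the planted effect
    (using the HC multiplier's sign).
    """
    truth = result.dataset.truth
    planted = truth.loc[truth["feature_kind"].isin(kinds)]
    gated = result.significant
    gated_pairs = {(r["exposure"], r["response"]): r["beta_meta"]
                   for _, r in gated.iterrows()}
    tp = fn = 0
    detected_flags = []
    for _, row in planted.iterrows():
        key = (row["exposure_name"], row["feature_name"])
        expected_sign = np.sign(row["beta"] * row["mult_HC"])
        hit = key in gated_pairs and np.sign(gated_pairs[key]) == expected_sign
        detected_flags.append(bool(hit))
        tp += hit
        fn += not hit
    planted_keys = set(zip(planted["exposure_name"], planted["feature_name"]))
    fp = sum(1 for k in gated_pairs
             if k not in planted_keys
             and gated.loc[(gated["exposure"] == k[0])
                           & (gated["response"] == k[1]),
                           "response_kind"].isin(kinds).any())
    n_tested = int(result.meta["response_kind"].isin(kinds).sum())
    tn = n_tested - tp - fn - fp
    sensitivity = tp / max(tp + fn, 1)
    return {"tp": int(tp), "fn": int(fn), "fp": int(fp), "tn": int(tn),
            "sensitivity": float(sensitivity),
            "detected": detected_flags}
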