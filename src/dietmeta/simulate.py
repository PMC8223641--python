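"""Seeded multi-cohort synthetic datasets with known planted effects.

Emulates the statistical structure the analysis assumes: four cohorts
of unequal size (HC, IBS, CD, UC); zero-inflated log-normal food
intakes with block-wise correlation (the blocks are the ground-truth
"dietary patterns"); compositional taxa abundances via a
logistic-normal model; log-normal pathway abundances; read depths
log-normal around 2e7 with roughly a tenth of samples below the
10-million-read filter; age/sex/depth covariate confounding; and
inflammation markers (Fcal, CgA) log-linearly tied to designated food
blocks.

Planted diet effects are defined on the *post-transform* scale
(arcsine-sqrt for taxa, log for pathways) against the within-cohort
z-scored energy-adjusted intake, so the generating coefficient is
directly comparable to what the association stage estimates. For
pathways this is exact; for taxa the bounded arcsine-sqrt range forces
clipping and row renormalisation, which attenuates large planted
effects (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import COHORTS, qc

_COHORT_AGE_MEAN = {"HC": 45.5, "IBS": 41.4, "CD": 40.6, "UC": 46.6}
_COHORT_MALE_P = {"HC": 0.48, "IBS": 0.17, "CD": 0.33, "UC": 0.48}
_COHORT_SMOKE_P = {"HC": 0.18, "IBS": 0.24, "CD": 0.28, "UC": 0.12}
_COHORT_STATIN_P = {"HC": 0.045, "IBS": 0.054, "CD": 0.039, "UC": 0.113}

#: Read-depth log-normal: median 2e7, sigma such that ~10% fall below 1e7.
_DEPTH_MEDIAN = 2e7
_DEPTH_SIGMA = math.log(2.0) / 1.2816

METADATA_COLUMNS = ["cohort", "age", "sex", "bmi", "smoking",
                    "antihypertensives", "antidiabetics", "statins",
                    "read_depth", "kcal", "fcal", "cga"]


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class PlantedEffect:
    """A linear diet effect on one feature's transformed abundance.

    ``beta`` multiplies the within-cohort z-score of the food's
    energy-adjusted intake (g/1000 kcal); ``multipliers`` scale it per
    cohort in HC, IBS, CD, UC order, so (1, 1, -1, 1) plants a
    sign-flipped, heterogeneous effect.
    """

    food: int
    feature: int
    kind: str = "pathway"
    beta: float = 0.5
    multipliers: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs, in one seeded, hashable bundle."""

    n_per_cohort: tuple[int, int, int, int] = (872, 223, 205, 124)  # HC,IBS,CD,UC
    n_foods: int = 40
    n_food_blocks: int = 8
    block_corr: float = 0.6
    zero_inflation: float = 0.3
    n_taxa: int = 80
    n_pathways: int = 120
    planted_effects: tuple[PlantedEffect, ...] = ()
    covariate_effects: dict = field(default_factory=lambda: {
        "age": 0.10, "sex": 0.05, "log_depth": 0.10, "kcal": 0.0})
    marker_effects: tuple = (("fcal", 0, 0.4), ("cga", 1, 0.3))
    noise_sd: float = 1.0
    taxa_dispersion: float = 1.0
    taxa_detection_limit: float = 1e-5
    # occasional near-detection-limit pathway measurements (strong low
    # outliers on the log scale, as in real HUMAnN tables); they also
    # keep the log-transform pseudocount far below typical abundances.
    pathway_low_rate: float = 0.005
    pathway_low_factor: float = 0.01
    min_depth: float = qc.MIN_DEPTH_READS
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_cohort) != len(COHORTS):
            raise SimulationError("n_per_cohort needs one size per cohort")
        for n in (*self.n_per_cohort, self.n_foods, self.n_food_blocks,
                  self.n_taxa, self.n_pathways):
            if int(n) < 1:
                raise SimulationError("all counts must be >= 1")
        if not 0.0 <= self.block_corr < 1.0:
            raise SimulationError("block_corr must lie in [0, 1)")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise SimulationError("zero_inflation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")
        if self.n_food_blocks > self.n_foods:
            raise SimulationError("more food blocks than foods")

    def validate_effects(self) -> None:
        limits = {"taxa": self.n_taxa, "pathway": self.n_pathways}
        for eff in self.planted_effects:
            if eff.kind not in limits:
                raise SimulationError(f"unknown feature kind {eff.kind!r}")
            if not 0 <= eff.food < self.n_foods:
                raise SimulationError(f"planted food index {eff.food} out of "
                                      f"range [0, {self.n_foods})")
            if not 0 <= eff.feature < limits[eff.kind]:
                raise SimulationError(
                    f"planted {eff.kind} index {eff.feature} out of range "
                    f"[0, {limits[eff.kind]})")
        for marker, block, _ in self.marker_effects:
            if marker not in ("fcal", "cga"):
                raise SimulationError(f"unknown marker {marker!r}")
            if not 0 <= block < self.n_food_blocks:
                raise SimulationError(f"marker block {block} out of range")


@dataclass
class SyntheticDataset:
    """A simulated multi-cohort study with its ground truth."""

    metadata: pd.DataFrame   # subjects x METADATA_COLUMNS
    intake: pd.DataFrame     # subjects x foods, g/day
    taxa: pd.DataFrame       # subjects x taxa, proportions (rows sum to 1)
    pathways: pd.DataFrame   # subjects x pathways, non-negative abundances
    truth: pd.DataFrame      # planted-effect table
    config: SimulationConfig | None = None

    @property
    def food_blocks(self) -> pd.Series:
        """Ground-truth block id per food, recovered from the food names."""
        return pd.Series(
            {f: int(f.rsplit("_b", 1)[1]) for f in self.intake.columns},
            name="block").loc[self.intake.columns]

    def validate(self) -> None:
        sums = self.taxa.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise SimulationError("taxa rows must sum to 1 +- 1e-9")
        if (self.intake.to_numpy() < 0).any():
            raise SimulationError("intakes must be non-negative")
        if not set(self.metadata["cohort"]).issubset(COHORTS):
            raise SimulationError("cohort labels outside the defined set")


def _food_name(i: int, block: int) -> str:
    return f"food{i:03d}_b{block:02d}"


def _taxon_name(j: int) -> str:
    return ("k__Bacteria|p__SimPhylum|c__SimClass|o__SimOrder"
            f"|f__SimFamily_{j // 10:02d}|g__SimGenus_{j // 5:02d}"
            f"|s__Sim_species_{j:03d}")


def _pathway_name(j: int) -> str:
    return f"PWY-{4000 + j}"


def _cohort_zscore(values: np.ndarray, cohort: np.ndarray,
                   include: np.ndarray) -> np.ndarray:
    """z-score within cohort, moments taken over ``include`` members."""
    out = np.zeros_like(values, dtype=float)
    for c in COHORTS:
        members = cohort == c
        pop = members & include
        ref = values[pop if pop.sum() >= 2 else members]
        sd = ref.std(ddof=1)
        out[members] = (values[members] - ref.mean()) / (sd if sd > 0 else 1.0)
    return out


def simulate_cohorts(config: SimulationConfig) -> SyntheticDataset:
    """Generate one seeded multi-cohort dataset (deterministic per config)."""
    config.validate_effects()
    rng = np.random.default_rng(config.seed)
    n_cohort = dict(zip(COHORTS, config.n_per_cohort))
    n = sum(config.n_per_cohort)
    cohort = np.repeat(list(COHORTS), list(config.n_per_cohort))
    subjects = pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id")

    # --- metadata -----------------------------------------------------
    age = np.clip(rng.normal([_COHORT_AGE_MEAN[c] for c in cohort], 13.5),
                  18, 90)
    sex = (rng.random(n) < [_COHORT_MALE_P[c] for c in cohort]).astype(int)
    bmi = np.clip(rng.normal(25.3, 4.3, n), 15, 50)
    smoking = (rng.random(n) < [_COHORT_SMOKE_P[c] for c in cohort]).astype(int)
    antihypertensives = (rng.random(n) < 0.08).astype(int)
    antidiabetics = (rng.random(n) < 0.02).astype(int)
    statins = (rng.random(n) < [_COHORT_STATIN_P[c] for c in cohort]).astype(int)
    depth = np.exp(rng.normal(math.log(_DEPTH_MEDIAN), _DEPTH_SIGMA, n))

    # --- foods: zero-inflated log-normal with block correlation ------
    blocks = np.array([i * config.n_food_blocks // config.n_foods
                       for i in range(config.n_foods)])
    mu_food = rng.uniform(2.5, 3.5, config.n_foods)
    factors = rng.standard_normal((n, config.n_food_blocks))
    eps = rng.standard_normal((n, config.n_foods))
    rho = config.block_corr
    latent = (math.sqrt(rho) * factors[:, blocks]
              + math.sqrt(1.0 - rho) * eps)
    present = rng.random((n, config.n_foods)) >= config.zero_inflation
    intake = present * np.exp(mu_food + 0.8 * latent)

    total = intake.sum(axis=1)
    kcal = np.clip(1200.0 + 700.0 * total / total.mean()
                   + rng.normal(0.0, 200.0, n), 500.0, None)

    # --- planted exposures on the scale the models will see -----------
    deep_enough = depth >= config.min_depth
    density = 1000.0 * intake / kcal[:, None]
    x_std = np.column_stack([
        _cohort_zscore(density[:, i], cohort, deep_enough)
        for i in range(config.n_foods)])
    mult_of = {eff: dict(zip(COHORTS, eff.multipliers))
               for eff in config.planted_effects}

    def planted_shift(kind: str, n_features: int) -> np.ndarray:
        shift = np.zeros((n, n_features))
        for eff in config.planted_effects:
            if eff.kind != kind:
                continue
            scale = np.array([mult_of[eff][c] for c in cohort]) * eff.beta
            shift[:, eff.feature] += scale * x_std[:, eff.food]
        return shift

    # --- covariate confounding ----------------------------------------
    cov_names = ["age", "sex", "log_depth", "kcal"]
    cov_raw = np.column_stack([age, sex, np.log10(depth), kcal])
    cov_z = (cov_raw - cov_raw.mean(axis=0)) / cov_raw.std(axis=0, ddof=1)
    cov_coef = np.array([config.covariate_effects.get(k, 0.0)
                         for k in cov_names])

    def covariate_shift(n_features: int) -> np.ndarray:
        loadings = rng.standard_normal((len(cov_names), n_features))
        return cov_z @ (loadings * cov_coef[:, None])

    # --- taxa: logistic-normal composition ----------------------------
    m_taxa = rng.normal(0.0, 1.2, config.n_taxa)
    taxa_cov = covariate_shift(config.n_taxa)
    eta = (m_taxa + taxa_cov
           + rng.normal(0.0, config.taxa_dispersion, (n, config.n_taxa)))
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    p[p < config.taxa_detection_limit] = 0.0
    p /= p.sum(axis=1, keepdims=True)
    taxa_shift = planted_shift("taxa", config.n_taxa)
    if taxa_shift.any():
        y = np.arcsin(np.sqrt(p)) + taxa_shift
        p = np.sin(np.clip(y, 0.0, math.pi / 2.0 - 1e-9)) ** 2
        p /= p.sum(axis=1, keepdims=True)

    # --- pathways: log-normal abundances ------------------------------
    mu_path = rng.normal(5.0, 1.0, config.n_pathways)
    path_cov = covariate_shift(config.n_pathways)
    log_v = (mu_path + path_cov + planted_shift("pathway", config.n_pathways)
             + rng.normal(0.0, config.noise_sd, (n, config.n_pathways)))
    pathways = np.exp(log_v)
    low = rng.random((n, config.n_pathways)) < config.pathway_low_rate
    pathways = np.where(low, pathways * config.pathway_low_factor, pathways)

    # --- inflammation markers tied to food-block means ----------------
    block_beta = {"fcal": np.zeros(config.n_food_blocks),
                  "cga": np.zeros(config.n_food_blocks)}
    for marker, block, beta in config.marker_effects:
        block_beta[marker][block] += beta
    block_centroid_z = np.column_stack([
        _cohort_zscore(intake[:, blocks == b].mean(axis=1), cohort,
                       deep_enough)
        for b in range(config.n_food_blocks)])
    marker_cov = cov_z @ cov_coef  # scalar confounding per subject
    log_fcal = (math.log(60.0) + block_centroid_z @ block_beta["fcal"]
                + marker_cov + rng.normal(0.0, 0.8, n))
    log_cga = (math.log(30.0) + block_centroid_z @ block_beta["cga"]
               + marker_cov + rng.normal(0.0, 0.8, n))

    # --- assemble ------------------------------------------------------
    food_names = [_food_name(i, b) for i, b in enumerate(blocks)]
    taxa_names = [_taxon_name(j) for j in range(config.n_taxa)]
    path_names = [_pathway_name(j) for j in range(config.n_pathways)]
    metadata = pd.DataFrame({
        "cohort": cohort, "age": age, "sex": sex, "bmi": bmi,
        "smoking": smoking, "antihypertensives": antihypertensives,
        "antidiabetics": antidiabetics, "statins": statins,
        "read_depth": depth, "kcal": kcal,
        "fcal": np.exp(log_fcal), "cga": np.exp(log_cga),
    }, index=subjects)

    truth_rows = []
    for eff in config.planted_effects:
        name = (taxa_names[eff.feature] if eff.kind == "taxa"
                else path_names[eff.feature])
        truth_rows.append({
            "exposure_kind": "food", "exposure_index": eff.food,
            "exposure_name": food_names[eff.food],
            "feature_kind": eff.kind, "feature_index": eff.feature,
            "feature_name": name, "beta": eff.beta,
            **{f"mult_{c}": m for c, m in zip(COHORTS, eff.multipliers)}})
    for marker, block, beta in config.marker_effects:
        truth_rows.append({
            "exposure_kind": "block", "exposure_index": block,
            "exposure_name": f"block{block:02d}",
            "feature_kind": marker, "feature_index": 0,
            "feature_name": marker, "beta": beta,
            **{f"mult_{c}": 1.0 for c in COHORTS}})
    truth_cols = ["exposure_kind", "exposure_index", "exposure_name",
                  "feature_kind", "feature_index", "feature_name", "beta",
                  *(f"mult_{c}" for c in COHORTS)]
    truth = pd.DataFrame(truth_rows, columns=truth_cols)

    dataset = SyntheticDataset(
        metadata=metadata,
        intake=pd.DataFrame(intake, index=subjects, columns=food_names),
        taxa=pd.DataFrame(p, index=subjects, columns=taxa_names),
        pathways=pd.DataFrame(pathways, index=subjects, columns=path_names),
        truth=truth, config=config)
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# on-disk dialects

FILES = {"metadata": "metadata.tsv", "intake": "intake.tsv",
         "taxa": "taxa_metaphlan.tsv", "pathways": "pathways_humann.tsv",
         "truth": "truth.tsv"}
_FLOAT_FMT = "%.17g"


def write_dataset(dataset: SyntheticDataset, directory) -> dict:
    """Write the five study tables in their external dialects.

    Taxa go out MetaPhlAn-style (clades x samples, percent 0-100);
    pathways HUMAnN-style (pathways x samples); metadata, intake and
    truth as plain TSVs. Values are written at full double precision so
    the module readers round-trip them bit-for-bit.
    """
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FILES.items()}
    try:
        dataset.metadata.to_csv(paths["metadata"], sep="\t",
                                float_format=_FLOAT_FMT)
        dataset.intake.to_csv(paths["intake"], sep="\t",
                              float_format=_FLOAT_FMT)
        taxa_pct = (dataset.taxa * 100.0).T
        taxa_pct.index.name = "clade_name"
        taxa_pct.to_csv(paths["taxa"], sep="\t", float_format=_FLOAT_FMT)
        pw = dataset.pathways.T
        pw.index.name = "# Pathway"
        pw.to_csv(paths["pathways"], sep="\t", float_format=_FLOAT_FMT)
        dataset.truth.to_csv(paths["truth"], sep="\t", index=False,
                             float_format=_FLOAT_FMT)
    except OSError as exc:
        raise SimulationError(f"failed writing {exc.filename}: {exc}") from exc
    return paths


def read_dataset(directory) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset` back into memory."""
    import pathlib

    directory = pathlib.Path(directory)
    paths = {k: directory / v for k, v in FILES.items()}
    metadata = pd.read_csv(paths["metadata"], sep="\t", index_col=0)
    intake = pd.read_csv(paths["intake"], sep="\t", index_col=0)
    taxa = qc.read_metaphlan(paths["taxa"], rank="species").values
    pathways = qc.read_humann(paths["pathways"]).values
    truth = pd.read_csv(paths["truth"], sep="\t")
    return SyntheticDataset(metadata=metadata, intake=intake,
                            taxa=taxa.loc[metadata.index],
                            pathways=pathways.loc[metadata.index],
                            truth=truth)


def null_config(**overrides) -> SimulationConfig:
    """A convenience config with no planted diet or marker effects."""
    defaults = dict(planted_effects=(), marker_effects=())
    defaults.update(overrides)
    return SimulationConfig(**defaults)
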