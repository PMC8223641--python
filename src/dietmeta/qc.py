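"""Microbiome abundance tables: readers, filters, transforms, outliers.

Consumes merged MetaPhlAn-style taxonomic tables (clade x sample,
percent) and HUMAnN-style pathway tables (pathway x sample), applies
the sample depth filter (default < 10 million reads removed), the
feature prevalence/abundance filters (default present in < 10% of
samples removed; taxa with mean relative abundance < 0.01% removed),
variance-stabilising transforms (arcsine square root for proportions,
log with a per-feature half-minimum pseudocount for pathways), and an
iterative two-sided Grubbs outlier mask per feature.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

MIN_DEPTH_READS = 1e7
MIN_PREVALENCE = 0.10
MIN_MEAN_ABUNDANCE = 1e-4  # 0.01% relative abundance, taxa only

_CLADE_RE = re.compile(r"^[kpcofgst]__[^|]*(\|[kpcofgst]__[^|]*)*$")
_RANK_PREFIX = {"kingdom": "k", "phylum": "p", "class": "c", "order": "o",
                "family": "f", "genus": "g", "species": "s", "strain": "t"}
_RANK_ORDER = "kpcofgst"


class QCError(ValueError):
    """Raised for malformed abundance tables or invalid QC inputs."""


@dataclass
class AbundanceTable:
    """Subjects x features abundance matrix with QC state.

    ``values`` holds proportions in [0, 1] for kind='taxa' and
    non-negative abundances for kind='pathway' (transformed scales after
    the corresponding transform). ``mask`` flags Grubbs-masked outlier
    cells (True = excluded from downstream models; the sample itself is
    retained).
    """

    values: pd.DataFrame
    kind: str
    depth: pd.Series | None = None
    mask: pd.DataFrame | None = None
    sample_filtered: bool = False
    feature_filtered: bool = False
    transformed: bool = False

    def __post_init__(self):
        if self.kind not in ("taxa", "pathway"):
            raise QCError(f"unknown feature kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def masked_values(self) -> pd.DataFrame:
        """Values with Grubbs-masked cells set to NaN."""
        if self.mask is None:
            return self.values
        return self.values.mask(self.mask)

    def with_depth(self, depth: pd.Series) -> "AbundanceTable":
        missing = self.values.index.difference(depth.index).tolist()
        if missing:
            raise QCError(f"read depth missing for subjects: {missing}")
        return replace(self, depth=depth.loc[self.values.index].astype(float))


@dataclass
class QCReport:
    """Bookkeeping of what each QC step removed."""

    n_samples_in: int = 0
    n_samples_removed_depth: int = 0
    removed_samples: list = field(default_factory=list)
    n_features_in: int = 0
    n_features_removed_prevalence: int = 0
    n_features_removed_abundance: int = 0
    removed_features: list = field(default_factory=list)
    n_cells_masked: int = 0

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.n_samples_removed_depth

    @property
    def n_features_out(self) -> int:
        return (self.n_features_in - self.n_features_removed_prevalence
                - self.n_features_removed_abundance)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("samples_in", self.n_samples_in),
            ("samples_removed_depth", self.n_samples_removed_depth),
            ("samples_out", self.n_samples_out),
            ("features_in", self.n_features_in),
            ("features_removed_prevalence", self.n_features_removed_prevalence),
            ("features_removed_abundance", self.n_features_removed_abundance),
            ("features_out", self.n_features_out),
            ("cells_masked_outlier", self.n_cells_masked),
        ]
        return pd.DataFrame(rows, columns=["quantity", "count"])


def _clade_rank(clade: str) -> str:
    return clade.rsplit("|", 1)[-1][0]


def read_metaphlan(path, rank: str = "species") -> AbundanceTable:
    """Read a merged MetaPhlAn-style TSV into proportions at one rank.

    Rows are clades (``k__...|s__...``), columns are samples, values are
    percentages 0-100 which are divided by 100. Only rows whose deepest
    rank equals ``rank`` are kept (so species-level excludes strain
    ``t__`` rows).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise QCError(f"no sample columns in {path}")
    prefix = _RANK_PREFIX.get(rank)
    if prefix is None:
        raise QCError(f"unknown rank {rank!r}")
    keep = []
    for lineno, clade in enumerate(df.index, start=2):  # line 1 is the header
        if not _CLADE_RE.match(str(clade)):
            raise QCError(f"malformed clade string at line {lineno}: {clade!r}")
        if _clade_rank(clade) == prefix:
            keep.append(clade)
    values = df.loc[keep].T.astype(float) / 100.0
    values.index.name = "subject_id"
    if ((values < -1e-12) | (values > 1 + 1e-12)).any().any():
        raise QCError("taxa proportions outside [0, 1] after percent conversion")
    return AbundanceTable(values=values.clip(lower=0.0, upper=1.0), kind="taxa")


def read_humann(path, drop_unmapped: bool = True) -> AbundanceTable:
    """Read a merged HUMAnN-style pathway TSV (community-level rows).

    Taxon-stratified rows (id containing ``|``) are dropped; UNMAPPED
    and UNINTEGRATED rows are dropped unless ``drop_unmapped=False``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise QCError(f"empty pathway table: {path}")
    ids = df.index.astype(str)
    keep = ~ids.str.contains(r"\|", regex=True)
    if drop_unmapped:
        bases = ids.str.split(":").str[0].str.strip()
        keep &= ~bases.isin(["UNMAPPED", "UNINTEGRATED"])
    df = df.loc[keep]
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise QCError(f"duplicate pathway ids: {dup}")
    values = df.T.astype(float)
    values.index.name = "subject_id"
    if (values.to_numpy() < 0).any():
        raise QCError("negative pathway abundances")
    return AbundanceTable(values=values, kind="pathway")


def filter_samples(table: AbundanceTable,
                   min_depth: float = MIN_DEPTH_READS,
                   report: QCReport | None = None
                   ) -> tuple[AbundanceTable, QCReport]:
    """Remove samples with sequencing depth strictly below ``min_depth``.

    A sample at exactly the threshold is kept ("below" read as strict).
    """
    if table.depth is None:
        raise QCError("no read depth attached; call with_depth() first")
    report = report or QCReport(n_samples_in=table.n_samples,
                                n_features_in=table.n_features)
    keep = table.depth >= min_depth
    removed = table.depth.index[~keep].tolist()
    report.n_samples_removed_depth += len(removed)
    report.removed_samples += removed
    out = replace(table, values=table.values.loc[keep],
                  depth=table.depth.loc[keep], sample_filtered=True)
    return out, report


def filter_features(table: AbundanceTable,
                    min_prevalence: float = MIN_PREVALENCE,
                    min_mean_abundance: float = MIN_MEAN_ABUNDANCE,
                    report: QCReport | None = None
                    ) -> tuple[AbundanceTable, QCReport]:
    """Remove rare features.

    A feature goes if it is nonzero in fewer than ``min_prevalence`` of
    retained samples, or — for taxa only, whose values are relative
    abundances — if its mean relative abundance is below
    ``min_mean_abundance``.
    """
    report = report or QCReport(n_samples_in=table.n_samples,
                                n_features_in=table.n_features)
    vals = table.values
    prevalence = (vals > 0).mean(axis=0)
    low_prev = prevalence < min_prevalence
    if table.kind == "taxa":
        low_abund = (vals.mean(axis=0) < min_mean_abundance) & ~low_prev
    else:
        low_abund = pd.Series(False, index=vals.columns)
    report.n_features_removed_prevalence += int(low_prev.sum())
    report.n_features_removed_abundance += int(low_abund.sum())
    drop = low_prev | low_abund
    report.removed_features += vals.columns[drop].tolist()
    out = replace(table, values=vals.loc[:, ~drop], feature_filtered=True)
    return out, report


def transform_taxa(table: AbundanceTable) -> AbundanceTable:
    """Arcsine square-root transform: p -> asin(sqrt(p)), onto [0, pi/2]."""
    if table.kind != "taxa":
        raise QCError("arcsine-sqrt transform applies to taxa proportions")
    vals = table.values.to_numpy()
    if ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
        raise QCError("values outside [0, 1]; cannot arcsine-sqrt transform")
    out = np.arcsin(np.sqrt(np.clip(vals, 0.0, 1.0)))
    return replace(table, values=pd.DataFrame(out, index=table.values.index,
                                              columns=table.values.columns),
                   transformed=True)


def transform_pathways(table: AbundanceTable) -> AbundanceTable:
    """Log transform with per-feature pseudocount.

    value -> ln(value + delta_f) with delta_f half the smallest nonzero
    value of the feature, keeping the map strictly increasing and
    features on comparable scales.
    """
    if table.kind != "pathway":
        raise QCError("log transform applies to pathway abundances")
    vals = table.values
    if (vals.to_numpy() < 0).any():
        raise QCError("negative pathway abundances; cannot log transform")
    all_zero = (vals <= 0).all(axis=0)
    if all_zero.any():
        raise QCError("all-zero features (no pseudocount definable): "
                      f"{vals.columns[all_zero].tolist()}")
    arr = vals.to_numpy(copy=True)
    with np.errstate(invalid="ignore"):
        delta = np.nanmin(np.where(arr > 0, arr, np.nan), axis=0) / 2.0
    out = np.log(arr + delta)
    return replace(table, values=pd.DataFrame(out, index=vals.index,
                                              columns=vals.columns),
                   transformed=True)


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t-distribution closed form."""
    if n < 3:
        return math.inf
    t = stats.t.ppf(alpha / (2.0 * n), n - 2)
    t2 = t * t
    return (n - 1) / math.sqrt(n) * math.sqrt(t2 / (n - 2 + t2))


def grubbs_mask(values, alpha: float = 0.05, max_iter: int = 5) -> np.ndarray:
    """Iterative two-sided Grubbs outlier test on one feature vector.

    Returns a boolean array flagging masked points (True = outlier).
    NaNs are ignored. With fewer than 3 non-missing values, or zero
    variance, nothing is masked.
    """
    x = np.asarray(values, dtype=float)
    mask = np.zeros(x.shape, dtype=bool)
    active = ~np.isnan(x)
    for _ in range(max_iter):
        idx = np.flatnonzero(active & ~mask)
        n = idx.size
        if n < 3:
            break
        xs = x[idx]
        mean = xs.mean()
        sd = xs.std(ddof=1)
        if sd <= 0:
            break
        dev = np.abs(xs - mean)
        imax = int(np.argmax(dev))
        g = dev[imax] / sd
        if g <= grubbs_critical(n, alpha):
            break
        mask[idx[imax]] = True
    return mask


def mask_outliers(table: AbundanceTable, alpha: float = 0.05,
                  max_iter: int = 5,
                  report: QCReport | None = None
                  ) -> tuple[AbundanceTable, QCReport]:
    """Apply the Grubbs mask per feature column of a transformed table."""
    report = report or QCReport(n_samples_in=table.n_samples,
                                n_features_in=table.n_features)
    arr = table.values.to_numpy()
    mask = np.zeros(arr.shape, dtype=bool)
    for j in range(arr.shape[1]):
        mask[:, j] = grubbs_mask(arr[:, j], alpha=alpha, max_iter=max_iter)
    report.n_cells_masked += int(mask.sum())
    mask_df = pd.DataFrame(mask, index=table.values.index,
                           columns=table.values.columns)
    return replace(table, mask=mask_df), report
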