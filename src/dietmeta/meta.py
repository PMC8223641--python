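"""Fixed-effect inverse-variance meta-analysis with heterogeneity gating.

Per-cohort coefficients are pooled with weights 1/SE^2, giving a
combined effect, z-score and p-value; Cochran's Q tests between-cohort
heterogeneity. p-values are Benjamini-Hochberg adjusted within a
family (by default one exposure x one response kind), and the dual
significance gate retains associations with FDR < 0.05 *and*
heterogeneity p > 0.05 — i.e. signals that are strong and consistent
across cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_MAX = 0.05
QP_MIN = 0.05

META_COLUMNS = ["exposure", "response", "response_kind", "k",
                "beta_meta", "se_meta", "z", "p_meta", "fdr",
                "Q", "q_df", "p_q", "direction_consistent"]


class MetaError(ValueError):
    """Raised for invalid meta-analysis inputs."""


def inverse_variance_pool(betas, ses):
    """Fixed-effect pooling with weights 1/SE^2.

    Returns (beta_meta, se_meta, z, p_meta) with the two-sided normal
    tail p-value.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1 or betas.size < 1:
        raise MetaError("betas and SEs must be equal-length 1-D, k >= 1")
    if (ses <= 0).any() or np.isnan(ses).any():
        raise MetaError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta_meta = float(np.sum(w * betas) / np.sum(w))
    se_meta = float(1.0 / np.sqrt(np.sum(w)))
    z = beta_meta / se_meta
    p = 2.0 * stats.norm.sf(abs(z))
    return beta_meta, se_meta, float(z), float(p)


def cochran_q(betas, ses, beta_meta: float):
    """Cochran's Q heterogeneity test against the pooled effect.

    Q = sum w_i (beta_i - beta_meta)^2 with w_i = 1/SE_i^2, chi-square
    with k - 1 df under homogeneity. Requires k >= 2.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 2:
        raise MetaError("Cochran's Q requires at least 2 cohorts")
    if (ses <= 0).any():
        raise MetaError("all standard errors must be positive")
    w = 1.0 / ses**2
    q = float(np.sum(w * (betas - beta_meta) ** 2))
    df = betas.size - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one family."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise MetaError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def direction_consistency(betas) -> bool:
    """True iff every per-cohort beta has the same strict sign.

    Any zero coefficient counts as inconsistent (no direction).
    """
    betas = np.asarray(betas, dtype=float)
    if betas.size < 2:
        raise MetaError("direction consistency needs at least 2 cohorts")
    return bool((betas > 0).all() or (betas < 0).all())


def significance_gate(meta: pd.DataFrame, fdr_max: float = FDR_MAX,
                      qp_min: float = QP_MIN) -> pd.DataFrame:
    """Dual gate: FDR strictly below ``fdr_max`` and heterogeneity p
    strictly above ``qp_min`` (homogeneous, consistent associations)."""
    keep = (meta["fdr"] < fdr_max) & (meta["p_q"] > qp_min)
    return meta.loc[keep].reset_index(drop=True)


def meta_analyze(associations: pd.DataFrame,
                 family: str = "per_exposure_kind",
                 min_k: int = 1) -> pd.DataFrame:
    """Pool a per-cohort association table across cohorts.

    Unusable per-cohort fits are dropped from their pair's pooling (the
    number pooled is recorded as k). FDR families: 'per_exposure_kind'
    (one exposure x all responses of one kind, the default), 'global'
    or 'refit' (a single family over the whole table).

    Per-cohort betas are carried through as beta_<cohort> columns.
    """
    usable = associations.loc[associations["usable"].astype(bool)]
    rows = []
    cohorts = sorted(associations["cohort"].unique()) if len(associations) else []
    for (exposure, response, kind), grp in usable.groupby(
            ["exposure", "response", "response_kind"], sort=True):
        betas = grp["beta"].to_numpy(dtype=float)
        ses = grp["se"].to_numpy(dtype=float)
        k = len(grp)
        if k < min_k:
            continue
        beta_meta, se_meta, z, p = inverse_variance_pool(betas, ses)
        if k >= 2:
            q, q_df, p_q = cochran_q(betas, ses, beta_meta)
            consistent = direction_consistency(betas)
        else:
            q, q_df, p_q, consistent = np.nan, 0, np.nan, False
        row = {"exposure": exposure, "response": response,
               "response_kind": kind, "k": k, "beta_meta": beta_meta,
               "se_meta": se_meta, "z": z, "p_meta": p, "fdr": np.nan,
               "Q": q, "q_df": q_df, "p_q": p_q,
               "direction_consistent": consistent}
        per_cohort = dict(zip(grp["cohort"], betas))
        for c in cohorts:
            row[f"beta_{c}"] = per_cohort.get(c, np.nan)
        rows.append(row)
    cols = META_COLUMNS + [f"beta_{c}" for c in cohorts]
    meta = pd.DataFrame(rows, columns=cols)
    if meta.empty:
        return meta
    if family in ("global", "refit"):
        meta["fdr"] = bh_adjust(meta["p_meta"].to_numpy())
    elif family == "per_exposure_kind":
        for _, idx in meta.groupby(["exposure", "response_kind"]).groups.items():
            meta.loc[idx, "fdr"] = bh_adjust(meta.loc[idx, "p_meta"].to_numpy())
    else:
        raise MetaError(f"unknown FDR family scheme {family!r}")
    return meta
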