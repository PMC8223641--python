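"""Per-cohort multivariate linear models.

Three model families, fitted separately within each cohort:

* microbial feature (arcsine-sqrt taxon / log pathway) ~ intercept +
  food or nutrient (energy-adjusted) + age + sex + log10 read depth
* microbial cluster centroid ~ intercept + food-cluster centroid +
  age + sex + log10 read depth + total kcal
* inflammation marker (log Fcal / log CgA) ~ intercept + food-cluster
  centroid + age + sex + log10 read depth + total kcal

Exposures are z-scored within each cohort by default so coefficients
are per standard deviation of intake and comparable across foods.
Fits are complete-case: outlier-masked feature values enter as NaN and
are dropped row-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_COMPLETE_CASES = 20

ASSOCIATION_COLUMNS = ["cohort", "exposure", "response", "response_kind",
                       "n", "df", "beta", "se", "t", "p", "usable", "reason"]


class AssociationError(ValueError):
    """Raised for invalid designs or inputs to the linear models."""


class RankDeficientError(AssociationError):
    """Raised when the design matrix is not full rank."""


@dataclass
class OLSFit:
    """Least-squares fit summary (all coefficients, not just the exposure)."""

    names: list
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    n: int
    rss: float

    def coef(self, name) -> dict:
        i = self.names.index(name)
        return {"beta": float(self.beta[i]), "se": float(self.se[i]),
                "t": float(self.t[i]), "p": float(self.p[i])}


def fit_ols(y, X, names=None) -> OLSFit:
    """Ordinary least squares with classical standard errors.

    ``X`` must include the intercept column. SEs come from
    sigma^2 (X'X)^-1 with sigma^2 = RSS / (n - k); two-sided p-values
    from the t distribution with n - k degrees of freedom.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise AssociationError("design must be 2-D")
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if y.shape != (n,):
        raise AssociationError(f"response length {y.shape} != design rows {n}")
    if n <= k:
        raise AssociationError(f"n = {n} <= number of parameters k = {k}")
    # Rank check via the QR diagonal so offending columns can be named.
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if (diag <= tol).any():
        bad = [names[i] for i in np.flatnonzero(diag <= tol)]
        raise RankDeficientError(
            f"design is rank deficient; collinear columns around: {bad}")
    beta = np.linalg.solve(r.T @ r, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(r.T @ r)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return OLSFit(names=list(names), beta=beta, se=se, t=t, p=p,
                  df=df, n=n, rss=rss)


@dataclass
class CohortData:
    """One cohort's model inputs.

    features maps a response kind (taxa / pathway / species_cluster /
    pathway_cluster / fcal / cga) to a subjects x responses frame on the
    modelling scale, with masked cells as NaN.
    """

    cohort: str
    exposures: pd.DataFrame
    features: dict[str, pd.DataFrame]
    covariates: pd.DataFrame
    kcal: pd.Series | None = None

    def covariate_frame(self, names) -> pd.DataFrame:
        cols = {}
        for name in names:
            if name in self.covariates.columns:
                cols[name] = self.covariates[name]
            elif name == "kcal" and self.kcal is not None:
                cols[name] = self.kcal
            else:
                raise AssociationError(
                    f"covariate {name!r} not available in cohort {self.cohort}")
        return pd.DataFrame(cols, index=self.covariates.index)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd <= 0:
        raise AssociationError("constant exposure; cannot standardize")
    return (x - x.mean()) / sd


def associate(exposure: pd.Series, response: pd.Series,
              covariates: pd.DataFrame, cohort: str, response_kind: str,
              min_n: int = MIN_COMPLETE_CASES,
              standardize_exposure: bool = True) -> dict:
    """Fit one exposure-response model in one cohort.

    Returns a flat record (see ASSOCIATION_COLUMNS). Degenerate designs
    (constant exposure, rank deficiency, too few complete cases) yield
    an unusable record with a reason instead of raising.
    """
    frame = pd.DataFrame({"__y": response, "__x": exposure}).join(covariates)
    frame = frame.dropna()
    record = {"cohort": cohort, "exposure": exposure.name,
              "response": response.name, "response_kind": response_kind,
              "n": int(len(frame)), "df": np.nan, "beta": np.nan,
              "se": np.nan, "t": np.nan, "p": np.nan,
              "usable": False, "reason": ""}
    k = 2 + covariates.shape[1]
    if len(frame) < max(min_n, k + 1):
        record["reason"] = f"only {len(frame)} complete cases"
        return record
    x = frame["__x"].to_numpy()
    try:
        if standardize_exposure:
            x = _standardize(x)
        X = np.column_stack([np.ones(len(frame)), x,
                             frame[list(covariates.columns)].to_numpy()])
        fit = fit_ols(frame["__y"].to_numpy(), X,
                      names=["intercept", "exposure", *covariates.columns])
    except AssociationError as exc:
        record["reason"] = str(exc)
        return record
    record.update(fit.coef("exposure"))
    record["df"] = fit.df
    record["usable"] = True
    return record


def _fit_many(X: np.ndarray, Y: np.ndarray):
    """OLS of every column of Y on a shared full-rank design X.

    Returns (beta, se, t, p) for the exposure column (index 1 of X).
    """
    n, k = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta_all = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta_all
    rss = np.einsum("ij,ij->j", resid, resid)
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    beta = beta_all[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df


def associate_cohort(data: CohortData, response_kind: str,
                     covariate_names, exposures=None,
                     min_n: int = MIN_COMPLETE_CASES,
                     standardize_exposure: bool = True) -> pd.DataFrame:
    """All exposure x response fits of one kind within one cohort.

    Responses sharing the (per-exposure) complete-case rows are fitted
    in one batched solve; responses with masked cells fall back to an
    individual complete-case fit.
    """
    features = data.features[response_kind]
    covs = data.covariate_frame(covariate_names)
    exposure_names = list(data.exposures.columns if exposures is None
                          else exposures)
    rows = []
    base = covs.dropna()
    for exp_name in exposure_names:
        x_full = data.exposures[exp_name].reindex(base.index)
        valid = x_full.notna()
        idx = base.index[valid]
        x = x_full.loc[idx].to_numpy()
        covs_arr = base.loc[idx].to_numpy()
        n = len(idx)
        k = 2 + covs_arr.shape[1]
        feat = features.reindex(idx)

        def degenerate(reason, resp_names, n_used=n):
            for r in resp_names:
                rows.append({"cohort": data.cohort, "exposure": exp_name,
                             "response": r, "response_kind": response_kind,
                             "n": int(n_used), "df": np.nan, "beta": np.nan,
                             "se": np.nan, "t": np.nan, "p": np.nan,
                             "usable": False, "reason": reason})

        if n < max(min_n, k + 1):
            degenerate(f"only {n} complete cases", features.columns)
            continue
        sd = x.std(ddof=1)
        if sd <= 0:
            degenerate("constant exposure within cohort", features.columns)
            continue
        x_std = (x - x.mean()) / sd if standardize_exposure else x
        X = np.column_stack([np.ones(n), x_std, covs_arr])
        clean = feat.columns[feat.notna().all(axis=0)]
        dirty = feat.columns[feat.isna().any(axis=0)]
        if len(clean):
            beta, se, t, p, df = _fit_many(X, feat[clean].to_numpy())
            for j, r in enumerate(clean):
                rows.append({"cohort": data.cohort, "exposure": exp_name,
                             "response": r, "response_kind": response_kind,
                             "n": n, "df": df, "beta": beta[j], "se": se[j],
                             "t": t[j], "p": p[j], "usable": bool(se[j] > 0),
                             "reason": "" if se[j] > 0 else "zero residual"})
        for r in dirty:
            rows.append(associate(
                data.exposures[exp_name], features[r], covs,
                cohort=data.cohort, response_kind=response_kind,
                min_n=min_n, standardize_exposure=standardize_exposure))
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)


def associate_all(cohort_data: dict[str, CohortData],
                  model_plan: list[tuple[str, tuple[str, ...]]],
                  min_n: int = MIN_COMPLETE_CASES,
                  standardize_exposure: bool = True) -> pd.DataFrame:
    """Run every (response kind, covariate set) model in every cohort."""
    tables = []
    for data in cohort_data.values():
        for response_kind, covariate_names in model_plan:
            if response_kind not in data.features:
                continue
            tables.append(associate_cohort(
                data, response_kind, covariate_names,
                min_n=min_n, standardize_exposure=standardize_exposure))
    if not tables:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def sensitivity_refit(significant: pd.DataFrame,
                      cohort_data: dict[str, CohortData],
                      base_covariates: dict[str, tuple],
                      extra_covariates=("bmi", "smoking", "antihypertensives",
                                        "antidiabetics", "statins"),
                      fdr_max: float = 0.05,
                      min_n: int = MIN_COMPLETE_CASES,
                      standardize_exposure: bool = True) -> pd.DataFrame:
    """Re-fit previously significant pairs with extended covariates.

    Each pair is refitted in every cohort with the extra covariates
    appended, re-pooled, and BH-adjusted within the refit family. The
    returned table flags which pairs keep FDR < ``fdr_max`` with an
    unchanged pooled-effect sign; the replicated fraction is stored in
    ``result.attrs['replication_fraction']`` (NaN when the input set is
    empty).
    """
    from . import meta as meta_mod

    for data in cohort_data.values():
        missing = [c for c in extra_covariates
                   if c not in data.covariates.columns]
        if missing:
            raise AssociationError(
                f"cohort {data.cohort} lacks sensitivity covariates: {missing}")

    if significant.empty:
        out = pd.DataFrame(columns=["exposure", "response", "response_kind",
                                    "beta_meta_orig", "beta_meta", "p_meta",
                                    "fdr", "replicated"])
        out.attrs["replication_fraction"] = float("nan")
        return out

    rows = []
    for _, sig in significant.iterrows():
        kind = sig["response_kind"]
        covariate_names = tuple(base_covariates[kind]) + tuple(extra_covariates)
        for data in cohort_data.values():
            covs = data.covariate_frame(covariate_names)
            rows.append(associate(
                data.exposures[sig["exposure"]],
                data.features[kind][sig["response"]], covs,
                cohort=data.cohort, response_kind=kind, min_n=min_n,
                standardize_exposure=standardize_exposure))
    refit = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    pooled = meta_mod.meta_analyze(refit, family="refit")
    pooled = pooled.merge(
        significant[["exposure", "response", "response_kind", "beta_meta"]]
        .rename(columns={"beta_meta": "beta_meta_orig"}),
        on=["exposure", "response", "response_kind"], how="left")
    pooled["replicated"] = ((pooled["fdr"] < fdr_max)
                            & (np.sign(pooled["beta_meta"])
                               == np.sign(pooled["beta_meta_orig"])))
    pooled.attrs["replication_fraction"] = float(pooled["replicated"].mean())
    return pooled
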