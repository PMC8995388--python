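"""Twin-clustered association scans.

Each binary lifetime outcome is regressed on the combined polygenic score
with a logit-link marginal model fitted by generalized estimating
equations (independence working correlation) and a sandwich covariance
clustered on twin pair, so standard errors are valid under the
within-pair dependence the working model ignores. Effect sizes are
reported as odds ratios per SD of the score with Wald 95% intervals;
variance explained is the Nagelkerke pseudo-R^2 increment of the score
term computed from ordinary logistic likelihoods; multiplicity is handled
by Benjamini-Hochberg FDR within each scan family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import MEDIATORS, OUTCOMES, REGISTER_ONLY_OUTCOMES


class FitError(RuntimeError):
    """Model could not be fitted (separation, collinearity, no cases)."""


@dataclass
class GeeFit:
    """Cluster-robust logistic marginal-model fit."""

    coefficients: pd.Series
    robust_se: pd.Series
    or_ci: pd.DataFrame  # columns OR, ci_low, ci_high
    p: pd.Series
    n_used: int
    n_clusters: int


BASE_COVARIATES = ["birth_year", "sex_male", "PC1", "PC2", "PC3", "PC4",
                   "PC5", "PC6", "followup_years"]


def fit_gee_logistic(y: np.ndarray, X: pd.DataFrame, cluster: np.ndarray,
                     working: str = "independence",
                     label: str = "") -> GeeFit:
    """GEE logistic fit with sandwich covariance clustered on ``cluster``.

    ``X`` must not contain an intercept column; one is added. Failures
    (non-convergence, separation producing non-finite estimates, constant
    outcome) raise :class:`FitError` naming ``label``.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise FitError(f"{label or 'outcome'}: outcome is constant")
    cov = {"independence": sm.cov_struct.Independence,
           "exchangeable": sm.cov_struct.Exchangeable}[working]()
    Xc = sm.add_constant(X, has_constant="raise")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GEE(y, Xc, groups=np.asarray(cluster),
                         family=sm.families.Binomial(), cov_struct=cov).fit()
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise FitError(f"{label or 'outcome'}: GEE failed ({exc})") from exc
    params = pd.Series(res.params, index=Xc.columns)
    se = pd.Series(np.asarray(res.bse), index=Xc.columns)
    if not (np.isfinite(params).all() and np.isfinite(se).all() and (se > 0).all()):
        raise FitError(f"{label or 'outcome'}: non-finite estimates (separation?)")
    if np.abs(params.drop("const")).max() > 30:
        raise FitError(f"{label or 'outcome'}: implausible coefficients "
                       "(quasi-separation)")
    zcrit = stats.norm.ppf(0.975)
    or_ci = pd.DataFrame({
        "OR": np.exp(params),
        "ci_low": np.exp(params - zcrit * se),
        "ci_high": np.exp(params + zcrit * se),
    })
    pvals = pd.Series(
        np.clip(2 * stats.norm.sf(np.abs(params / se)), np.finfo(float).tiny, 1.0),
        index=Xc.columns)
    return GeeFit(coefficients=params, robust_se=se, or_ci=or_ci, p=pvals,
                  n_used=len(y), n_clusters=len(np.unique(cluster)))


def _logit_loglike(y: np.ndarray, X: np.ndarray) -> float:
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return float(res.llf)


def nagelkerke_delta_r2(y: np.ndarray, X_full: pd.DataFrame,
                        X_null: pd.DataFrame) -> float:
    """Nagelkerke pseudo-R^2 increment of the full over the null model, in
    percent. Likelihoods come from ordinary (independence) logistic fits;
    the intercept-only model anchors both Cox-Snell terms."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        raise FitError("empty outcome vector")
    ll0 = _logit_loglike(y, np.ones((n, 1)))
    denom = 1.0 - np.exp(2.0 * ll0 / n)

    def nagelkerke(X: pd.DataFrame) -> float:
        ll = _logit_loglike(y, sm.add_constant(X, has_constant="raise"))
        cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
        return cox_snell / denom

    return (nagelkerke(X_full) - nagelkerke(X_null)) * 100.0


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p <= 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _design(cohort: pd.DataFrame, pcprs: pd.Series, ancestry: pd.DataFrame,
            drop_sex: bool = False) -> pd.DataFrame:
    df = cohort.set_index("individual_id")
    X = pd.DataFrame(index=df.index)
    X["pc_prs"] = pcprs.reindex(df.index)
    X["birth_year"] = df["birth_year"].astype(float)
    if not drop_sex:
        X["sex_male"] = (df["sex"] == "male").astype(float)
    for c in ancestry.columns:
        X[c] = ancestry[c].reindex(df.index)
    X["followup_years"] = df["followup_years"].astype(float)
    if X.isna().any().any():
        raise FitError("design matrix contains missing values")
    return X


def _stratum_mask(cohort: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=cohort.index)
    return cohort["sex"] == stratum


def association_scan(cohort: pd.DataFrame, pcprs: pd.Series,
                     ancestry: pd.DataFrame,
                     outcomes: list[str] | None = None,
                     sources: tuple[str, ...] = ("combined", "register", "selfreport"),
                     strata: tuple[str, ...] = ("all", "male", "female"),
                     working: str = "independence") -> pd.DataFrame:
    """Per outcome x ascertainment source x sex stratum association table.

    FDR adjustment is applied separately within each (source, stratum)
    family across outcomes; rows whose fit failed (e.g. zero cases in a
    stratum) are emitted with ``failed=True`` and excluded from their FDR
    family.
    """
    outcomes = list(outcomes) if outcomes is not None else [
        k for k in OUTCOMES if f"{k}_combined" in cohort.columns]
    rows = []
    for stratum in strata:
        mask = _stratum_mask(cohort, stratum).to_numpy()
        sub = cohort.loc[mask]
        X = _design(sub, pcprs, ancestry, drop_sex=stratum != "all")
        X_null = X.drop(columns="pc_prs")
        for source in sources:
            for k in outcomes:
                col = f"{k}_{source}"
                row = {"outcome": k, "source": source, "stratum": stratum,
                       "OR": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                       "p_raw": np.nan, "p_adj": np.nan, "delta_r2": np.nan,
                       "n": len(sub), "n_cases": int(sub[col].sum()),
                       "failed": False}
                try:
                    fit = fit_gee_logistic(sub[col].to_numpy(), X,
                                           sub["family_id"].to_numpy(),
                                           working=working,
                                           label=f"{k}/{source}/{stratum}")
                    row.update(OR=fit.or_ci.loc["pc_prs", "OR"],
                               ci_low=fit.or_ci.loc["pc_prs", "ci_low"],
                               ci_high=fit.or_ci.loc["pc_prs", "ci_high"],
                               p_raw=fit.p["pc_prs"],
                               delta_r2=nagelkerke_delta_r2(
                                   sub[col].to_numpy(), X, X_null))
                except FitError:
                    row["failed"] = True
                rows.append(row)
    out = pd.DataFrame(rows)
    for (source, stratum), grp in out.groupby(["source", "stratum"]):
        ok = grp.index[~grp["failed"]]
        if len(ok):
            out.loc[ok, "p_adj"] = bh_fdr(out.loc[ok, "p_raw"])
    return out


def moderation_scan(cohort: pd.DataFrame, pcprs: pd.Series,
                    ancestry: pd.DataFrame,
                    outcomes: list[str] | None = None,
                    moderators: list[str] | None = None,
                    working: str = "independence") -> pd.DataFrame:
    """Score x risk-factor interaction tests on the combined outcomes.

    Each model adds the moderator main effect and the product term to the
    main association model; the product-term OR/CI/p is reported and
    BH-FDR is applied across the whole moderation family.
    """
    outcomes = list(outcomes) if outcomes is not None else [
        k for k in OUTCOMES if f"{k}_combined" in cohort.columns]
    moderators = list(moderators) if moderators is not None else list(MEDIATORS)
    X_base = _design(cohort, pcprs, ancestry)
    rows = []
    for m in moderators:
        mcol = m if MEDIATORS.get(m, "binary") == "binary" else "bmi"
        mvals = cohort.set_index("individual_id")[mcol].astype(float)
        for k in outcomes:
            row = {"outcome": k, "moderator": m, "OR": np.nan,
                   "ci_low": np.nan, "ci_high": np.nan,
                   "p_raw": np.nan, "p_adj": np.nan, "failed": False}
            if mvals.std(ddof=0) == 0:
                row["failed"] = True
                rows.append(row)
                continue
            X = X_base.copy()
            X[m] = mvals
            X[f"pc_prs_x_{m}"] = X["pc_prs"] * mvals
            try:
                fit = fit_gee_logistic(cohort[f"{k}_combined"].to_numpy(), X,
                                       cohort["family_id"].to_numpy(),
                                       working=working, label=f"{k}x{m}")
                term = f"pc_prs_x_{m}"
                row.update(OR=fit.or_ci.loc[term, "OR"],
                           ci_low=fit.or_ci.loc[term, "ci_low"],
                           ci_high=fit.or_ci.loc[term, "ci_high"],
                           p_raw=fit.p[term])
            except FitError:
                row["failed"] = True
            rows.append(row)
    out = pd.DataFrame(rows)
    ok = out.index[~out["failed"]]
    if len(ok):
        out.loc[ok, "p_adj"] = bh_fdr(out.loc[ok, "p_raw"])
    return out


def sex_difference_test(assoc: pd.DataFrame) -> pd.DataFrame:
    """Two-sample z-test on the male vs female log-ORs from a stratified scan."""
    rows = []
    for k, grp in assoc[assoc["stratum"].isin(["male", "female"])].groupby("outcome"):
        bys = grp.set_index("stratum")
        if bys["failed"].any() or not {"male", "female"} <= set(bys.index):
            continue
        for src in bys["source"].unique():
            g = grp[grp["source"] == src].set_index("stratum")
            if len(g) < 2:
                continue
            b = np.log(g["OR"])
            se = (np.log(g["ci_high"]) - np.log(g["ci_low"])) / (2 * stats.norm.ppf(0.975))
            z = (b["male"] - b["female"]) / np.hypot(se["male"], se["female"])
            rows.append({"outcome": k, "source": src, "z": z,
                         "p": 2 * stats.norm.sf(abs(z))})
    return pd.DataFrame(rows)


__all__ = ["GeeFit", "FitError", "fit_gee_logistic", "nagelkerke_delta_r2",
           "bh_fdr", "association_scan", "moderation_scan",
           "sex_difference_test", "REGISTER_ONLY_OUTCOMES"]
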