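"""Regression-based counterfactual mediation with twin-pair bootstrap.

For exposure A (the standardized polygenic score), mediator M, outcome Y
and covariates C, two models are fitted:

* mediator model: logistic M ~ A + C (binary M) or linear M ~ A + C
  (continuous M), coefficients ``beta``;
* outcome model: logistic Y ~ A + M + C, coefficients ``theta``,
  without an A x M product term.

Under the rare-outcome approximation the natural effects for the contrast
(a*, a) have closed forms. Continuous M:

    log NDE  = theta_A (a - a*)
    log PNIE = theta_M beta_A (a - a*)

Binary M:

    NDE  = exp(theta_A (a - a*))
    PNIE = [(1 + e^{b(a*)}) (1 + e^{theta_M + b(a)})] /
           [(1 + e^{b(a)}) (1 + e^{theta_M + b(a*)})],
    b(x) = beta_0 + beta_A x + beta_C' c_ref

and the total effect factorizes as TE = NDE x PNIE. When the outcome is
not rare the same estimands are computed by Monte-Carlo counterfactual
standardization (draw M under each exposure level, average risks, form
odds ratios). Confidence intervals come from a percentile bootstrap that
resamples twin pairs, preserving the cluster structure.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

from .config import MEDIATORS, OUTCOMES, MediationConfig


class MediationError(RuntimeError):
    pass


@dataclass
class MediatorFit:
    kind: str                 # "binary" | "continuous"
    params: pd.Series         # const, prs, covariates
    resid_sd: float | None = None


@dataclass
class MediationResult:
    mediator: str
    outcome: str
    te_or: float
    nde_or: float
    pnie_or: float
    te_ci: tuple[float, float]
    nde_ci: tuple[float, float]
    pnie_ci: tuple[float, float]
    boot_se_log: dict[str, float]
    p_pnie: float
    proportion_mediated: float
    pm_inconsistent: bool
    classification: str
    theta: pd.Series
    beta_m: pd.Series
    n_boot_used: int
    n_boot_dropped: int
    unstable: bool = False
    extras: dict = field(default_factory=dict)


def _fit_logistic(y: np.ndarray, X: pd.DataFrame,
                  start: np.ndarray | None = None) -> pd.Series:
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(np.asarray(y, dtype=float), X,
                     family=sm.families.Binomial()).fit(start_params=start)
    params = pd.Series(res.params, index=X.columns)
    if not res.converged or not np.isfinite(params).all() or \
            np.abs(params).max() > 50:
        raise MediationError("logistic fit did not converge (separation?)")
    return params


def _fit_linear(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.Series, float]:
    coef, _, rank, _ = np.linalg.lstsq(X.to_numpy(), np.asarray(y, dtype=float),
                                       rcond=None)
    if rank < X.shape[1]:
        raise MediationError("collinear design in mediator model")
    resid = np.asarray(y, dtype=float) - X.to_numpy() @ coef
    dof = max(len(y) - X.shape[1], 1)
    return pd.Series(coef, index=X.columns), float(np.sqrt(resid @ resid / dof))


def fit_mediator_model(m: np.ndarray, a: np.ndarray, C: pd.DataFrame,
                       mediator_type: str,
                       start: np.ndarray | None = None) -> MediatorFit:
    """Mediator regression M ~ A + C of the declared type."""
    X = pd.DataFrame({"const": 1.0, "prs": np.asarray(a, dtype=float)})
    for c in C.columns:
        X[c] = C[c].to_numpy(dtype=float)
    if mediator_type == "binary":
        vals = np.unique(m)
        if len(vals) < 2:
            raise MediationError("binary mediator is constant")
        return MediatorFit("binary", _fit_logistic(m, X, start=start))
    if mediator_type == "continuous":
        params, sd = _fit_linear(m, X)
        return MediatorFit("continuous", params, resid_sd=sd)
    raise ValueError(f"unknown mediator type {mediator_type!r}")


def fit_outcome_model(y: np.ndarray, a: np.ndarray, m: np.ndarray,
                      C: pd.DataFrame,
                      start: np.ndarray | None = None) -> pd.Series:
    """Logistic outcome regression Y ~ A + M + C (no product term)."""
    X = pd.DataFrame({"const": 1.0, "prs": np.asarray(a, dtype=float),
                      "mediator": np.asarray(m, dtype=float)})
    for c in C.columns:
        X[c] = C[c].to_numpy(dtype=float)
    return _fit_logistic(y, X, start=start)


def _cov_terms(params: pd.Series, c_ref: pd.Series, skip: tuple[str, ...]) -> float:
    keys = [k for k in params.index if k not in skip]
    if not keys:
        return 0.0
    return float(sum(params[k] * c_ref.get(k, 0.0) for k in keys))


def counterfactual_effects(theta: pd.Series, beta: MediatorFit,
                           config: MediationConfig,
                           c_ref: pd.Series | None = None,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[float, float, float]:
    """(TE, NDE, PNIE) odds ratios for the configured exposure contrast.

    With ``config.rare_outcome`` the closed forms above are used;
    otherwise the effects are computed by Monte-Carlo counterfactual
    standardization with ``config.mc_draws`` draws (covariates held at
    ``c_ref``).
    """
    if c_ref is None:
        c_ref = pd.Series(dtype=float)
    if not config.rare_outcome:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        eff = standardized_effects_mc(theta, beta, config.exposure_contrast,
                                      c_ref, n_draws=config.mc_draws, rng=rng)
        return eff["te_or"], eff["nde_or"], eff["pnie_or"]
    a_star, a = config.exposure_contrast
    d = a - a_star
    nde = math.exp(theta["prs"] * d)
    if beta.kind == "continuous":
        pnie = math.exp(theta["mediator"] * beta.params["prs"] * d)
    else:
        b_cov = _cov_terms(beta.params, c_ref, skip=("const", "prs"))
        t2 = theta["mediator"]

        def lin(x):
            return beta.params["const"] + beta.params["prs"] * x + b_cov

        pnie = ((1.0 + math.exp(lin(a_star))) * (1.0 + math.exp(t2 + lin(a)))) / \
               ((1.0 + math.exp(lin(a))) * (1.0 + math.exp(t2 + lin(a_star))))
    return nde * pnie, nde, pnie


def standardized_effects_mc(theta: pd.Series, beta: MediatorFit,
                            contrast: tuple[float, float],
                            c_ref: pd.Series, n_draws: int,
                            rng: np.random.Generator) -> dict[str, float]:
    """Monte-Carlo counterfactual standardization at fixed covariates.

    Draws the mediator under each exposure level (independent draws per
    arm so the delta-method standard errors below are exact), averages
    outcome risks, and forms odds-ratio contrasts:

        TE   = odds E[Y(a, M_a)]     / odds E[Y(a*, M_a*)]
        NDE  = odds E[Y(a, M_a*)]    / odds E[Y(a*, M_a*)]
        PNIE = odds E[Y(a*, M_a)]    / odds E[Y(a*, M_a*)]

    Returns the three ORs plus Monte-Carlo SEs of their logs.
    """
    a_star, a = contrast
    t_cov = _cov_terms(theta, c_ref, skip=("const", "prs", "mediator"))
    b_cov = _cov_terms(beta.params, c_ref, skip=("const", "prs"))

    def draw_m(x: float) -> np.ndarray:
        lin = beta.params["const"] + beta.params["prs"] * x + b_cov
        if beta.kind == "binary":
            return (rng.random(n_draws) < special.expit(lin)).astype(float)
        return lin + beta.resid_sd * rng.standard_normal(n_draws)

    def risk(x_y: float, m: np.ndarray) -> tuple[float, float]:
        r = special.expit(theta["const"] + theta["prs"] * x_y
                          + theta["mediator"] * m + t_cov)
        return float(r.mean()), float(r.var(ddof=1) / len(r))

    r_a_ma, v1 = risk(a, draw_m(a))
    r_a_mastar, v2 = risk(a, draw_m(a_star))
    r_astar_ma, v3 = risk(a_star, draw_m(a))
    r_astar_mastar, v4 = risk(a_star, draw_m(a_star))

    def odds(r):
        return r / (1.0 - r)

    def log_se(r1, v1_, r2, v2_):
        # d log odds / d r = 1 / (r (1 - r)); arms are independent
        return math.sqrt(v1_ / (r1 * (1 - r1)) ** 2 + v2_ / (r2 * (1 - r2)) ** 2)

    return {
        "te_or": odds(r_a_ma) / odds(r_astar_mastar),
        "nde_or": odds(r_a_mastar) / odds(r_astar_mastar),
        "pnie_or": odds(r_astar_ma) / odds(r_astar_mastar),
        "te_log_se": log_se(r_a_ma, v1, r_astar_mastar, v4),
        "nde_log_se": log_se(r_a_mastar, v2, r_astar_mastar, v4),
        "pnie_log_se": log_se(r_astar_ma, v3, r_astar_mastar, v4),
    }


def proportion_mediated(te_or: float, pnie_or: float) -> tuple[float, bool]:
    """log(PNIE)/log(TE) with an inconsistency flag outside [0, 1].

    Raises for an exactly null total effect, where the ratio is undefined.
    """
    if te_or <= 0 or pnie_or <= 0:
        raise ValueError("odds ratios must be positive")
    if te_or == 1.0:
        raise MediationError("proportion mediated undefined: total effect OR is 1")
    pm = math.log(pnie_or) / math.log(te_or)
    return pm, not 0.0 <= pm <= 1.0


def classify_mediation(pnie_ci: tuple[float, float],
                       nde_ci: tuple[float, float]) -> str:
    """full: indirect path significant, direct path not; partial: both;
    none: no significant indirect path (all judged by the CI covering 1)."""
    pnie_sig = not pnie_ci[0] <= 1.0 <= pnie_ci[1]
    nde_sig = not nde_ci[0] <= 1.0 <= nde_ci[1]
    if not pnie_sig:
        return "none"
    return "partial" if nde_sig else "full"


def _point_effects(data: pd.DataFrame, mediator_col: str, mediator_type: str,
                   outcome_col: str, covariates: list[str],
                   config: MediationConfig, c_ref: pd.Series,
                   rng: np.random.Generator | None = None,
                   start_m: np.ndarray | None = None,
                   start_y: np.ndarray | None = None,
                   ) -> tuple[tuple[float, float, float], MediatorFit, pd.Series]:
    C = data[covariates]
    mfit = fit_mediator_model(data[mediator_col].to_numpy(),
                              data["prs"].to_numpy(), C, mediator_type,
                              start=start_m)
    theta = fit_outcome_model(data[outcome_col].to_numpy(),
                              data["prs"].to_numpy(),
                              data[mediator_col].to_numpy(), C, start=start_y)
    effects = counterfactual_effects(theta, mfit, config, c_ref=c_ref, rng=rng)
    return effects, mfit, theta


def cluster_bootstrap(data: pd.DataFrame, mediator: str, outcome: str,
                      config: MediationConfig,
                      covariates: list[str] | None = None,
                      mediator_type: str | None = None,
                      mediator_col: str | None = None,
                      outcome_col: str | None = None) -> MediationResult:
    """Full mediation analysis of one (mediator, outcome) pair.

    ``data`` holds one row per individual with columns ``family_id``,
    ``prs``, the mediator (model scale), the binary outcome, and the
    covariates. Twin pairs are resampled with replacement; each replicate
    refits both models (warm-started at the full-data estimates) and
    replicates that fail to converge are dropped and counted. Covariate
    reference values are the full-data means, held fixed across
    replicates.
    """
    covariates = covariates if covariates is not None else []
    mediator_type = mediator_type or MEDIATORS.get(mediator, "binary")
    mediator_col = mediator_col or mediator
    outcome_col = outcome_col or outcome
    c_ref = data[covariates].mean() if covariates else pd.Series(dtype=float)
    pair_key = zlib.crc32(f"{mediator}->{outcome}".encode())
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(pair_key,)))

    (te, nde, pnie), mfit, theta = _point_effects(
        data, mediator_col, mediator_type, outcome_col, covariates, config,
        c_ref, rng=rng)

    families = data["family_id"].to_numpy()
    unique_fams, fam_codes = np.unique(families, return_inverse=True)
    fam_rows = [np.flatnonzero(fam_codes == i) for i in range(len(unique_fams))]
    start_m = mfit.params.to_numpy() if mfit.kind == "binary" else None
    start_y = theta.to_numpy()

    logs = {"te": [], "nde": [], "pnie": []}
    dropped = 0
    for _ in range(config.n_boot):
        fam_draw = rng.integers(0, len(unique_fams), size=len(unique_fams))
        rows = np.concatenate([fam_rows[f] for f in fam_draw])
        boot = data.iloc[rows]
        try:
            (te_b, nde_b, pnie_b), _, _ = _point_effects(
                boot, mediator_col, mediator_type, outcome_col, covariates,
                config, c_ref, rng=rng, start_m=start_m, start_y=start_y)
        except MediationError:
            dropped += 1
            continue
        logs["te"].append(math.log(te_b))
        logs["nde"].append(math.log(nde_b))
        logs["pnie"].append(math.log(pnie_b))

    n_used = len(logs["te"])
    if n_used == 0:
        raise MediationError(f"all bootstrap replicates failed for {mediator}->{outcome}")
    unstable = dropped > 0.05 * config.n_boot
    if unstable:
        warnings.warn(f"{mediator}->{outcome}: {dropped} bootstrap replicates "
                      "dropped (>5%)", stacklevel=2)
    alpha = 1.0 - config.ci_level
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))

    def ci(key):
        arr = np.asarray(logs[key])
        lo, hi = np.percentile(arr, qs)
        return float(np.exp(lo)), float(np.exp(hi))

    boot_se = {k: float(np.std(v, ddof=1)) if n_used > 1 else 0.0
               for k, v in logs.items()}
    se_pnie = boot_se["pnie"]
    p_pnie = (2 * stats.norm.sf(abs(math.log(pnie)) / se_pnie)
              if se_pnie > 0 else (0.0 if pnie != 1.0 else 1.0))
    try:
        pm, pm_flag = proportion_mediated(te, pnie)
    except MediationError:
        pm, pm_flag = float("nan"), True
    pnie_ci, nde_ci, te_ci = ci("pnie"), ci("nde"), ci("te")
    return MediationResult(
        mediator=mediator, outcome=outcome, te_or=te, nde_or=nde, pnie_or=pnie,
        te_ci=te_ci, nde_ci=nde_ci, pnie_ci=pnie_ci, boot_se_log=boot_se,
        p_pnie=p_pnie, proportion_mediated=pm, pm_inconsistent=pm_flag,
        classification=classify_mediation(pnie_ci, nde_ci),
        theta=theta, beta_m=mfit.params, n_boot_used=n_used,
        n_boot_dropped=dropped, unstable=unstable)


def mediation_scan(cohort: pd.DataFrame, pcprs: pd.Series,
                   ancestry: pd.DataFrame, config: MediationConfig,
                   outcomes: list[str] | None = None,
                   mediators: list[str] | None = None,
                   covariates: bool = True) -> pd.DataFrame:
    """All mediator x outcome pairs, skipping BMI as a mediator of obesity
    (the mediator and outcome would measure the same construct). BH-FDR is
    applied to the indirect-effect p-values across the scan family."""
    from .association import bh_fdr  # local import avoids a cycle

    outcomes = list(outcomes) if outcomes is not None else [
        k for k in OUTCOMES if f"{k}_combined" in cohort.columns]
    mediators = list(mediators) if mediators is not None else list(MEDIATORS)

    df = cohort.set_index("individual_id")
    data = pd.DataFrame({
        "family_id": df["family_id"],
        "prs": pcprs.reindex(df.index),
        "birth_year": df["birth_year"].astype(float),
        "sex_male": (df["sex"] == "male").astype(float),
        "followup_years": df["followup_years"].astype(float),
    })
    for c in ancestry.columns:
        data[c] = ancestry[c].reindex(df.index)
    covs = (["birth_year", "sex_male", "followup_years"]
            + list(ancestry.columns)) if covariates else []
    for m in mediators:
        data[m] = df[m if MEDIATORS.get(m, "binary") == "binary" else "bmi"].astype(float)
    rows = []
    for m in mediators:
        for k in outcomes:
            if m == "bmi" and k == "obesity":
                continue
            data[k] = df[f"{k}_combined"].astype(float)
            try:
                res = cluster_bootstrap(data, m, k, config, covariates=covs,
                                        mediator_type=MEDIATORS.get(m, "binary"),
                                        mediator_col=m, outcome_col=k)
            except MediationError as exc:
                rows.append({"mediator": m, "outcome": k, "failed": True,
                             "error": str(exc)})
                continue
            rows.append({
                "mediator": m, "outcome": k, "failed": False, "error": "",
                "proportion_mediated": res.proportion_mediated,
                "pm_inconsistent": res.pm_inconsistent,
                "pnie_or": res.pnie_or, "pnie_low": res.pnie_ci[0],
                "pnie_high": res.pnie_ci[1],
                "nde_or": res.nde_or, "nde_low": res.nde_ci[0],
                "nde_high": res.nde_ci[1],
                "te_or": res.te_or, "te_low": res.te_ci[0],
                "te_high": res.te_ci[1],
                "classification": res.classification,
                "p_pnie": res.p_pnie, "p_adj": np.nan,
                "n_boot_used": res.n_boot_used,
                "n_boot_dropped": res.n_boot_dropped,
            })
    out = pd.DataFrame(rows)
    ok = out.index[~out["failed"]] if len(out) else []
    if len(ok):
        p = out.loc[ok, "p_pnie"].clip(lower=np.finfo(float).tiny, upper=1.0)
        out.loc[ok, "p_adj"] = bh_fdr(p)
    return out
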