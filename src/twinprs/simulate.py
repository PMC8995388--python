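"""Synthetic twin-cohort generator with known ground truth.

Every input the downstream pipeline needs is simulated here: a discovery
GWAS summary-statistics table, an unrelated LD reference panel, MZ/DZ twin
target genotypes, four life-course mediators, and dual-ascertained
(register and self-report) binary lifetime outcomes.

The genotype model is deliberately simple but exercises every code path
that matters downstream:

* one synthetic chromosome, evenly spaced positions, block-diagonal LD;
* within a block all variants share a MAF and adjacent haplotype alleles
  are copied with probability ``block_ld``, so the expected adjacent-pair
  dosage correlation equals ``block_ld`` exactly;
* MZ co-twins receive identical genotypes; DZ co-twins draw independently
  from four parental haplotypes, giving the textbook 0.5 expected
  within-pair dosage correlation;
* outcomes follow a logistic model with a direct polygenic-score term and
  mediator-carried indirect terms, the intercept solved numerically to hit
  the target marginal prevalence; register and self-report flags are then
  drawn from the latent status with per-outcome sensitivity/specificity,
  conditionally independent given the latent status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .config import MEDIATORS, SimConfig, TrueEffects
from .panel import GenotypePanel

# Fixed substream labels so each stage is reproducible in isolation.
_STAGE_PANEL = 1
_STAGE_EFFECTS = 2
_STAGE_SUMSTATS = 3
_STAGE_TWINS = 4
_STAGE_PHENO = 5

_SNP_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
              ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_AMBIG_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_INDEL_PAIRS = [("A", "AT"), ("AT", "A"), ("C", "CAG"), ("CT", "C")]


class SimulationError(RuntimeError):
    pass


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage generator spawned from the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def _block_assignment(n_variants: int, n_blocks: int) -> np.ndarray:
    return np.repeat(np.arange(n_blocks),
                     np.diff(np.linspace(0, n_variants, n_blocks + 1).astype(int)))


def _simulate_haplotypes(rng: np.random.Generator, n_hap: int,
                         blocks: np.ndarray, mafs: np.ndarray,
                         block_ld: float) -> np.ndarray:
    """Copy-with-refresh Markov haplotypes: within a block, each allele is a
    copy of its left neighbour with probability ``block_ld`` and a fresh
    Bernoulli(MAF) draw otherwise. Blocks are independent."""
    n_var = len(blocks)
    h = np.empty((n_hap, n_var), dtype=np.int8)
    fresh = rng.random((n_hap, n_var)) < mafs
    copy = rng.random((n_hap, n_var)) < block_ld
    block_start = np.r_[True, blocks[1:] != blocks[:-1]]
    h[:, 0] = fresh[:, 0]
    for j in range(1, n_var):
        if block_start[j]:
            h[:, j] = fresh[:, j]
        else:
            h[:, j] = np.where(copy[:, j], h[:, j - 1], fresh[:, j])
    return h


def _variant_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_variants
    blocks = _block_assignment(n, config.n_blocks)
    block_maf = rng.uniform(*config.maf_range, size=config.n_blocks)
    maf = block_maf[blocks]

    n_amb = round(config.ambiguous_fraction * n)
    n_indel = round(config.indel_fraction * n)
    perm = rng.permutation(n)
    amb_idx = perm[:n_amb]
    indel_idx = perm[n_amb:n_amb + n_indel]

    pair_choice = rng.integers(0, len(_SNP_PAIRS), size=n)
    ref = np.array([_SNP_PAIRS[i][0] for i in pair_choice], dtype=object)
    alt = np.array([_SNP_PAIRS[i][1] for i in pair_choice], dtype=object)
    for i in amb_idx:
        ref[i], alt[i] = _AMBIG_PAIRS[i % len(_AMBIG_PAIRS)]
    for i in indel_idx:
        ref[i], alt[i] = _INDEL_PAIRS[i % len(_INDEL_PAIRS)]

    n_low = round(config.info_low_fraction * n)
    info = rng.uniform(0.8, 1.0, size=n)
    low_idx = rng.permutation(n)[:n_low]
    info[low_idx] = rng.uniform(0.3, 0.8, size=n_low)

    pos = (np.arange(n) + 1) * config.variant_spacing_bp
    return pd.DataFrame({
        "variant_id": [f"rs{i + 1:06d}" for i in range(n)],
        "chrom": "1",
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "maf": maf,
        "info": info,
        "block": blocks,
    })


def simulate_reference_panel(config: SimConfig) -> GenotypePanel:
    """Unrelated-individuals dosage panel that doubles as the LD reference."""
    rng = stage_rng(config.seed, _STAGE_PANEL)
    variants = _variant_table(config, rng)
    blocks = variants["block"].to_numpy()
    mafs = variants["maf"].to_numpy()
    h1 = _simulate_haplotypes(rng, config.n_reference, blocks, mafs, config.block_ld)
    h2 = _simulate_haplotypes(rng, config.n_reference, blocks, mafs, config.block_ld)
    dosages = (h1 + h2).astype(float)
    samples = [f"ref{i + 1:05d}" for i in range(config.n_reference)]
    return GenotypePanel(variants=variants, dosages=dosages, samples=samples)


def default_true_effects(config: SimConfig, **overrides) -> TrueEffects:
    """TrueEffects with per-variant liability effects drawn for this config.

    A deterministic fraction ``null_fraction`` of variants get exactly zero
    effect; the rest draw N(0, causal_beta_sd^2).
    """
    rng = stage_rng(config.seed, _STAGE_EFFECTS)
    n = config.n_variants
    n_null = round(config.null_fraction * n)
    beta = rng.normal(0.0, config.causal_beta_sd, size=n)
    null_idx = rng.permutation(n)[:n_null]
    beta[null_idx] = 0.0
    return TrueEffects(beta_true=beta, **overrides)


def simulate_summary_stats(panel: GenotypePanel, truth: TrueEffects,
                           config: SimConfig) -> pd.DataFrame:
    """Noisy discovery GWAS estimates around the true liability effects.

    The standard error follows the usual logistic-GWAS approximation
    ``se = 1 / sqrt(2 p (1-p) N phi (1-phi))`` with ``phi`` the discovery
    case fraction, so estimates converge on truth as the discovery sample
    grows.
    """
    beta_true = np.asarray(truth.beta_true, dtype=float)
    if beta_true.shape != (panel.n_variants,):
        raise ValueError(
            f"beta_true length {beta_true.shape} does not match "
            f"{panel.n_variants} panel variants")
    rng = stage_rng(config.seed, _STAGE_SUMSTATS)
    n_total = config.discovery_n_case + config.discovery_n_control
    phi = config.discovery_n_case / n_total
    maf = panel.variants["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_total * phi * (1.0 - phi))
    beta_hat = beta_true + rng.normal(size=panel.n_variants) * se
    z = beta_hat / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    out = panel.variants[["variant_id", "chrom", "pos", "maf", "info"]].copy()
    out["effect_allele"] = panel.variants["alt"]
    out["other_allele"] = panel.variants["ref"]
    out["beta"] = beta_hat
    out["se"] = se
    out["p"] = p
    return out[["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                "beta", "se", "p", "info", "maf"]]


def simulate_twin_genotypes(panel: GenotypePanel,
                            config: SimConfig) -> tuple[GenotypePanel, pd.DataFrame]:
    """Twin-pair target genotypes plus a cohort skeleton.

    MZ co-twins are genotypically identical; DZ co-twins each draw one of
    two haplotypes from each of two simulated parents, independently.
    """
    if "block" not in panel.variants.columns:
        raise ValueError("panel lacks LD-block metadata; use a simulated panel")
    rng = stage_rng(config.seed, _STAGE_TWINS)
    n_pairs = config.n_pairs
    n_mz = round(config.mz_fraction * n_pairs)
    n_dz = n_pairs - n_mz
    blocks = panel.variants["block"].to_numpy()
    mafs = panel.variants["maf"].to_numpy()

    def haps(n):
        return _simulate_haplotypes(rng, n, blocks, mafs, config.block_ld)

    dosages = np.empty((2 * n_pairs, panel.n_variants), dtype=float)
    # MZ pairs first: one genotype, duplicated.
    mz_geno = (haps(n_mz) + haps(n_mz)).astype(float)
    dosages[0:2 * n_mz:2] = mz_geno
    dosages[1:2 * n_mz:2] = mz_geno
    # DZ pairs: four parental haplotypes, each child transmits independently.
    pat = haps(2 * n_dz).reshape(n_dz, 2, -1)
    mat = haps(2 * n_dz).reshape(n_dz, 2, -1)
    pick = rng.integers(0, 2, size=(n_dz, 2, 2))  # (pair, child, parent)
    rows = np.arange(n_dz)
    for child in range(2):
        geno = (pat[rows, pick[:, child, 0]] + mat[rows, pick[:, child, 1]]).astype(float)
        dosages[2 * n_mz + child::2] = geno

    zygosity = np.repeat(np.r_[["MZ"] * n_mz, ["DZ"] * n_dz], 2)
    family = np.repeat([f"fam{i + 1:06d}" for i in range(n_pairs)], 2)
    ind_id = [f"{f}_{t + 1}" for f in dict.fromkeys(family) for t in range(2)]

    sex_pair = np.where(rng.random(n_pairs) < config.female_fraction, "female", "male")
    sex = np.repeat(sex_pair, 2)
    # DZ co-twins may be opposite-sex; redraw twin 2 of DZ pairs.
    dz_second = np.zeros(2 * n_pairs, dtype=bool)
    dz_second[2 * n_mz + 1::2] = True
    sex = sex.astype(object)
    sex[dz_second] = np.where(rng.random(n_dz) < config.female_fraction,
                              "female", "male")

    lo, hi = config.birth_year_range
    birth_pair = rng.integers(lo, hi + 1, size=n_pairs)
    followup = np.clip(rng.normal(config.followup_mean, config.followup_sd,
                                  size=2 * n_pairs), 0.0, None)

    cohort = pd.DataFrame({
        "individual_id": ind_id,
        "family_id": family,
        "zygosity": zygosity,
        "sex": sex,
        "birth_year": np.repeat(birth_pair, 2),
        "followup_years": followup,
    })
    twin_panel = GenotypePanel(variants=panel.variants.copy(), dosages=dosages,
                               samples=list(cohort["individual_id"]))
    return twin_panel, cohort


def true_polygenic_score(panel: GenotypePanel, beta_true: np.ndarray) -> pd.Series:
    """Standardized genetic liability score from the true effects."""
    raw = panel.imputed_dosages() @ np.asarray(beta_true, dtype=float)
    sd = raw.std()
    if sd == 0:
        raise SimulationError("true polygenic score has zero variance")
    return pd.Series((raw - raw.mean()) / sd, index=panel.samples, name="true_prs")


def solve_logit_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + lp)) == target, by bracketed root find."""
    if not 0.0 < target < 1.0:
        raise SimulationError(f"target prevalence {target} not attainable")

    def f(c):
        return special.expit(c + lp).mean() - target

    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise SimulationError(f"no intercept attains prevalence {target}")
    return optimize.brentq(f, lo, hi, xtol=1e-10)


def simulate_phenotypes(true_prs: pd.Series, cohort: pd.DataFrame,
                        truth: TrueEffects, config: SimConfig) -> pd.DataFrame:
    """Mediators, latent outcomes, and dual ascertainment flags.

    Binary mediators follow logistic models in the score (intercepts solved
    for the target mediator prevalence); BMI is linear-Gaussian on the
    kg/m^2 scale. Each latent outcome follows a logistic model in the
    score, the four mediators (model scale), and the covariates; register
    and self-report flags are drawn from the latent status through
    per-outcome (sensitivity, specificity).
    """
    prs = np.asarray(true_prs.loc[cohort["individual_id"]], dtype=float)
    if abs(prs.mean()) > 1e-3 or abs(prs.std() - 1.0) > 1e-2:
        raise ValueError("true_prs must be standardized to mean 0, SD 1")
    rng = stage_rng(config.seed, _STAGE_PHENO)
    out = cohort.copy()
    n = len(out)

    # --- mediators ---------------------------------------------------------
    for name, kind in MEDIATORS.items():
        b1 = truth.beta1[name]
        if kind == "binary":
            a0 = solve_logit_intercept(b1 * prs, truth.mediator_prevalence[name])
            out[name] = (rng.random(n) < special.expit(a0 + b1 * prs)).astype(int)
        else:  # BMI: unit-variance latent so b1 is the slope on the model scale
            if not abs(b1) < 1.0:
                raise SimulationError("beta1 for a continuous mediator must be in (-1, 1)")
            latent = b1 * prs + np.sqrt(1.0 - b1 * b1) * rng.normal(size=n)
            out["bmi_highest"] = truth.bmi_mean + truth.bmi_sd * latent
    scaled = out["bmi_highest"].to_numpy()
    out["bmi"] = (scaled - scaled.mean()) / scaled.std()

    # --- covariate terms (decade scale keeps coefficients interpretable) ---
    by = out["birth_year"].to_numpy(dtype=float)
    fu = out["followup_years"].to_numpy(dtype=float)
    cov_lp = (truth.gamma_birth_year * (by - by.mean()) / 10.0
              + truth.gamma_sex_male * (out["sex"] == "male").to_numpy()
              + truth.gamma_followup * (fu - fu.mean()) / 10.0)

    med_model = {name: out[name if MEDIATORS[name] == "binary" else "bmi"].to_numpy(dtype=float)
                 for name in MEDIATORS}

    # --- outcomes and ascertainment ----------------------------------------
    for k, prev in truth.baseline_prevalence.items():
        lp = truth.theta1[k] * prs + cov_lp
        for m, t2 in truth.theta2[k].items():
            lp = lp + t2 * med_model[m]
        c = solve_logit_intercept(lp, prev)
        latent = (rng.random(n) < special.expit(c + lp)).astype(int)
        sr, fr = truth.sens_register[k], truth.spec_register[k]
        ss, fs = truth.sens_self[k], truth.spec_self[k]
        u1, u2 = rng.random(n), rng.random(n)
        register = np.where(latent == 1, u1 < sr, u1 < 1.0 - fr).astype(int)
        selfrep = np.where(latent == 1, u2 < ss, u2 < 1.0 - fs).astype(int)
        out[f"{k}_register"] = register
        out[f"{k}_selfreport"] = selfrep
        out[f"{k}_combined"] = (register | selfrep).astype(int)
        out[f"{k}_latent"] = latent  # ground truth, dropped when writing files
    return out


@dataclass
class SimulatedCohort:
    """Bundle of every artifact a full simulation produces."""

    config: SimConfig
    truth: TrueEffects
    reference: GenotypePanel
    summary_stats: pd.DataFrame
    twin_panel: GenotypePanel
    cohort: pd.DataFrame
    true_prs: pd.Series


def simulate_cohort(config: SimConfig,
                    truth: TrueEffects | None = None) -> SimulatedCohort:
    """Run the whole generative chain under one config."""
    reference = simulate_reference_panel(config)
    if truth is None:
        truth = default_true_effects(config)
    elif truth.beta_true is None:
        truth.beta_true = default_true_effects(config).beta_true
    sumstats = simulate_summary_stats(reference, truth, config)
    twin_panel, skeleton = simulate_twin_genotypes(reference, config)
    true_prs = true_polygenic_score(twin_panel, truth.beta_true)
    cohort = simulate_phenotypes(true_prs, skeleton, truth, config)
    return SimulatedCohort(config=config, truth=truth, reference=reference,
                           summary_stats=sumstats, twin_panel=twin_panel,
                           cohort=cohort, true_prs=true_prs)
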