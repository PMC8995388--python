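"""Configuration objects shared across the pipeline.

Defaults encode the study conditions the package is designed around: a
mid-to-late-life twin cohort with sixteen lifetime somatic outcomes
ascertained from both national registers and self-report, four life-course
risk factors (education, highest-ever BMI, tobacco use, alcohol misuse),
and a polygenic score built from an external case-control discovery GWAS.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field


#: The sixteen lifetime somatic outcomes, grouped by disease area.
OUTCOMES: tuple[str, ...] = (
    "ischemic_heart_disease",
    "heart_failure",
    "cerebrovascular_disease",
    "peripheral_vascular_disease",
    "hypertension",
    "obesity",
    "type2_diabetes",
    "type1_diabetes",
    "rheumatoid_arthritis",
    "psoriasis",
    "inflammatory_bowel_disease",
    "migraine",
    "epilepsy",
    "dementia",
    "parkinson_disease",
    "sleep_disorder",
)

#: Outcomes with no self-report instrument; cases come from registers only.
REGISTER_ONLY_OUTCOMES: frozenset[str] = frozenset({"dementia", "sleep_disorder"})

#: Life-course risk factors used as mediators/moderators, with their type.
MEDIATORS: dict[str, str] = {
    "education": "binary",  # more than basic schooling vs basic only
    "bmi": "continuous",    # highest-ever BMI, standardized for modelling
    "tobacco": "binary",    # ever used cigarettes or snuff
    "alcohol": "binary",    # composite problematic-alcohol-use indicator
}

#: Marginal lifetime prevalence targets for the combined (register OR
#: self-report) outcome definition, on the cohort scale the generator
#: emulates.
DEFAULT_PREVALENCE: dict[str, float] = {
    "ischemic_heart_disease": 0.113,
    "heart_failure": 0.110,
    "cerebrovascular_disease": 0.158,
    "peripheral_vascular_disease": 0.049,
    "hypertension": 0.256,
    "obesity": 0.144,
    "type2_diabetes": 0.052,
    "type1_diabetes": 0.015,
    "rheumatoid_arthritis": 0.056,
    "psoriasis": 0.057,
    "inflammatory_bowel_disease": 0.023,
    "migraine": 0.207,
    "epilepsy": 0.022,
    "dementia": 0.035,
    "parkinson_disease": 0.044,
    "sleep_disorder": 0.119,
}

#: Default direct log-odds of one SD of the polygenic score on each outcome.
DEFAULT_THETA1: dict[str, float] = {
    "ischemic_heart_disease": math.log(1.06),
    "heart_failure": math.log(1.08),
    "cerebrovascular_disease": math.log(1.08),
    "peripheral_vascular_disease": math.log(1.20),
    "hypertension": math.log(1.04),
    "obesity": math.log(1.14),
    "type2_diabetes": math.log(1.05),
    "type1_diabetes": math.log(1.21),
    "rheumatoid_arthritis": math.log(1.14),
    "psoriasis": math.log(1.06),
    "inflammatory_bowel_disease": math.log(1.01),
    "migraine": math.log(1.07),
    "epilepsy": math.log(1.06),
    "dementia": math.log(1.05),
    "parkinson_disease": 0.0,
    "sleep_disorder": math.log(1.04),
}


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic twin-cohort generator.

    Genotypes live on one synthetic chromosome with evenly spaced positions
    and block-diagonal LD so that a physical clumping window is meaningful.
    Within a block all variants share a minor allele frequency and adjacent
    haplotype alleles are identical with probability ``block_ld``, which
    makes ``block_ld`` the expected adjacent-pair dosage correlation.
    """

    seed: int = 0
    n_variants: int = 2000
    n_blocks: int = 40
    block_ld: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    variant_spacing_bp: int = 20_000
    n_reference: int = 1000
    n_pairs: int = 2000
    mz_fraction: float = 0.35
    null_fraction: float = 0.7
    causal_beta_sd: float = 0.03
    discovery_n_case: int = 19_099
    discovery_n_control: int = 34_194
    info_low_fraction: float = 0.05
    ambiguous_fraction: float = 0.05
    indel_fraction: float = 0.02
    birth_year_range: tuple[int, int] = (1911, 1958)
    followup_mean: float = 12.0
    followup_sd: float = 2.0
    female_fraction: float = 0.53

    def __post_init__(self) -> None:
        for name in ("mz_fraction", "null_fraction", "info_low_fraction",
                     "ambiguous_fraction", "indel_fraction", "female_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.block_ld < 1.0:
            raise ConfigError(f"block_ld must be in [0, 1), got {self.block_ld}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must be ordered within (0, 0.5], got {self.maf_range}")
        for name in ("n_variants", "n_blocks", "n_reference", "variant_spacing_bp",
                     "discovery_n_case", "discovery_n_control"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_pairs < 2:
            raise ConfigError("n_pairs must be at least 2")
        if self.ambiguous_fraction + self.indel_fraction > 1.0:
            raise ConfigError("ambiguous_fraction + indel_fraction exceed 1")


@dataclass
class TrueEffects:
    """Ground-truth generative parameters of the synthetic cohort.

    ``beta_true`` are per-variant additive effects on the liability scale;
    ``theta1`` the direct log-OR of the standardized polygenic score on
    each outcome; ``beta1``/``theta2`` the score->mediator and
    mediator->outcome paths that carry the indirect effects. Register and
    self-report flags are noisy views of the latent lifetime status with
    per-outcome sensitivity/specificity.
    """

    beta_true: "object" = None  # numpy array, length n_variants
    theta1: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THETA1))
    theta2: dict[str, dict[str, float]] = field(default_factory=dict)
    beta1: dict[str, float] = field(default_factory=lambda: {
        "education": -0.15, "bmi": 0.10, "tobacco": 0.15, "alcohol": 0.20,
    })
    mediator_prevalence: dict[str, float] = field(default_factory=lambda: {
        "education": 0.55, "tobacco": 0.50, "alcohol": 0.15,
    })
    bmi_mean: float = 25.5
    bmi_sd: float = 3.8
    baseline_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    sens_register: dict[str, float] = field(default_factory=dict)
    spec_register: dict[str, float] = field(default_factory=dict)
    sens_self: dict[str, float] = field(default_factory=dict)
    spec_self: dict[str, float] = field(default_factory=dict)
    gamma_birth_year: float = -0.10   # per decade of birth year (younger -> lower risk)
    gamma_sex_male: float = 0.15
    gamma_followup: float = 0.05      # per decade of register follow-up

    def __post_init__(self) -> None:
        default_theta2 = {"education": -0.25, "bmi": 0.20,
                          "tobacco": 0.25, "alcohol": 0.30}
        for k in self.baseline_prevalence:
            self.theta2.setdefault(k, dict(default_theta2))
            self.sens_register.setdefault(k, 0.60)
            self.spec_register.setdefault(k, 0.995)
            if k in REGISTER_ONLY_OUTCOMES:
                self.sens_self.setdefault(k, 0.0)
                self.spec_self.setdefault(k, 1.0)
            else:
                self.sens_self.setdefault(k, 0.70)
                self.spec_self.setdefault(k, 0.98)
        for name in ("sens_register", "spec_register", "sens_self", "spec_self"):
            for k, v in getattr(self, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{name}[{k}] must be in [0, 1], got {v}")
        for k, v in self.baseline_prevalence.items():
            if not 0.0 < v < 1.0:
                raise ConfigError(f"baseline_prevalence[{k}] must be in (0, 1), got {v}")

    @property
    def outcomes(self) -> list[str]:
        return list(self.baseline_prevalence)


@dataclass
class PrsConfig:
    """Scoring parameters: clumping, p-value thresholds, and QC cut-offs."""

    thresholds: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0)
    clump_r2: float = 0.1
    clump_window_bp: int = 1_000_000
    info_min: float = 0.8

    def __post_init__(self) -> None:
        ts = tuple(self.thresholds)
        if len(ts) < 1 or any(not 0.0 < t <= 1.0 for t in ts):
            raise ConfigError(f"thresholds must lie in (0, 1], got {ts}")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ConfigError("thresholds must be strictly increasing")
        if not 0.0 < self.clump_r2 < 1.0:
            raise ConfigError(f"clump_r2 must be in (0, 1), got {self.clump_r2}")
        if self.clump_window_bp <= 0:
            raise ConfigError("clump_window_bp must be positive")
        self.thresholds = ts


@dataclass
class MediationConfig:
    """Counterfactual mediation settings.

    The exposure contrast defaults to one SD of the standardized polygenic
    score (0 -> 1). ``rare_outcome`` selects the closed-form odds-ratio
    decomposition (valid when the outcome is rare); when disabled the
    effects are computed by Monte-Carlo counterfactual standardization.
    """

    n_boot: int = 5000
    ci_level: float = 0.95
    exposure_contrast: tuple[float, float] = (0.0, 1.0)
    rare_outcome: bool = True
    mc_draws: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ConfigError("n_boot must be at least 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError("ci_level must be in (0, 1)")
        a_star, a = self.exposure_contrast
        if a == a_star:
            raise ConfigError("exposure_contrast endpoints must differ")


def config_fingerprint(*configs) -> dict:
    """JSON-serializable snapshot of one or more config dataclasses."""
    out = {}
    for cfg in configs:
        d = dataclasses.asdict(cfg)
        for k, v in list(d.items()):
            if hasattr(v, "tolist"):
                d[k] = v.tolist()
        out[type(cfg).__name__] = d
    return out
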