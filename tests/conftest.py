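import numpy as np
import pandas as pd
import pytest

import twinprs as tp
from twinprs.config import PrsConfig, SimConfig, TrueEffects


def make_skeleton(n_pairs: int, rng: np.random.Generator) -> pd.DataFrame:
    """Minimal twin-cohort skeleton (no genotypes) for phenotype simulation."""
    fam = np.repeat([f"fam{i:05d}" for i in range(n_pairs)], 2)
    return pd.DataFrame({
        "individual_id": [f"{f}_{t + 1}" for i, f in enumerate(dict.fromkeys(fam))
                          for t in range(2)],
        "family_id": fam,
        "zygosity": "DZ",
        "sex": rng.choice(["male", "female"], size=2 * n_pairs),
        "birth_year": np.repeat(rng.integers(1911, 1959, size=n_pairs), 2),
        "followup_years": rng.uniform(5, 16, size=2 * n_pairs),
    })


def pair_correlated_prs(n_pairs: int, rng: np.random.Generator,
                        rho: float = 0.5) -> np.ndarray:
    """Standardized score with within-pair correlation rho."""
    shared = np.repeat(rng.standard_normal(n_pairs), 2)
    own = rng.standard_normal(2 * n_pairs)
    prs = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    return (prs - prs.mean()) / prs.std()


def null_truth(outcomes=("hypertension",), **overrides) -> TrueEffects:
    """A generative world with no score effects and perfect ascertainment."""
    kw = dict(
        theta1={k: 0.0 for k in outcomes},
        theta2={k: {m: 0.0 for m in tp.MEDIATORS} for k in outcomes},
        beta1={m: 0.0 for m in tp.MEDIATORS},
        baseline_prevalence={k: tp.config.DEFAULT_PREVALENCE[k] for k in outcomes},
        sens_register={k: 1.0 for k in outcomes},
        spec_register={k: 1.0 for k in outcomes},
        sens_self={k: 1.0 for k in outcomes},
        spec_self={k: 1.0 for k in outcomes},
        gamma_birth_year=0.0, gamma_sex_male=0.0, gamma_followup=0.0,
    )
    kw.update(overrides)
    return TrueEffects(**kw)


@pytest.fixture(scope="session")
def small_sim():
    """One small but complete simulated cohort shared across tests."""
    cfg = SimConfig(seed=7, n_pairs=300, n_variants=400, n_blocks=10,
                    n_reference=400)
    return tp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def scored(small_sim):
    """PRS-engine outputs on the shared cohort."""
    cfg = PrsConfig()
    harm = tp.harmonize(small_sim.summary_stats, small_sim.twin_panel, cfg)
    index_variants = tp.ld_clump(harm, small_sim.reference, cfg)
    matrix = tp.score_prs(small_sim.twin_panel, index_variants, harm, cfg)
    combined = tp.pc_prs(matrix)
    pcs = tp.ancestry_pcs(small_sim.twin_panel, small_sim.cohort, k=6)
    return {"config": cfg, "harmonized": harm, "index_variants": index_variants,
            "matrix": matrix, "pcprs": combined, "pcs": pcs}
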