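"""Polygenic score engine: QC/harmonization, LD clumping, multi-threshold
scoring, principal-component combination, and ancestry PCs.

The score for individual *i* at p-value threshold *t* is

    PRS_i(t) = sum_{j: p_j <= t, j in clumped set} beta_j * dosage_ij,

with weights aligned to the allele the target panel counts. The eight
threshold scores are standardized and combined into a single score by
taking the first principal component of the score matrix, which captures
the shared signal across thresholds without picking a single threshold
post hoc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PrsConfig
from .panel import GenotypePanel, is_ambiguous, is_indel

QC_REASONS = ("not_in_target", "ambiguous", "indel_or_multiallelic",
              "low_info", "allele_mismatch")


class PrsError(ValueError):
    pass


@dataclass
class HarmonizedVariants:
    """Summary statistics matched to the target panel.

    ``table`` keeps one row per retained variant with ``beta`` aligned to
    the target's counted (ALT) allele; ``qc_report`` counts exclusions by
    reason and satisfies retained + sum(excluded) == input rows.
    """

    table: pd.DataFrame
    qc_report: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.table)


@dataclass
class PrsMatrix:
    """Individuals x thresholds score matrix with per-column SNP counts."""

    scores: pd.DataFrame
    n_snps: pd.Series
    standardized: bool = False

    def standardize(self) -> "PrsMatrix":
        """Column-wise z-scores; zero-variance columns propagate NaN."""
        s = self.scores
        sd = s.std(axis=0, ddof=0)
        z = (s - s.mean(axis=0)) / sd.replace(0.0, np.nan)
        return PrsMatrix(scores=z, n_snps=self.n_snps.copy(), standardized=True)


@dataclass
class PcPrs:
    """Single combined score: first PC of the standardized score matrix."""

    score: pd.Series
    loadings: pd.Series
    variance_explained: float


def harmonize(stats: pd.DataFrame, panel: GenotypePanel,
              config: PrsConfig) -> HarmonizedVariants:
    """Match summary statistics to the target panel and align weights.

    Exclusions, applied in order and counted once per variant: absent from
    the target; indel or multi-allelic; strand-ambiguous (A/T, C/G);
    imputation INFO below ``config.info_min`` (the boundary value is
    kept); allele pair not matching the target's REF/ALT. When the
    summary-statistics effect allele is the target REF, the weight is
    negated and the allele columns swapped so ``beta`` always applies to
    the counted ALT dose.
    """
    dup = stats["variant_id"][stats["variant_id"].duplicated()]
    if len(dup):
        raise PrsError(f"duplicate variant_id in summary stats: {dup.iloc[0]}")
    qc = {k: 0 for k in QC_REASONS}
    pvars = panel.variants.set_index("variant_id")

    rows = []
    for rec in stats.itertuples(index=False):
        if rec.variant_id not in pvars.index:
            qc["not_in_target"] += 1
            continue
        tgt = pvars.loc[rec.variant_id]
        ea, oa = str(rec.effect_allele), str(rec.other_allele)
        if is_indel(ea, oa) or is_indel(str(tgt["ref"]), str(tgt["alt"])):
            qc["indel_or_multiallelic"] += 1
            continue
        if is_ambiguous(ea, oa):
            qc["ambiguous"] += 1
            continue
        if rec.info < config.info_min:
            qc["low_info"] += 1
            continue
        if {ea, oa} != {str(tgt["ref"]), str(tgt["alt"])}:
            qc["allele_mismatch"] += 1
            continue
        beta = float(rec.beta)
        if ea == str(tgt["ref"]):  # target counts the other allele: flip
            beta, ea, oa = -beta, oa, ea
        rows.append({"variant_id": rec.variant_id, "chrom": tgt["chrom"],
                     "pos": int(tgt["pos"]), "effect_allele": ea,
                     "other_allele": oa, "beta": beta, "p": float(rec.p),
                     "info": float(rec.info), "maf": float(tgt["maf"])})
    table = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                        "effect_allele", "other_allele",
                                        "beta", "p", "info", "maf"])
    qc["retained"] = len(table)
    assert qc["retained"] + sum(qc[k] for k in QC_REASONS) == len(stats)
    return HarmonizedVariants(table=table, qc_report=qc)


def _pairwise_r2(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of one dosage column against many."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc @ xc) * (Yc * Yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ Yc) / denom, 0.0)
    return r * r


def ld_clump(harmonized: HarmonizedVariants, ld_ref: GenotypePanel,
             config: PrsConfig) -> list[str]:
    """Greedy p-value-ordered clumping against a reference panel.

    Repeatedly take the smallest-p unclaimed variant as an index and claim
    every unclaimed variant within ``clump_window_bp`` of it whose squared
    dosage correlation (in ``ld_ref``) exceeds ``clump_r2``. Ties on p are
    broken by position then variant id so results are deterministic.
    Returns index variant ids sorted by position.
    """
    tab = harmonized.table
    if tab.empty:
        return []
    idx_map = ld_ref.variant_index()
    missing = [v for v in tab["variant_id"] if v not in idx_map.index]
    if missing:
        raise PrsError(f"variant absent from LD reference: {missing[0]}")
    order = tab.sort_values(["p", "pos", "variant_id"],
                            kind="mergesort").reset_index(drop=True)
    dos = ld_ref.imputed_dosages()[:, idx_map.loc[order["variant_id"]].to_numpy()]
    pos = order["pos"].to_numpy()
    chrom = order["chrom"].to_numpy()
    unclaimed = np.ones(len(order), dtype=bool)
    index_rows: list[int] = []
    for i in range(len(order)):
        if not unclaimed[i]:
            continue
        unclaimed[i] = False
        index_rows.append(i)
        near = (unclaimed & (chrom == chrom[i])
                & (np.abs(pos - pos[i]) <= config.clump_window_bp))
        if near.any():
            r2 = _pairwise_r2(dos[:, i], dos[:, near])
            claim = np.where(near)[0][r2 > config.clump_r2]
            unclaimed[claim] = False
    kept = order.iloc[index_rows].sort_values("pos")
    return list(kept["variant_id"])


def score_prs(panel: GenotypePanel, index_variants: list[str],
              harmonized: HarmonizedVariants, config: PrsConfig) -> PrsMatrix:
    """Weighted dosage sums at each p-value threshold over the clumped set.

    Missing dosages are mean-imputed per variant. Thresholds admitting no
    variant yield an all-zero column with ``n_snps == 0``; these are later
    dropped before the PC step.
    """
    tab = harmonized.table.set_index("variant_id").loc[list(index_variants)]
    dos = panel.dosage_for(list(tab.index))
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.where(np.isnan(dos))
        dos = dos.copy()
        dos[nan_r, nan_c] = col_mean[nan_c]
    beta = tab["beta"].to_numpy()
    p = tab["p"].to_numpy()
    cols, counts = {}, {}
    for t in config.thresholds:
        mask = p <= t
        cols[f"prs_{t:g}"] = dos[:, mask] @ beta[mask]
        counts[f"prs_{t:g}"] = int(mask.sum())
    scores = pd.DataFrame(cols, index=panel.samples)
    return PrsMatrix(scores=scores, n_snps=pd.Series(counts), standardized=False)


def pc_prs(prs: PrsMatrix) -> PcPrs:
    """First principal component of the standardized threshold scores.

    Zero-SNP and zero-variance columns are dropped with a warning; at
    least two usable columns are required. The component sign is fixed so
    the combined score correlates positively with the most inclusive
    threshold column, and the returned score is re-standardized.
    """
    n_snps = prs.n_snps
    usable = [c for c in prs.scores.columns
              if n_snps[c] > 0 and prs.scores[c].std(ddof=0) > 0]
    dropped = [c for c in prs.scores.columns if c not in usable]
    if dropped:
        warnings.warn(f"dropping degenerate PRS columns before PCA: {dropped}",
                      stacklevel=2)
    if len(usable) < 2:
        raise PrsError(f"need at least 2 non-degenerate PRS columns, have {len(usable)}")
    sub = PrsMatrix(scores=prs.scores[usable], n_snps=n_snps[usable])
    z = sub.standardize().scores.to_numpy()
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    loadings = vt[0]
    if np.corrcoef(pc1, z[:, -1])[0, 1] < 0:
        pc1, loadings = -pc1, -loadings
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    score = pd.Series((pc1 - pc1.mean()) / pc1.std(ddof=0),
                      index=prs.scores.index, name="pc_prs")
    return PcPrs(score=score,
                 loadings=pd.Series(loadings, index=usable, name="loading"),
                 variance_explained=var_explained)


def ld_prune(panel: GenotypePanel, r2_max: float = 0.2,
             window_bp: int = 1_000_000) -> list[str]:
    """Position-ordered greedy LD pruning: keep a variant unless it exceeds
    ``r2_max`` with an already-kept variant within the window."""
    v = panel.variants.sort_values(["chrom", "pos"]).reset_index()
    dos = panel.imputed_dosages()[:, v["index"].to_numpy()]
    pos = v["pos"].to_numpy()
    chrom = v["chrom"].to_numpy()
    kept: list[int] = []
    for i in range(len(v)):
        near = [j for j in kept
                if chrom[j] == chrom[i] and abs(int(pos[i]) - int(pos[j])) <= window_bp]
        if near:
            r2 = _pairwise_r2(dos[:, i], dos[:, near])
            if (r2 > r2_max).any():
                continue
        kept.append(i)
    return list(v.loc[kept, "variant_id"])


def ancestry_pcs(panel: GenotypePanel, cohort: pd.DataFrame, k: int = 6,
                 prune_r2: float = 0.2,
                 prune_window_bp: int = 1_000_000) -> pd.DataFrame:
    """Ancestry covariate PCs: loadings from one twin per family, projected.

    Variants are LD-pruned, dosages standardized using the unrelated set's
    moments, loadings computed by SVD on the unrelated individuals only
    (so within-pair relatedness cannot shape the axes), and every
    individual is then projected onto those loadings.
    """
    keep_ids = ld_prune(panel, r2_max=prune_r2, window_bp=prune_window_bp)
    dos = panel.dosage_for(keep_ids)
    sample_pos = pd.Series(np.arange(panel.n_samples), index=panel.samples)
    first_per_family = cohort.drop_duplicates("family_id")["individual_id"]
    unrel = sample_pos.loc[first_per_family].to_numpy()

    mu = dos[unrel].mean(axis=0)
    sd = dos[unrel].std(axis=0, ddof=0)
    ok = sd > 0
    z_unrel = (dos[unrel][:, ok] - mu[ok]) / sd[ok]
    u, s, vt = np.linalg.svd(z_unrel, full_matrices=False)
    tol = s[0] * max(z_unrel.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if k > rank:
        raise PrsError(f"requested {k} ancestry PCs but usable rank is {rank}")
    z_all = (dos[:, ok] - mu[ok]) / sd[ok]
    proj = z_all @ vt[:k].T / s[:k] * np.sqrt(len(unrel))
    return pd.DataFrame(proj, index=panel.samples,
                        columns=[f"PC{i + 1}" for i in range(k)])
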