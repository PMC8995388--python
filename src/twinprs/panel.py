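"""In-memory genotype container used by the simulator, scorer and IO layer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

#: Columns every variant table must carry.
VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt", "maf", "info")


def is_ambiguous(ref: str, alt: str) -> bool:
    """True for strand-ambiguous (A/T or C/G) SNPs."""
    return {ref, alt} in AMBIGUOUS_PAIRS


def is_indel(ref: str, alt: str) -> bool:
    return len(ref) != 1 or len(alt) != 1


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x variants) plus variant metadata.

    Dosages count the ALT allele and may contain NaN for sporadic missing
    genotypes. The same container serves as target panel and LD reference.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants")
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant_id in panel: {dup}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> pd.Series:
        """Map variant_id -> column position."""
        return pd.Series(np.arange(self.n_variants), index=self.variants["variant_id"])

    def dosage_for(self, variant_ids) -> np.ndarray:
        idx = self.variant_index()
        missing = [v for v in variant_ids if v not in idx.index]
        if missing:
            raise KeyError(f"variants absent from panel: {missing[:5]}")
        return self.dosages[:, idx.loc[list(variant_ids)].to_numpy()]

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with per-variant mean imputation of missing entries."""
        d = self.dosages
        if not np.isnan(d).any():
            return d
        d = d.copy()
        col_mean = np.nanmean(d, axis=0)
        nan_r, nan_c = np.where(np.isnan(d))
        d[nan_r, nan_c] = col_mean[nan_c]
        return d

    def subset_samples(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            variants=self.variants.copy(),
            dosages=self.dosages[keep],
            samples=[self.samples[i] for i in np.atleast_1d(keep)],
        )
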