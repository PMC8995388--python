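"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as VCF with a per-genotype ``DS`` (dosage) field
(``AF`` and ``R2`` INFO keys carry allele frequency and imputation
quality) or as a PLINK-style transposed text dosage table. Summary
statistics are tab-delimited with a fixed header; phenotypes are CSV.
Reading validates the structural invariants (unique ids, two individuals
per family, combined = register OR self-report) and reports offending
records by name.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .panel import GenotypePanel

SUMSTATS_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele",
                    "other_allele", "beta", "p", "info", "maf"]


class FormatError(ValueError):
    pass


# --------------------------------------------------------------------------
# VCF dosage
# --------------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as an uncompressed VCF with FORMAT/DS dosages."""
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(panel.variants["chrom"].astype(str)):
        header.contigs.add(chrom, length=int(panel.variants["pos"].max()) + 1)
    header.info.add("AF", number="A", type="Float", description="ALT allele frequency")
    header.info.add("R2", number=1, type="Float", description="Imputation quality")
    header.formats.add("DS", number=1, type="Float", description="ALT dosage")
    for s in panel.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, v in enumerate(panel.variants.itertuples(index=False)):
            rec = vcf.new_record(contig=str(v.chrom), start=int(v.pos) - 1,
                                 stop=int(v.pos) - 1 + len(str(v.ref)),
                                 alleles=(str(v.ref), str(v.alt)), id=str(v.variant_id))
            rec.info["AF"] = (float(v.maf),)
            rec.info["R2"] = float(v.info)
            col = panel.dosages[:, j]
            for i, s in enumerate(panel.samples):
                rec.samples[s]["DS"] = None if np.isnan(col[i]) else float(col[i])
            vcf.write(rec)


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a dosage VCF written by :func:`write_vcf` (or compatible)."""
    with pysam.VariantFile(str(path)) as vcf:
        if "DS" not in vcf.header.formats:
            raise FormatError(
                "VCF has no FORMAT/DS dosage field; use the text-dosage "
                "reader (read_text_dosage) for hard-call data")
        samples = list(vcf.header.samples)
        rows, cols = [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(f"{rec.id}: expected exactly one ALT allele")
            af = rec.info.get("AF", (np.nan,))
            af = af[0] if isinstance(af, tuple) else af
            rows.append({"variant_id": rec.id, "chrom": rec.chrom,
                         "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0],
                         "maf": min(af, 1 - af) if af == af else np.nan,
                         "info": rec.info.get("R2", np.nan)})
            ds = [rec.samples[s].get("DS") for s in samples]
            cols.append([np.nan if d is None else float(d) for d in ds])
    variants = pd.DataFrame(rows)
    return GenotypePanel(variants=variants,
                         dosages=np.asarray(cols, dtype=float).T,
                         samples=samples)


# --------------------------------------------------------------------------
# PLINK-style transposed text dosage
# --------------------------------------------------------------------------

def write_text_dosage(panel: GenotypePanel, path: str | Path) -> None:
    """One row per variant: metadata columns then per-sample ALT dosages."""
    meta = panel.variants[["variant_id", "chrom", "pos", "ref", "alt",
                           "maf", "info"]].copy()
    dos = pd.DataFrame(panel.dosages.T, columns=panel.samples)
    pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA")


def read_text_dosage(path: str | Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt", "maf", "info"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise FormatError(f"text dosage file missing columns {missing}")
    samples = [c for c in df.columns if c not in meta_cols]
    if not samples:
        raise FormatError("text dosage file has no sample columns")
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    return GenotypePanel(variants=variants,
                         dosages=df[samples].to_numpy(dtype=float).T,
                         samples=samples)


# --------------------------------------------------------------------------
# Summary statistics / phenotypes / truth sidecar
# --------------------------------------------------------------------------

def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"summary stats missing columns {missing}")
    df["chrom"] = df["chrom"].astype(str)
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate variant_id in summary stats: {dup.iloc[0]}")
    bad = df.index[(df["p"] <= 0) | (df["p"] > 1)]
    if len(bad):
        raise FormatError(
            f"p-value outside (0, 1] at line {bad[0] + 2} "
            f"({df.loc[bad[0], 'variant_id']})")
    return df


def write_phenotypes(cohort: pd.DataFrame, path: str | Path,
                     drop_latent: bool = True) -> None:
    out = cohort
    if drop_latent:
        out = cohort[[c for c in cohort.columns if not c.endswith("_latent")]]
    out.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["individual_id", "family_id", "zygosity", "sex",
                "birth_year", "followup_years"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table missing columns {missing}")
    dup = df["individual_id"][df["individual_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate individual_id: {dup.iloc[0]}")
    sizes = df.groupby("family_id").size()
    bad = sizes.index[sizes != 2]
    if len(bad):
        raise FormatError(
            f"family {bad[0]} has {sizes[bad[0]]} members; twin files must "
            "have exactly 2 per family")
    if (df["followup_years"] < 0).any():
        raise FormatError("negative followup_years")
    for col in df.columns:
        if col.endswith("_combined"):
            k = col[:-len("_combined")]
            expected = (df[f"{k}_register"].astype(int)
                        | df[f"{k}_selfreport"].astype(int))
            if not (df[col].astype(int) == expected).all():
                raise FormatError(f"{col} is not register OR selfreport")
    return df


def write_truth(truth, path: str | Path) -> None:
    """Machine-readable ground-truth sidecar (for tests and audits)."""
    d = {k: (v.tolist() if hasattr(v, "tolist") else v)
         for k, v in vars(truth).items()}
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
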