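"""End-to-end orchestration: simulate -> score -> associate -> mediate.

A single :class:`RunConfig` (optionally loaded from YAML) drives the whole
run; every stage persists its artifact so runs are byte-reproducible under
a fixed global seed and restartable from intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import io
from .association import association_scan, moderation_scan
from .config import (MediationConfig, PrsConfig, SimConfig, TrueEffects,
                     config_fingerprint)
from .mediation import mediation_scan
from .prs import ancestry_pcs, harmonize, ld_clump, pc_prs, score_prs
from .simulate import simulate_cohort

log = logging.getLogger("twinprs")

STAGES = ("simulate", "score", "associate", "moderate", "mediate", "report")


class PipelineError(RuntimeError):
    pass


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, as in printed prevalence tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_percent(cases: int, n: int) -> float:
    """Printed prevalence: 100*cases/n, rounded half-up to one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round_half_up(100.0 * cases / n, 1)


def assemble_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Recompute combined flags (register OR self-report) in place-safe copy."""
    out = cohort.copy()
    outcome_names = [c[:-len("_register")] for c in cohort.columns
                     if c.endswith("_register")]
    if not outcome_names:
        raise PipelineError("no register flags present in cohort table")
    for k in outcome_names:
        if f"{k}_selfreport" not in cohort.columns:
            raise PipelineError(f"missing self-report flag for {k}")
        out[f"{k}_combined"] = (out[f"{k}_register"].astype(int)
                                | out[f"{k}_selfreport"].astype(int))
    return out


def prevalence_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cases and percent prevalence by ascertainment source per outcome."""
    n = len(cohort)
    rows = []
    for col in cohort.columns:
        if not col.endswith("_combined"):
            continue
        k = col[:-len("_combined")]
        row = {"outcome": k, "n": n}
        for source in ("combined", "register", "selfreport"):
            cases = int(cohort[f"{k}_{source}"].sum())
            row[f"n_{source}"] = cases
            row[f"pct_{source}"] = prevalence_percent(cases, n)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    outdir: str = "twinprs_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    prs: PrsConfig = field(default_factory=PrsConfig)
    mediation: MediationConfig = field(default_factory=MediationConfig)
    fdr_level: float = 0.05
    stages: tuple[str, ...] = STAGES
    ancestry_k: int = 6
    mediation_outcomes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages {sorted(unknown)}")
        # the global seed deterministically drives every stage
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.mediation = dataclasses.replace(self.mediation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, klass in (("sim", SimConfig), ("prs", PrsConfig),
                           ("mediation", MediationConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in kwargs[key].items()}
                kwargs[key] = klass(**sub)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)


@dataclass
class RunReport:
    stages_run: list[str]
    counts: dict
    qc: dict
    fingerprint: dict
    significant: dict


def run_pipeline(config: RunConfig,
                 truth: TrueEffects | None = None) -> RunReport:
    """Execute the requested stages in order, persisting each artifact.

    A stage failure raises :class:`PipelineError` naming the stage;
    artifacts of completed stages remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(stages_run=[], counts={}, qc={}, significant={},
                       fingerprint=config_fingerprint(config.sim, config.prs,
                                                      config.mediation))
    state: dict = {}

    def stage(name):
        return name in config.stages

    try:
        if stage("simulate"):
            log.info("stage simulate: %d pairs, %d variants",
                     config.sim.n_pairs, config.sim.n_variants)
            sim = simulate_cohort(config.sim, truth=truth)
            io.write_vcf(sim.reference, out / "reference.vcf")
            io.write_vcf(sim.twin_panel, out / "target.vcf")
            io.write_text_dosage(sim.twin_panel, out / "target.dosage.tsv")
            io.write_summary_stats(sim.summary_stats, out / "sumstats.tsv")
            io.write_phenotypes(sim.cohort, out / "phenotypes.csv")
            io.write_truth(sim.truth, out / "truth.json")
            state.update(sim=sim, cohort=sim.cohort, sumstats=sim.summary_stats,
                         target=sim.twin_panel, reference=sim.reference)
            report.counts["individuals"] = len(sim.cohort)
            report.counts["variants"] = sim.twin_panel.n_variants
            report.stages_run.append("simulate")
    except Exception as exc:
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    try:
        if stage("score"):
            cohort, target = state["cohort"], state["target"]
            harm = harmonize(state["sumstats"], target, config.prs)
            index_variants = ld_clump(harm, state["reference"], config.prs)
            prs_matrix = score_prs(target, index_variants, harm, config.prs)
            combined = pc_prs(prs_matrix)
            pcs = ancestry_pcs(target, cohort, k=config.ancestry_k)
            prs_matrix.scores.to_csv(out / "prs_matrix.csv")
            combined.score.to_frame().to_csv(out / "pc_prs.csv")
            pcs.to_csv(out / "ancestry_pcs.csv")
            (out / "qc_report.json").write_text(json.dumps({
                "harmonization": harm.qc_report,
                "n_index_variants": len(index_variants),
                "n_snps_per_threshold": prs_matrix.n_snps.to_dict(),
                "pc_variance_explained": combined.variance_explained,
            }, indent=1))
            state.update(pcprs=combined.score, pcs=pcs)
            report.qc["harmonization"] = harm.qc_report
            report.counts["index_variants"] = len(index_variants)
            report.stages_run.append("score")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage score failed: {exc}") from exc

    try:
        if stage("associate"):
            assoc = association_scan(state["cohort"], state["pcprs"], state["pcs"])
            assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
            state["assoc"] = assoc
            main = assoc[(assoc["source"] == "combined") & (assoc["stratum"] == "all")]
            report.significant["association"] = list(
                main.loc[main["p_adj"] < config.fdr_level, "outcome"])
            report.counts["association_rows"] = len(assoc)
            report.stages_run.append("associate")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage associate failed: {exc}") from exc

    try:
        if stage("moderate"):
            mod = moderation_scan(state["cohort"], state["pcprs"], state["pcs"])
            mod.to_csv(out / "moderation.tsv", sep="\t", index=False)
            report.significant["moderation"] = [
                f"{r.moderator}->{r.outcome}" for r in
                mod.loc[mod["p_adj"] < config.fdr_level].itertuples()]
            report.counts["moderation_rows"] = len(mod)
            report.stages_run.append("moderate")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage moderate failed: {exc}") from exc

    try:
        if stage("mediate"):
            med = mediation_scan(
                state["cohort"], state["pcprs"], state["pcs"], config.mediation,
                outcomes=(list(config.mediation_outcomes)
                          if config.mediation_outcomes else None))
            med.to_csv(out / "mediation.tsv", sep="\t", index=False)
            sig = med[(~med["failed"]) & (med["p_adj"] < config.fdr_level)]
            sig.to_csv(out / "mediation_significant.tsv", sep="\t", index=False)
            report.significant["mediation"] = [
                f"{r.mediator}->{r.outcome}" for r in sig.itertuples()]
            report.counts["mediation_rows"] = len(med)
            report.stages_run.append("mediate")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage mediate failed: {exc}") from exc

    try:
        if stage("report"):
            prev = prevalence_table(state["cohort"])
            prev.to_csv(out / "prevalence.tsv", sep="\t", index=False)
            report.counts["outcomes"] = len(prev)
            report.stages_run.append("report")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage report failed: {exc}") from exc

    (out / "run_report.json").write_text(json.dumps(
        dataclasses.asdict(report), indent=1, default=str))
    return report
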