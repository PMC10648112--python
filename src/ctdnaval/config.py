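"""Run configuration and end-to-end orchestration.

A single JSON/YAML-serializable document configures the whole pipeline:
vendor reporting policy, LDT policy, simulation parameters, study design
(tiers, input masses, replicates, cohort size) and the master seed. Unknown
keys are rejected. ``run_end_to_end`` executes simulate -> report ->
validate -> concordance deterministically and writes an output manifest
with checksums, so a rerun with the same config reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, Field

from . import concordance as conc
from . import fixtures, metrics, simulate, vcfio
from .reporting import LdtPolicy
from .vendor import ReportingPolicy
from .variants import FilterStatus


class ReportingPolicyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cutoff_actionable_percent: float = 0.1
    cutoff_hotspot_percent: float = 0.3
    cutoff_other_percent: float = 0.5
    homopolymer_min_len: int = 4

    def build(self) -> ReportingPolicy:
        return ReportingPolicy(**self.model_dump())


class LdtPolicyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_alt_reads: int = 2
    rescue_vaf_min_percent: float = 10.0
    reporting_cutoff_percent: float = 0.25
    germline_rescuable: bool = True

    def build(self) -> LdtPolicy:
        return LdtPolicy(
            min_alt_reads=self.min_alt_reads,
            rescue_vaf_min_percent=self.rescue_vaf_min_percent,
            reporting_cutoff_percent=self.reporting_cutoff_percent,
            germline_rescuable=self.germline_rescuable,
        )


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    depth_median_by_input: dict[int, int] = Field(
        default_factory=lambda: {30: 3841, 40: 4400, 50: 5069, 60: 5130}
    )
    depth_dispersion: float = 0.1
    recovery_beta: float = 1.0
    fp_rate_per_library: float = 0.68
    fp_vaf_scale_percent: float = 0.2
    germline_vaf_mean: float = 50.0
    germline_vaf_sd: float = 5.0

    def build(self) -> simulate.SimulationParams:
        return simulate.SimulationParams(**self.model_dump())


class StudyDesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tiers: list[float] = Field(default_factory=lambda: [2.0, 1.0, 0.5, 0.25, 0.125, 0.0])
    input_ng: list[int] = Field(default_factory=lambda: [50])
    replicates: int = 3
    cohort_patients: int = 20


class RunConfig(BaseModel):
    """Top-level configuration; serializable to/from one JSON document."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    log_level: str = "INFO"
    reporting_policy: ReportingPolicyConfig = Field(default_factory=ReportingPolicyConfig)
    ldt_policy: LdtPolicyConfig = Field(default_factory=LdtPolicyConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    design: StudyDesignConfig = Field(default_factory=StudyDesignConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the full pipeline deterministically and write a result bundle.

    Stages: simulate reference-standard replicates and a clinical cohort;
    run the LDT reporting pipeline; compute the tiered metrics; compute
    standard-vs-LDT concordance on both the simulated cohort and the
    packaged clinical fixture. Returns the summary dict (also written as
    ``summary.json``) and records every output file with its checksum in
    ``outputs_manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.simulation.build()
    ldt_policy = config.ldt_policy.build()
    vendor_policy = config.reporting_policy.build()
    design = config.design

    panel = simulate.make_reference_panel(config.seed)
    runs = simulate.simulate_replicates(
        panel, design.tiers, design.input_ng, design.replicates, params, seed=config.seed
    )
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    manifest_entries = []
    for run in runs:
        path = vcfio.write_library_vcf(run, vcf_dir / f"{run.library_id}.vcf")
        manifest_entries.append(
            {
                "path": str(path.relative_to(out)),
                "library_id": run.library_id,
                "sample_id": run.sample_id,
                "input_ng": run.input_ng,
                "operator_id": run.operator_id,
                "run_id": run.run_id,
                "tier_vaf_percent": run.tier_vaf_percent,
                "dialect": "unfiltered",
            }
        )
    vcfio.write_manifest(manifest_entries, out / "runs_manifest.json")

    def reportable(call):
        return metrics.ldt_reportable(call, ldt_policy)

    positive_runs = [r for r in runs if r.tier_vaf_percent]
    tallies = metrics.tally_detections(positive_runs, panel, reportable)
    _write_tallies(tallies, out / "sensitivity.tsv")
    summary: dict[str, Any] = {"seed": config.seed, "n_reference_libraries": len(runs)}
    wt_runs = [r for r in runs if r.tier_vaf_percent == 0.0]
    if wt_runs:
        spec = metrics.specificity(wt_runs, panel, reportable)
        summary["specificity"] = {"tn": spec.tn, "fp": spec.fp, "ratio": spec.ratio}
    for ng in design.input_ng:
        snv_rows = [
            t
            for t in tallies
            if t.input_ng == ng and t.variant_type.value == "SNV" and t.tier_vaf_percent > 0
        ]
        if snv_rows:
            summary[f"lod95_snv_{ng}ng"] = metrics.lod95(snv_rows)

    cohort = simulate.simulate_clinical_cohort(
        design.cohort_patients, params, seed=config.seed + 1
    )
    summary["cohort"] = _cohort_concordance(cohort, vendor_policy, ldt_policy)

    table3 = fixtures.load_table3()
    summary["clinical_fixture_ppa"] = {
        mode: {
            "concordant": (res := conc.ppa_from_variant_table(table3, mode)).concordant,
            "ortho_only": res.ortho_only,
            "percent": round(res.percent, 1),
        }
        for mode in ("standard", "ldt")
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "outputs_manifest.json")
    outputs = {str(p.relative_to(out)): _sha256(p) for p in files}
    (out / "outputs_manifest.json").write_text(json.dumps(outputs, indent=2) + "\n")
    return summary


def _cohort_concordance(cohort, vendor_policy, ldt_policy) -> dict[str, Any]:
    out = {}
    for mode, reports in (
        ("standard", cohort.standard_reports(vendor_policy)),
        ("ldt", cohort.ldt_reports(ldt_policy)),
    ):
        pairs = conc.build_pairs(reports, cohort.ortho_reports)
        try:
            res = conc.ppa(pairs)
            out[mode] = {
                "concordant": res.concordant,
                "ortho_only": res.ortho_only,
                "percent": round(res.percent, 1),
            }
        except metrics.UndefinedMetricError:
            out[mode] = None
    return out


def _write_tallies(tallies, path: Path) -> None:
    lines = ["variant_type\ttier_vaf_percent\tinput_ng\tdetected\ttotal\tsensitivity"]
    for t in tallies:
        lines.append(
            f"{t.variant_type.value}\t{t.tier_vaf_percent:g}\t{t.input_ng}"
            f"\t{t.detected}\t{t.total}\t{metrics.sensitivity(t):.4f}"
        )
    path.write_text("\n".join(lines) + "\n")
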