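"""Packaged fixture tables for the in-text validation results.

The analytical-performance counts (tiered sensitivity; specificity / PPV /
LoD-95), the 81-variant clinical concordance table, the PPA summary, the
pre/post-treatment VAF table, and the two homopolymer reference indels are
shipped as TSV transcriptions so every analysis stage is exercisable with
no external download. Marginal counts are asserted at load time.

The two reference indels carry their published coordinates and alleles; the
surrounding +-50 bp context strings are *synthetic* stand-ins that embed the
described homopolymer runs (a 6 bp A run for the APC insertion, a 5 bp C
run for the TP53 deletion), since no genome is bundled.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Iterator

from dataclasses import dataclass

from .concordance import ClinicalVariantRow, PpaResult
from .metrics import DetectionCount
from .variants import (
    Classification,
    ReferenceContext,
    TruthVariant,
    VariantKey,
    VariantModelError,
    VariantType,
    parse_classification,
)

FIXTURE_NAMES = (
    "table1",
    "table2",
    "table3",
    "table4",
    "table6",
    "reference_indels",
)

_FILES = {
    "table1": "table1_sensitivity.tsv",
    "table2": "table2_performance.tsv",
    "table3": "table3_clinical_variants.tsv",
    "table4": "table4_ppa.tsv",
    "table6": "table6_treatment.tsv",
    "reference_indels": "reference_indels.tsv",
}

_VALID_REASONS = {"", "G", "C", "R", "PHI"}


class FixtureError(VariantModelError):
    """Unknown fixture or integrity failure in packaged data."""


def _rows(filename: str) -> Iterator[dict]:
    ref = resources.files("ctdnaval.data").joinpath(filename)
    with ref.open("r", newline="") as fh:
        yield from csv.DictReader(fh, delimiter="\t")


@dataclass(frozen=True)
class PerformanceRow:
    """One input-mass row of the specificity/PPV/LoD-95 summary."""

    input_ng: int
    ppv_tp: int
    ppv_fp: int
    lod95_snv_percent: float
    specificity_tn: int
    specificity_fp: int


@dataclass(frozen=True)
class TreatmentRow:
    """One variant of one patient in the pre/post-treatment comparison."""

    cancer_type: str
    patient_id: str
    gene: str
    protein_change: str
    classification: Classification
    filter_note: str
    pre_vaf_percent: float
    post_vaf_percent: float
    post_detected: bool


def load_table1() -> list[DetectionCount]:
    counts = [
        DetectionCount(
            variant_type=VariantType(r["variant_type"]),
            tier_vaf_percent=float(r["tier_vaf_percent"]),
            input_ng=int(r["input_ng"]),
            detected=int(r["detected"]),
            total=int(r["total"]),
        )
        for r in _rows(_FILES["table1"])
    ]
    if len(counts) != 40:  # 2 variant types x 4 inputs x 5 tiers
        raise FixtureError(f"sensitivity table has {len(counts)} cells, expected 40")
    return counts


def load_table2() -> list[PerformanceRow]:
    rows = [
        PerformanceRow(
            input_ng=int(r["input_ng"]),
            ppv_tp=int(r["ppv_tp"]),
            ppv_fp=int(r["ppv_fp"]),
            lod95_snv_percent=float(r["lod95_snv_percent"]),
            specificity_tn=int(r["specificity_tn"]),
            specificity_fp=int(r["specificity_fp"]),
        )
        for r in _rows(_FILES["table2"])
    ]
    if [r.input_ng for r in rows] != [30, 40, 50, 60]:
        raise FixtureError("performance table must cover inputs 30/40/50/60 ng")
    return rows


def load_table3() -> list[ClinicalVariantRow]:
    rows = []
    for r in _rows(_FILES["table3"]):
        reason = r["filter_reason"].strip()
        if reason not in _VALID_REASONS:
            raise FixtureError(f"invalid filter reason {reason!r}")
        unfiltered = r["test_vaf_unfiltered_percent"].strip()
        rows.append(
            ClinicalVariantRow(
                gene=r["gene"],
                cdna_change=r["cdna_change"],
                protein_change=r["protein_change"],
                ortho_vaf_percent=float(r["ortho_vaf_percent"]),
                test_vaf_reported_percent=float(r["test_vaf_reported_percent"]),
                test_vaf_unfiltered_percent=float(unfiltered) if unfiltered else None,
                filter_reason=reason,
                below_ldt_cutoff=bool(int(r["below_ldt_cutoff"])),
                ortho_false_negative=bool(int(r["ortho_false_negative"])),
                classification=parse_classification(r["classification"]),
                tumor_type=r["tumor_type"],
                patient_id=r["patient_id"],
                clinical_in_ppa=bool(int(r["clinical_in_ppa"])),
            )
        )
    if len(rows) != 81:
        raise FixtureError(f"clinical variant table has {len(rows)} rows, expected 81")
    patients = {r.patient_id for r in rows}
    if len(patients) != 27:
        raise FixtureError(f"clinical variant table covers {len(patients)} patients, expected 27")
    return rows


def load_table4() -> dict[str, PpaResult]:
    out = {
        r["pipeline"]: PpaResult(concordant=int(r["concordant"]), ortho_only=int(r["ortho_only"]))
        for r in _rows(_FILES["table4"])
    }
    if set(out) != {"standard", "ldt"}:
        raise FixtureError("PPA table must cover the standard and LDT pipelines")
    return out


def load_table6() -> list[TreatmentRow]:
    rows = [
        TreatmentRow(
            cancer_type=r["cancer_type"],
            patient_id=r["patient_id"],
            gene=r["gene"],
            protein_change=r["protein_change"],
            classification=parse_classification(r["classification"]),
            filter_note=r["filter_note"].strip(),
            pre_vaf_percent=float(r["pre_vaf_percent"]),
            post_vaf_percent=float(r["post_vaf_percent"]),
            post_detected=bool(int(r["post_detected"])),
        )
        for r in _rows(_FILES["table6"])
    ]
    if len({r.patient_id for r in rows}) != 10:
        raise FixtureError("treatment table must cover 10 patients")
    return rows


def load_reference_indels() -> list[TruthVariant]:
    """The two homopolymer indels always suppressed by the vendor RPT filter.

    Coordinates and alleles are the published ones; the embedded reference
    context is synthetic (see module docstring).
    """
    out = []
    for r in _rows(_FILES["reference_indels"]):
        context = ReferenceContext(
            chrom=r["chrom"], start=int(r["context_start"]), seq=r["synthetic_context_seq"]
        )
        key = VariantKey(r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        if context.slice(key.pos, len(key.ref)) != key.ref:
            raise FixtureError(f"context disagrees with ref allele for {key}")
        out.append(
            TruthVariant(
                key=key,
                gene=r["gene"],
                homopolymer_context=True,
                expected_vaf_percent=0.0,
                context=context,
            )
        )
    if len(out) != 2:
        raise FixtureError("expected exactly two reference homopolymer indels")
    return out


_LOADERS = {
    "table1": load_table1,
    "table2": load_table2,
    "table3": load_table3,
    "table4": load_table4,
    "table6": load_table6,
    "reference_indels": load_reference_indels,
}


def load_fixture(name: str):
    """Load a packaged fixture by name (see :data:`FIXTURE_NAMES`)."""
    try:
        loader = _LOADERS[name]
    except KeyError:
        raise FixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return loader()
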