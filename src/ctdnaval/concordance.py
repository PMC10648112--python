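"""Orthogonal-assay concordance for clinical call sets.

Pairs each (patient, variant) observation between the test assay and an
independent previously validated comparator, excludes off-shared-panel and
below-LLOD observations, and computes positive percent agreement (PPA) for
clinically significant variants under either reporting pipeline. Also
provides the test-vs-comparator VAF regression and pre/post-treatment VAF
comparison.

PPA treats the comparator as a non-reference standard: the denominator is
its positive calls (concordant positives + comparator-only calls); negative
and overall agreement are out of scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .metrics import LinearityFit, linearity_fit
from .reporting import LdtPolicy, ReportedCall
from .variants import (
    CLINICALLY_SIGNIFICANT,
    Classification,
    VariantCall,
    VariantKey,
    VariantModelError,
)
from .metrics import UndefinedMetricError


class PairClass(enum.Enum):
    CONCORDANT_POSITIVE = "CONCORDANT_POSITIVE"
    TEST_ONLY = "TEST_ONLY"
    ORTHO_ONLY = "ORTHO_ONLY"
    EXCLUDED_BELOW_LLOD = "EXCLUDED_BELOW_LLOD"
    EXCLUDED_OFF_PANEL = "EXCLUDED_OFF_PANEL"


#: Default 33-gene test panel.
TEST_PANEL_GENES = frozenset(
    {
        "AKT1", "ALK", "APC", "ARID1A", "ATM", "BRAF", "BRCA1", "BRCA2",
        "BRIP1", "CCND1", "CDH1", "CSF1R", "EGFR", "ERBB2", "ESR1", "FGFR1",
        "FGFR2", "FGFR3", "IDH1", "IDH2", "KIT", "KRAS", "MET", "MYC",
        "NRAS", "NTRK1", "PDGFRA", "PIK3CA", "POLD1", "POLE", "RET", "ROS1",
        "TP53",
    }
)

#: Test-panel genes the orthogonal comparator does not cover.
ORTHO_UNCOVERED_GENES = frozenset({"BRIP1", "CSF1R", "POLD1", "POLE"})


@dataclass(frozen=True)
class PanelSpec:
    """Gene coverage of the two assays; concordance is scored on the overlap."""

    test_genes: frozenset[str] = TEST_PANEL_GENES
    ortho_genes: frozenset[str] = TEST_PANEL_GENES - ORTHO_UNCOVERED_GENES

    @property
    def shared_genes(self) -> frozenset[str]:
        return self.test_genes & self.ortho_genes


@dataclass(frozen=True)
class Llods:
    """Lower reporting limits of the two assays, percent VAF."""

    test_percent: float = 0.25
    ortho_percent: float = 0.3


@dataclass
class ConcordancePair:
    """One variant's paired test/comparator observation for one patient."""

    key: VariantKey
    gene: str
    classification: Classification
    patient_id: str
    ortho_vaf_percent: float
    test_vaf_percent: float
    concordance_class: PairClass
    test_vaf_unfiltered_percent: Optional[float] = None
    filter_reason: str = ""


def build_pairs(
    test_reports: Mapping[str, Sequence[VariantCall]],
    ortho_reports: Mapping[str, Sequence[VariantCall]],
    panels: PanelSpec | None = None,
    llods: Llods | None = None,
) -> list[ConcordancePair]:
    """Pair per-patient test and comparator call sets into concordance classes.

    Off-shared-panel genes are excluded; an observation below the detecting
    assay's LLOD is excluded rather than scored as a discordance. Duplicate
    keys per patient on one side raise an ambiguity error.
    """
    panels = panels or PanelSpec()
    llods = llods or Llods()
    pairs: list[ConcordancePair] = []
    for patient in sorted(set(test_reports) | set(ortho_reports)):
        test_by_key = _unique_by_key(test_reports.get(patient, ()), patient, "test")
        ortho_by_key = _unique_by_key(ortho_reports.get(patient, ()), patient, "comparator")
        for key in sorted(set(test_by_key) | set(ortho_by_key)):
            t, o = test_by_key.get(key), ortho_by_key.get(key)
            gene = (t or o).gene
            cls = (t or o).classification
            if t is not None and o is not None and t.classification is not Classification.UNCLASSIFIED:
                cls = t.classification
            t_vaf = t.vaf_percent if t is not None else 0.0
            o_vaf = o.vaf_percent if o is not None else 0.0
            if gene and gene not in panels.shared_genes:
                pc = PairClass.EXCLUDED_OFF_PANEL
            else:
                t_pos = t is not None and t_vaf >= llods.test_percent
                o_pos = o is not None and o_vaf >= llods.ortho_percent
                if t_pos and o_pos:
                    pc = PairClass.CONCORDANT_POSITIVE
                elif t_pos:
                    pc = PairClass.TEST_ONLY
                elif o_pos:
                    pc = PairClass.ORTHO_ONLY
                else:
                    pc = PairClass.EXCLUDED_BELOW_LLOD
            pairs.append(
                ConcordancePair(
                    key=key,
                    gene=gene,
                    classification=cls,
                    patient_id=patient,
                    ortho_vaf_percent=o_vaf,
                    test_vaf_percent=t_vaf,
                    concordance_class=pc,
                )
            )
    return pairs


def _unique_by_key(
    calls: Iterable[VariantCall], patient: str, side: str
) -> dict[VariantKey, VariantCall]:
    out: dict[VariantKey, VariantCall] = {}
    for call in calls:
        if call.key in out:
            raise VariantModelError(
                f"duplicate {side} call for {call.key} in patient {patient}"
            )
        out[call.key] = call
    return out


@dataclass
class PpaResult:
    """Positive percent agreement with raw concordant/missed counts."""

    concordant: int
    ortho_only: int

    @property
    def denominator(self) -> int:
        return self.concordant + self.ortho_only

    @property
    def ratio(self) -> float:
        return self.concordant / self.denominator

    @property
    def percent(self) -> float:
        return 100.0 * self.ratio


def ppa(pairs: Iterable[ConcordancePair], restrict_clinical: bool = True) -> PpaResult:
    """PPA = concordant positives / (concordant positives + comparator-only).

    With ``restrict_clinical`` only pathogenic / likely pathogenic pairs are
    considered. Excluded pairs never enter numerator or denominator.
    """
    tp = fn = 0
    for pair in pairs:
        if restrict_clinical and pair.classification not in CLINICALLY_SIGNIFICANT:
            continue
        if pair.concordance_class is PairClass.CONCORDANT_POSITIVE:
            tp += 1
        elif pair.concordance_class is PairClass.ORTHO_ONLY:
            fn += 1
    if tp + fn == 0:
        raise UndefinedMetricError("PPA undefined: no comparator-positive pairs")
    return PpaResult(concordant=tp, ortho_only=fn)


def vaf_correlation(
    pairs: Iterable[ConcordancePair] | Sequence[tuple[float, float]],
    include_zero_sides: bool = False,
) -> LinearityFit:
    """OLS of test VAF (Y) on comparator VAF (X) over usable pairs.

    A pair is usable when both sides carry a nonzero VAF (for test-side
    filtered variants the unfiltered VAF stands in), unless
    ``include_zero_sides`` keeps single-sided detections at 0.
    """
    xy: list[tuple[float, float]] = []
    for item in pairs:
        if isinstance(item, ConcordancePair):
            t = (
                item.test_vaf_unfiltered_percent
                if item.test_vaf_unfiltered_percent is not None
                else item.test_vaf_percent
            )
            x, y = item.ortho_vaf_percent, t
        else:
            x, y = item
        if include_zero_sides or (x > 0 and y > 0):
            xy.append((x, y))
    if len(xy) < 2:
        raise VariantModelError("VAF correlation requires >= 2 usable pairs")
    return linearity_fit([y for _, y in xy], [x for x, _ in xy])


@dataclass
class TimepointDelta:
    """Per-variant VAF change between paired pre/post-treatment reports."""

    key: VariantKey
    gene: str
    protein_change: str
    pre_vaf_percent: float
    post_vaf_percent: float

    @property
    def absolute_change(self) -> float:
        return self.post_vaf_percent - self.pre_vaf_percent

    @property
    def relative_change(self) -> Optional[float]:
        if self.pre_vaf_percent == 0:
            return None
        return self.absolute_change / self.pre_vaf_percent


def compare_timepoints(
    pre_report: Sequence[ReportedCall | VariantCall],
    post_report: Sequence[ReportedCall | VariantCall],
    patient_id: str | None = None,
) -> list[TimepointDelta]:
    """Per-variant VAF deltas between two timepoints of one patient.

    Variants detected at only one timepoint are retained with the other
    side at 0. A patient mismatch between the two reports is an error.
    """

    def as_calls(report) -> list[VariantCall]:
        return [r.call if isinstance(r, ReportedCall) else r for r in report]

    pre_calls, post_calls = as_calls(pre_report), as_calls(post_report)
    samples = {c.sample_id for c in pre_calls + post_calls if c.sample_id}
    if patient_id is not None:
        samples |= {patient_id}
    if len(samples) > 1:
        raise VariantModelError(f"timepoint reports mix patients: {sorted(samples)}")
    pre_by_key = {c.key: c for c in pre_calls}
    post_by_key = {c.key: c for c in post_calls}
    deltas = []
    for key in sorted(set(pre_by_key) | set(post_by_key)):
        pre_c, post_c = pre_by_key.get(key), post_by_key.get(key)
        ref = pre_c or post_c
        deltas.append(
            TimepointDelta(
                key=key,
                gene=ref.gene,
                protein_change=ref.protein_change,
                pre_vaf_percent=pre_c.vaf_percent if pre_c else 0.0,
                post_vaf_percent=post_c.vaf_percent if post_c else 0.0,
            )
        )
    return deltas


# ---------------------------------------------------------------------------
# Clinical variant-table rows (transcribed concordance fixture)
# ---------------------------------------------------------------------------


@dataclass
class ClinicalVariantRow:
    """One row of the clinical concordance variant table.

    ``test_vaf_reported_percent`` is the standard pipeline's reported VAF
    (0 when the vendor software filtered the call); for filtered calls
    ``test_vaf_unfiltered_percent`` carries the unfiltered-report VAF and
    ``filter_reason`` the rejection code (G, R, C, or PHI for "no reason
    provided"). ``clinical_in_ppa`` marks rows counted as clinically
    significant in the agreement tally.
    """

    gene: str
    cdna_change: str
    protein_change: str
    ortho_vaf_percent: float
    test_vaf_reported_percent: float
    test_vaf_unfiltered_percent: Optional[float]
    filter_reason: str  # "", "G", "R", "C", "PHI"
    below_ldt_cutoff: bool
    ortho_false_negative: bool
    classification: Classification
    tumor_type: str
    patient_id: str
    clinical_in_ppa: bool

    @property
    def effective_test_vaf(self) -> float:
        """Unfiltered VAF when the call was filtered, else the reported VAF."""
        if self.test_vaf_unfiltered_percent is not None:
            return self.test_vaf_unfiltered_percent
        return self.test_vaf_reported_percent


_REASON_TO_RESCUE_GATE = {"G": "germline", "R": "vaf", "C": "vaf", "PHI": "vaf"}


def row_detected_standard(row: ClinicalVariantRow) -> bool:
    """Detection under the vendor's standard reporting: the call appears in
    the filtered report (reported VAF > 0, including actionable calls below
    the LDT's 0.25% cutoff)."""
    return row.test_vaf_reported_percent > 0


def row_detected_ldt(row: ClinicalVariantRow, policy: LdtPolicy | None = None) -> bool:
    """Detection under the LDT pipeline, applied to the table row.

    Unfiltered calls are reported iff VAF >= the 0.25% cutoff. Filtered
    calls are rescued per the classification-aware rules (germline: any
    VAF; repeat/complex/unspecified: VAF >= 10%) and then subjected to the
    same cutoff.
    """
    policy = policy or LdtPolicy()
    if not row.filter_reason:
        return row.test_vaf_reported_percent >= policy.reporting_cutoff_percent
    if row.classification not in CLINICALLY_SIGNIFICANT:
        return False
    vaf = row.test_vaf_unfiltered_percent or 0.0
    gate = _REASON_TO_RESCUE_GATE.get(row.filter_reason)
    if gate == "germline":
        rescued = policy.germline_rescuable
    elif gate == "vaf":
        rescued = vaf >= policy.rescue_vaf_min_percent
    else:
        raise VariantModelError(f"unknown filter reason {row.filter_reason!r}")
    return rescued and vaf >= policy.reporting_cutoff_percent


def classify_variant_table(
    rows: Sequence[ClinicalVariantRow],
    pipeline: str = "ldt",
    llods: Llods | None = None,
    policy: LdtPolicy | None = None,
) -> list[tuple[ClinicalVariantRow, PairClass]]:
    """Assign a concordance class to every table row under one pipeline."""
    if pipeline not in {"standard", "ldt"}:
        raise VariantModelError(f"pipeline must be 'standard' or 'ldt', got {pipeline!r}")
    llods = llods or Llods()
    out = []
    for row in rows:
        ortho_pos = row.ortho_vaf_percent >= llods.ortho_percent
        if pipeline == "standard":
            test_pos = row_detected_standard(row)
        else:
            test_pos = row_detected_ldt(row, policy)
        if test_pos and ortho_pos:
            pc = PairClass.CONCORDANT_POSITIVE
        elif test_pos:
            pc = PairClass.TEST_ONLY
        elif ortho_pos:
            pc = PairClass.ORTHO_ONLY
        else:
            pc = PairClass.EXCLUDED_BELOW_LLOD
        out.append((row, pc))
    return out


def ppa_from_variant_table(
    rows: Sequence[ClinicalVariantRow],
    pipeline: str = "ldt",
    llods: Llods | None = None,
    policy: LdtPolicy | None = None,
) -> PpaResult:
    """Clinically significant PPA over the annotated variant table.

    Rows enter the tally iff flagged ``clinical_in_ppa``; detection status
    on each side is derived by applying the selected pipeline's rules to
    the row's VAFs, filter reason and classification.
    """
    classed = classify_variant_table(rows, pipeline=pipeline, llods=llods, policy=policy)
    tp = fn = 0
    for row, pc in classed:
        if not row.clinical_in_ppa:
            continue
        if pc is PairClass.CONCORDANT_POSITIVE:
            tp += 1
        elif pc is PairClass.ORTHO_ONLY:
            fn += 1
    if tp + fn == 0:
        raise UndefinedMetricError("PPA undefined on this table")
    return PpaResult(concordant=tp, ortho_only=fn)


def variant_table_correlation(
    rows: Sequence[ClinicalVariantRow],
    include_test_only_outliers: bool = False,
) -> LinearityFit:
    """VAF regression over the variant table under the documented rule.

    Pairs where either side is 0 are excluded (filtered test calls
    contribute their unfiltered VAF). Test-only detections the comparator
    missed entirely are excluded by default.
    """
    xy = []
    for row in rows:
        x, y = row.ortho_vaf_percent, row.effective_test_vaf
        if row.ortho_false_negative and not include_test_only_outliers:
            continue
        if x > 0 and y > 0:
            xy.append((x, y))
    return vaf_correlation(xy)
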