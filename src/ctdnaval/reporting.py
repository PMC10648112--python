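"""The modified clinical reporting pipeline of the laboratory-developed test.

The vendor's standard algorithm suppresses clinically relevant somatic
variants with high VAF as presumed germline, and indels in repeat or complex
contexts regardless of classification. The LDT pipeline instead starts from
the *unfiltered* variant report and applies, in order:

1. single-read removal (calls supported by fewer than ``min_alt_reads``);
2. classification-aware rescue of filtered calls -- pathogenic or likely
   pathogenic calls filtered as germline are retained at any VAF, and
   pathogenic or likely pathogenic calls filtered as RPT / CMPLX / with no
   stated reason are retained when VAF >= 10%;
3. a clinical reporting cutoff of VAF >= 0.25% for all variant classes.

Rescued germline-filtered calls carry a germline caveat for the report text
rather than being suppressed.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .variants import (
    CLINICALLY_SIGNIFICANT,
    Classification,
    FilterStatus,
    LibraryRun,
    VariantCall,
    VariantKey,
    VariantModelError,
)

logger = logging.getLogger(__name__)


class RescueProvenance(enum.Enum):
    NONE = "NONE"
    RESCUED_GERMLINE = "RESCUED_GERMLINE"
    RESCUED_RPT = "RESCUED_RPT"
    RESCUED_CMPLX = "RESCUED_CMPLX"
    RESCUED_UNSPECIFIED = "RESCUED_UNSPECIFIED"


_PROVENANCE_BY_FILTER = {
    FilterStatus.GRM: RescueProvenance.RESCUED_GERMLINE,
    FilterStatus.RPT: RescueProvenance.RESCUED_RPT,
    FilterStatus.CMPLX: RescueProvenance.RESCUED_CMPLX,
    FilterStatus.UNSPECIFIED: RescueProvenance.RESCUED_UNSPECIFIED,
}


@dataclass(frozen=True)
class LdtPolicy:
    """Parameters of the modified reporting pipeline.

    ``rescue_vaf_min_percent`` gates rescue of RPT/CMPLX/unspecified-filtered
    calls; germline-filtered pathogenic or likely pathogenic calls are
    rescued at any VAF when ``germline_rescuable``. The reporting cutoff is
    applied after rescue, to every variant class.
    """

    min_alt_reads: int = 2
    rescue_vaf_min_percent: float = 10.0
    reporting_cutoff_percent: float = 0.25
    rescuable_filters: frozenset[FilterStatus] = frozenset(
        {FilterStatus.RPT, FilterStatus.CMPLX, FilterStatus.UNSPECIFIED}
    )
    germline_rescuable: bool = True

    def __post_init__(self) -> None:
        if self.reporting_cutoff_percent <= 0:
            raise VariantModelError("reporting_cutoff_percent must be > 0")
        if self.rescue_vaf_min_percent <= self.reporting_cutoff_percent:
            raise VariantModelError("rescue VAF gate must exceed the reporting cutoff")
        if self.min_alt_reads < 1:
            raise VariantModelError("min_alt_reads must be >= 1")


@dataclass
class ReportedCall:
    """A call retained for the clinical report, with rescue provenance."""

    call: VariantCall
    rescue_provenance: RescueProvenance = RescueProvenance.NONE
    germline_flag: bool = False

    def __post_init__(self) -> None:
        if self.germline_flag != (
            self.rescue_provenance is RescueProvenance.RESCUED_GERMLINE
        ):
            raise VariantModelError(
                "germline_flag must mark exactly the germline-rescued calls"
            )
        if (
            self.rescue_provenance is not RescueProvenance.NONE
            and self.call.filter_status is FilterStatus.PASS
        ):
            raise VariantModelError("a PASS call cannot carry rescue provenance")


@dataclass
class ClinicalReport:
    """Sorted report rows plus warnings recorded during annotation."""

    rows: list[ReportedCall] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def keys(self) -> list[VariantKey]:
        return [r.call.key for r in self.rows]


def drop_single_read(
    calls: Iterable[VariantCall], policy: LdtPolicy | None = None
) -> list[VariantCall]:
    """Retain exactly the calls with alt_reads >= the policy minimum (default 2)."""
    policy = policy or LdtPolicy()
    return [c for c in calls if c.alt_reads >= policy.min_alt_reads]


def annotate_classifications(
    calls: Iterable[VariantCall],
    classifications: Mapping[VariantKey, Classification],
) -> tuple[list[VariantCall], list[str]]:
    """Attach classifications from a lookup table; unknown keys become UNCLASSIFIED.

    A filtered call missing from the table is recorded as a warning, since a
    missing classification can suppress a rescue.
    """
    annotated: list[VariantCall] = []
    warnings: list[str] = []
    for call in calls:
        cls = classifications.get(call.key)
        if cls is None:
            if call.filter_status is not FilterStatus.PASS:
                msg = f"no classification for filtered call {call.key}; treated as UNCLASSIFIED"
                warnings.append(msg)
                logger.warning(msg)
            annotated.append(call.with_classification(Classification.UNCLASSIFIED))
        else:
            annotated.append(call.with_classification(cls))
    return annotated, warnings


def rescue(
    calls: Iterable[VariantCall], policy: LdtPolicy | None = None
) -> list[ReportedCall]:
    """Apply the classification-aware rescue rules to an annotated call list.

    PASS calls pass through with provenance NONE. Germline-filtered calls
    are retained (any VAF) iff pathogenic or likely pathogenic. RPT, CMPLX
    and unspecified-filtered calls are retained iff pathogenic or likely
    pathogenic AND VAF >= the 10% rescue gate. Everything else is dropped.
    """
    policy = policy or LdtPolicy()
    out: list[ReportedCall] = []
    for call in calls:
        status = call.filter_status
        if status is FilterStatus.PASS:
            out.append(ReportedCall(call))
            continue
        clinical = call.classification in CLINICALLY_SIGNIFICANT
        if status is FilterStatus.GRM:
            if policy.germline_rescuable and clinical:
                out.append(
                    ReportedCall(call, RescueProvenance.RESCUED_GERMLINE, germline_flag=True)
                )
                logger.info("rescued germline-filtered %s at %.2f%% VAF", call.key, call.vaf_percent)
            else:
                logger.info("dropped GRM call %s (%s)", call.key, call.classification.value)
        elif status in policy.rescuable_filters:
            if clinical and call.vaf_percent >= policy.rescue_vaf_min_percent:
                out.append(ReportedCall(call, _PROVENANCE_BY_FILTER[status]))
                logger.info(
                    "rescued %s-filtered %s at %.2f%% VAF", status.value, call.key, call.vaf_percent
                )
            else:
                logger.info("dropped %s call %s", status.value, call.key)
        else:
            logger.info("dropped call %s with filter %s", call.key, status.value)
    return out


def apply_reporting_cutoff(
    reported: Iterable[ReportedCall], policy: LdtPolicy | None = None
) -> list[ReportedCall]:
    """Retain exactly the reported calls with VAF >= the clinical cutoff (inclusive)."""
    policy = policy or LdtPolicy()
    kept: list[ReportedCall] = []
    for row in reported:
        if row.call.vaf_percent >= policy.reporting_cutoff_percent:
            kept.append(row)
        else:
            logger.info(
                "suppressed %s at %.3f%% VAF (below %.2f%% reporting cutoff)",
                row.call.key,
                row.call.vaf_percent,
                policy.reporting_cutoff_percent,
            )
    return kept


def _sort_key(row: ReportedCall) -> tuple:
    k = row.call.key
    return (k.chrom, k.pos, k.alt)


def run_ldt_pipeline(
    unfiltered_run: LibraryRun | Sequence[VariantCall],
    classifications: Mapping[VariantKey, Classification] | None = None,
    policy: LdtPolicy | None = None,
) -> ClinicalReport:
    """Full LDT reporting pipeline on an unfiltered-dialect call set.

    Composition: single-read removal -> classification annotation ->
    rescue -> reporting cutoff. Rows are sorted by (chrom, pos, alt). The
    pipeline is idempotent: running it on the calls of its own report
    changes nothing.
    """
    policy = policy or LdtPolicy()
    calls = unfiltered_run.calls if isinstance(unfiltered_run, LibraryRun) else list(unfiltered_run)
    calls = drop_single_read(calls, policy)
    warnings: list[str] = []
    if classifications is not None:
        calls, warnings = annotate_classifications(calls, classifications)
    rows = apply_reporting_cutoff(rescue(calls, policy), policy)
    rows.sort(key=_sort_key)
    return ClinicalReport(rows=rows, warnings=warnings)
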