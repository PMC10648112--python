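"""Core variant domain model: keys, calls, truth variants, library runs.

Coordinates are 1-based, VCF-style, with an anchor base for indels. VAFs are
carried on the 0-100 percent scale throughout the package; fractional views
are derived where a computation needs them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

_DNA = frozenset("ACGT")


class VariantType(enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class FilterStatus(enum.Enum):
    """FILTER annotation on a call.

    PASS calls appear in the filtered report. GRM (presumed germline),
    RPT (near or within a repeat region) and CMPLX (complex representation)
    are vendor rejection codes seen only in the unfiltered report.
    UNSPECIFIED marks a call rejected with no reason given in the FILTER
    column.
    """

    PASS = "PASS"
    GRM = "GRM"
    RPT = "RPT"
    CMPLX = "CMPLX"
    UNSPECIFIED = "UNSPECIFIED"


class Classification(enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    VUS = "VUS"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    BENIGN = "BENIGN"
    UNCLASSIFIED = "UNCLASSIFIED"


#: Classifications that make a call eligible for rescue and count as
#: "clinically significant" in agreement statistics.
CLINICALLY_SIGNIFICANT = frozenset(
    {Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC}
)

#: Classifications counted as false positives in specificity/PPV tallies.
FP_CLASSIFICATIONS = frozenset(
    {Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC, Classification.VUS}
)


class HotspotTier(enum.Enum):
    """Reporting tier of a position under the vendor's standard cutoffs."""

    ACTIONABLE = "ACTIONABLE"
    COSMIC_HOTSPOT = "COSMIC_HOTSPOT"
    OTHER = "OTHER"


class VariantModelError(ValueError):
    """Invalid variant-domain value or operation."""


class RepresentationError(VariantModelError):
    """Variant representation disagrees with the reference context."""


class AmbiguityError(VariantModelError):
    """Duplicate identical variant keys where uniqueness is required."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Genomic identity of a variant: (chrom, pos, ref, alt).

    pos is 1-based. For indels the key is expected to be left-aligned and
    parsimony-reduced (single shared anchor base); :func:`normalize_variant`
    produces that canonical form.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantModelError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise VariantModelError("ref and alt must be nonempty")
        if self.ref == self.alt:
            raise VariantModelError(f"ref == alt ({self.ref}) is not a variant")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _DNA:
                raise VariantModelError(f"allele {allele!r} not drawn from ACGT")

    @property
    def variant_type(self) -> VariantType:
        return VariantType.SNV if len(self.ref) == len(self.alt) == 1 else VariantType.INDEL

    @property
    def is_indel(self) -> bool:
        return self.variant_type is VariantType.INDEL

    def __str__(self) -> str:  # chr17:7579420 CC>C
        return f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"


@dataclass(frozen=True)
class ReferenceContext:
    """A window of reference sequence anchored at a 1-based start position."""

    chrom: str
    start: int  # 1-based genomic position of seq[0]
    seq: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise VariantModelError("context start must be >= 1")
        if not set(self.seq) <= _DNA:
            raise VariantModelError("context sequence must be ACGT only")

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def covers(self, pos: int, length: int = 1) -> bool:
        return self.start <= pos and pos + length - 1 <= self.end

    def base(self, pos: int) -> str:
        if not self.covers(pos):
            raise VariantModelError(f"position {pos} outside context [{self.start},{self.end}]")
        return self.seq[pos - self.start]

    def slice(self, pos: int, length: int) -> str:
        if not self.covers(pos, length):
            raise VariantModelError(
                f"interval [{pos},{pos + length - 1}] outside context [{self.start},{self.end}]"
            )
        return self.seq[pos - self.start : pos - self.start + length]


@dataclass
class VariantCall:
    """One observed variant in one library."""

    key: VariantKey
    sample_id: str = ""
    gene: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    vaf_percent: float = 0.0
    alt_reads: int = 0
    depth: int = 0
    filter_status: FilterStatus = FilterStatus.PASS
    classification: Classification = Classification.UNCLASSIFIED
    hotspot_tier: HotspotTier = HotspotTier.OTHER

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_percent <= 100.0:
            raise VariantModelError(f"vaf_percent {self.vaf_percent} outside [0, 100]")
        if self.alt_reads < 0 or self.depth < 0:
            raise VariantModelError("read counts must be nonnegative")
        if self.alt_reads > self.depth:
            raise VariantModelError(
                f"alt_reads {self.alt_reads} exceeds depth {self.depth} at {self.key}"
            )

    @property
    def variant_type(self) -> VariantType:
        return self.key.variant_type

    def with_classification(self, classification: Classification) -> "VariantCall":
        return replace(self, classification=classification)


@dataclass(frozen=True)
class TruthVariant:
    """A known variant of a reference-standard truth panel at one VAF tier."""

    key: VariantKey
    gene: str
    homopolymer_context: bool = False
    expected_vaf_percent: float = 0.0
    context: Optional[ReferenceContext] = None

    _TIERS = (2.0, 1.0, 0.5, 0.25, 0.125, 0.0)

    def __post_init__(self) -> None:
        if self.expected_vaf_percent not in self._TIERS:
            raise VariantModelError(
                f"expected_vaf_percent {self.expected_vaf_percent} not a dilution tier"
            )

    @property
    def variant_type(self) -> VariantType:
        return self.key.variant_type

    def at_tier(self, tier_vaf_percent: float) -> "TruthVariant":
        return TruthVariant(
            key=self.key,
            gene=self.gene,
            homopolymer_context=self.homopolymer_context,
            expected_vaf_percent=tier_vaf_percent,
            context=self.context,
        )


@dataclass
class LibraryRun:
    """One sequenced library and its variant calls."""

    library_id: str
    sample_id: str = ""
    input_ng: Optional[int] = None
    operator_id: str = ""
    run_id: str = ""
    tier_vaf_percent: Optional[float] = None
    calls: list[VariantCall] = field(default_factory=list)

    def calls_by_key(self) -> dict[VariantKey, VariantCall]:
        out: dict[VariantKey, VariantCall] = {}
        for call in self.calls:
            if call.key in out:
                raise AmbiguityError(f"duplicate call for {call.key} in {self.library_id}")
            out[call.key] = call
        return out


def normalize_variant(key: VariantKey, reference_context: ReferenceContext) -> VariantKey:
    """Return the canonical left-aligned, parsimony-reduced form of ``key``.

    Uses the standard left-alignment procedure: shared trailing bases are
    trimmed (re-reading reference sequence on the left when an allele would
    empty), then shared leading bases beyond the single indel anchor are
    trimmed. Idempotent: normalizing a canonical key returns it unchanged.

    Raises :class:`RepresentationError` when the ref allele disagrees with
    the reference context.
    """
    if reference_context.chrom != key.chrom:
        raise RepresentationError(
            f"context chrom {reference_context.chrom} != key chrom {key.chrom}"
        )
    if not reference_context.covers(key.pos, len(key.ref)):
        raise RepresentationError(f"context does not cover {key}")
    if reference_context.slice(key.pos, len(key.ref)) != key.ref:
        raise RepresentationError(
            f"ref allele {key.ref} disagrees with reference at {key.chrom}:{key.pos}"
        )

    pos, ref, alt = key.pos, key.ref, key.alt
    changed = True
    while changed:
        changed = False
        # trim shared trailing base
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        # an emptied allele: extend both to the left with the reference base
        if not ref or not alt:
            if pos <= reference_context.start:
                raise RepresentationError(
                    f"context too short to left-align {key} (need base left of {pos})"
                )
            pos -= 1
            left = reference_context.base(pos)
            ref, alt = left + ref, left + alt
            changed = True
    # trim shared leading bases down to a single anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # pure SNV/MNV residue: no anchor base needed
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    if len(ref) != len(alt) and len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(key.chrom, pos, ref, alt)


@dataclass
class MatchResult:
    """Partition of two call sets into matched pairs and per-side residue."""

    pairs: list[tuple[VariantCall, VariantCall]]
    only_a: list[VariantCall]
    only_b: list[VariantCall]


def match_calls(
    set_a: Sequence[VariantCall] | Iterable[VariantCall],
    set_b: Sequence[VariantCall] | Iterable[VariantCall],
) -> MatchResult:
    """Match calls between two sets on normalized (chrom, pos, ref, alt).

    Keys are assumed already normalized. Each call is matched at most once;
    the pairs plus the two residues form an exhaustive partition. Duplicate
    identical keys within one set raise :class:`AmbiguityError`.
    """
    a_list, b_list = list(set_a), list(set_b)
    by_key_a: dict[VariantKey, VariantCall] = {}
    for call in a_list:
        if call.key in by_key_a:
            raise AmbiguityError(f"duplicate key {call.key} in first call set")
        by_key_a[call.key] = call
    by_key_b: dict[VariantKey, VariantCall] = {}
    for call in b_list:
        if call.key in by_key_b:
            raise AmbiguityError(f"duplicate key {call.key} in second call set")
        by_key_b[call.key] = call

    pairs = [(by_key_a[k], by_key_b[k]) for k in by_key_a if k in by_key_b]
    only_a = [c for c in a_list if c.key not in by_key_b]
    only_b = [c for c in b_list if c.key not in by_key_a]
    return MatchResult(pairs=pairs, only_a=only_a, only_b=only_b)


_CLASSIFICATION_ALIASES = {
    "PATH.": Classification.PATHOGENIC,
    "PATH": Classification.PATHOGENIC,
    "PATHOGENIC": Classification.PATHOGENIC,
    "LIK. PATH.": Classification.LIKELY_PATHOGENIC,
    "LIK. PATH": Classification.LIKELY_PATHOGENIC,
    "LIK.PATH.": Classification.LIKELY_PATHOGENIC,
    "LIKELY_PATHOGENIC": Classification.LIKELY_PATHOGENIC,
    "UNC. SIG.": Classification.VUS,
    "UNC. SIG": Classification.VUS,
    "VUS": Classification.VUS,
    "LIK.BEN.": Classification.LIKELY_BENIGN,
    "LIK. BEN.": Classification.LIKELY_BENIGN,
    "LIKELY_BENIGN": Classification.LIKELY_BENIGN,
    "BENIGN": Classification.BENIGN,
    "UNCLASSIFIED": Classification.UNCLASSIFIED,
    "": Classification.UNCLASSIFIED,
}


def parse_classification(text: str) -> Classification:
    """Parse a classification label, accepting clinical-report shorthand."""
    try:
        return _CLASSIFICATION_ALIASES[text.strip().upper()]
    except KeyError:
        raise VariantModelError(f"unknown classification label {text!r}") from None
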