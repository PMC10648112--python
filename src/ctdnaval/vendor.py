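"""Emulation of the vendor pipeline's standard reporting rules.

Two behaviours of the commercial analysis software are modelled because the
simulator and the standard-pipeline concordance arm depend on them: the
tiered VAF reporting cutoffs (actionable / COSMIC-hotspot / all other
positions) and the homopolymer repeat filter applied to indels. The vendor's
germline filter has no published criteria, so GRM status is never derived
here -- it is read from input FILTER fields or assigned by the simulator's
generative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .variants import (
    HotspotTier,
    FilterStatus,
    ReferenceContext,
    TruthVariant,
    VariantCall,
    VariantKey,
    VariantModelError,
)


@dataclass(frozen=True)
class ReportingPolicy:
    """Standard vendor reporting cutoffs, in percent VAF.

    Defaults: clinically actionable variants are called down to 0.1% VAF,
    COSMIC hotspots are reported at or above 0.3%, and all other panel
    positions at or above 0.5%. Insertions/deletions in homopolymers of
    at least ``homopolymer_min_len`` bases are suppressed as RPT.
    """

    cutoff_actionable_percent: float = 0.1
    cutoff_hotspot_percent: float = 0.3
    cutoff_other_percent: float = 0.5
    homopolymer_min_len: int = 4

    def __post_init__(self) -> None:
        if not (
            self.cutoff_actionable_percent
            <= self.cutoff_hotspot_percent
            <= self.cutoff_other_percent
        ):
            raise VariantModelError("cutoffs must be ordered actionable <= hotspot <= other")
        if self.homopolymer_min_len < 1:
            raise VariantModelError("homopolymer_min_len must be >= 1")

    def cutoff_for(self, tier: HotspotTier) -> float:
        if tier is HotspotTier.ACTIONABLE:
            return self.cutoff_actionable_percent
        if tier is HotspotTier.COSMIC_HOTSPOT:
            return self.cutoff_hotspot_percent
        return self.cutoff_other_percent


def standard_cutoff(call: VariantCall, policy: ReportingPolicy | None = None) -> bool:
    """True iff the call's VAF meets its tier's cutoff (inclusive boundary)."""
    policy = policy or ReportingPolicy()
    return call.vaf_percent >= policy.cutoff_for(call.hotspot_tier)


def _indel_event(key: VariantKey) -> tuple[str, str] | None:
    """Return (kind, bases) for a simple anchored indel key, else None.

    kind is "ins" or "del"; bases are the inserted or deleted sequence.
    """
    if len(key.ref) == 1 and len(key.alt) > 1 and key.alt[0] == key.ref:
        return "ins", key.alt[1:]
    if len(key.alt) == 1 and len(key.ref) > 1 and key.ref[0] == key.alt:
        return "del", key.ref[1:]
    if len(key.ref) != len(key.alt):
        # complex indel (e.g. delins); not a pure homopolymer event
        return "complex", ""
    return None


def homopolymer_run_length(context: ReferenceContext, pos: int, base: str) -> int:
    """Length of the reference run of ``base`` adjacent to anchor ``pos``.

    Counts contiguous copies of ``base`` ending at ``pos`` (leftwards) plus
    contiguous copies starting at ``pos + 1`` (rightwards). For a
    left-aligned indel key this is the run the event inserts into or
    deletes from.
    """
    run = 0
    p = pos
    while context.covers(p) and context.base(p) == base:
        run += 1
        p -= 1
    p = pos + 1
    while context.covers(p) and context.base(p) == base:
        run += 1
        p += 1
    return run


def homopolymer_filter(
    variant: TruthVariant | VariantCall | VariantKey,
    context: ReferenceContext | None = None,
    policy: ReportingPolicy | None = None,
) -> FilterStatus:
    """RPT for an indel in a homopolymer run of >= the policy minimum, else PASS.

    SNVs always PASS. A pure function of the allele and its local reference
    context. ``context`` may be omitted when ``variant`` is a TruthVariant
    carrying its own embedded context.
    """
    policy = policy or ReportingPolicy()
    key = variant if isinstance(variant, VariantKey) else variant.key
    if context is None and isinstance(variant, TruthVariant):
        context = variant.context
    if key.variant_type.value == "SNV":
        return FilterStatus.PASS
    if context is None:
        raise VariantModelError(f"no reference context supplied for indel {key}")
    if not context.covers(key.pos):
        raise VariantModelError(f"context does not cover indel locus {key}")

    event = _indel_event(key)
    if event is None or event[0] == "complex":
        return FilterStatus.PASS
    _, bases = event
    if len(set(bases)) != 1:
        return FilterStatus.PASS  # multi-base event, not a homopolymer slide
    run = homopolymer_run_length(context, key.pos, bases[0])
    if run >= policy.homopolymer_min_len:
        return FilterStatus.RPT
    return FilterStatus.PASS
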