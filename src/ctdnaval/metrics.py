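"""Analytical-performance statistics over reference-standard runs.

Tiered sensitivity, specificity, positive predictive value, the
tier-discrete 95% limit of detection, per-allele linearity, replicate
concordance, and one-way ANOVA of replicate VAFs across DNA input amounts.
All count-ratio metrics are exact fractions of their integer tallies.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .reporting import LdtPolicy
from .variants import (
    FP_CLASSIFICATIONS,
    FilterStatus,
    LibraryRun,
    TruthVariant,
    VariantCall,
    VariantKey,
    VariantModelError,
    VariantType,
)

#: Sentinel returned by :func:`lod95` when no tier reaches 95% detection.
NOT_REACHED = "NOT_REACHED"

#: A predicate deciding whether a call counts as detected/reportable.
ReportableRule = Callable[[VariantCall], bool]


def ldt_reportable(call: VariantCall, policy: LdtPolicy | None = None) -> bool:
    """Detection rule of the LDT on unfiltered reference-standard calls.

    A call counts as detected when it survives single-read removal and the
    0.25% reporting cutoff and is not suppressed by a vendor filter (truth
    variants in reference standards carry no pathogenicity rescue context,
    so filtered calls count as undetected).
    """
    policy = policy or LdtPolicy()
    return (
        call.filter_status is FilterStatus.PASS
        and call.alt_reads >= policy.min_alt_reads
        and call.vaf_percent >= policy.reporting_cutoff_percent
    )


class UndefinedMetricError(VariantModelError):
    """Metric requested on an empty denominator."""


@dataclass
class DetectionCount:
    """Detected/total tally for one (variant type, tier, input) cell."""

    variant_type: VariantType
    tier_vaf_percent: float
    input_ng: Optional[int]
    detected: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.detected <= self.total:
            raise VariantModelError(
                f"detected {self.detected} outside [0, total={self.total}]"
            )

    @property
    def ratio(self) -> float:
        return sensitivity(self)


def sensitivity(counts: DetectionCount) -> float:
    """TP / (TP + FN), i.e. detected/total for a tally cell."""
    if counts.total == 0:
        raise UndefinedMetricError("sensitivity undefined for total = 0")
    return counts.detected / counts.total


def tally_detections(
    runs: Iterable[LibraryRun],
    truth: Sequence[TruthVariant],
    reportable: ReportableRule = ldt_reportable,
) -> list[DetectionCount]:
    """Tally truth-variant detections across replicate reference runs.

    A truth variant counts as detected in a run iff a call matching its key
    is reportable under ``reportable``. Rows are grouped by
    (variant_type, tier, input_ng); totals are data-driven:
    (panel variants of that type) x (replicate runs in the group).
    """
    detected: dict[tuple, int] = defaultdict(int)
    total: dict[tuple, int] = defaultdict(int)
    for run in runs:
        if run.tier_vaf_percent is None:
            raise VariantModelError(f"run {run.library_id} lacks a tier annotation")
        calls = {c.key: c for c in run.calls}
        for tv in truth:
            group = (tv.variant_type, run.tier_vaf_percent, run.input_ng)
            total[group] += 1
            call = calls.get(tv.key)
            if call is not None and reportable(call):
                detected[group] += 1
    rows = [
        DetectionCount(vt, tier, ng, detected[(vt, tier, ng)], tot)
        for (vt, tier, ng), tot in total.items()
    ]
    rows.sort(key=lambda r: (r.variant_type.value, -r.tier_vaf_percent, r.input_ng or 0))
    return rows


@dataclass
class SpecificityResult:
    tn: int
    fp: int

    @property
    def ratio(self) -> float:
        return self.tn / (self.tn + self.fp)


def specificity(
    wt_runs: Sequence[LibraryRun],
    truth: Sequence[TruthVariant],
    reportable: ReportableRule = ldt_reportable,
) -> SpecificityResult:
    """TN / (TN + FP) over wild-type (0% tier) replicate libraries.

    TN counts truth-panel positions with no reportable call, summed over
    libraries; FP counts reportable calls classified pathogenic, likely
    pathogenic or VUS that are not in the truth panel.
    """
    wt_runs = list(wt_runs)
    if not wt_runs:
        raise UndefinedMetricError("specificity requires at least one wild-type run")
    truth_keys = {tv.key for tv in truth}
    tn = 0
    fp = 0
    for run in wt_runs:
        called = {c.key for c in run.calls if reportable(c)}
        tn += sum(1 for k in truth_keys if k not in called)
        fp += sum(
            1
            for c in run.calls
            if reportable(c)
            and c.key not in truth_keys
            and c.classification in FP_CLASSIFICATIONS
        )
    return SpecificityResult(tn=tn, fp=fp)


def ppv(tp: int, fp: int) -> float:
    """TP / (TP + FP). TP pools detections across positive tiers and replicates."""
    if tp + fp == 0:
        raise UndefinedMetricError("PPV undefined for TP + FP = 0")
    return tp / (tp + fp)


def lod95(
    sensitivity_by_tier: Mapping[float, float] | Sequence[DetectionCount],
    threshold: float = 0.95,
) -> float | str:
    """Tier-discrete 95% limit of detection.

    Returns the smallest tested VAF tier whose sensitivity is >= the
    threshold, provided every larger tested tier also reaches it;
    :data:`NOT_REACHED` when no tier qualifies.
    """
    if not isinstance(sensitivity_by_tier, Mapping):
        rows = list(sensitivity_by_tier)
        sensitivity_by_tier = {r.tier_vaf_percent: sensitivity(r) for r in rows}
    if not sensitivity_by_tier:
        raise VariantModelError("lod95 requires at least one tier")
    tiers = sorted(sensitivity_by_tier, reverse=True)  # largest first
    lod: float | str = NOT_REACHED
    for tier in tiers:
        if sensitivity_by_tier[tier] >= threshold:
            lod = tier
        else:
            break  # a failing tier invalidates any smaller one
    return lod


@dataclass
class LinearityFit:
    """Ordinary least squares of observed on expected VAF, percent scale."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise VariantModelError("linearity fit requires >= 2 points")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise VariantModelError(f"r_squared {self.r_squared} outside [0, 1]")


def linearity_fit(
    observed_vaf_percent: Sequence[float], expected_vaf_percent: Sequence[float]
) -> LinearityFit:
    """Fit observed mean VAFs against expected tier values for one allele."""
    obs = np.asarray(observed_vaf_percent, dtype=float)
    exp = np.asarray(expected_vaf_percent, dtype=float)
    if obs.shape != exp.shape or obs.size < 2:
        raise VariantModelError("linearity fit needs matching arrays with >= 2 tiers")
    if np.ptp(exp) == 0:
        raise VariantModelError("expected tiers are all identical")
    res = stats.linregress(exp, obs)
    rvalue = 0.0 if np.isnan(res.rvalue) else res.rvalue  # constant observed -> no correlation
    return LinearityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(rvalue**2),
        n_points=int(obs.size),
    )


def replicate_concordance(
    run_a: LibraryRun,
    run_b: LibraryRun,
    truth: Sequence[TruthVariant],
    reportable: ReportableRule = ldt_reportable,
) -> float:
    """Fraction of truth-panel variants with identical detection status in both runs."""
    if run_a.tier_vaf_percent != run_b.tier_vaf_percent:
        raise VariantModelError(
            f"tier mismatch: {run_a.tier_vaf_percent} vs {run_b.tier_vaf_percent}"
        )
    if not truth:
        raise VariantModelError("empty truth panel")
    calls_a = {c.key: c for c in run_a.calls}
    calls_b = {c.key: c for c in run_b.calls}

    def status(calls: dict[VariantKey, VariantCall], tv: TruthVariant) -> bool:
        call = calls.get(tv.key)
        return call is not None and reportable(call)

    agree = sum(1 for tv in truth if status(calls_a, tv) == status(calls_b, tv))
    return agree / len(truth)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    group_sizes: list[int] = field(default_factory=list)


def input_anova(vafs_by_input: Mapping[int, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA of replicate VAFs across input-mass groups.

    Degenerate data (all groups identical constants, zero variance
    everywhere) is reported as F = 0, p = 1: no evidence of a group effect.
    """
    groups = {ng: np.asarray(v, dtype=float) for ng, v in vafs_by_input.items()}
    if len(groups) < 2:
        raise VariantModelError("ANOVA requires >= 2 input groups")
    for ng, values in groups.items():
        if values.size < 2:
            raise VariantModelError(f"group {ng} ng has < 2 replicates")
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return AnovaResult(0.0, 1.0, [a.size for a in arrays])
    f_stat, p_val = stats.f_oneway(*arrays)
    return AnovaResult(float(f_stat), float(p_val), [a.size for a in arrays])


def detection_probability(
    tier_vaf_percent: float,
    depth: int,
    recovery_beta: float = 1.0,
    min_alt_reads: int = 2,
    cutoff_percent: float = 0.25,
) -> float:
    """Closed-form per-variant detection probability under binomial sampling.

    P(X >= max(min_alt_reads, ceil(cutoff * depth / 100))) with
    X ~ Binomial(depth, tier * beta / 100): the analytic benchmark the
    simulator's empirical sensitivity must match.
    """
    if depth <= 0:
        raise VariantModelError("depth must be positive")
    p = tier_vaf_percent * recovery_beta / 100.0
    if p <= 0:
        return 0.0
    k_min = max(min_alt_reads, int(np.ceil(cutoff_percent * depth / 100.0)))
    return float(stats.binom.sf(k_min - 1, depth, p))
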