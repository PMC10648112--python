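"""Synthetic data generators with the statistical structure the analysis assumes.

Two generators are provided. ``simulate_library`` emulates a tiered
reference-standard library: per truth variant, unique-read depth is drawn
around the input-mass-specific median (negative-binomial overdispersion),
supporting reads are binomial in the tier allele fraction times a template
recovery factor, and the two homopolymer indels are always emitted with the
vendor RPT filter. False positives arrive as a Poisson stream of low-VAF
calls. ``simulate_clinical_cohort`` builds paired test/comparator clinical
call sets with known truth, including germline-looking high-VAF somatic
variants flagged GRM on the test side -- the situation the rescue rules
exist for.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .concordance import ORTHO_UNCOVERED_GENES, TEST_PANEL_GENES
from .fixtures import load_reference_indels
from .reporting import LdtPolicy, run_ldt_pipeline
from .vendor import ReportingPolicy, homopolymer_filter, standard_cutoff
from .variants import (
    Classification,
    FilterStatus,
    LibraryRun,
    ReferenceContext,
    TruthVariant,
    VariantCall,
    VariantKey,
    VariantModelError,
)

DILUTION_TIERS = (2.0, 1.0, 0.5, 0.25, 0.125, 0.0)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generative model.

    ``depth_median_by_input`` defaults to the measured median unique-read
    depths per DNA input mass. ``depth_dispersion`` is the negative-binomial
    overdispersion (variance = m + dispersion * m^2; 0 gives constant
    depth). ``recovery_beta`` scales the tier allele fraction for imperfect
    template representation. False positives arrive at
    ``fp_rate_per_library`` (Poisson mean) with exponentially distributed
    VAFs of scale ``fp_vaf_scale_percent``, so roughly 70% fall below the
    0.25% reporting cutoff.
    """

    depth_median_by_input: Mapping[int, int] = field(
        default_factory=lambda: {30: 3841, 40: 4400, 50: 5069, 60: 5130}
    )
    depth_dispersion: float = 0.1
    recovery_beta: float = 1.0
    fp_rate_per_library: float = 0.68
    fp_vaf_scale_percent: float = 0.2
    germline_vaf_mean: float = 50.0
    germline_vaf_sd: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.recovery_beta <= 1:
            raise VariantModelError("recovery_beta must be in (0, 1]")
        if self.depth_dispersion < 0 or self.fp_rate_per_library < 0:
            raise VariantModelError("rates must be nonnegative")

    def median_depth(self, input_ng: int) -> int:
        try:
            return self.depth_median_by_input[input_ng]
        except KeyError:
            raise VariantModelError(f"no depth median configured for {input_ng} ng") from None


# Fixed truth-panel loci: 15 SNVs and 7 non-homopolymer indels on panel
# genes (synthetic coordinates); the 2 published homopolymer indels are
# appended from the fixture. Indel context strings are constructed so that
# no adjacent homopolymer run reaches 4 bp.
_PANEL_SNVS = [
    ("AKT1", "chr14", 105246551, "C", "T"),
    ("ALK", "chr2", 29443695, "G", "A"),
    ("BRAF", "chr7", 140453136, "A", "T"),
    ("EGFR", "chr7", 55259515, "T", "G"),
    ("ERBB2", "chr17", 37880220, "T", "C"),
    ("ESR1", "chr6", 152419923, "A", "G"),
    ("IDH1", "chr2", 209113112, "C", "T"),
    ("KIT", "chr4", 55599321, "A", "C"),
    ("KRAS", "chr12", 25398284, "C", "A"),
    ("MET", "chr7", 116411990, "G", "T"),
    ("NRAS", "chr1", 115256529, "T", "C"),
    ("PIK3CA", "chr3", 178936091, "G", "A"),
    ("RET", "chr10", 43609994, "G", "T"),
    ("ROS1", "chr6", 117645578, "C", "G"),
    ("TP53", "chr17", 7577120, "G", "A"),
]

_PANEL_PLAIN_INDELS = [
    # (gene, chrom, pos, ref, alt, context window around pos)
    ("APC", "chr5", 112174631, "ATG", "A", "GACTGATGCATAGCTGACTG"),
    ("ATM", "chr11", 108117787, "G", "GCT", "ATCCAGTCGATGCACTGATC"),
    ("BRCA1", "chr17", 41245466, "TAC", "T", "GGATCTACGTCATGCAGTGA"),
    ("BRCA2", "chr13", 32914437, "GT", "G", "CAGTCAGTCACGATGCATCA"),
    ("CDH1", "chr16", 68847301, "C", "CAG", "TGACTCAGTCATGACTGACT"),
    ("EGFR", "chr7", 55242464, "AGGAATTAAGAGAAGC", "A", "CATCTCCGAAAGCCAACAAGGAAATCCTCGATG"),
    ("FGFR2", "chr10", 123279562, "CT", "C", "AGTCACTGCATCAGTGATCG"),
]


def _plain_indel_truth(gene, chrom, pos, ref, alt, window) -> TruthVariant:
    # centre the supplied window on the anchor position
    start = pos - len(window) // 2
    idx = pos - start
    seq = window[:idx] + ref + window[idx + len(ref) :]
    # pad to keep the original window length
    seq = seq[: len(window)] if len(seq) >= len(window) else seq + window[len(seq) :]
    context = ReferenceContext(chrom=chrom, start=start, seq=seq)
    return TruthVariant(
        key=VariantKey(chrom, pos, ref, alt),
        gene=gene,
        homopolymer_context=False,
        expected_vaf_percent=0.0,
        context=context,
    )


def make_reference_panel(seed: int = 0) -> list[TruthVariant]:
    """Deterministic 24-variant truth panel: 15 SNVs and 9 indels.

    Exactly two indels sit in homopolymer context >= 4 bp -- the published
    APC insertion (6 bp A run) and TP53 deletion (5 bp C run) -- and are
    the ones the vendor repeat filter permanently suppresses. The panel is
    identical for every seed; the argument is accepted for interface
    uniformity with the other generators.
    """
    del seed
    panel = [
        TruthVariant(key=VariantKey(chrom, pos, ref, alt), gene=gene)
        for gene, chrom, pos, ref, alt in _PANEL_SNVS
    ]
    panel += [_plain_indel_truth(*spec) for spec in _PANEL_PLAIN_INDELS]
    panel += load_reference_indels()
    return panel


def _draw_depth(rng: np.random.Generator, mean: int, dispersion: float) -> int:
    if dispersion <= 0:
        return int(mean)
    r = 1.0 / dispersion
    depth = int(rng.negative_binomial(r, r / (r + mean)))
    return max(depth, 1)


_FP_GENES = sorted(TEST_PANEL_GENES)


def simulate_library(
    panel: Sequence[TruthVariant],
    tier_vaf_percent: float,
    input_ng: int,
    params: SimulationParams | None = None,
    seed: int = 0,
    library_id: str | None = None,
    operator_id: str = "op1",
    run_id: str = "run1",
    vendor_policy: ReportingPolicy | None = None,
) -> LibraryRun:
    """Simulate one unfiltered-dialect reference-standard library.

    Per truth variant: depth ~ NB around the input-mass median, alt reads ~
    Binomial(depth, tier * recovery_beta / 100), VAF = 100 * alt / depth.
    Variants with at least one supporting read become calls; homopolymer
    indels are flagged RPT by the vendor repeat filter, everything else
    PASS. Injected false positives are low-VAF PASS calls classified VUS
    or (less often) pathogenic. Fully reproducible from the seed.
    """
    params = params or SimulationParams()
    vendor_policy = vendor_policy or ReportingPolicy()
    if tier_vaf_percent not in DILUTION_TIERS:
        raise VariantModelError(f"tier {tier_vaf_percent} not in {DILUTION_TIERS}")
    mean_depth = params.median_depth(input_ng)
    rng = np.random.default_rng(seed)
    sample_id = f"RS-{tier_vaf_percent:g}pct"
    calls: list[VariantCall] = []
    p_alt = tier_vaf_percent * params.recovery_beta / 100.0
    for tv in panel:
        depth = _draw_depth(rng, mean_depth, params.depth_dispersion)
        alt = int(rng.binomial(depth, p_alt)) if p_alt > 0 else 0
        if alt == 0:
            continue
        status = homopolymer_filter(tv, policy=vendor_policy)
        calls.append(
            VariantCall(
                key=tv.key,
                sample_id=sample_id,
                gene=tv.gene,
                vaf_percent=100.0 * alt / depth,
                alt_reads=alt,
                depth=depth,
                filter_status=status,
            )
        )
    # Poisson stream of low-VAF false positives at synthetic off-panel loci
    n_fp = int(rng.poisson(params.fp_rate_per_library))
    truth_keys = {tv.key for tv in panel}
    for i in range(n_fp):
        gene = _FP_GENES[int(rng.integers(len(_FP_GENES)))]
        ref = "ACGT"[int(rng.integers(4))]
        alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(3))) % 4]
        pos = int(1_000_000 + rng.integers(1, 500_000))
        key = VariantKey("chr20", pos, ref, alt)
        while key in truth_keys:
            key = VariantKey(key.chrom, key.pos + 1, key.ref, key.alt)
        depth = _draw_depth(rng, mean_depth, params.depth_dispersion)
        vaf = float(rng.exponential(params.fp_vaf_scale_percent))
        alt = max(1, int(round(vaf * depth / 100.0)))
        calls.append(
            VariantCall(
                key=key,
                sample_id=sample_id,
                gene=gene,
                vaf_percent=100.0 * alt / depth,
                alt_reads=alt,
                depth=depth,
                filter_status=FilterStatus.PASS,
                classification=(
                    Classification.VUS if rng.random() < 0.8 else Classification.PATHOGENIC
                ),
            )
        )
    return LibraryRun(
        library_id=library_id or f"sim-{tier_vaf_percent:g}-{input_ng}ng-{seed}",
        sample_id=sample_id,
        input_ng=input_ng,
        operator_id=operator_id,
        run_id=run_id,
        tier_vaf_percent=tier_vaf_percent,
        calls=calls,
    )


def simulate_replicates(
    panel: Sequence[TruthVariant],
    tiers: Sequence[float],
    input_ng_list: Sequence[int],
    replicates: int,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> list[LibraryRun]:
    """Replicate design: ``replicates`` libraries per (tier, input) cell."""
    seq = np.random.SeedSequence(seed)
    runs = []
    children = iter(seq.spawn(len(tiers) * len(input_ng_list) * replicates))
    for tier in tiers:
        for ng in input_ng_list:
            for rep in range(replicates):
                child_seed = int(next(children).generate_state(1)[0] % (2**31))
                runs.append(
                    simulate_library(
                        panel,
                        tier,
                        ng,
                        params,
                        seed=child_seed,
                        library_id=f"sim-{tier:g}-{ng}ng-r{rep + 1}",
                        operator_id=f"op{1 + rep % 2}",
                        run_id=f"run{1 + rep}",
                    )
                )
    return runs


# ---------------------------------------------------------------------------
# Clinical cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortTruthVariant:
    """Ground truth for one somatic or germline variant of one patient."""

    patient_id: str
    key: VariantKey
    gene: str
    true_vaf_percent: float
    classification: Classification
    germline: bool
    test_filter: FilterStatus


@dataclass
class SimulatedCohort:
    """Paired test/comparator call sets with known truth for scoring."""

    truth: list[CohortTruthVariant]
    test_unfiltered: dict[str, list[VariantCall]]
    ortho_reports: dict[str, list[VariantCall]]

    @property
    def classifications(self) -> dict[VariantKey, Classification]:
        return {t.key: t.classification for t in self.truth}

    def standard_reports(self, policy: ReportingPolicy | None = None) -> dict[str, list[VariantCall]]:
        """Test-side reports under the vendor's standard rules: PASS calls
        meeting their tier cutoff."""
        policy = policy or ReportingPolicy()
        return {
            patient: [
                c
                for c in calls
                if c.filter_status is FilterStatus.PASS and standard_cutoff(c, policy)
            ]
            for patient, calls in self.test_unfiltered.items()
        }

    def ldt_reports(self, policy: LdtPolicy | None = None) -> dict[str, list[VariantCall]]:
        """Test-side reports under the modified rescue-and-cutoff pipeline."""
        cls = self.classifications
        out = {}
        for patient, calls in self.test_unfiltered.items():
            report = run_ldt_pipeline(calls, cls, policy)
            out[patient] = [r.call for r in report.rows]
        return out


_SHARED_GENES = sorted(TEST_PANEL_GENES - ORTHO_UNCOVERED_GENES)

_SOMATIC_CLASS_CHOICES = [
    Classification.PATHOGENIC,
    Classification.LIKELY_PATHOGENIC,
    Classification.VUS,
]
_SOMATIC_CLASS_P = [0.45, 0.15, 0.40]


def simulate_clinical_cohort(
    n_patients: int,
    params: SimulationParams | None = None,
    seed: int = 0,
    mean_variants_per_patient: float = 3.0,
    grm_flag_rate: float = 0.5,
    other_filter_rate: float = 0.08,
    test_depth: int = 2829,
    ortho_depth: int = 4000,
    test_llod_percent: float = 0.25,
    ortho_llod_percent: float = 0.3,
) -> SimulatedCohort:
    """Simulate a clinical cohort observed by both assays.

    Each patient carries 1 + Poisson(mean - 1) somatic variants with
    log-normal true VAFs. On the test side, high-VAF (>= 30%) variants are
    flagged GRM at ``grm_flag_rate`` (the germline-filter failure mode the
    rescue rules address), and other variants are flagged RPT / CMPLX /
    UNSPECIFIED at ``other_filter_rate`` each; a call carries at most one flag.
    The comparator observes the same truth with independent binomial noise
    and its own 0.3% reporting limit.
    """
    if n_patients < 1:
        raise VariantModelError("n_patients must be >= 1")
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    truth: list[CohortTruthVariant] = []
    test_unfiltered: dict[str, list[VariantCall]] = {}
    ortho_reports: dict[str, list[VariantCall]] = {}
    used_positions: set[int] = set()
    for i in range(n_patients):
        patient = f"SIM-{i + 1:03d}"
        n_var = 1 + int(rng.poisson(max(mean_variants_per_patient - 1.0, 0.0)))
        test_calls: list[VariantCall] = []
        ortho_calls: list[VariantCall] = []
        for _ in range(n_var):
            gene = _SHARED_GENES[int(rng.integers(len(_SHARED_GENES)))]
            pos = int(rng.integers(1_000_000, 50_000_000))
            while pos in used_positions:
                pos += 1
            used_positions.add(pos)
            ref = "ACGT"[int(rng.integers(4))]
            alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
            key = VariantKey("chr1", pos, ref, alt)
            germline = rng.random() < 0.15
            if germline:
                vaf = float(np.clip(rng.normal(params.germline_vaf_mean, params.germline_vaf_sd), 5, 100))
                cls = Classification.VUS if rng.random() < 0.7 else Classification.PATHOGENIC
            else:
                vaf = float(np.clip(rng.lognormal(1.2, 1.4), 0.05, 95.0))
                cls = rng.choice(_SOMATIC_CLASS_CHOICES, p=_SOMATIC_CLASS_P)
            # test-side filter assignment
            status = FilterStatus.PASS
            if (germline or vaf >= 30.0) and rng.random() < grm_flag_rate:
                status = FilterStatus.GRM
            elif rng.random() < 3 * other_filter_rate:
                status = [FilterStatus.RPT, FilterStatus.CMPLX, FilterStatus.UNSPECIFIED][
                    int(rng.integers(3))
                ]
            truth.append(
                CohortTruthVariant(
                    patient_id=patient,
                    key=key,
                    gene=gene,
                    true_vaf_percent=vaf,
                    classification=cls,
                    germline=germline,
                    test_filter=status,
                )
            )
            t_alt = int(rng.binomial(test_depth, vaf / 100.0))
            if t_alt >= 1:
                test_calls.append(
                    VariantCall(
                        key=key,
                        sample_id=patient,
                        gene=gene,
                        vaf_percent=100.0 * t_alt / test_depth,
                        alt_reads=t_alt,
                        depth=test_depth,
                        filter_status=status,
                        classification=cls,
                    )
                )
            o_alt = int(rng.binomial(ortho_depth, vaf / 100.0))
            o_vaf = 100.0 * o_alt / ortho_depth
            if o_alt >= 1 and o_vaf >= ortho_llod_percent:
                ortho_calls.append(
                    VariantCall(
                        key=key,
                        sample_id=patient,
                        gene=gene,
                        vaf_percent=o_vaf,
                        alt_reads=o_alt,
                        depth=ortho_depth,
                        filter_status=FilterStatus.PASS,
                        classification=cls,
                    )
                )
        test_unfiltered[patient] = test_calls
        ortho_reports[patient] = ortho_calls
    return SimulatedCohort(
        truth=truth, test_unfiltered=test_unfiltered, ortho_reports=ortho_reports
    )
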