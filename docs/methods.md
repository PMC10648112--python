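# Methods

## Problem setting

A clinical laboratory validating a commercial hybrid-capture ctDNA panel as
a laboratory-developed test (LDT) must quantify analytical performance
against manufactured reference standards and clinical concordance against
an independent assay, and must fix a reporting policy. The vendor pipeline
under study emits two VCF reports per library — a filtered report applying
its standard rules and an unfiltered report — and its standard rules
suppress some clinically relevant somatic variants: high-VAF pathogenic
calls flagged as presumed germline (`GRM`), and indels flagged as
repeat-region (`RPT`), complex (`CMPLX`), or rejected with no stated
reason. This package implements the reporting and statistics side of that
validation; alignment, deduplication and primary variant calling are out
of scope, as are copy-number, fusion and MSI detection and automated
pathogenicity classification (classifications are consumed as input).

## Variant representation

Coordinates are 1-based VCF-style with an anchor base for indels; keys are
left-aligned and parsimony-reduced by the standard algorithm (trim shared
trailing bases, re-reading reference sequence leftwards when an allele
empties; then trim shared leading bases down to a single anchor).
Normalization is idempotent and is property-tested against a sequence-edit
oracle. VAFs are stored on the 0–100 percent scale exactly as clinical
reports print them; fractions are derived views. All matching is on
normalized `(chrom, pos, ref, alt)`.

The packaged truth-panel indels carry their published coordinates and
alleles; their ±50 bp reference contexts are **synthetic** stand-ins that
embed the described homopolymer runs (6 bp A run for the APC insertion,
5 bp C run for the TP53 deletion), since no genome is bundled. The
homopolymer filter depends only on the event allele and the run length
adjacent to the anchor, so synthetic context is sufficient for its
behaviour.

## Vendor rule emulation

Only the two documented behaviours are emulated: the tiered VAF cutoffs
(actionable 0.1%, COSMIC hotspot 0.3%, other 0.5%, all inclusive at the
boundary) and the repeat filter for insertions/deletions in homopolymers
≥ 4 bp. The germline filter's criteria are unpublished; `GRM` status is
therefore never derived — it is read from input FILTER fields or assigned
by the cohort simulator's generative model. "Near or within repeat
region" is implemented only for homopolymers, the one criterion stated;
tandem-repeat proximity is deliberately not invented. The hotspot cutoff
is applied per-allele.

## The LDT reporting pipeline

Stage order: single-read removal (alt reads ≥ 2) → classification
annotation → rescue → reporting cutoff, with rows sorted by
`(chrom, pos, alt)`. Rescue retains PASS calls unchanged; germline-filtered
calls iff pathogenic or likely pathogenic (no VAF gate — the rescued call
carries a germline caveat in the report rather than being suppressed); and
RPT/CMPLX/unspecified-filtered calls iff pathogenic or likely pathogenic
*and* VAF ≥ 10%. The 0.25% clinical cutoff applies after rescue, to every
class, so a rescued 69% germline-filtered call is reported while a 0.13%
actionable call (reported by the vendor's 0.1% rule) is not. Both VAF
gates are inclusive. Calls present only in the unfiltered report with no
FILTER reason are treated as rescuable exactly like RPT/CMPLX. A filtered
call missing from the classification table is downgraded to UNCLASSIFIED
with a recorded warning, since a silent lookup miss would suppress a
rescue. The pipeline is idempotent and never alters a VAF; its output call
set is a subset of its input.

Whether single-read removal precedes or follows classification does not
affect any result; it is implemented removal-first.

## Validation metrics

All count metrics are exact integer-ratio computations. Detection tallies
are grouped by (variant type, tier, input mass) with data-driven
denominators — the 40 ng row of the packaged sensitivity table has
denominators of 60 and 75 at some tiers, implying 4–5 replicates, so
replicate counts are never hard-coded. A truth variant counts as detected
in a run iff a matching call is reportable under the supplied rule; the
default rule (PASS filter, ≥ 2 alt reads, VAF ≥ 0.25%) makes the two
homopolymer indels permanently undetectable, reproducing the 7/9 per-run
indel ceiling.

LoD-95 is tier-discrete: the smallest tested tier with sensitivity ≥ 95%,
valid only if every larger tested tier also passes; otherwise
`NOT_REACHED`. No probit/logistic fit is used for acceptance.

Specificity uses wild-type (0% tier) libraries: TN counts truth-panel
positions with no reportable call per library; FP counts reportable calls
outside the panel classified pathogenic, likely pathogenic or VUS (benign
and likely benign calls are not errors of clinical consequence).

Replicate concordance is the fraction of the 24 truth-panel variants with
identical detection status in two same-tier runs; this denominator
reproduces the printed 23/24 = 95.8% case, whereas a union-of-calls
denominator would not and is rejected.

ANOVA across input masses is one-way fixed-effects on replicate VAF (or
depth) measurements. All-constant input returns F = 0, p = 1 (no evidence
of a group effect) rather than NaN. The depth-vs-input comparison in the
source validation has no stated method; using the same one-way ANOVA on
depths is an assumption of this package.

## Orthogonal concordance

Concordance treats the comparator as a non-reference standard: PPA =
concordant positives / (concordant positives + comparator-only positives),
restricted to pathogenic / likely pathogenic variants; NPA/OPA are out of
scope. Pairing excludes genes outside the shared panel (the comparator
does not cover BRIP1, CSF1R, POLD1, POLE) and observations below the
detecting side's LLOD (test 0.25%, comparator 0.3%); exclusions never
enter numerator or denominator. Test-only detections (comparator misses)
do not enter PPA.

On the packaged 81-variant clinical table, detection status per pipeline
is *recomputed from the row's data*: the standard pipeline's status is a
nonzero reported VAF (which includes two actionable calls at 0.13% and
0.16%, reported under the vendor's 0.1% rule but below the LDT cutoff);
the LDT status applies the rescue gates and the 0.25% cutoff to the
unfiltered VAF and classification. One bookkeeping ambiguity remains: the
printed clinical denominator is 48, while strict re-derivation from the
table's classification column yields 47. The table therefore carries an
explicit `clinical_in_ppa` annotation column; it marks every pathogenic /
likely pathogenic row plus one stop-gain row (CCND1 E279*, printed as
uncertain significance) whose inclusion reproduces all four printed
counts (40/8 and 44/4). This is surfaced as an annotation, not silently
resolved, and is the single documented deviation between the printed
counts and rule-only re-derivation.

The VAF regression (test on comparator, OLS) uses the documented inclusion
rule: filtered test calls contribute their unfiltered VAF; pairs with
either side at zero are excluded; the one comparator false negative
(test-only at 14.3%, confirmed by digital PCR) is excluded by default and
configurable. Under this rule the 67 usable pairs give
Y = 0.9645 X + 0.957 with R² = 0.9695, against the reported
Y = 0.9626 X + 1.043, R² = 0.9676 — agreement to ~0.2%, consistent with
transcription rounding of the printed VAFs.

## Synthetic data generators

The reference-standard simulator emulates a tiered multiplexed control:
a fixed 24-variant panel (15 SNVs, 9 indels; exactly two indels in
homopolymer context, always emitted RPT-filtered), dilution tiers
2/1/0.5/0.25/0.125/0% VAF, and at least three replicate libraries per
(tier, input) cell. Per variant, unique-read depth is negative-binomial
around the measured per-input medians {30 ng: 3841, 40 ng: 4400,
50 ng: 5069, 60 ng: 5130} with dispersion 0.1 (variance = m + 0.1 m²; the
source reports only medians, so the dispersion is a stated assumption);
supporting reads are Binomial(depth, tier·β/100) with template recovery
β = 1 by default; VAF = 100·alt/depth. False positives arrive as
Poisson(0.68) per library — 52 observed FP calls over 76 libraries — with
exponential VAFs of scale 0.2% so that roughly 70% fall below the 0.25%
cutoff, qualitatively matching the observed 22-of-52; this is a modeling
choice, not a claimed reproduction. Under a zero-dispersion configuration
the empirical per-variant detection rate matches the closed form
P(Binomial(D, fβ/100) ≥ max(2, ⌈0.0025·D⌉)) within three standard errors
over 1000 libraries (asserted in the test suite).

The clinical cohort generator draws per-patient somatic variants with
log-normal true VAFs plus ~15% germline contaminants near 50% VAF, flags
high-VAF calls GRM at a configurable rate and others RPT/CMPLX/unspecified
at low rates, and lets the comparator observe the same truth with
independent binomial noise at its own 0.3% limit. It reproduces the
structural property the rescue rules rely on: rescue can only convert
comparator-only pairs into concordant pairs, so LDT PPA ≥ standard PPA on
every cohort.

What the generators do **not** model: read-level errors and error spectra,
UMI/duplex consensus, sequence-context-dependent FP rates, CHIP,
tumor-fraction dynamics, and inter-library correlation of artifacts.
Passing tests on synthetic data therefore validate the *bookkeeping and
statistics*, not the wet-lab error behaviour of any real assay.

Every generator is a pure function of (parameters, seed); simulated VCFs
are byte-identical across reruns of the same seed.

## Problem sizes and numerical choices

The test suite uses 1000 simulated libraries for the parameter-recovery
check, 100 cohorts of 10 patients for the rescue-monotonicity check, 200
seeds for the linearity oracle (per-tier means of 10 replicate libraries,
where the slope stays within [0.9, 1.1]), and 1000 simulations for ANOVA
type-I calibration — sizes chosen so the whole suite runs in a few
seconds while keeping Monte-Carlo standard errors well inside the asserted
bands. Count-ratio metrics are exact rational arithmetic on integers;
boundary comparisons (cutoffs, gates) are all inclusive `>=` per the
stated rules; report ordering is deterministic by genomic coordinate.

## Known limitations

- Panel identities beyond the two published homopolymer indels are
  synthetic; the commercial reference standard's full variant list is not
  reproduced.
- The vendor's germline, quality and deduplication logic is not modeled;
  only its documented reporting rules are emulated.
- Per-library appendix-level results (per-allele VAF tables, FP
  inventories, depth-significance p-values, inter-run R²) are not
  reproducible from the packaged tables; the corresponding computations
  are exercised on synthetic data instead.
- Confidence intervals on the count metrics are not part of the headline
  outputs (the validation reports point estimates); Wilson intervals could
  be added without changing any tally.
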