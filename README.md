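# ctdnaval

Analytical-validation toolkit for a plasma ctDNA next-generation-sequencing
laboratory-developed test (LDT).

Clinical laboratories that adopt a commercial ctDNA panel must validate it
— and often must *modify its reporting rules* — before clinical use. A known
failure mode of vendor pipelines is suppressing clinically relevant somatic
variants: high-VAF pathogenic calls filtered as presumed germline, and
indels filtered as repeat-region or complex artifacts. `ctdnaval` models
the reporting side of such a validation for a 33-gene hybrid-capture panel:

- **Variant model and I/O** — VCF 4.2 call sets in a *filtered* and an
  *unfiltered* dialect (FILTER codes `GRM`/`RPT`/`CMPLX`, or `.` for
  "no reason provided"), indel left-alignment and parsimony reduction,
  call matching, TSV clinical reports and classification tables.
- **Vendor rule emulation** — the standard tiered reporting cutoffs
  (actionable ≥ 0.1%, COSMIC hotspot ≥ 0.3%, other positions ≥ 0.5% VAF)
  and the repeat filter that suppresses indels in homopolymers ≥ 4 bp.
- **The modified LDT reporting pipeline** — starting from the unfiltered
  report: remove single-read calls; rescue pathogenic / likely pathogenic
  calls filtered as germline (any VAF) or as RPT/CMPLX/unspecified
  (VAF ≥ 10%); then apply a clinical reporting cutoff of VAF ≥ 0.25% to
  every variant class. Rescued germline-filtered calls carry a caveat flag.
- **Validation metrics** — tiered sensitivity TP/(TP+FN), specificity
  TN/(TN+FP) on wild-type runs, PPV TP/(TP+FP), the tier-discrete 95%
  limit of detection (smallest VAF tier with ≥ 95% detection, all larger
  tiers also passing), per-allele linearity by OLS, replicate concordance
  over the 24-variant truth panel, and one-way ANOVA of replicate VAFs
  across DNA input masses.
- **Orthogonal-assay concordance** — per-patient variant pairing with
  off-panel and below-LLOD exclusions, positive percent agreement
  PPA = TP/(TP+FN) for clinically significant variants under either
  pipeline, test-vs-comparator VAF regression, and pre/post-treatment VAF
  deltas.
- **Synthetic data** — a tiered reference-standard simulator (15 SNVs +
  9 indels, VAF tiers 2/1/0.5/0.25/0.125/0%; negative-binomial depth around
  per-input medians; binomial read sampling; Poisson low-VAF false
  positives) and a paired test/comparator clinical cohort generator with
  known truth, plus packaged transcriptions of the validation count tables
  and the 81-variant clinical concordance table.

## Worked example

```bash
python examples/03_orthogonal_concordance.py
```

```
81 variants across 27 patients

standard pipeline: PPA 83.3% (40/48 comparator-positive clinical variants)
     ldt pipeline: PPA 91.7% (44/48 comparator-positive clinical variants)

VAF regression (test on comparator, 67 pairs): Y = 0.9645 X + 0.957, R^2 = 0.9695
```

Of 48 comparator-positive pathogenic / likely pathogenic variants, the
vendor's standard reporting agrees on 40 (83.3%). The rescue rules recover
six filtered calls (two germline-filtered, one repeat-filtered, one
complex-filtered, two with no stated reason, all at VAF ≥ 10% where
gated), while the 0.25% clinical cutoff drops two sub-cutoff actionable
calls — net PPA 91.7%. The VAF regression shows the two assays agree
nearly one-to-one on quantification. The other examples cover tiered
reference-standard metrics (`01`), the reporting pipeline itself (`02`),
treatment monitoring (`04`) and deterministic end-to-end orchestration
(`05`).

A thin CLI wraps the same library calls:

```bash
ctdnaval simulate --tier 2.0 --tier 0.5 --replicates 3 --seed 1 --out-dir sim/
ctdnaval report --unfiltered-vcf sim/sim-2-50ng-r1.vcf --out report.tsv
ctdnaval validate --manifest sim/manifest.json --out-dir metrics/
ctdnaval concordance
```

## Layout

```
src/ctdnaval/     library (variants, vcfio, vendor, reporting, metrics,
                  concordance, simulate, fixtures, config, cli)
src/ctdnaval/data/  packaged fixture tables (TSV)
examples/         narrative scripts, one per capability
tests/            pytest suite (unit, property-based, acceptance)
docs/methods.md   model, assumptions, parameter choices, limitations
```
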