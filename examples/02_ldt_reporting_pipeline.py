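"""Run the modified clinical reporting pipeline on an unfiltered call set.

Constructs a colon-cancer-like unfiltered report containing three PASS
somatic variants, a likely pathogenic variant wrongly filtered as germline
at 69% VAF, a VUS germline contaminant, and a one-read artifact, then shows
which calls the rescue rules retain. The germline-rescued call carries a
caveat flag for the report text instead of being suppressed.
"""

from ctdnaval import run_ldt_pipeline
from ctdnaval.variants import (
    Classification,
    FilterStatus,
    VariantCall,
    VariantKey,
)

C, F = Classification, FilterStatus


def call(pos, gene, vaf, filt=F.PASS, cls=C.UNCLASSIFIED, alt_reads=None):
    return VariantCall(
        key=VariantKey("chr1", pos, "A", "G"),
        gene=gene,
        vaf_percent=vaf,
        alt_reads=alt_reads if alt_reads is not None else max(2, int(vaf * 10)),
        depth=1000,
        filter_status=filt,
        classification=cls,
    )


unfiltered = [
    call(100, "APC", 73.48, cls=C.PATHOGENIC),
    call(200, "KRAS", 34.9, cls=C.PATHOGENIC),
    call(300, "TP53", 71.44, cls=C.PATHOGENIC),
    call(400, "BRAF", 69.0, filt=F.GRM, cls=C.LIKELY_PATHOGENIC),
    call(500, "ARID1A", 45.0, filt=F.GRM, cls=C.VUS),
    call(600, "EGFR", 0.1, alt_reads=1),
]

report = run_ldt_pipeline(unfiltered)
print("gene    VAF%    provenance            germline caveat")
for row in report.rows:
    print(
        f"{row.call.gene:<7} {row.call.vaf_percent:>6.2f}  "
        f"{row.rescue_provenance.value:<20}  {'yes' if row.germline_flag else 'no'}"
    )
print(f"\n{len(unfiltered) - len(report.rows)} of {len(unfiltered)} calls suppressed "
      "(VUS germline contaminant and single-read artifact).")
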