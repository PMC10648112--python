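"""Readers and writers for the formats the pipeline consumes and emits.

VCF 4.2 call sets (filtered and unfiltered dialects, read through pysam),
the TSV clinical report, the TSV variant-classification table, and the JSON
run manifest. The vendor VCF dialect's tag names are not standardized, so
the reader accepts a configurable tag map; defaults cover the simulated
call sets written by this package (INFO/AF as a fraction, FORMAT AD + DP).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pysam

from .reporting import ClinicalReport, ReportedCall, RescueProvenance
from .variants import (
    Classification,
    FilterStatus,
    HotspotTier,
    LibraryRun,
    VariantCall,
    VariantKey,
    VariantModelError,
    parse_classification,
)

Dialect = Literal["filtered", "unfiltered"]

_KNOWN_FILTERS = {f.value: f for f in FilterStatus}


class FormatError(VariantModelError):
    """Malformed input file."""


class ConsistencyError(VariantModelError):
    """Internally inconsistent record (e.g. alt reads at zero depth)."""


@dataclass(frozen=True)
class VcfTagMap:
    """Where to find allele frequency and read support in a VCF dialect."""

    af_info: str = "AF"
    af_scale: Literal["fraction", "percent"] = "fraction"
    ad_format: str = "AD"
    dp_format: str = "DP"
    gene_info: str = "GENE"
    hotspot_info: str = "HS"


def read_call_vcf(
    path: str | Path,
    dialect: Dialect = "unfiltered",
    tag_map: VcfTagMap | None = None,
    library_id: str | None = None,
    sample_id: str = "",
    input_ng: int | None = None,
    operator_id: str = "",
    run_id: str = "",
    tier_vaf_percent: float | None = None,
) -> LibraryRun:
    """Read a VCF call set into a :class:`LibraryRun`, one call per ALT allele.

    In the unfiltered dialect a record with '.' or missing FILTER is a
    rejected call with no stated reason and maps to UNSPECIFIED; in the
    filtered dialect every retained record is treated as PASS unless a
    rejection code is present (which would be a dialect violation and is
    surfaced as a format error).
    """
    tag_map = tag_map or VcfTagMap()
    path = Path(path)
    calls: list[VariantCall] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            calls.extend(_calls_from_record(rec, dialect, tag_map, sample_id, path))
    return LibraryRun(
        library_id=library_id or path.stem,
        sample_id=sample_id,
        input_ng=input_ng,
        operator_id=operator_id,
        run_id=run_id,
        tier_vaf_percent=tier_vaf_percent,
        calls=calls,
    )


def _filter_status(rec, dialect: Dialect, path: Path) -> FilterStatus:
    names = list(rec.filter.keys())
    if not names or names == ["."]:
        return FilterStatus.UNSPECIFIED if dialect == "unfiltered" else FilterStatus.PASS
    if len(names) > 1:
        raise FormatError(f"{path}: multiple FILTER codes {names} at {rec.chrom}:{rec.pos}")
    name = names[0]
    if name not in _KNOWN_FILTERS:
        raise FormatError(f"{path}: unknown FILTER code {name!r} at {rec.chrom}:{rec.pos}")
    status = _KNOWN_FILTERS[name]
    if dialect == "filtered" and status is not FilterStatus.PASS:
        raise FormatError(
            f"{path}: rejection code {name} in filtered-dialect file at {rec.chrom}:{rec.pos}"
        )
    return status


def _calls_from_record(
    rec, dialect: Dialect, tag_map: VcfTagMap, sample_id: str, path: Path
) -> list[VariantCall]:
    if rec.alts is None:
        return []
    status = _filter_status(rec, dialect, path)
    gene = str(rec.info.get(tag_map.gene_info, "")) if tag_map.gene_info in rec.info else ""
    hotspot = HotspotTier.OTHER
    if tag_map.hotspot_info in rec.info:
        hotspot = HotspotTier(str(rec.info[tag_map.hotspot_info]))
    afs = rec.info.get(tag_map.af_info)
    if afs is not None and not isinstance(afs, (tuple, list)):
        afs = (afs,)
    sample = rec.samples[0] if rec.samples else None
    ad = None
    depth = None
    if sample is not None:
        if tag_map.ad_format in sample and sample[tag_map.ad_format] is not None:
            ad = sample[tag_map.ad_format]
        if tag_map.dp_format in sample and sample[tag_map.dp_format] is not None:
            depth = int(sample[tag_map.dp_format])
    if depth is None and ad is not None:
        depth = int(sum(x or 0 for x in ad))
    calls = []
    for i, alt in enumerate(rec.alts):
        alt_reads = int(ad[i + 1]) if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None else 0
        dp = depth if depth is not None else 0
        if dp == 0 and alt_reads > 0:
            raise ConsistencyError(
                f"{path}: depth 0 with {alt_reads} alt reads at {rec.chrom}:{rec.pos}"
            )
        if afs is not None and i < len(afs) and afs[i] is not None:
            vaf = float(afs[i]) * (100.0 if tag_map.af_scale == "fraction" else 1.0)
        elif dp > 0:
            vaf = 100.0 * alt_reads / dp
        else:
            vaf = 0.0
        calls.append(
            VariantCall(
                key=VariantKey(rec.chrom, rec.pos, rec.ref, alt),
                sample_id=sample_id,
                gene=gene,
                vaf_percent=min(vaf, 100.0),
                alt_reads=alt_reads,
                depth=dp,
                filter_status=status,
                hotspot_tier=hotspot,
            )
        )
    return calls


_VCF_HEADER_LINES = [
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele frequency (fraction)">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC gene symbol">',
    '##INFO=<ID=HS,Number=1,Type=String,Description="Hotspot reporting tier">',
    '##FILTER=<ID=GRM,Description="Filtered as presumed germline">',
    '##FILTER=<ID=RPT,Description="Filtered as near or within repeat region">',
    '##FILTER=<ID=CMPLX,Description="Filtered as complex variant">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Unique read depth">',
]


def write_library_vcf(run: LibraryRun, path: str | Path) -> Path:
    """Write a LibraryRun as a deterministic single-sample VCF 4.2 text file.

    Rejected calls with UNSPECIFIED status are written with FILTER '.'
    (the unfiltered-dialect convention for "no reason provided").
    """
    path = Path(path)
    chroms = sorted({c.key.chrom for c in run.calls}, key=_chrom_order)
    lines = ["##fileformat=VCFv4.2", f"##source=ctdnaval library {run.library_id}"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += _VCF_HEADER_LINES
    sample = run.sample_id or run.library_id
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    for call in sorted(run.calls, key=lambda c: (_chrom_order(c.key.chrom), c.key.pos, c.key.alt)):
        if call.filter_status is FilterStatus.UNSPECIFIED:
            filt = "."
        else:
            filt = call.filter_status.value
        info = f"AF={call.vaf_percent / 100.0:.6f}"
        if call.gene:
            info += f";GENE={call.gene}"
        if call.hotspot_tier is not HotspotTier.OTHER:
            info += f";HS={call.hotspot_tier.value}"
        ad = f"{max(call.depth - call.alt_reads, 0)},{call.alt_reads}"
        lines.append(
            "\t".join(
                [
                    call.key.chrom,
                    str(call.key.pos),
                    ".",
                    call.key.ref,
                    call.key.alt,
                    ".",
                    filt,
                    info,
                    "GT:AD:DP",
                    f"0/1:{ad}:{call.depth}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _chrom_order(chrom: str) -> tuple:
    name = chrom.removeprefix("chr")
    return (0, int(name)) if name.isdigit() else (1, name)


REPORT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "cdna_change",
    "protein_change",
    "vaf_percent",
    "alt_reads",
    "depth",
    "classification",
    "filter_status",
    "rescue_provenance",
    "germline_flag",
    "sample_id",
]


def write_report_tsv(rows: Iterable[ReportedCall] | ClinicalReport, path: str | Path) -> Path:
    """Write clinical report rows with a stable schema and deterministic order.

    Rows are sorted by (chrom, pos, alt); the file round-trips through
    :func:`read_report_tsv` field-for-field.
    """
    if isinstance(rows, ClinicalReport):
        rows = rows.rows
    path = Path(path)
    ordered = sorted(rows, key=lambda r: (_chrom_order(r.call.key.chrom), r.call.key.pos, r.call.key.alt))
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for row in ordered:
            c = row.call
            writer.writerow(
                [
                    c.key.chrom,
                    c.key.pos,
                    c.key.ref,
                    c.key.alt,
                    c.gene,
                    c.cdna_change,
                    c.protein_change,
                    repr(c.vaf_percent),
                    c.alt_reads,
                    c.depth,
                    c.classification.value,
                    c.filter_status.value,
                    row.rescue_provenance.value,
                    int(row.germline_flag),
                    c.sample_id,
                ]
            )
    return path


def read_report_tsv(path: str | Path) -> list[ReportedCall]:
    """Read back a clinical report TSV written by :func:`write_report_tsv`."""
    path = Path(path)
    rows: list[ReportedCall] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != REPORT_COLUMNS:
            raise FormatError(f"{path}: unexpected report columns {reader.fieldnames}")
        for rec in reader:
            call = VariantCall(
                key=VariantKey(rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"]),
                sample_id=rec["sample_id"],
                gene=rec["gene"],
                cdna_change=rec["cdna_change"],
                protein_change=rec["protein_change"],
                vaf_percent=float(rec["vaf_percent"]),
                alt_reads=int(rec["alt_reads"]),
                depth=int(rec["depth"]),
                filter_status=FilterStatus(rec["filter_status"]),
                classification=Classification(rec["classification"]),
            )
            rows.append(
                ReportedCall(
                    call=call,
                    rescue_provenance=RescueProvenance(rec["rescue_provenance"]),
                    germline_flag=bool(int(rec["germline_flag"])),
                )
            )
    return rows


@dataclass
class ClassificationTable:
    """Variant classifications and hotspot tiers keyed by variant identity."""

    classifications: dict[VariantKey, Classification] = field(default_factory=dict)
    hotspot_tiers: dict[VariantKey, HotspotTier] = field(default_factory=dict)


def read_classification_tsv(path: str | Path) -> ClassificationTable:
    """Read a variant-classification table.

    Expected columns: gene, cdna_change, chrom, pos, ref, alt,
    classification, hotspot_tier (the last may be empty -> OTHER).
    """
    path = Path(path)
    table = ClassificationTable()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "pos", "ref", "alt", "classification"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: classification table missing columns {required}")
        for rec in reader:
            key = VariantKey(rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"])
            table.classifications[key] = parse_classification(rec["classification"])
            tier = (rec.get("hotspot_tier") or "").strip()
            table.hotspot_tiers[key] = HotspotTier(tier) if tier else HotspotTier.OTHER
    return table


def write_manifest(runs: Sequence[Mapping], path: str | Path) -> Path:
    """Write a JSON run manifest: one entry per library VCF with metadata."""
    path = Path(path)
    path.write_text(json.dumps({"runs": list(runs)}, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path) -> list[dict]:
    path = Path(path)
    doc = json.loads(path.read_text())
    if not isinstance(doc, dict) or "runs" not in doc:
        raise FormatError(f"{path}: manifest must be an object with a 'runs' list")
    return list(doc["runs"])


def load_runs_from_manifest(path: str | Path, tag_map: VcfTagMap | None = None) -> list[LibraryRun]:
    """Load every library VCF listed in a manifest, relative to the manifest."""
    path = Path(path)
    runs = []
    for entry in read_manifest(path):
        vcf_path = Path(entry["path"])
        if not vcf_path.is_absolute():
            vcf_path = path.parent / vcf_path
        runs.append(
            read_call_vcf(
                vcf_path,
                dialect=entry.get("dialect", "unfiltered"),
                tag_map=tag_map,
                library_id=entry.get("library_id"),
                sample_id=entry.get("sample_id", ""),
                input_ng=entry.get("input_ng"),
                operator_id=entry.get("operator_id", ""),
                run_id=entry.get("run_id", ""),
                tier_vaf_percent=entry.get("tier_vaf_percent"),
            )
        )
    return runs
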