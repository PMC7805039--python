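"""End-to-end conversion: tabular summary statistics → indexed GWAS-VCF.

Orchestrates ingest → validation → harmonisation → indel normalisation →
karyotypic sort → write → positional + rsid indexing, streaming throughout
so memory stays bounded for tables larger than memory.  Data-quality
problems (unparseable rows, validation violations, harmonisation failures)
are counted and reported, never silently dropped; ``strict`` promotes them
to an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

from .errors import IngestError
from .harmonize import (
    FastaReference,
    InMemoryReference,
    ReferenceGenome,
    harmonize_record,
    load_rsid_map,
    normalize_record,
    sort_karyotypic,
)
from .errors import NormalizationError
from .ingest import RowIssue, iter_rows, load_schema
from .model import ColumnSchema, StudyMetadata, validate_record
from .vcf_io import build_header, index_positions, index_rsids, write_gwasvcf

__all__ = ["ConvertReport", "convert_sumstats", "open_reference"]

log = logging.getLogger("gwasvcfkit")

_MAX_KEPT_ISSUES = 1000


@dataclass
class ConvertReport:
    """Row-count ledger of one conversion.

    ``n_read == n_rejected_parse + n_rejected_validation + harmonised rows``
    and every harmonised row is either written or excluded.
    """

    out_path: Path
    n_read: int = 0
    n_rejected_parse: int = 0
    n_rejected_validation: int = 0
    n_normalization_failed: int = 0
    n_excluded: int = 0
    n_flagged: int = 0
    n_written: int = 0
    harmonisation: dict = field(default_factory=dict)
    issues: list = field(default_factory=list)
    tbi_path: Optional[Path] = None
    rsidx_path: Optional[Path] = None

    @property
    def n_rejected(self) -> int:
        return self.n_rejected_parse + self.n_rejected_validation


def open_reference(ref, preload: bool = True) -> ReferenceGenome:
    """Accept a ReferenceGenome instance or a FASTA path; ``preload`` reads
    whole contigs into memory (much faster for dense per-row lookups)."""
    if isinstance(ref, ReferenceGenome):
        return ref
    path = Path(ref)
    if preload:
        return InMemoryReference.from_fasta(path)
    return FastaReference(path)


def _rename_chrom(chrom: str, style: Optional[str]) -> str:
    if style == "strip" and chrom.startswith("chr"):
        return chrom[3:]
    if style == "add" and not chrom.startswith("chr"):
        return "chr" + chrom
    return chrom


def convert_sumstats(
    sumstats,
    schema: Union[ColumnSchema, str, Path, dict],
    reference,
    out_path,
    *,
    metadata: Optional[StudyMetadata] = None,
    trait_id: Optional[str] = None,
    keep_incompatible: bool = False,
    strict: bool = False,
    chr_style: Optional[str] = None,
    rsid_map=None,
    chunk_size: int = 250_000,
    build_indexes: bool = True,
    preload_reference: bool = True,
) -> ConvertReport:
    """Convert one summary-statistics table into an indexed GWAS-VCF file.

    Parameters of note: ``keep_incompatible`` emits harmonisation/
    normalisation failures with a FILTER label instead of excluding them;
    ``chr_style`` ('strip'/'add') renames chromosomes to match the
    reference contigs — never applied silently, only on request;
    ``rsid_map`` is a dbSNP-like annotation source (path or mapping) used
    for rows lacking an rsid column; ``strict`` raises if any row was
    rejected.  Returns the full row-count ledger.
    """
    if not isinstance(schema, ColumnSchema):
        schema = load_schema(schema)
    ref = open_reference(reference, preload=preload_reference)
    contigs = ref.contigs
    if rsid_map is not None and not isinstance(rsid_map, dict):
        rsid_map = load_rsid_map(rsid_map)

    sumstats = Path(sumstats)
    if trait_id is None:
        trait_id = metadata.trait_id if metadata is not None else (
            sumstats.name.split(".")[0] or "trait"
        )
    if metadata is None:
        metadata = StudyMetadata(trait_id=trait_id, source_file=sumstats.name)
    metadata = replace(
        metadata,
        trait_id=trait_id,
        contigs=tuple(contigs),
        genome_assembly=metadata.genome_assembly or "unknown",
        source_file=metadata.source_file or sumstats.name,
    )

    report = ConvertReport(out_path=Path(out_path))
    counts = {s: 0 for s in ("unchanged", "swapped", "incompatible", "not_in_reference")}

    def note(issue: RowIssue):
        if len(report.issues) < _MAX_KEPT_ISSUES:
            report.issues.append(issue)

    def harmonised_stream():
        for lineno, rec, issue in iter_rows(sumstats, schema, trait_id):
            report.n_read += 1
            if rec is None:
                report.n_rejected_parse += 1
                note(issue)
                continue
            if chr_style:
                rec.chrom = _rename_chrom(rec.chrom, chr_style)
            if rsid_map is not None and "rsid" not in rec.info:
                rsid = rsid_map.get((rec.chrom, rec.pos))
                if rsid is not None:
                    rec.info["rsid"] = rsid
            violations = validate_record(rec, contigs)
            # contig/length checks are harmonisation's job (not_in_reference)
            violations = [v for v in violations
                          if v.code not in ("CONTIG_UNKNOWN", "POSITION_PAST_CONTIG_END")]
            if violations:
                report.n_rejected_validation += 1
                note(RowIssue(lineno, violations[0].code, violations[0].message))
                continue
            outcome = harmonize_record(rec, ref)
            counts[outcome.status] += 1
            if outcome.status in ("incompatible", "not_in_reference"):
                if keep_incompatible and outcome.status == "incompatible":
                    outcome.record.filters.add("HARMONISATION_FAILED")
                    yield outcome.record
                else:
                    report.n_excluded += 1
                    note(RowIssue(lineno, outcome.status.upper(), outcome.detail))
                continue
            try:
                yield normalize_record(outcome.record, ref)
            except NormalizationError as exc:
                report.n_normalization_failed += 1
                if keep_incompatible:
                    outcome.record.filters.add("NORMALISATION_FAILED")
                    yield outcome.record
                else:
                    report.n_excluded += 1
                    note(RowIssue(lineno, "NORMALISATION_FAILED", str(exc)))

    format_fields = ["ES", "SE", "LP"]
    if schema.source("af") is not None:
        format_fields.append("AF")
    if schema.source("ss") is not None:
        format_fields.append("SS")
    header = build_header([metadata], format_fields=format_fields)

    ordered = sort_karyotypic(harmonised_stream(), contigs, chunk_size=chunk_size)
    write_report = write_gwasvcf(ordered, header, out_path)
    report.n_written = write_report.n_written
    report.harmonisation = counts
    if keep_incompatible:
        report.n_flagged = counts["incompatible"] + report.n_normalization_failed

    log.info(
        "convert: read=%d written=%d rejected_parse=%d rejected_validation=%d "
        "excluded=%d flagged=%d harmonisation=%s",
        report.n_read, report.n_written, report.n_rejected_parse,
        report.n_rejected_validation, report.n_excluded, report.n_flagged, counts,
    )
    if strict and (report.n_rejected or report.n_excluded):
        raise IngestError(
            f"strict mode: {report.n_rejected} rejected and "
            f"{report.n_excluded} excluded rows"
        )
    if build_indexes:
        report.tbi_path = index_positions(out_path)
        report.rsidx_path = index_rsids(out_path).db_path
    return report
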