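"""GWAS-VCF serialization, indexing, export and multi-trait merging.

The on-disk format is VCF 4.2 with GWAS-specific conventions: one variant
per body row (multiallelic sites pre-split), per-trait association
statistics in sample columns (FORMAT fields ES, SE, LP and optionally AF,
SS, in that fixed order), the dbSNP locus identifier in ``INFO/RSID``
(never in the ID column, because an rsid names a locus rather than an
allelic substitution), study/trait metadata in structured ``##SAMPLE``
header lines, BGZF block compression, a tabix positional index, and an
rsid→coordinate index stored as a single-table SQLite database compatible
with the rsidx layout.

Writing is strict — unsorted input, duplicate IDs and undeclared fields are
fatal — so that every file this module produces is valid by construction.
Reading goes through pysam (htslib), which doubles as an independent check
that the files we write are plain, conformant VCF.
"""

from __future__ import annotations

import datetime as _dt
import math
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import pysam

from . import __version__
from .errors import IndexingError, MergeError, WriteError
from .model import (
    GwasRecord,
    StudyMetadata,
    TraitStats,
    check_id_uniqueness,
    p_from_lp,
    validate_record,
)
from .harmonize import sort_karyotypic

__all__ = [
    "GWAS_VCF_SPEC_VERSION",
    "FORMAT_DEFS",
    "INFO_DEFS",
    "FILTER_DEFS",
    "build_header",
    "write_gwasvcf",
    "read_gwasvcf",
    "iter_gwasvcf",
    "read_header_metadata",
    "index_positions",
    "index_rsids",
    "rsid_lookup",
    "export_tsv",
    "merge_traits",
    "validate_file",
    "WriteReport",
]

GWAS_VCF_SPEC_VERSION = "1.2"

#: Fixed FORMAT field order: ES:SE:LP[:AF:SS].  A fixed order keeps output
#: bytes deterministic for reproducibility testing.
FORMAT_ORDER = ("ES", "SE", "LP", "AF", "SS")

FORMAT_DEFS = {
    "ES": ("A", "Float", "Effect size estimate relative to the alternative (effect) allele"),
    "SE": ("A", "Float", "Standard error of effect size estimate"),
    "LP": ("A", "Float", "-log10 p-value for effect estimate"),
    "AF": ("A", "Float", "Alternative allele frequency in trait subset"),
    "SS": ("A", "Integer", "Sample size used to estimate genetic effect"),
}

INFO_DEFS = {
    "AF": ("A", "Float", "Alternative allele frequency in the population"),
    "RSID": ("1", "String", "dbSNP locus identifier (identifies the site, not the substitution)"),
}

FILTER_DEFS = {
    "HARMONISATION_FAILED": "Neither allele matches the reference sequence at this position",
    "NORMALISATION_FAILED": "Indel could not be left-aligned within the contig",
}

_FLOAT_FMT = "{:.6g}"


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return "."
    return _FLOAT_FMT.format(value)


# ---------------------------------------------------------------------------
# Header
# ---------------------------------------------------------------------------

def _quote(value) -> str:
    if isinstance(value, int):
        return str(value)
    text = str(value).replace('"', r'\"')
    return f'"{text}"'


def build_header(
    metadata: Sequence[StudyMetadata],
    format_fields: Sequence[str] = ("ES", "SE", "LP"),
    info_fields: Sequence[str] = ("AF", "RSID"),
) -> str:
    """Build the GWAS-VCF header text (without trailing newline).

    Emits the fileformat/specification version lines, assembly and one
    ``##contig`` line per contig, INFO/FORMAT/FILTER definitions with
    ID/Number/Type/Description, one structured ``##SAMPLE`` line per trait
    carrying study metadata, and the ``#CHROM`` column line ending with
    FORMAT followed by one column per trait id.
    """
    if not metadata:
        raise WriteError("at least one StudyMetadata block is required")
    trait_ids = [m.trait_id for m in metadata]
    if len(set(trait_ids)) != len(trait_ids):
        dupes = sorted({t for t in trait_ids if trait_ids.count(t) > 1})
        raise WriteError(f"duplicate trait ids in header: {dupes}")
    contigs = tuple(metadata[0].contigs)
    if not contigs:
        raise WriteError("header requires a non-empty contig list")
    for m in metadata[1:]:
        if tuple(m.contigs) != contigs:
            raise WriteError(f"trait {m.trait_id!r} declares different contigs")
        if m.genome_assembly != metadata[0].genome_assembly:
            raise WriteError(f"trait {m.trait_id!r} declares a different assembly")

    fields = [f for f in FORMAT_ORDER if f in format_fields]
    if set(format_fields) - set(FORMAT_ORDER):
        raise WriteError(
            f"unknown FORMAT fields: {sorted(set(format_fields) - set(FORMAT_ORDER))}"
        )
    for required in ("ES", "SE", "LP"):
        if required not in fields:
            raise WriteError(f"FORMAT field {required} is mandatory")

    today = _dt.date.today().isoformat()
    lines = [
        "##fileformat=VCFv4.2",
        f"##fileDate={metadata[0].file_date or today}",
        f"##source=gwasvcfkit-{__version__}",
        f"##gwas_vcf_specification={GWAS_VCF_SPEC_VERSION}",
    ]
    if metadata[0].genome_assembly:
        lines.append(f"##assembly={metadata[0].genome_assembly}")
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    for fid in info_fields:
        num, typ, desc = INFO_DEFS[fid]
        lines.append(f'##INFO=<ID={fid},Number={num},Type={typ},Description="{desc}">')
    for fid, desc in FILTER_DEFS.items():
        lines.append(f'##FILTER=<ID={fid},Description="{desc}">')
    for fid in fields:
        num, typ, desc = FORMAT_DEFS[fid]
        lines.append(f'##FORMAT=<ID={fid},Number={num},Type={typ},Description="{desc}">')
    for m in metadata:
        pairs = [f"ID={m.trait_id}"]
        optional = [
            ("TraitLabel", m.trait_label or None),
            ("TraitOntology", m.trait_ontology),
            ("StudyID", m.study_id),
            ("TotalSamples", m.sample_size),
            ("Ancestry", m.ancestry),
            ("Units", m.units),
            ("AssociationTest", m.association_test),
            ("SourceFile", m.source_file or None),
            ("FileDate", m.file_date or None),
        ]
        pairs += [f"{k}={_quote(v)}" for k, v in optional if v is not None]
        lines.append(f"##SAMPLE=<{','.join(pairs)}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(trait_ids)
    )
    return "\n".join(lines)


_STRUCT_RE = re.compile(r'(\w+)=("(?:[^"\\]|\\.)*"|[^,>]*)')


def _parse_structured(line: str) -> dict:
    inner = line[line.index("<") + 1:line.rindex(">")]
    out = {}
    for key, raw in _STRUCT_RE.findall(inner):
        if raw.startswith('"') and raw.endswith('"'):
            raw = raw[1:-1].replace(r'\"', '"')
        out[key] = raw
    return out


def _header_lines(path) -> List[str]:
    lines = []
    with pysam.BGZFile(str(path), "rb") as fh:
        for raw in fh:
            line = raw.decode()
            if not line.startswith("#"):
                break
            lines.append(line.rstrip("\r\n"))
            if line.startswith("#CHROM"):
                break
    return lines


def read_header_metadata(path) -> List[StudyMetadata]:
    """Recover one :class:`StudyMetadata` per trait from a GWAS-VCF header."""
    contigs: list = []
    assembly = ""
    file_date = ""
    samples: dict = {}
    chrom_line = None
    for line in _header_lines(path):
        if line.startswith("##contig="):
            d = _parse_structured(line)
            contigs.append((d["ID"], int(d["length"])))
        elif line.startswith("##assembly="):
            assembly = line.split("=", 1)[1]
        elif line.startswith("##fileDate="):
            file_date = line.split("=", 1)[1]
        elif line.startswith("##SAMPLE="):
            d = _parse_structured(line)
            samples[d["ID"]] = d
        elif line.startswith("#CHROM"):
            chrom_line = line
    if chrom_line is None:
        raise WriteError(f"{path}: no #CHROM header line")
    trait_ids = chrom_line.split("\t")[9:]
    out = []
    for tid in trait_ids:
        d = samples.get(tid, {})
        ss = d.get("TotalSamples")
        out.append(StudyMetadata(
            trait_id=tid,
            trait_label=d.get("TraitLabel", ""),
            trait_ontology=d.get("TraitOntology"),
            study_id=d.get("StudyID"),
            sample_size=int(ss) if ss not in (None, "") else None,
            ancestry=d.get("Ancestry"),
            units=d.get("Units"),
            association_test=d.get("AssociationTest"),
            source_file=d.get("SourceFile", ""),
            file_date=d.get("FileDate", file_date),
            genome_assembly=assembly,
            contigs=tuple(contigs),
        ))
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

@dataclass
class WriteReport:
    path: Path
    n_written: int = 0
    counts: dict = field(default_factory=dict)


def _info_string(info: dict) -> str:
    parts = []
    if info.get("af") is not None:
        parts.append("AF=" + _FLOAT_FMT.format(info["af"]))
    if info.get("rsid") is not None:
        parts.append("RSID=" + str(info["rsid"]))
    for key, value in info.items():
        if key in ("af", "rsid"):
            continue
        parts.append(f"{key.upper()}={value}")
    return ";".join(parts) if parts else "."


def _sample_cell(st: Optional[TraitStats], fields: Sequence[str]) -> str:
    if st is None or st.is_empty():
        return "."
    vals = []
    for f in fields:
        if f == "ES":
            vals.append(_fmt(st.es))
        elif f == "SE":
            vals.append(_fmt(st.se))
        elif f == "LP":
            vals.append(_fmt(st.lp))
        elif f == "AF":
            vals.append(_fmt(st.af))
        elif f == "SS":
            vals.append("." if st.ss is None else str(st.ss))
    return ":".join(vals)


def write_gwasvcf(
    records: Iterable[GwasRecord],
    header: str,
    path,
    bgzf: bool = True,
) -> WriteReport:
    """Write sorted records under the given header; BGZF-compress by default.

    Enforces the format's structural guarantees at write time: records must
    arrive in karyotypic order (a position regression within a contig is
    fatal), every non-null ID must be unique, every trait and FORMAT field
    used in the body must be declared in the header.  Streams its input —
    memory use is O(1) in the number of records (plus the set of non-null
    IDs).
    """
    path = Path(path)
    header_lines = header.split("\n")
    chrom_line = header_lines[-1]
    if not chrom_line.startswith("#CHROM"):
        raise WriteError("header must end with the #CHROM column line")
    trait_ids = chrom_line.split("\t")[9:]
    fields = []
    contigs = []
    for line in header_lines:
        if line.startswith("##FORMAT="):
            fields.append(_parse_structured(line)["ID"])
        elif line.startswith("##contig="):
            d = _parse_structured(line)
            contigs.append((d["ID"], int(d["length"])))
    fields = [f for f in FORMAT_ORDER if f in fields]
    rank = {name: i for i, (name, _l) in enumerate(contigs)}
    has_af = "AF" in fields
    has_ss = "SS" in fields

    seen_ids: set = set()
    prev = (-1, -1)
    n = 0
    out = pysam.BGZFile(str(path), "wb") if bgzf else open(path, "wb")
    try:
        out.write((header + "\n").encode())
        for rec in records:
            if rec.chrom not in rank:
                raise WriteError(
                    f"record at {rec.chrom}:{rec.pos}: contig not declared in header"
                )
            key = (rank[rec.chrom], rec.pos)
            if key < prev:
                raise WriteError(
                    f"unsorted input at {rec.chrom}:{rec.pos} (position regression); "
                    f"run sort_karyotypic first"
                )
            prev = key
            if rec.ident is not None:
                if rec.ident in seen_ids:
                    raise WriteError(f"duplicate variant ID {rec.ident!r}")
                seen_ids.add(rec.ident)
            cells = []
            for tid in rec.stats:
                if tid not in trait_ids:
                    raise WriteError(
                        f"record at {rec.chrom}:{rec.pos} carries undeclared trait {tid!r}"
                    )
            for tid in trait_ids:
                st = rec.stats.get(tid)
                if st is not None:
                    if st.af is not None and not has_af:
                        raise WriteError("FORMAT field AF used in body but not declared")
                    if st.ss is not None and not has_ss:
                        raise WriteError("FORMAT field SS used in body but not declared")
                cells.append(_sample_cell(st, fields))
            line = "\t".join([
                rec.chrom,
                str(rec.pos),
                rec.ident if rec.ident is not None else ".",
                rec.ref_allele,
                rec.alt_allele,
                "." if rec.qual is None else _FLOAT_FMT.format(rec.qual),
                ";".join(sorted(rec.filters)) if rec.filters else ".",
                _info_string(rec.info),
                ":".join(fields),
            ] + cells)
            out.write((line + "\n").encode())
            n += 1
    finally:
        out.close()
    return WriteReport(path=path, n_written=n)


# ---------------------------------------------------------------------------
# Reading (through pysam/htslib)
# ---------------------------------------------------------------------------

def _scalar(value):
    if isinstance(value, tuple):
        value = value[0] if value else None
    if value is None:
        return None
    return value


def record_from_pysam(rec, trait_ids: Sequence[str]) -> GwasRecord:
    """Convert one pysam VariantRecord into a :class:`GwasRecord`."""
    info = {}
    af = _scalar(rec.info.get("AF"))
    if af is not None:
        info["af"] = float(af)
    rsid = rec.info.get("RSID")
    if rsid is not None:
        info["rsid"] = str(rsid)
    stats = {}
    for tid in trait_ids:
        s = rec.samples[tid]
        es = _scalar(s.get("ES"))
        se = _scalar(s.get("SE"))
        lp = _scalar(s.get("LP"))
        taf = _scalar(s.get("AF")) if "AF" in s else None
        ss = _scalar(s.get("SS")) if "SS" in s else None
        st = TraitStats(
            es=None if es is None else float(es),
            se=None if se is None else float(se),
            lp=None if lp is None else float(lp),
            af=None if taf is None else float(taf),
            ss=None if ss is None else int(ss),
        )
        if not st.is_empty():
            stats[tid] = st
    return GwasRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        ref_allele=rec.ref,
        alt_allele=rec.alts[0] if rec.alts else "",
        ident=rec.id,
        qual=rec.qual,
        filters=set(rec.filter.keys()) - {"PASS"},
        info=info,
        stats=stats,
    )


def iter_gwasvcf(path, region=None) -> Iterator[GwasRecord]:
    """Iterate records of a GWAS-VCF file (optionally within a region)."""
    with pysam.VariantFile(str(path)) as vf:
        trait_ids = list(vf.header.samples)
        it = vf.fetch(region.chrom, region.start - 1, region.end) if region else vf
        for rec in it:
            yield record_from_pysam(rec, trait_ids)


def read_gwasvcf(path) -> Tuple[List[StudyMetadata], List[GwasRecord]]:
    """Read a whole GWAS-VCF file into memory."""
    return read_header_metadata(path), list(iter_gwasvcf(path))


# ---------------------------------------------------------------------------
# Indexing
# ---------------------------------------------------------------------------

def _check_bgzf(path):
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] != b"\x1f\x8b" or len(magic) < 4 or magic[3] != 0x04:
        raise IndexingError(
            f"{path} is not BGZF-compressed; write with bgzf=True (or recompress "
            f"with bgzip) before indexing"
        )


def index_positions(path, csi: bool = False) -> Path:
    """Build a tabix positional index (.tbi, or .csi) over a sorted BGZF VCF."""
    path = Path(path)
    _check_bgzf(path)
    try:
        pysam.tabix_index(str(path), preset="vcf", force=True, csi=csi)
    except Exception as exc:
        raise IndexingError(
            f"tabix indexing of {path} failed ({exc}); ensure the file is "
            f"coordinate-sorted BGZF VCF"
        ) from exc
    return path.with_name(path.name + (".csi" if csi else ".tbi"))


@dataclass
class RsidIndexReport:
    db_path: Path
    n_indexed: int = 0
    n_missing: int = 0
    n_malformed: int = 0
    n_conflicts: int = 0


_RSID_NUM_RE = re.compile(r"rs(\d+)\Z")


def index_rsids(path, db_path=None) -> RsidIndexReport:
    """Build the rsid→coordinate index (rsidx-layout SQLite database).

    One row per distinct rsid: ``rsid_to_coord(rsid INTEGER PRIMARY KEY,
    chrom TEXT, coord INTEGER)``.  Since an rsid identifies a locus, sibling
    records of a split multiallelic site collapse onto one row; lookup
    followed by a positional fetch recovers all of them.  Records without an
    rsid are simply absent (counted); malformed rsids are skipped with a
    warning count.
    """
    path = Path(path)
    db_path = Path(db_path) if db_path else path.with_name(path.name + ".rsidx")
    report = RsidIndexReport(db_path=db_path)
    if db_path.exists():
        db_path.unlink()
    con = sqlite3.connect(db_path)
    try:
        con.execute(
            "CREATE TABLE rsid_to_coord ("
            "rsid INTEGER PRIMARY KEY, chrom TEXT, coord INTEGER)"
        )
        seen: dict = {}
        batch = []
        with pysam.BGZFile(str(path), "rb") as fh:
            for raw in fh:
                line = raw.decode()
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t", 8)
                rsid = None
                for kv in parts[7].split(";"):
                    if kv.startswith("RSID="):
                        rsid = kv[5:]
                        break
                if rsid is None:
                    report.n_missing += 1
                    continue
                m = _RSID_NUM_RE.fullmatch(rsid)
                if m is None:
                    report.n_malformed += 1
                    continue
                num = int(m.group(1))
                locus = (parts[0], int(parts[1]))
                if num in seen:
                    if seen[num] != locus:
                        report.n_conflicts += 1
                    continue
                seen[num] = locus
                batch.append((num, locus[0], locus[1]))
                if len(batch) >= 100_000:
                    con.executemany("INSERT INTO rsid_to_coord VALUES (?,?,?)", batch)
                    batch = []
        if batch:
            con.executemany("INSERT INTO rsid_to_coord VALUES (?,?,?)", batch)
        con.commit()
        report.n_indexed = len(seen)
    finally:
        con.close()
    return report


def rsid_lookup(db_path, rsid: Union[str, int]) -> Optional[Tuple[str, int]]:
    """Map an rsid to its (chrom, pos) locus; None if absent from the index."""
    if isinstance(rsid, str):
        m = _RSID_NUM_RE.fullmatch(rsid)
        if m is None:
            raise ValueError(f"malformed rsid {rsid!r}; expected rs[0-9]+")
        num = int(m.group(1))
    else:
        num = int(rsid)
    con = sqlite3.connect(db_path)
    try:
        row = con.execute(
            "SELECT chrom, coord FROM rsid_to_coord WHERE rsid = ?", (num,)
        ).fetchone()
    finally:
        con.close()
    return (row[0], row[1]) if row else None


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

_EXPORT_MISSING = "NA"
_EXPORT_FMT = "{:.10g}"

#: NHGRI-EBI GWAS Catalog standard headings plus toolkit extras.
GWAS_CATALOG_COLUMNS = (
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
    "p_value",
    "effect_allele_frequency",
    "n",
    "rsid",
    "trait_id",
)

_RECORD_COLUMNS = {
    "chromosome": lambda r: r.chrom,
    "base_pair_location": lambda r: r.pos,
    "variant_id": lambda r: r.ident,
    "effect_allele": lambda r: r.alt_allele,
    "other_allele": lambda r: r.ref_allele,
    "rsid": lambda r: r.info.get("rsid"),
}
_STAT_COLUMNS = {
    "beta": lambda s: s.es,
    "standard_error": lambda s: s.se,
    "p_value": lambda s: None if s.lp is None else p_from_lp(s.lp),
    "neg_log_10_p_value": lambda s: s.lp,
    "effect_allele_frequency": lambda s: s.af,
    "n": lambda s: s.ss,
}


def _cell_text(value) -> str:
    if value is None:
        return _EXPORT_MISSING
    if isinstance(value, float):
        return _EXPORT_FMT.format(value)
    return str(value)


def export_tsv(
    source,
    out=None,
    columns: Optional[Sequence[str]] = None,
    wide: bool = False,
) -> Optional[str]:
    """Export records to delimited text with standardised column headings.

    ``source`` is a GWAS-VCF path or an iterable of records.  Long form
    (default) emits one row per record × trait with statistics present;
    wide form emits one row per record with per-trait statistic columns
    suffixed ``_<trait_id>``.  P values are recomputed from LP on demand.
    Returns the text when ``out`` is None, else writes to ``out``.
    """
    if isinstance(source, (str, Path)):
        records: Iterable[GwasRecord] = iter_gwasvcf(source)
        trait_ids = [m.trait_id for m in read_header_metadata(source)]
    else:
        records = list(source)
        trait_ids = sorted({t for r in records for t in r.stats})

    cols = list(columns) if columns else list(GWAS_CATALOG_COLUMNS)
    available = set(_RECORD_COLUMNS) | set(_STAT_COLUMNS) | {"trait_id"}
    unknown = [c for c in cols if c not in available]
    if unknown:
        raise WriteError(
            f"unknown export columns {unknown}; available: {sorted(available)}"
        )
    if wide and "trait_id" in cols:
        cols.remove("trait_id")

    lines = []
    if wide:
        header = []
        for c in cols:
            if c in _STAT_COLUMNS:
                header += [f"{c}_{t}" for t in trait_ids]
            else:
                header.append(c)
        lines.append("\t".join(header))
        for rec in records:
            row = []
            for c in cols:
                if c in _STAT_COLUMNS:
                    for t in trait_ids:
                        st = rec.stats.get(t)
                        row.append(_cell_text(_STAT_COLUMNS[c](st) if st else None))
                else:
                    row.append(_cell_text(_RECORD_COLUMNS[c](rec)))
            lines.append("\t".join(row))
    else:
        lines.append("\t".join(cols))
        for rec in records:
            for t in trait_ids:
                st = rec.stats.get(t)
                if st is None or st.is_empty():
                    continue
                row = []
                for c in cols:
                    if c == "trait_id":
                        row.append(t)
                    elif c in _STAT_COLUMNS:
                        row.append(_cell_text(_STAT_COLUMNS[c](st)))
                    else:
                        row.append(_cell_text(_RECORD_COLUMNS[c](rec)))
                lines.append("\t".join(row))
    text = "\n".join(lines) + "\n"
    if out is None:
        return text
    Path(out).write_text(text)
    return None


# ---------------------------------------------------------------------------
# Multi-trait merge
# ---------------------------------------------------------------------------

@dataclass
class MergeReport:
    path: Path
    n_records: int
    trait_ids: list


def merge_traits(paths: Sequence, out_path, index: bool = True) -> MergeReport:
    """Merge single-trait (or multi-trait) GWAS-VCFs into one multi-trait file.

    Inputs must share the genome assembly and contig list; trait ids must
    not collide.  The output holds the union of loci — a trait missing at a
    variant gets null statistics in its sample column — sorted, written and
    re-indexed.  Variant IDs are kept only when they do not conflict across
    inputs.
    """
    if not paths:
        raise MergeError("no input files")
    all_meta: List[StudyMetadata] = []
    merged: dict = {}
    fields_needed = {"ES", "SE", "LP"}
    for p in paths:
        metadata, records = read_gwasvcf(p)
        for m in metadata:
            if any(m.trait_id == other.trait_id for other in all_meta):
                raise MergeError(f"trait id {m.trait_id!r} occurs in more than one input")
            if all_meta:
                if tuple(m.contigs) != tuple(all_meta[0].contigs):
                    raise MergeError(f"{p}: contig list differs from first input")
                if m.genome_assembly != all_meta[0].genome_assembly:
                    raise MergeError(
                        f"{p}: genome assembly {m.genome_assembly!r} != "
                        f"{all_meta[0].genome_assembly!r}"
                    )
            all_meta.append(m)
        for rec in records:
            for st in rec.stats.values():
                if st.af is not None:
                    fields_needed.add("AF")
                if st.ss is not None:
                    fields_needed.add("SS")
            key = rec.key()
            if key not in merged:
                merged[key] = rec
            else:
                tgt = merged[key]
                tgt.stats.update(rec.stats)
                for k, v in rec.info.items():
                    tgt.info.setdefault(k, v)
                if rec.ident is not None:
                    if tgt.ident is None:
                        tgt.ident = rec.ident
                    elif tgt.ident != rec.ident:
                        tgt.ident = None  # conflicting caller-supplied IDs

    # Drop IDs that would collide across different variants.
    id_count: dict = {}
    for rec in merged.values():
        if rec.ident is not None:
            id_count[rec.ident] = id_count.get(rec.ident, 0) + 1
    for rec in merged.values():
        if rec.ident is not None and id_count[rec.ident] > 1:
            rec.ident = None

    contigs = tuple(all_meta[0].contigs)
    header = build_header(all_meta, format_fields=sorted(fields_needed))
    ordered = sort_karyotypic(merged.values(), contigs)
    report = write_gwasvcf(ordered, header, out_path)
    if index:
        index_positions(out_path)
        index_rsids(out_path)
    return MergeReport(
        path=Path(out_path),
        n_records=report.n_written,
        trait_ids=[m.trait_id for m in all_meta],
    )


# ---------------------------------------------------------------------------
# File validation
# ---------------------------------------------------------------------------

@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str = ""


def validate_file(path) -> List[CheckResult]:
    """Run header, per-record, ID-uniqueness and sort-order checks.

    Returns one PASS/FAIL result per check; data problems are results, not
    exceptions.
    """
    results = []
    try:
        metadata = read_header_metadata(path)
        contigs = metadata[0].contigs if metadata else ()
        if not metadata or not contigs:
            raise WriteError("no traits or contigs declared")
        results.append(CheckResult(
            "header", True,
            f"{len(metadata)} trait(s), {len(contigs)} contig(s)",
        ))
    except Exception as exc:
        results.append(CheckResult("header", False, str(exc)))
        return results

    rank = {name: i for i, (name, _l) in enumerate(contigs)}
    n_violations = 0
    n_records = 0
    first_detail = ""
    sorted_ok = True
    prev = (-1, -1)
    records_for_ids = []
    for rec in iter_gwasvcf(path):
        n_records += 1
        violations = validate_record(rec, contigs)
        if violations:
            n_violations += len(violations)
            if not first_detail:
                first_detail = f"{rec.chrom}:{rec.pos} {violations[0]}"
        key = (rank.get(rec.chrom, math.inf), rec.pos)
        if key < prev:
            sorted_ok = False
        prev = key
        if rec.ident is not None:
            records_for_ids.append(rec)
    results.append(CheckResult(
        "records",
        n_violations == 0,
        f"{n_records} records, {n_violations} violations"
        + (f"; first: {first_detail}" if first_detail else ""),
    ))
    dupes = check_id_uniqueness(records_for_ids)
    results.append(CheckResult(
        "id_uniqueness",
        not dupes,
        "all non-null IDs unique" if not dupes else f"duplicated IDs: {dupes[:5]}",
    ))
    results.append(CheckResult(
        "sort_order",
        sorted_ok,
        "karyotypic order" if sorted_ok else "position regression detected",
    ))
    return results
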