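"""Retrieval over indexed GWAS-VCF files, plus a desk-scale benchmark harness.

Interval and point queries go through the tabix positional index; rsid
queries resolve the locus through the rsid index (rsids name loci, so a
split multiallelic site returns all sibling records) and then fetch by
position; P-value-threshold queries are a full linear scan — there is no
index over statistics, which is exactly why this query class is the slow
path.

The benchmark harness mirrors a query-performance evaluation at desk scale:
the same four query classes against the same records stored either as
indexed BGZF GWAS-VCF or as a plain unindexed TSV scanned line by line,
single-threaded, with repetition means and 95% confidence intervals.
Timings are informational — they depend on the hardware — and only
qualitative orderings are meaningful.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from scipy import stats as _sstats

from .errors import BenchmarkError, QueryError
from .model import GwasRecord, QueryRegion, lp_from_p
from .vcf_io import iter_gwasvcf, read_header_metadata, record_from_pysam, rsid_lookup

__all__ = [
    "query_interval",
    "query_rsid",
    "query_pvalue",
    "RsidQueryResult",
    "run_benchmark",
    "BenchmarkCell",
    "BenchmarkReport",
]


def _require(path, suffixes, hint) -> None:
    path = Path(path)
    if not any(path.with_name(path.name + s).exists() for s in suffixes):
        raise QueryError(f"no index found for {path}; {hint}")


# ---------------------------------------------------------------------------
# Query classes
# ---------------------------------------------------------------------------

def query_interval(path, region: QueryRegion) -> List[GwasRecord]:
    """Fetch records with ``pos`` inside a 1-based inclusive interval.

    Pos-anchored semantics: a deletion belongs to its anchor position only,
    so a record whose REF spans into the region from the left is excluded.
    Requires the tabix positional index.
    """
    _require(path, (".tbi", ".csi"), "run index_positions first")
    with pysam.VariantFile(str(path)) as vf:
        trait_ids = list(vf.header.samples)
        if region.chrom not in vf.header.contigs:
            return []
        out = []
        try:
            it = vf.fetch(region.chrom, region.start - 1, region.end)
        except ValueError:
            # contig declared in the header but absent from the index
            # (no records on it): an empty result, not an error
            return []
        for rec in it:
            # tabix returns REF-overlap; keep pos-anchored records only
            if region.start <= rec.pos <= region.end:
                out.append(record_from_pysam(rec, trait_ids))
        return out


@dataclass
class RsidQueryResult:
    """Records at the locus an rsid maps to; ``found`` distinguishes an rsid
    absent from the index from an indexed locus with no records."""

    rsid: str
    found: bool
    locus: Optional[Tuple[str, int]] = None
    records: List[GwasRecord] = field(default_factory=list)


def query_rsid(path, rsid: str, db_path=None, allele: Optional[Tuple[str, str]] = None) -> RsidQueryResult:
    """Fetch all records at the locus identified by an rsid.

    A split multiallelic site shares one rsid across its sibling records,
    so more than one record may come back; pass ``allele=(ref, alt)`` to
    filter the output down to the target substitution.
    """
    path = Path(path)
    db = Path(db_path) if db_path else path.with_name(path.name + ".rsidx")
    if not db.exists():
        raise QueryError(f"no rsid index at {db}; run index_rsids first")
    locus = rsid_lookup(db, rsid)
    if locus is None:
        return RsidQueryResult(rsid=rsid, found=False)
    chrom, pos = locus
    records = query_interval(path, QueryRegion(chrom, pos, pos))
    if allele is not None:
        ref, alt = allele
        records = [r for r in records if r.ref_allele == ref and r.alt_allele == alt]
    return RsidQueryResult(rsid=rsid, found=True, locus=locus, records=records)


def query_pvalue(path, p_threshold: float, trait_id: Optional[str] = None) -> Iterator[GwasRecord]:
    """Stream records significant at ``P < p_threshold`` (strict).

    A record matches when ``lp > -log10(threshold)`` for the chosen trait,
    or for *any* trait when ``trait_id`` is None; missing LP never matches.
    Full linear scan — no index assists this query class.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise QueryError(f"P threshold must be in (0, 1], got {p_threshold}")
    lp_min = lp_from_p(p_threshold)
    for rec in iter_gwasvcf(path):
        if trait_id is not None:
            st = rec.stats.get(trait_id)
            if st is not None and st.lp is not None and st.lp > lp_min:
                yield rec
        else:
            for st in rec.stats.values():
                if st.lp is not None and st.lp > lp_min:
                    yield rec
                    break


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

QUERY_CLASSES = ("position", "rsid", "interval", "pvalue")
MEDIA = ("gwasvcf", "tsv")

#: TSV column layout expected by the scan side of the benchmark (the
#: default long-form export of :func:`gwasvcfkit.vcf_io.export_tsv`).
_TSV_COLS = {"chrom": 0, "pos": 1, "effect": 2, "other": 3, "p": 6, "rsid": 9}


@dataclass
class BenchmarkCell:
    query_class: str
    medium: str
    mean_s: float
    ci_low: float
    ci_high: float
    n_results: int
    repetitions: int


@dataclass
class BenchmarkReport:
    cells: List[BenchmarkCell]
    n_variants: int

    def cell(self, query_class: str, medium: str) -> BenchmarkCell:
        for c in self.cells:
            if c.query_class == query_class and c.medium == medium:
                return c
        raise KeyError((query_class, medium))

    def to_tsv(self) -> str:
        lines = ["query_class\tmedium\tmean_s\tci_low\tci_high\tn_results\trepetitions"]
        for c in self.cells:
            lines.append(
                f"{c.query_class}\t{c.medium}\t{c.mean_s:.6f}\t{c.ci_low:.6f}"
                f"\t{c.ci_high:.6f}\t{c.n_results}\t{c.repetitions}"
            )
        return "\n".join(lines) + "\n"


def _mean_ci(durations: Sequence[float]) -> Tuple[float, float, float]:
    arr = np.asarray(durations, dtype=float)
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, mean, mean
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    t = float(_sstats.t.ppf(0.975, arr.size - 1))
    return mean, mean - t * sem, mean + t * sem


def _tsv_lines(path):
    with open(path, "rt") as fh:
        first = True
        for line in fh:
            if first:
                first = False
                continue  # header row
            yield line


def _vcf_body_lines(path):
    with pysam.BGZFile(str(path), "rb") as fh:
        for raw in fh:
            if raw[:1] != b"#":
                yield raw.decode()


def _media_consistent(path_vcf, path_tsv) -> int:
    """Check both media hold the same records; return the record count."""
    n_vcf = 0
    h_vcf = 0
    for line in _vcf_body_lines(path_vcf):
        parts = line.split("\t", 5)
        h_vcf ^= hash((parts[0], parts[1], parts[3], parts[4]))
        n_vcf += 1
    n_tsv = 0
    h_tsv = 0
    c = _TSV_COLS
    for line in _tsv_lines(path_tsv):
        parts = line.rstrip("\n").split("\t")
        h_tsv ^= hash((parts[c["chrom"]], parts[c["pos"]], parts[c["other"]], parts[c["effect"]]))
        n_tsv += 1
    if n_vcf != n_tsv or h_vcf != h_tsv:
        raise BenchmarkError(
            f"record sets differ between media (VCF: {n_vcf} records, TSV: "
            f"{n_tsv} rows); the comparison would be meaningless"
        )
    return n_vcf


def run_benchmark(
    path_vcf,
    path_tsv,
    repetitions: int = 100,
    seed: int = 0,
    interval_size: int = 1_000_000,
    p_threshold: float = 5e-8,
) -> BenchmarkReport:
    """Time the four query classes on indexed GWAS-VCF vs unindexed TSV.

    Both files must hold identical records (the TSV being the long-form
    single-trait export of the VCF).  Query targets — one position, one
    rsid, one interval of ``interval_size`` — are drawn deterministically
    from the file with ``seed``.  Every operation is single-threaded.
    Returns mean wall-clock seconds with 95% CIs per (query class, medium)
    cell; numbers are hardware-dependent and informational only.
    """
    if repetitions < 1:
        raise BenchmarkError("repetitions must be >= 1")
    path_vcf, path_tsv = Path(path_vcf), Path(path_tsv)
    n_variants = _media_consistent(path_vcf, path_tsv)
    if n_variants == 0:
        raise BenchmarkError("no records to benchmark")

    rng = np.random.default_rng(seed)
    target_idx = int(rng.integers(0, n_variants))
    target = None
    for i, line in enumerate(_vcf_body_lines(path_vcf)):
        if i == target_idx:
            parts = line.split("\t", 8)
            rsid = None
            for kv in parts[7].split(";"):
                if kv.startswith("RSID="):
                    rsid = kv[5:]
            target = (parts[0], int(parts[1]), rsid)
            break
    chrom, pos, rsid = target
    if rsid is None:
        raise BenchmarkError("benchmark target record has no rsid; regenerate with rsids")
    metadata = read_header_metadata(path_vcf)
    contig_len = dict(metadata[0].contigs)[chrom]
    iv_start = max(1, min(pos - interval_size // 2, contig_len - interval_size + 1))
    iv_end = min(contig_len, iv_start + interval_size - 1)
    lp_min = lp_from_p(p_threshold)

    # --- GWAS-VCF operations (tabix index / rsidx / linear scan) ---------
    tabix = pysam.TabixFile(str(path_vcf))
    db = path_vcf.with_name(path_vcf.name + ".rsidx")

    def vcf_position():
        return sum(1 for _ in tabix.fetch(chrom, pos - 1, pos))

    def vcf_rsid():
        locus = rsid_lookup(db, rsid)
        if locus is None:
            return 0
        return sum(1 for _ in tabix.fetch(locus[0], locus[1] - 1, locus[1]))

    def vcf_interval():
        return sum(1 for _ in tabix.fetch(chrom, iv_start - 1, iv_end))

    def vcf_pvalue():
        n = 0
        fmt_idx = None
        for line in _vcf_body_lines(path_vcf):
            parts = line.rstrip("\n").split("\t")
            if fmt_idx is None:
                fmt_idx = parts[8].split(":").index("LP")
            cell = parts[9].split(":")
            if len(cell) > fmt_idx and cell[fmt_idx] != ".":
                if float(cell[fmt_idx]) > lp_min:
                    n += 1
        return n

    # --- TSV operations (naive line scans) -------------------------------
    c = _TSV_COLS

    def tsv_position():
        n = 0
        pos_s = str(pos)
        for line in _tsv_lines(path_tsv):
            parts = line.split("\t")
            if parts[c["chrom"]] == chrom and parts[c["pos"]] == pos_s:
                n += 1
        return n

    def tsv_rsid():
        n = 0
        for line in _tsv_lines(path_tsv):
            parts = line.rstrip("\n").split("\t")
            if parts[c["rsid"]] == rsid:
                n += 1
        return n

    def tsv_interval():
        n = 0
        for line in _tsv_lines(path_tsv):
            parts = line.split("\t")
            if parts[c["chrom"]] == chrom and iv_start <= int(parts[c["pos"]]) <= iv_end:
                n += 1
        return n

    def tsv_pvalue():
        n = 0
        for line in _tsv_lines(path_tsv):
            parts = line.split("\t")
            tok = parts[c["p"]]
            if tok != "NA" and float(tok) < p_threshold:
                n += 1
        return n

    ops = {
        ("position", "gwasvcf"): vcf_position,
        ("rsid", "gwasvcf"): vcf_rsid,
        ("interval", "gwasvcf"): vcf_interval,
        ("pvalue", "gwasvcf"): vcf_pvalue,
        ("position", "tsv"): tsv_position,
        ("rsid", "tsv"): tsv_rsid,
        ("interval", "tsv"): tsv_interval,
        ("pvalue", "tsv"): tsv_pvalue,
    }

    cells = []
    try:
        for qc in QUERY_CLASSES:
            for medium in MEDIA:
                fn = ops[(qc, medium)]
                durations = []
                n_results = 0
                for _ in range(repetitions):
                    t0 = time.perf_counter()
                    n_results = fn()
                    durations.append(time.perf_counter() - t0)
                mean, lo, hi = _mean_ci(durations)
                cells.append(BenchmarkCell(qc, medium, mean, lo, hi, n_results, repetitions))
    finally:
        tabix.close()
    return BenchmarkReport(cells=cells, n_variants=n_variants)
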