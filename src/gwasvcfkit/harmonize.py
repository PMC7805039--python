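"""Allele harmonisation and variant normalisation against a reference genome.

Harmonisation rewrites each record so its non-effect (REF) allele matches
the reference sequence, which makes effect-size directionality consistent
across studies: if the input's *effect* allele is the one matching the
reference, the alleles are exchanged, the effect size negated and every
allele frequency complemented.  Records where neither allele matches are
incompatible (no strand flipping is ever attempted — palindromic A/T and
C/G variants make strand inference unsafe, so reverse-complement-only
matches are reported, never repaired).

Normalisation rewrites indels to the unique leftmost, minimal (trimmed)
spelling so that equivalent representations of one edit compare equal.
"""

from __future__ import annotations

import heapq
import pickle
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import pyfaidx

from .errors import NormalizationError, ReferenceError_, SortOrderError
from .model import GwasRecord, HarmonisationOutcome, TraitStats

__all__ = [
    "ReferenceGenome",
    "FastaReference",
    "InMemoryReference",
    "MultiAllelicSite",
    "harmonize_record",
    "normalize_variant",
    "normalize_record",
    "split_multiallelic",
    "sort_karyotypic",
    "load_rsid_map",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Reference genome access
# ---------------------------------------------------------------------------

class ReferenceGenome:
    """Lookup contract: ``fetch(chrom, start, end)`` with 1-based inclusive
    coordinates returning exactly ``end - start + 1`` uppercase bases, plus
    an ordered ``contigs`` list of (name, length).  Out-of-range requests
    raise, never truncate."""

    contigs: Tuple[Tuple[str, int], ...]

    def fetch(self, chrom: str, start: int, end: int) -> str:  # pragma: no cover
        raise NotImplementedError

    def contig_length(self, chrom: str) -> Optional[int]:
        for name, length in self.contigs:
            if name == chrom:
                return length
        return None

    def _check_range(self, chrom: str, start: int, end: int, length: Optional[int]):
        if length is None:
            raise ReferenceError_(f"contig {chrom!r} not in reference")
        if start < 1 or end < start or end > length:
            raise ReferenceError_(
                f"range {chrom}:{start}-{end} outside contig of length {length}"
            )


class FastaReference(ReferenceGenome):
    """Reference genome backed by an indexed FASTA file (FAI built on demand)."""

    def __init__(self, path):
        self.path = Path(path)
        self._fa = pyfaidx.Fasta(str(self.path), as_raw=True, sequence_always_upper=True)
        self.contigs = tuple((name, len(self._fa[name])) for name in self._fa.keys())
        self._lengths = dict(self.contigs)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        self._check_range(chrom, start, end, self._lengths.get(chrom))
        return str(self._fa[chrom][start - 1:end])

    def close(self):
        self._fa.close()


class InMemoryReference(ReferenceGenome):
    """Reference genome held as plain strings; used for speed (whole-contig
    preload) and for synthetic fixtures."""

    def __init__(self, sequences: dict):
        self._seq = {name: seq.upper() for name, seq in sequences.items()}
        self.contigs = tuple((name, len(seq)) for name, seq in self._seq.items())
        self._lengths = dict(self.contigs)

    @classmethod
    def from_fasta(cls, path) -> "InMemoryReference":
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    def fetch(self, chrom: str, start: int, end: int) -> str:
        self._check_range(chrom, start, end, self._lengths.get(chrom))
        return self._seq[chrom][start - 1:end]


# ---------------------------------------------------------------------------
# Harmonisation
# ---------------------------------------------------------------------------

def _flip_stats(stats: dict) -> dict:
    out = {}
    for trait, st in stats.items():
        out[trait] = TraitStats(
            es=None if st.es is None else -st.es,
            se=st.se,
            lp=st.lp,
            af=None if st.af is None else 1.0 - st.af,
            ss=st.ss,
        )
    return out


def harmonize_record(record: GwasRecord, ref: ReferenceGenome) -> HarmonisationOutcome:
    """Make the record's REF (non-effect) allele match the reference genome.

    Decision order:

    1. REF allele equals the reference sequence at ``pos`` → ``unchanged``.
       (For indel pairs like A/AT both alleles are reference-compatible,
       so the input's designation of the non-effect allele is trusted.)
    2. Else, ALT allele equals the reference over its own length →
       ``swapped``: alleles exchanged, ``es := -es``, every ``af`` (site and
       per-trait) complemented.
    3. Else ``incompatible`` — with a distinguishing detail when the alleles
       would only match after reverse complement (possible strand issue;
       never repaired).

    A locus outside the reference (unknown contig, position past the contig
    end) gives ``not_in_reference``.  Harmonisation is idempotent: applying
    it to its own output returns ``unchanged``.
    """
    length = ref.contig_length(record.chrom)
    if length is None:
        return HarmonisationOutcome(
            record, "not_in_reference", f"contig {record.chrom!r} not in reference"
        )
    span_ref = record.pos + len(record.ref_allele) - 1
    span_alt = record.pos + len(record.alt_allele) - 1
    if record.pos < 1 or min(span_ref, span_alt) > length:
        return HarmonisationOutcome(
            record, "not_in_reference",
            f"{record.chrom}:{record.pos} outside contig of length {length}",
        )

    def seq_at(n: int) -> Optional[str]:
        if record.pos + n - 1 > length:
            return None
        return ref.fetch(record.chrom, record.pos, record.pos + n - 1)

    ref_seq = seq_at(len(record.ref_allele))
    if ref_seq == record.ref_allele:
        return HarmonisationOutcome(record, "unchanged", "non-effect allele matches reference")

    alt_seq = seq_at(len(record.alt_allele))
    if alt_seq == record.alt_allele:
        info = dict(record.info)
        if info.get("af") is not None:
            info["af"] = 1.0 - info["af"]
        swapped = replace(
            record,
            ref_allele=record.alt_allele,
            alt_allele=record.ref_allele,
            info=info,
            stats=_flip_stats(record.stats),
        )
        return HarmonisationOutcome(
            swapped, "swapped",
            "effect allele matched reference; alleles exchanged, ES negated, AF complemented",
        )

    if ref_seq is not None and (
        _revcomp(record.ref_allele) == ref_seq
        or (alt_seq is not None and _revcomp(record.alt_allele) == alt_seq)
    ):
        return HarmonisationOutcome(
            record, "incompatible",
            "alleles match the reference only after reverse complement; "
            "forward-strand policy forbids strand flipping",
        )
    return HarmonisationOutcome(
        record, "incompatible",
        f"neither allele matches reference sequence {ref_seq!r} at "
        f"{record.chrom}:{record.pos}",
    )


# ---------------------------------------------------------------------------
# Normalisation (left-align + trim)
# ---------------------------------------------------------------------------

def normalize_variant(
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    ref: ReferenceGenome,
) -> Tuple[int, str, str]:
    """Return the unique leftmost, minimal spelling of a variant.

    Precondition: ``ref_allele`` equals the reference sequence at
    ``pos .. pos+len-1`` (run after :func:`harmonize_record`).  The
    algorithm is the standard left-align-and-trim fixpoint:

    1. while both alleles end with the same base and both have length ≥ 2,
       drop the last base;
    2. if either allele would become empty, prepend the reference base at
       ``pos - 1`` to both and decrement ``pos``; repeat 1–2 to fixpoint;
    3. while both alleles begin with the same base and both have length ≥ 2,
       drop the first base and increment ``pos``.

    Applying the result to the reference yields a haplotype identical to
    applying the input spelling.  SNVs are fixed points.  A variant whose
    left extension would run past the contig start cannot be anchored and
    raises :class:`NormalizationError`.
    """
    r, a = ref_allele, alt_allele
    if len(r) == 1 and len(a) == 1:
        return pos, r, a
    while True:
        while len(r) >= 2 and len(a) >= 2 and r[-1] == a[-1]:
            r, a = r[:-1], a[:-1]
        if r[-1] != a[-1] or (len(r) >= 2 and len(a) >= 2):
            break
        # One allele is a prefix of the other and would empty on the next
        # trim: extend left with the preceding reference base.
        if pos <= 1:
            raise NormalizationError(
                f"variant at {chrom}:{pos} ({ref_allele}>{alt_allele}) cannot be "
                f"left-aligned: extension reaches the contig start"
            )
        base = ref.fetch(chrom, pos - 1, pos - 1)
        r, a = base + r[:-1], base + a[:-1]
        pos -= 1
    while len(r) >= 2 and len(a) >= 2 and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    return pos, r, a


def normalize_record(record: GwasRecord, ref: ReferenceGenome) -> GwasRecord:
    """Apply :func:`normalize_variant` to a harmonised record."""
    pos, r, a = normalize_variant(
        record.chrom, record.pos, record.ref_allele, record.alt_allele, ref
    )
    if (pos, r, a) == (record.pos, record.ref_allele, record.alt_allele):
        return record
    return replace(record, pos=pos, ref_allele=r, alt_allele=a)


# ---------------------------------------------------------------------------
# Multiallelic splitting
# ---------------------------------------------------------------------------

@dataclass
class MultiAllelicSite:
    """A locus with ``k >= 1`` alternative alleles and per-alt statistics
    (``stats[i]`` maps trait id → :class:`TraitStats` for ``alts[i]``)."""

    chrom: str
    pos: int
    ref_allele: str
    alts: Sequence[str]
    stats: Sequence[dict]
    rsid: Optional[str] = None
    info: Optional[dict] = None


def split_multiallelic(site: MultiAllelicSite) -> List[GwasRecord]:
    """Split a multiallelic site into one record per alternative allele.

    Each record shares the input chrom/pos/REF and carries its own ALT and
    statistics; the site-level rsid is copied into every record's info
    (rsids identify loci, not substitutions, so siblings legitimately share
    one).  Records should be normalised afterwards — siblings of an indel
    site typically end up at different positions/spellings.
    """
    if len(site.alts) < 1:
        raise ValueError("multiallelic site must have at least one alternative allele")
    if len(site.stats) != len(site.alts):
        raise ValueError(
            f"site {site.chrom}:{site.pos} has {len(site.alts)} alts but "
            f"{len(site.stats)} statistics blocks"
        )
    out = []
    for alt, stats in zip(site.alts, site.stats):
        info = dict(site.info or {})
        if site.rsid is not None:
            info["rsid"] = site.rsid
        out.append(GwasRecord(
            chrom=site.chrom,
            pos=site.pos,
            ref_allele=site.ref_allele,
            alt_allele=alt,
            info=info,
            stats={t: replace(s) for t, s in stats.items()},
        ))
    return out


# ---------------------------------------------------------------------------
# Karyotypic sort
# ---------------------------------------------------------------------------

def sort_karyotypic(
    records: Iterable[GwasRecord],
    contigs: Sequence,
    chunk_size: int = 250_000,
    tmp_dir=None,
) -> Iterator[GwasRecord]:
    """Sort records by (header contig order, position, REF, ALT), stably.

    Streams its input; once more than ``chunk_size`` records are buffered,
    sorted chunks are spilled to temporary files and merged, so memory stays
    bounded for inputs larger than memory.  A record on an undeclared contig
    is fatal (the header's contig list *defines* the order).
    """
    rank = {name: i for i, (name, _len) in enumerate(contigs)}

    def key(rec: GwasRecord, seq: int):
        try:
            r = rank[rec.chrom]
        except KeyError:
            raise SortOrderError(
                f"record at {rec.chrom}:{rec.pos}: contig {rec.chrom!r} is not declared"
            ) from None
        return (r, rec.pos, rec.ref_allele, rec.alt_allele, seq)

    buf: list = []
    spills: list = []
    tmp = None
    seq = 0
    try:
        for rec in records:
            buf.append((key(rec, seq), rec))
            seq += 1
            if len(buf) >= chunk_size:
                buf.sort(key=lambda kv: kv[0])
                if tmp is None:
                    tmp = tempfile.TemporaryDirectory(
                        prefix="gwasvcf-sort-", dir=tmp_dir
                    )
                path = Path(tmp.name) / f"chunk-{len(spills):05d}.pkl"
                with open(path, "wb") as fh:
                    pickle.dump(buf, fh, protocol=pickle.HIGHEST_PROTOCOL)
                spills.append(path)
                buf = []

        buf.sort(key=lambda kv: kv[0])
        if not spills:
            for _k, rec in buf:
                yield rec
            return

        def read_chunk(path):
            with open(path, "rb") as fh:
                yield from pickle.load(fh)

        streams = [read_chunk(p) for p in spills] + [iter(buf)]
        for _k, rec in heapq.merge(*streams, key=lambda kv: kv[0]):
            yield rec
    finally:
        if tmp is not None:
            tmp.cleanup()


# ---------------------------------------------------------------------------
# rsid annotation source
# ---------------------------------------------------------------------------

def load_rsid_map(path) -> dict:
    """Load a dbSNP-style rsid↔locus mapping into ``{(chrom, pos): rsid}``.

    Accepts either a VCF (rsid taken from the ID column) or a 3-column TSV
    ``rsid<TAB>chrom<TAB>pos`` (header optional).  Intended for annotating
    input tables that lack an rsid column.
    """
    path = Path(path)
    mapping: dict = {}
    import gzip as _gzip

    with open(path, "rb") as fh:
        magic = fh.read(2)
    opener = _gzip.open if magic == b"\x1f\x8b" else open
    with opener(path, "rt") as fh:
        first = True
        for line in fh:
            line = line.rstrip("\r\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 5 and parts[1].isdigit():
                # VCF body line: CHROM POS ID REF ALT ...
                chrom, pos, rsid = parts[0], int(parts[1]), parts[2]
            elif len(parts) >= 3:
                rsid, chrom = parts[0], parts[1]
                if first and not parts[2].isdigit():
                    first = False
                    continue  # header row
                pos = int(parts[2])
            else:
                continue
            first = False
            if rsid and rsid != "." and rsid.startswith("rs"):
                mapping[(chrom, pos)] = rsid
    return mapping
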