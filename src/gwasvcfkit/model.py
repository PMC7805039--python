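"""Core data model for GWAS summary statistics stored as GWAS-VCF.

The unit of storage is one variant — a single reference/alternative allele
substitution at a 1-based position — carrying per-trait association
statistics.  The alternative allele is always the *effect* allele, so the
sign of the effect size is unambiguous across studies.  Per-trait statistics
live in VCF sample columns (one column per trait); the site-level rsid, if
known, lives in INFO because an rsid identifies a locus, not an allelic
substitution, and therefore cannot serve as the unique per-row ID.

Everything in this module is pure data + validation; serialization lives in
:mod:`gwasvcfkit.vcf_io`.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "LP_CAP",
    "GwasRecord",
    "TraitStats",
    "StudyMetadata",
    "ColumnSchema",
    "HarmonisationOutcome",
    "QueryRegion",
    "Violation",
    "lp_from_p",
    "p_from_lp",
    "validate_record",
    "check_id_uniqueness",
]

#: LP value stored when the input P value underflowed to exactly zero.
#: Keeps such variants at the top of any significance ranking without
#: inventing precision the source never had.
LP_CAP = 999.0

_ALLELE_RE = re.compile(r"[ACGT]+\Z")
_RSID_RE = re.compile(r"rs\d+\Z")


# ---------------------------------------------------------------------------
# P value <-> -log10 P
# ---------------------------------------------------------------------------

def lp_from_p(p: float, *, where: str = "") -> float:
    """Convert a P value to LP = -log10(P).

    Parameters
    ----------
    p:
        Association P value, required to lie in [0, 1].  ``p == 0``
        (an underflow in the source tool) is stored as :data:`LP_CAP`
        with a warning rather than +inf.
    where:
        Optional context (e.g. ``"line 42"``) included in error messages.

    Raises
    ------
    ValueError
        If ``p`` is outside [0, 1] or not finite.
    """
    ctx = f" ({where})" if where else ""
    if not math.isfinite(p) or p < 0.0 or p > 1.0:
        raise ValueError(f"P value outside [0, 1]: {p!r}{ctx}")
    if p == 0.0:
        warnings.warn(
            f"P value of exactly 0 (underflow in source){ctx}; "
            f"storing LP={LP_CAP:g}",
            stacklevel=2,
        )
        return LP_CAP
    return -math.log10(p)


def p_from_lp(lp: float) -> float:
    """Inverse of :func:`lp_from_p`: P = 10**(-LP)."""
    return 10.0 ** (-lp)


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class TraitStats:
    """Association statistics of one trait at one variant.

    ``es`` is the effect size of the *alternative* (effect) allele, in the
    trait's units; ``se`` its standard error; ``lp`` the -log10 P value;
    ``af`` the effect-allele frequency in the analysed sample; ``ss`` the
    per-variant sample size.  Any field may be ``None`` (missing), which is
    distinct from zero.
    """

    es: Optional[float] = None
    se: Optional[float] = None
    lp: Optional[float] = None
    af: Optional[float] = None
    ss: Optional[int] = None

    def is_empty(self) -> bool:
        return (
            self.es is None
            and self.se is None
            and self.lp is None
            and self.af is None
            and self.ss is None
        )


@dataclass(slots=True)
class GwasRecord:
    """One variant and its per-trait association statistics.

    Exactly one alternative allele per record: multiallelic sites are split
    into separate records before this type is constructed.  ``filters``
    empty means PASS/null.  ``info`` may carry ``af`` (site-level
    alternative-allele frequency in [0, 1]) and ``rsid`` (dbSNP locus
    identifier, ``rs`` followed by digits).  ``stats`` maps trait id to
    :class:`TraitStats` in file column order.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ident: Optional[str] = None
    qual: Optional[float] = None
    filters: set = field(default_factory=set)
    info: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def key(self) -> tuple:
        """Identity of the allelic substitution."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(slots=True)
class StudyMetadata:
    """Header metadata for one trait (one VCF sample column).

    ``contigs`` is the ordered (name, length) list that defines the
    karyotypic sort order of the file body; all traits in one file share the
    same contigs and genome assembly.
    """

    trait_id: str
    trait_label: str = ""
    trait_ontology: Optional[str] = None
    study_id: Optional[str] = None
    sample_size: Optional[int] = None
    ancestry: Optional[str] = None
    units: Optional[str] = None
    association_test: Optional[str] = None
    source_file: str = ""
    file_date: str = ""
    genome_assembly: str = ""
    contigs: tuple = ()


@dataclass(frozen=True)
class ColumnSchema:
    """Declarative mapping from an input table's columns to semantic fields.

    ``columns`` maps field names (``chrom``, ``pos``, ``effect_allele``,
    ``other_allele``, ``es`` | ``or``, ``p`` | ``lp``, and optionally
    ``se``, ``af``, ``ss``, ``rsid``, ``ident``) to either a header name or
    a 0-based column index.  ``position_base`` declares the input coordinate
    convention (0 or 1); output is always 1-based.
    """

    columns: Mapping[str, Union[str, int]]
    delimiter: str = "\t"
    missing_tokens: frozenset = frozenset({"NA", "", "."})
    position_base: int = 1
    header_row: bool = True

    def source(self, fieldname: str):
        return self.columns.get(fieldname)


#: Harmonisation status codes.
HARMONISATION_STATUSES = ("unchanged", "swapped", "incompatible", "not_in_reference")


@dataclass(slots=True)
class HarmonisationOutcome:
    """A record plus a status describing what harmonisation did to it.

    ``swapped`` means the input's effect allele matched the reference, so
    the alleles were exchanged, the effect size negated and every allele
    frequency complemented.  ``incompatible`` / ``not_in_reference`` records
    are excluded from output (or emitted with a FILTER label, per converter
    flag).
    """

    record: GwasRecord
    status: str
    detail: str = ""


@dataclass(frozen=True)
class QueryRegion:
    """1-based, inclusive genomic interval; a point query has start == end."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"region start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"region end {self.end} precedes start {self.start}"
            )

    @classmethod
    def parse(cls, text: str) -> "QueryRegion":
        """Parse ``CHR:START-END`` or ``CHR:POS``."""
        chrom, _, span = text.partition(":")
        if not chrom or not span:
            raise ValueError(f"cannot parse region {text!r}; expected CHR:START-END")
        lo, _, hi = span.partition("-")
        start = int(lo.replace(",", ""))
        end = int(hi.replace(",", "")) if hi else start
        return cls(chrom, start, end)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """A machine-readable validation failure; violations are data, not
    exceptions."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.code}: {self.message}"


def _contig_map(contigs: Sequence) -> dict:
    return {name: length for name, length in contigs}


def validate_record(record: GwasRecord, contigs: Sequence) -> list:
    """Check every record invariant; return a list of :class:`Violation`.

    An empty list means the record is valid: position is 1-based and within
    its declared contig, alleles are non-identical A/C/G/T strings, the
    optional site frequency is a probability and the rsid well-formed, and
    per-trait statistics are individually sane.  Pure function — no I/O, no
    mutation.
    """
    v: list = []
    if record.pos < 1:
        v.append(Violation(
            "POSITION_NOT_ONE_BASED",
            f"position {record.pos} at {record.chrom}: coordinates must start at one",
        ))
    for label, allele in (("REF", record.ref_allele), ("ALT", record.alt_allele)):
        if not _ALLELE_RE.fullmatch(allele or ""):
            v.append(Violation(
                "ALLELE_NOT_ACGT",
                f"{label} allele {allele!r} contains characters outside A/C/G/T",
            ))
    if record.ref_allele == record.alt_allele:
        v.append(Violation(
            "ALLELES_IDENTICAL",
            f"REF and ALT are both {record.ref_allele!r}",
        ))
    cmap = _contig_map(contigs)
    if record.chrom not in cmap:
        v.append(Violation(
            "CONTIG_UNKNOWN",
            f"chromosome {record.chrom!r} is not a declared contig",
        ))
    elif record.pos >= 1 and record.pos + max(len(record.ref_allele), 1) - 1 > cmap[record.chrom]:
        v.append(Violation(
            "POSITION_PAST_CONTIG_END",
            f"{record.chrom}:{record.pos} (REF length {len(record.ref_allele)}) "
            f"exceeds contig length {cmap[record.chrom]}",
        ))
    af = record.info.get("af")
    if af is not None and not (0.0 <= af <= 1.0):
        v.append(Violation("AF_OUT_OF_RANGE", f"site AF {af} outside [0, 1]"))
    rsid = record.info.get("rsid")
    if rsid is not None and not _RSID_RE.fullmatch(str(rsid)):
        v.append(Violation("RSID_MALFORMED", f"rsid {rsid!r} does not match rs[0-9]+"))
    for trait_id, st in record.stats.items():
        if st.se is not None and not st.se > 0:
            v.append(Violation(
                "SE_NOT_POSITIVE", f"trait {trait_id}: SE {st.se} must be > 0"
            ))
        if st.lp is not None and st.lp < 0:
            v.append(Violation(
                "LP_NEGATIVE", f"trait {trait_id}: LP {st.lp} must be >= 0"
            ))
        if st.af is not None and not (0.0 <= st.af <= 1.0):
            v.append(Violation(
                "AF_OUT_OF_RANGE", f"trait {trait_id}: AF {st.af} outside [0, 1]"
            ))
        if st.ss is not None and st.ss < 1:
            v.append(Violation(
                "SS_NOT_POSITIVE", f"trait {trait_id}: sample size {st.ss} must be >= 1"
            ))
    return v


def check_id_uniqueness(records: Iterable[GwasRecord]) -> list:
    """Return every non-null variant ID that occurs in more than one record.

    Null (``None``) IDs are exempt — any number of records may leave the ID
    column null.  Order of the result follows first appearance of the
    duplicated ID.
    """
    counts: Counter = Counter()
    order: list = []
    for rec in records:
        if rec.ident is None:
            continue
        counts[rec.ident] += 1
        if counts[rec.ident] == 2:
            order.append(rec.ident)
    return order
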