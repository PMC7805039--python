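"""Read tabular summary statistics under a user-defined column schema.

GWAS tools emit summary statistics in wildly different tabular layouts
(plink, GCTA, BOLT-LMM, METAL, Neale-lab dumps, ...).  Rather than guessing
column semantics, the converter requires an explicit schema document that
maps semantic fields to source columns.  Reading is conservative: rows that
cannot be parsed are reported with their line number and reason, never
silently dropped, and the row-count ledger (read = emitted + rejected)
always balances.
"""

from __future__ import annotations

import gzip
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Tuple, Union

from .errors import IngestError, SchemaError
from .model import ColumnSchema, GwasRecord, TraitStats, lp_from_p

__all__ = [
    "MANDATORY_FIELDS",
    "OPTIONAL_FIELDS",
    "RowIssue",
    "IngestResult",
    "load_schema",
    "iter_rows",
    "read_rows",
]

#: Fields that must be mapped (``es`` may be replaced by ``or``, and either
#: ``p`` or ``lp`` satisfies the significance requirement).
MANDATORY_FIELDS = ("chrom", "pos", "effect_allele", "other_allele")
EFFECT_FIELDS = ("es", "or")
SIGNIFICANCE_FIELDS = ("p", "lp")
OPTIONAL_FIELDS = ("se", "af", "ss", "rsid", "ident")

_ALL_FIELDS = set(MANDATORY_FIELDS) | set(EFFECT_FIELDS) | set(SIGNIFICANCE_FIELDS) | set(OPTIONAL_FIELDS)
_SCHEMA_KEYS = {"columns", "delimiter", "missing_tokens", "position_base", "header_row"}

DEFAULT_MISSING_TOKENS = frozenset({"NA", "", "."})


@dataclass(frozen=True)
class RowIssue:
    """A rejected (or otherwise noteworthy) input row."""

    line: int
    code: str
    message: str


@dataclass
class IngestResult:
    """Everything read from one table: candidates, issues, and the ledger
    of row counts (``read == emitted + rejected`` always)."""

    records: list = field(default_factory=list)
    issues: list = field(default_factory=list)
    n_read: int = 0
    n_emitted: int = 0
    n_rejected: int = 0


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

def load_schema(source: Union[str, Path, dict]) -> ColumnSchema:
    """Load and validate a schema document (JSON file/string or dict).

    The document is a flat object::

        {
          "columns": {"chrom": "CHR", "pos": "BP", "effect_allele": "A1",
                      "other_allele": "A2", "es": "BETA", "se": "SE",
                      "p": "P"},
          "delimiter": "\\t",
          "missing_tokens": ["NA", "", "."],
          "position_base": 1,
          "header_row": true
        }

    Column values are header names (when ``header_row`` is true) or 0-based
    integer indexes.  Unknown keys — at either level — are rejected loudly so
    that typos cannot silently unmap a field.
    """
    if isinstance(source, dict):
        doc = source
    else:
        source = Path(source) if not str(source).lstrip().startswith("{") else source
        if isinstance(source, Path):
            try:
                doc = json.loads(source.read_text())
            except OSError as exc:
                raise SchemaError(f"cannot read schema document {source}: {exc}") from exc
            except json.JSONDecodeError as exc:
                raise SchemaError(f"schema document {source} is not valid JSON: {exc}") from exc
        else:
            try:
                doc = json.loads(source)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"schema string is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("schema document must be a JSON object")

    unknown = set(doc) - _SCHEMA_KEYS
    if unknown:
        raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
    columns = doc.get("columns")
    if not isinstance(columns, dict) or not columns:
        raise SchemaError("schema must contain a non-empty 'columns' mapping")
    unknown_fields = set(columns) - _ALL_FIELDS
    if unknown_fields:
        raise SchemaError(
            f"unknown column fields: {sorted(unknown_fields)}; "
            f"known fields: {sorted(_ALL_FIELDS)}"
        )
    for f in MANDATORY_FIELDS:
        if f not in columns:
            raise SchemaError(f"{f.upper()}_UNMAPPED: mandatory field {f!r} has no column")
    if not any(f in columns for f in EFFECT_FIELDS):
        raise SchemaError("ES_UNMAPPED: map an 'es' (beta) or 'or' (odds ratio) column")
    if all(f in columns for f in EFFECT_FIELDS):
        raise SchemaError("map either 'es' or 'or', not both")
    if not any(f in columns for f in SIGNIFICANCE_FIELDS):
        raise SchemaError("P_UNMAPPED: map a 'p' or 'lp' column")

    position_base = doc.get("position_base", 1)
    if position_base not in (0, 1):
        raise SchemaError(f"position_base must be 0 or 1, got {position_base!r}")
    missing = doc.get("missing_tokens")
    tokens = DEFAULT_MISSING_TOKENS if missing is None else DEFAULT_MISSING_TOKENS | set(missing)
    header_row = bool(doc.get("header_row", True))
    for name, col in columns.items():
        if isinstance(col, bool) or not isinstance(col, (str, int)):
            raise SchemaError(f"column for {name!r} must be a header name or integer index")
        if isinstance(col, int) and col < 0:
            raise SchemaError(f"column index for {name!r} must be >= 0")
        if isinstance(col, str) and not header_row:
            raise SchemaError(
                f"column for {name!r} is a header name but header_row is false"
            )
    return ColumnSchema(
        columns=dict(columns),
        delimiter=doc.get("delimiter", "\t"),
        missing_tokens=frozenset(tokens),
        position_base=int(position_base),
        header_row=header_row,
    )


# ---------------------------------------------------------------------------
# Row reading
# ---------------------------------------------------------------------------

def _open_text(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            if data[:2] == b"\x1f\x8b":
                data = gzip.decompress(data)
            try:
                return io.StringIO(data.decode("utf-8"))
            except UnicodeDecodeError as exc:
                raise IngestError(f"input stream is not UTF-8 text: {exc}") from exc
        return io.StringIO(data)
    path = Path(source)
    try:
        with open(path, "rb") as fh:
            magic = fh.read(2)
    except OSError as exc:
        raise IngestError(f"cannot open {path}: {exc}") from exc
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _resolve_indexes(schema: ColumnSchema, header: Optional[list]) -> dict:
    idx = {}
    for name, col in schema.columns.items():
        if isinstance(col, int):
            idx[name] = col
        else:
            if header is None:
                raise IngestError(
                    f"schema names column {col!r} for {name!r} but the table has no header row"
                )
            try:
                idx[name] = header.index(col)
            except ValueError:
                raise IngestError(
                    f"column {col!r} (for field {name!r}) not found in header: {header}"
                ) from None
    return idx


def iter_rows(
    source,
    schema: ColumnSchema,
    trait_id: str = "trait",
) -> Iterator[Tuple[int, Optional[GwasRecord], Optional[RowIssue]]]:
    """Stream a table, yielding ``(line_number, candidate, issue)`` triples.

    Exactly one of ``candidate``/``issue`` is non-None per data row.  Line
    numbers are 1-based over the physical file (header included).  Rows are
    yielded in input order; sorting is the serializer's job.
    """
    fh = _open_text(source)
    lineno = 0
    try:
        header = None
        if schema.header_row:
            first = fh.readline()
            lineno += 1
            if first == "":
                raise IngestError("input table is empty (no header row)")
            header = first.rstrip("\r\n").split(schema.delimiter)
        idx = _resolve_indexes(schema, header)
        ncols_needed = max(idx.values()) + 1

        for raw in fh:
            lineno += 1
            line = raw.rstrip("\r\n")
            if not line:
                continue
            parts = line.split(schema.delimiter)
            rec, issue = _parse_row(parts, idx, ncols_needed, schema, trait_id, lineno)
            yield lineno, rec, issue
    except UnicodeDecodeError as exc:
        raise IngestError(f"input is not decodable text: {exc}") from exc
    finally:
        fh.close()


def _parse_row(parts, idx, ncols_needed, schema, trait_id, lineno):
    miss = schema.missing_tokens

    def reject(code, message):
        return None, RowIssue(lineno, code, message)

    if len(parts) < ncols_needed:
        return reject("TOO_FEW_COLUMNS", f"{len(parts)} columns, need {ncols_needed}")

    def cell(name):
        i = idx.get(name)
        return None if i is None else parts[i]

    def numeric(name, required=False):
        tok = cell(name)
        if tok is None or tok in miss:
            if required:
                raise _RowError("MISSING_REQUIRED", f"field {name!r} is missing")
            return None
        try:
            val = float(tok)
        except ValueError:
            raise _RowError("NOT_NUMERIC", f"field {name!r} = {tok!r} is not numeric")
        if not math.isfinite(val):
            raise _RowError("NOT_FINITE", f"field {name!r} = {tok!r} is not finite")
        return val

    try:
        chrom = cell("chrom")
        if chrom is None or chrom in miss:
            raise _RowError("MISSING_REQUIRED", "chromosome is missing")
        pos_tok = cell("pos")
        if pos_tok is None or pos_tok in miss:
            raise _RowError("MISSING_REQUIRED", "position is missing")
        try:
            pos = int(pos_tok)
        except ValueError:
            raise _RowError("NOT_NUMERIC", f"position {pos_tok!r} is not an integer")
        pos += 1 - schema.position_base
        if pos < 1:
            raise _RowError(
                "POSITION_NOT_ONE_BASED",
                f"position {pos} after base correction; coordinates must start at one",
            )

        effect = (cell("effect_allele") or "").upper()
        other = (cell("other_allele") or "").upper()
        for label, a in (("effect", effect), ("other", other)):
            if not a or any(c not in "ACGT" for c in a):
                raise _RowError(
                    "ALLELE_NOT_ACGT",
                    f"{label} allele {a!r} is not an explicit A/C/G/T haplotype",
                )

        if "es" in idx:
            es = numeric("es", required=True)
        else:
            orv = numeric("or", required=True)
            if orv <= 0:
                raise _RowError("OR_NOT_POSITIVE", f"odds ratio {orv} must be > 0")
            es = math.log(orv)
        se = numeric("se")
        if se is not None and se <= 0:
            raise _RowError("SE_NOT_POSITIVE", f"SE {se} must be > 0")

        p = numeric("p") if "p" in idx else None
        lp = numeric("lp") if "lp" in idx else None
        if p is not None:
            try:
                lp_from_p_val = lp_from_p(p, where=f"line {lineno}")
            except ValueError as exc:
                raise _RowError("P_OUT_OF_RANGE", str(exc))
            if lp is not None and not math.isclose(lp, lp_from_p_val, rel_tol=1e-3, abs_tol=1e-3):
                raise _RowError(
                    "P_LP_INCONSISTENT",
                    f"mapped P {p} implies LP {lp_from_p_val:.4f} but LP column says {lp}",
                )
            lp = lp_from_p_val
        if lp is not None and lp < 0:
            raise _RowError("LP_NEGATIVE", f"LP {lp} must be >= 0")

        af = numeric("af")
        if af is not None and not (0.0 <= af <= 1.0):
            raise _RowError("AF_OUT_OF_RANGE", f"allele frequency {af} outside [0, 1]")
        ss_val = numeric("ss")
        ss = None
        if ss_val is not None:
            ss = int(round(ss_val))
            if ss < 1:
                raise _RowError("SS_NOT_POSITIVE", f"sample size {ss} must be >= 1")

        info = {}
        rsid = cell("rsid")
        if rsid is not None and rsid not in miss:
            info["rsid"] = rsid
        ident = cell("ident")
        ident = None if ident is None or ident in miss else ident

        rec = GwasRecord(
            chrom=chrom,
            pos=pos,
            ref_allele=other,
            alt_allele=effect,
            ident=ident,
            info=info,
            stats={trait_id: TraitStats(es=es, se=se, lp=lp, af=af, ss=ss)},
        )
        return rec, None
    except _RowError as exc:
        return reject(exc.code, exc.message)


class _RowError(Exception):
    def __init__(self, code, message):
        super().__init__(message)
        self.code = code
        self.message = message


def read_rows(source, schema: ColumnSchema, trait_id: str = "trait") -> IngestResult:
    """Read a whole table into an :class:`IngestResult`.

    Thin collector over :func:`iter_rows` for inputs that fit in memory;
    the streaming form is what the conversion pipeline uses.
    """
    result = IngestResult()
    for _, rec, issue in iter_rows(source, schema, trait_id):
        result.n_read += 1
        if rec is not None:
            result.records.append(rec)
            result.n_emitted += 1
        else:
            result.issues.append(issue)
            result.n_rejected += 1
    return result
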