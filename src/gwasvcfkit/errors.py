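"""Exception hierarchy for the toolkit.

Data-quality problems in individual rows are *not* exceptions — they are
reported as issues/violations so that messy input files can still be
converted.  Exceptions are reserved for conditions that invalidate a whole
operation (bad schema, unsorted input handed to the writer, missing index,
...).
"""


class GwasVcfError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(GwasVcfError):
    """The column-schema document is invalid (missing/unknown mappings)."""


class IngestError(GwasVcfError):
    """The input table cannot be read at all (not per-row problems)."""


class ReferenceError_(GwasVcfError):
    """A reference-genome lookup was out of range or malformed."""


class NormalizationError(GwasVcfError):
    """A variant cannot be left-aligned (e.g. runs off the contig start)."""


class SortOrderError(GwasVcfError):
    """Records are not in karyotypic order, or a contig is undeclared."""


class WriteError(GwasVcfError):
    """Serialization failed (duplicate IDs, undeclared fields, disk)."""


class IndexingError(GwasVcfError):
    """Positional or rsid index could not be built."""


class QueryError(GwasVcfError):
    """A query could not be executed (missing index, bad region/threshold)."""


class MergeError(GwasVcfError):
    """Multi-trait merge preconditions violated (assembly/contig/trait-id)."""


class SimulationError(GwasVcfError):
    """Synthetic-data generation was asked for something impossible."""


class BenchmarkError(GwasVcfError):
    """Benchmark preconditions violated (record sets differ between media)."""
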