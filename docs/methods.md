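# Methods

This note documents the models, algorithms and design choices behind
gwasvcf-kit: what the format guarantees, how harmonisation and
normalisation work, what the synthetic-data generator does and does not
emulate, and the numerical conventions the implementation fixes where the
format itself is silent.

## The storage model

A GWAS-VCF file is a VCF 4.2 file with additional conventions:

- **One variant per body row.** A variant is a single REF→ALT allelic
  substitution at a 1-based position. Multiallelic loci are split into
  sibling rows before serialization; the siblings share chrom/pos/REF and
  (when known) the `INFO/RSID` locus identifier.
- **ALT is the effect allele.** The per-trait effect size `ES` always
  refers to one dose of the ALT allele, which removes the main source of
  sign errors in downstream causal-inference and risk-score work.
- **Traits are sample columns.** Each trait's statistics at a variant are
  a FORMAT cell with fields in the fixed order `ES:SE:LP[:AF:SS]`
  (effect size, its standard error, −log₁₀ P, effect-allele frequency,
  per-variant sample size). The fixed order makes output bytes
  deterministic, which the reproducibility tests rely on. Missing values
  are the VCF null token `.`; a trait absent at a variant has an
  all-null cell, so missing is always distinguishable from zero.
- **rsid is locus metadata, not an ID.** dbSNP identifiers name sites and
  do not distinguish alternative alleles at a site, so they go in
  `INFO/RSID`. The ID column holds a caller-supplied unique string or
  `.`; the writer enforces uniqueness of non-null IDs.
- **Header as audit trail.** Assembly + ordered contig list (which
  *defines* the karyotypic sort order), INFO/FORMAT/FILTER definitions,
  and one structured `##SAMPLE` line per trait carrying study metadata
  (label, ontology, study ID, sample size, ancestry, units, test, source
  file, date).
- **QUAL is always null.** Variant-calling quality has no meaning for
  summary statistics, so no per-variant quality model is defined.

P↔LP conversion is exact (`LP = −log10 P`); a P value of exactly 0 — an
underflow in the source tool — is stored as `LP = 999` with a warning,
which preserves the "most significant" ranking without inventing
precision. Serialized floats use 6 significant digits, exceeding the
precision of any upstream P value while keeping files compact; the
round-trip tests bound the induced error well below 4 significant
figures.

## Ingest

Column semantics are never guessed: a JSON schema document maps semantic
fields (`chrom`, `pos`, `effect_allele`, `other_allele`, `es` or `or`,
`p` or `lp`, optionally `se`, `af`, `ss`, `rsid`, `ident`) to header
names or 0-based indexes, and declares the delimiter, missing-value
tokens (default `NA`, empty, `.`), header presence and the input
coordinate base (0 or 1 — output is always 1-based). Unknown keys are
rejected loudly. An `or` column is converted to `es = ln(OR)` at ingest.
If both `p` and `lp` are mapped they are cross-checked per row.

Per-row failures (non-numeric fields, symbolic alleles like `I`/`D`/`R`,
P outside [0, 1], short rows) are reported with line number and reason,
never silently dropped; row counts always conserve
(read = emitted + rejected). Alleles are required to be explicit A/C/G/T
haplotypes — indel rows lacking the VCF anchor base (e.g. REF `-`)
cannot be re-anchored without knowing the source tool's convention and
are rejected rather than guessed at.

## Harmonisation

Goal: the non-effect allele of every record equals the reference genome
sequence, so effect directionality is comparable across studies. For a
record at position p:

1. If the stated non-effect allele equals the reference sequence over its
   length → `unchanged`.
2. Else if the stated *effect* allele equals the reference over its own
   length → `swapped`: alleles exchanged, `es := −es`, and every allele
   frequency (site-level and per-trait — both are ALT-referenced by
   definition) complemented `af := 1 − af`.
3. Else `incompatible`. If an allele would match only after reverse
   complement, the detail message says so, but the record is still
   rejected: alleles are assumed forward-strand, and palindromic A/T and
   C/G variants make strand inference fundamentally unsafe, so the
   toolkit never flips strands silently.

A locus outside the reference (unknown contig, position beyond the
contig end) is `not_in_reference`. Harmonisation is an involution on
swapped inputs (the negation and complement invert exactly, which the
tests check to full float precision) and idempotent on its own output.

Two edge cases are resolved explicitly:

- **Indel orientation is trusted as given.** For an indel pair such as
  A/AT, *both* alleles are reference-compatible (each matches the
  reference over its own length), so a swap is undetectable in
  principle; rule 1 fires first and the input's designation of the
  non-effect allele wins.
- **Palindromic SNVs** follow the same direct-match rule; no frequency
  heuristics are applied.

Incompatible/not-found records are excluded with a logged count by
default; `--keep-incompatible` emits them with FILTER
`HARMONISATION_FAILED` instead.

## Indel normalisation (left-align + trim)

Equivalent spellings of one edit (e.g. deleting one T from a TTTT run)
must compare equal, so after harmonisation every variant is rewritten to
the unique leftmost, minimal representation by the standard fixpoint
algorithm: (1) while both alleles end with the same base and both have
length ≥ 2, drop the last base; (2) if either allele would become empty,
prepend the reference base at p−1 to both and decrement p; repeat to
fixpoint; (3) trim shared leading bases (keeping length ≥ 1),
incrementing p. SNVs are fixed points. Applying the result to the
reference provably yields the same edited haplotype as the input
spelling. A variant whose left extension reaches the contig start cannot
be anchored and is flagged rather than emitted mis-spelled.

The canonical form equals the spelling with minimal total allele length
and, among those, the smallest position — the property the brute-force
test oracle checks by exhaustively enumerating every spelling of the
edited haplotype over a small contig. Exotic degenerate repeats could in
principle be canonicalised differently by other normalisers; the
fixpoint above is the documented contract here.

## Sorting, writing, indexing

Records are sorted by (header contig order, position, REF, ALT), stably,
with an external merge (sorted chunks spilled to temporary files) so
memory stays bounded for inputs larger than memory. The writer streams:
it enforces sort order, ID uniqueness and declared-field usage on the
fly, BGZF-compresses, and never buffers the record stream. Positional
indexing is tabix (TBI, or CSI on request) via htslib. The rsid index is
a single-table SQLite database
`rsid_to_coord(rsid INTEGER PRIMARY KEY, chrom TEXT, coord INTEGER)` —
the rsidx layout, for interoperability with that tool. Because rsids name
loci, a split multiallelic site occupies one index row; lookup followed
by a positional fetch returns all sibling records, and callers can filter
to the target substitution.

## Queries

Interval/point queries go through the tabix index with pos-anchored
semantics: a record belongs to its anchor position only, matching how
the index keys records and keeping naive-scan equivalence trivial to
state. P-value queries are strict (`LP > −log10 t`, i.e. P < t) linear
scans over the whole file — deliberately so, since no index assists
statistics-valued queries; missing LP never matches. rsid queries
resolve the locus through the SQLite index, with "rsid absent from the
index" explicitly distinct from "locus with no records".

The benchmark harness times the four query classes (single position,
rsid, 1-Mb interval, P threshold) on the same records stored as indexed
BGZF GWAS-VCF versus a flat unindexed TSV scanned line by line,
single-threaded, reporting repetition means with t-based 95% confidence
intervals. Absolute timings are hardware-dependent and informational;
only the direction (indexed lookups beat flat scans for positional
classes at million-variant scale) is asserted, and nothing is asserted
for the P-value class, where a linear scan is the only strategy on
either medium.

## Synthetic data generator

The generator emulates the structure of a densely imputed biobank-scale
quantitative-trait GWAS dump: per-variant rows with CHR, BP, A1 (effect),
A2 (other), BETA, SE, P, AF, N and rsid columns, over a seeded random
reference genome. Defaults: two contigs (500 kb + 300 kb) carrying
10,000 variant sites; 15% indels (1–3 bp, half placed in injected
homopolymer/dinucleotide repeat tracts of 8–16 bp so normalisation has
real work to do); 4% multiallelic sites; 25% allele swaps; half of the
indels emitted in a random non-canonical spelling drawn from the
enumerated equivalent spellings; 1% malformed rows; small per-field
missingness (1% P, 5% AF, 2% N, 2% rsid). Variant sites sit on a 48-bp
slot grid so one variant's left-alignment can never collide with a
neighbour's footprint; exceeding the slot capacity of a contig is an
error, not a silent densification.

Statistics are Wald-consistent by construction: a true effect
δ ~ N(0, τ²) with τ = 0.02 SD units; SE ~ |N(0, 0.01)| + 0.005
(biobank-scale precision); observed β = δ + SE·z with z ~ N(0,1);
P = 2Φ(−|β/SE|); AF ~ U(0.01, 0.99); N constant at 350,000. Setting
τ = 0 yields exactly uniform P values, which the test suite verifies by
Kolmogorov–Smirnov. β and SE are written at full (repr) precision so
that swap recovery can be asserted to exact float equality.

Every emitted row has exactly one ledger entry: trait, row index,
perturbation class (clean / swapped / respelled_indel /
multiallelic_member / incompatible / corrupt — the classes partition the
rows) and the true harmonised record. Swaps are injected only on
biallelic SNV rows because an indel swap is undetectable by reference
matching (see above) — injecting one would manufacture an unfixable
error no harmoniser could recover. Multiallelic injection is likewise
SNV-only: a second alternative base at the site, sharing the rsid.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium, realistic allele
frequency spectra, genotype-level sampling, strand-flipped inputs,
genome-build mismatches, or allele frequencies that covary with effect
size. The tests demonstrate that the mechanics of conversion,
harmonisation, normalisation, indexing and querying are exact; they say
nothing about scientific properties of any particular GWAS.

## Problem sizes used in the checks

The shipped test suite and `scripts/acceptance.py` run at desk scale,
chosen so each stage is exercised beyond its buffering/chunking
boundaries: round-trip fidelity at 10⁴ variants × 2 traits;
harmonisation recovery at 10⁴ rows with a 30% swap rate and 50
incompatible rows; normalisation against the brute-force oracle on 10³
respelled indels; query-vs-scan agreement at 10⁵ variants × 5 traits
(tests) and 2×10⁴ × 2 (script); the benchmark at 10⁶ variants × 10
contigs, 3 repetitions, single thread. All randomness is seeded;
reported values are recomputed at run time.

## Known limitations

- No BCF (binary) writer; read-side tools convert if needed.
- No genome-assembly liftover: the declared assembly must match the
  supplied reference.
- No strand repair (by design, see harmonisation).
- The GWAS-specific header key names (`##SAMPLE` attributes,
  `##gwas_vcf_specification`) are documented here and versioned, but
  byte-compatibility with other GWAS-VCF writers' header vocabulary is
  not guaranteed.
- The P-value query class is a linear scan; files intended for repeated
  significance filtering would benefit from a precomputed INFO
  significance flag, which this version does not write.
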