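"""Deterministic synthetic GWAS inputs with a known-ground-truth ledger.

Emulates a densely imputed single-trait summary-statistics dump (one row
per variant: coordinate, effect/other allele, beta, SE, P, allele
frequency, sample size, rsid) together with the reference genome it was
called against, and injects — in controlled, ledger-recorded fractions —
the real-world heterogeneity the toolkit must repair: allele swaps with
pre-negated effect sizes, indels in non-left-aligned spellings,
multiallelic sites emitted as sibling rows, rows incompatible with the
reference, malformed rows, and missing values.

Statistics are Wald-consistent: the observed effect is the true effect
plus ``se``-scaled Gaussian noise and ``P = 2 * Phi(-|beta/se|)``, so P↔LP
round-trips are internally coherent and P values are Uniform(0, 1) when the
true effect variance is zero.  Every emitted row has exactly one ledger
entry recording its true harmonised form and its perturbation class; the
classes partition the rows.  Same config + seed → byte-identical outputs.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pyfaidx
from scipy.stats import norm

from .errors import SimulationError
from .harmonize import InMemoryReference
from .model import StudyMetadata

__all__ = [
    "SimulationConfig",
    "SyntheticReference",
    "SumstatsSim",
    "make_reference",
    "simulate_sumstats",
    "equivalent_spellings",
    "canonical_spelling",
    "write_rsid_map",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Perturbation classes; every emitted row belongs to exactly one.
CLASSES = (
    "clean",
    "swapped",
    "respelled_indel",
    "multiallelic_member",
    "incompatible",
    "corrupt",
)

#: TSV column layout of the emitted tables (Neale-lab-style dense dump).
TSV_COLUMNS = ("CHR", "BP", "A1", "A2", "BETA", "SE", "P", "AF", "N", "RSID")

SCHEMA_DOC = {
    "columns": {
        "chrom": "CHR",
        "pos": "BP",
        "effect_allele": "A1",
        "other_allele": "A2",
        "es": "BETA",
        "se": "SE",
        "p": "P",
        "af": "AF",
        "ss": "N",
        "rsid": "RSID",
    },
    "delimiter": "\t",
    "position_base": 1,
    "header_row": True,
}

#: Distance between variant slots; wide enough that left-alignment of one
#: indel can never run into a neighbouring variant's footprint.
_SLOT = 48
_EDGE = 50


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Effect model: true per-variant effects are N(0, ``effect_sd``); the
    observed beta adds se-scaled Gaussian noise where
    ``se ~ |N(0, se_scale)| + se_floor``; P is the two-sided Wald P value.
    Defaults emulate a well-powered biobank-scale quantitative-trait GWAS
    (uniform effect-allele frequencies, constant sample size) with modest
    real-world mess.  ``swap_fraction`` applies to biallelic SNV rows only:
    for indel pairs like A/AT both alleles are reference-compatible, so an
    injected swap would be undetectable by construction.
    """

    seed: int = 0
    contig_names: Tuple[str, ...] = ("1", "2")
    contig_lengths: Tuple[int, ...] = (500_000, 300_000)
    variants_per_contig: Tuple[int, ...] = (6_000, 4_000)
    n_traits: int = 1
    indel_fraction: float = 0.15
    multiallelic_fraction: float = 0.04
    swap_fraction: float = 0.25
    respell_fraction: float = 0.5
    corrupt_fraction: float = 0.01
    n_incompatible: int = 0
    missing_fraction: Tuple[Tuple[str, float], ...] = (
        ("p", 0.01), ("af", 0.05), ("ss", 0.02), ("rsid", 0.02),
    )
    effect_sd: float = 0.02
    se_scale: float = 0.01
    se_floor: float = 0.005
    sample_size: int = 350_000
    repeat_tracts_per_contig: int = 60
    gzip_output: bool = False

    def __post_init__(self):
        for f in _dc_fields(self):
            if f.name.endswith("_fraction") and f.name != "missing_fraction":
                v = getattr(self, f.name)
                if not (0.0 <= v <= 1.0):
                    raise SimulationError(f"{f.name} must be in [0, 1], got {v}")
        for key, v in self.missing_fraction:
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"missing_fraction[{key}] must be in [0, 1]")
        if not (len(self.contig_names) == len(self.contig_lengths)
                == len(self.variants_per_contig)):
            raise SimulationError(
                "contig_names, contig_lengths and variants_per_contig must align"
            )
        if any(length < 50 for length in self.contig_lengths):
            raise SimulationError("contig lengths must be >= 50")
        if self.n_traits < 1:
            raise SimulationError("n_traits must be >= 1")
        if self.n_incompatible < 0:
            raise SimulationError("n_incompatible must be >= 0")

    @property
    def missing(self) -> Dict[str, float]:
        return dict(self.missing_fraction)

    def trait_ids(self) -> List[str]:
        return [f"trait_{i + 1}" for i in range(self.n_traits)]


# ---------------------------------------------------------------------------
# Variant spelling enumeration (generator-internal oracle)
# ---------------------------------------------------------------------------

def equivalent_spellings(
    seq: str, pos: int, ref: str, alt: str, window: int = 24
) -> List[Tuple[int, str, str]]:
    """All (pos', ref', alt') spellings of the same edit within a window.

    Two spellings are equivalent when applying them to the contig produces
    the same edited haplotype.  Enumeration scans every anchor position and
    reference-allele length inside ``window`` bases either side of the
    input and keeps the candidates whose reconstruction matches; the input
    spelling itself is always in the result.  Sorted by
    (position, REF length, ALT length, ALT).
    """
    lo = max(0, pos - 1 - window)                      # 0-based window start
    hi = min(len(seq), pos - 1 + len(ref) + window)
    a = seq[lo:hi]
    i0 = pos - 1 - lo
    e = a[:i0] + alt + a[i0 + len(ref):]
    delta = len(e) - len(a)
    # A candidate (i, lr) is valid iff the windows agree on the first i
    # bases and on the trailing len(a)-i-lr bases; precompute the longest
    # common prefix/suffix once instead of comparing slices per candidate.
    lcp = 0
    for x, y in zip(a, e):
        if x != y:
            break
        lcp += 1
    lcs = 0
    for x, y in zip(reversed(a), reversed(e)):
        if x != y:
            break
        lcs += 1
    out = set()
    for i in range(min(lcp, len(a) - 1) + 1):
        lr_min = max(1, len(a) - lcs - i, 1 - delta)
        for lr in range(lr_min, len(a) - i + 1):
            r = a[i:i + lr]
            c = e[i:i + delta + lr]
            if r != c:
                out.add((lo + i + 1, r, c))
    return sorted(out, key=lambda t: (t[0], len(t[1]), len(t[2]), t[2]))


def canonical_spelling(seq: str, pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Leftmost-minimal spelling: minimal total allele length, then leftmost."""
    spellings = equivalent_spellings(seq, pos, ref, alt)
    return min(spellings, key=lambda t: (len(t[1]) + len(t[2]), t[0]))


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticReference:
    """Synthetic reference: in-memory sequences, FASTA/FAI paths (when
    written), and the ledger of injected repeat tracts."""

    reference: InMemoryReference
    contigs: Tuple[Tuple[str, int], ...]
    tracts: pd.DataFrame            # contig, start (1-based), length, motif
    fasta_path: Optional[Path] = None
    fai_path: Optional[Path] = None

    def sequence(self, chrom: str) -> str:
        return self.reference.fetch(chrom, 1, dict(self.contigs)[chrom])


def make_reference(config: SimulationConfig, out_dir=None) -> SyntheticReference:
    """Generate random contigs seeded from the config, with repeat tracts.

    Homopolymer and dinucleotide tracts (8–16 bases) are written at known
    slot-aligned offsets — recorded in the tract ledger — to give indel
    normalisation real work to do.  With ``out_dir`` the sequences are also
    written as wrapped FASTA plus a FAI index.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    sequences: Dict[str, str] = {}
    tract_rows = []
    for name, length in zip(config.contig_names, config.contig_lengths):
        arr = _BASES[rng.integers(0, 4, size=length)]
        n_slots = max(0, (length - 2 * _EDGE) // _SLOT)
        n_tracts = min(config.repeat_tracts_per_contig, n_slots)
        slots = rng.choice(n_slots, size=n_tracts, replace=False) if n_tracts else []
        for slot in np.sort(np.asarray(slots, dtype=int)):
            start0 = _EDGE + int(slot) * _SLOT + 8       # 0-based tract start
            tlen = int(rng.integers(8, 17))
            if rng.random() < 0.5:
                motif = chr(_BASES[rng.integers(0, 4)][0])
            else:
                i, j = rng.choice(4, size=2, replace=False)
                motif = chr(_BASES[i][0]) + chr(_BASES[j][0])
            tract = (motif * tlen)[:tlen]
            arr[start0:start0 + tlen] = np.frombuffer(tract.encode(), dtype="S1")
            tract_rows.append((name, start0 + 1, tlen, motif, int(slot)))
        sequences[name] = arr.tobytes().decode()
    tracts = pd.DataFrame(
        tract_rows, columns=["contig", "start", "length", "motif", "slot"]
    )
    ref = SyntheticReference(
        reference=InMemoryReference(sequences),
        contigs=tuple(zip(config.contig_names, config.contig_lengths)),
        tracts=tracts,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "reference.fa"
        with open(fasta, "w") as fh:
            for name in config.contig_names:
                fh.write(f">{name}\n")
                seq = sequences[name]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        pyfaidx.Faidx(str(fasta)).close()
        ref.fasta_path = fasta
        ref.fai_path = Path(str(fasta) + ".fai")
    return ref


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class _Site:
    chrom: str
    pos: int          # canonical (left-aligned, trimmed) position
    ref: str
    alt: str
    rsid: str
    is_indel: bool
    member: bool      # second allele of a multiallelic site


@dataclass
class SumstatsSim:
    """Output bundle: per-trait tables, the combined ground-truth ledger,
    the matching schema document, and header metadata ready for conversion."""

    config: SimulationConfig
    reference: SyntheticReference
    tables: Dict[str, Path]
    ledger: pd.DataFrame
    ledger_path: Path
    schema_path: Path
    metadata: List[StudyMetadata]


def _draw_sites(config: SimulationConfig, ref: SyntheticReference, rng) -> List[_Site]:
    sites: List[_Site] = []
    rs_used: set = set()

    def new_rsid() -> str:
        while True:
            n = int(rng.integers(10_000, 2_000_000_000))
            if n not in rs_used:
                rs_used.add(n)
                return f"rs{n}"

    tract_by_contig = {
        name: ref.tracts[ref.tracts.contig == name] for name in config.contig_names
    }
    for name, length, n_sites in zip(
        config.contig_names, config.contig_lengths, config.variants_per_contig
    ):
        seq = ref.sequence(name)
        n_slots = max(0, (length - 2 * _EDGE) // _SLOT)
        if n_sites > n_slots:
            raise SimulationError(
                f"contig {name}: {n_sites} variants exceed capacity "
                f"{n_slots} (length {length}, slot {_SLOT})"
            )
        n_indels = int(round(n_sites * config.indel_fraction))
        tract_slots = list(tract_by_contig[name].slot) if len(tract_by_contig[name]) else []
        rng.shuffle(tract_slots)
        n_tract_indels = min(n_indels, len(tract_slots))
        indel_slots = tract_slots[:n_tract_indels]
        pool = np.setdiff1d(np.arange(n_slots), np.asarray(tract_slots, dtype=int))
        if n_sites - n_tract_indels > len(pool):
            raise SimulationError(
                f"contig {name}: variant density exceeds slot capacity "
                f"({n_sites} sites, {len(pool)} free slots)"
            )
        picked = rng.choice(pool, size=n_sites - n_tract_indels, replace=False)
        indel_slots += list(picked[: n_indels - n_tract_indels])
        snv_slots = list(picked[n_indels - n_tract_indels:])

        def base_at(pos0: int) -> str:
            return seq[pos0]

        contig_sites: List[_Site] = []
        for slot in indel_slots:
            pos0 = _EDGE + int(slot) * _SLOT + 8          # 0-based anchor
            dlen = int(rng.integers(1, 4))
            if rng.random() < 0.5:                        # deletion
                raw = (pos0 + 1, seq[pos0:pos0 + 1 + dlen], seq[pos0])
            else:                                         # insertion (local duplication)
                ins = seq[pos0 + 1:pos0 + 1 + dlen]
                raw = (pos0 + 1, seq[pos0], seq[pos0] + ins)
            pos, r, a = canonical_spelling(seq, *raw)
            contig_sites.append(_Site(name, pos, r, a, new_rsid(), True, False))
        for slot in snv_slots:
            pos0 = _EDGE + int(slot) * _SLOT + int(rng.integers(0, 8))
            refb = base_at(pos0)
            alts = [b for b in "ACGT" if b != refb]
            contig_sites.append(_Site(
                name, pos0 + 1, refb, alts[int(rng.integers(0, 3))],
                new_rsid(), False, False,
            ))
        # multiallelic members: add a second alternative allele at SNV sites
        snv_sites = [s for s in contig_sites if not s.is_indel]
        n_multi = min(int(round(n_sites * config.multiallelic_fraction)), len(snv_sites))
        for s in [snv_sites[i] for i in rng.choice(len(snv_sites), size=n_multi, replace=False)] if n_multi else []:
            others = [b for b in "ACGT" if b not in (s.ref, s.alt)]
            sites_alt = others[int(rng.integers(0, len(others)))]
            contig_sites.append(_Site(
                s.chrom, s.pos, s.ref, sites_alt, s.rsid, False, True,
            ))
        sites.extend(contig_sites)
    return sites


def _assign_classes(config: SimulationConfig, sites: List[_Site], rng) -> List[str]:
    n = len(sites)
    classes = ["multiallelic_member" if s.member else "clean" for s in sites]
    for i, s in enumerate(sites):
        if s.is_indel and classes[i] == "clean" and rng.random() < config.respell_fraction:
            classes[i] = "respelled_indel"
    eligible_snv = [
        i for i, s in enumerate(sites) if not s.is_indel and classes[i] == "clean"
    ]
    rng.shuffle(eligible_snv)
    n_inc = config.n_incompatible
    if n_inc > len(eligible_snv):
        raise SimulationError(
            f"cannot inject {n_inc} incompatible rows; only "
            f"{len(eligible_snv)} eligible SNV rows"
        )
    for i in eligible_snv[:n_inc]:
        classes[i] = "incompatible"
    for i in eligible_snv[n_inc:]:
        if rng.random() < config.swap_fraction:
            classes[i] = "swapped"
    n_corrupt = int(round(n * config.corrupt_fraction))
    if n_corrupt:
        for i in rng.choice(n, size=n_corrupt, replace=False):
            classes[int(i)] = "corrupt"
    return classes


_CORRUPTIONS = ("bad_pos", "symbolic_allele", "bad_beta", "p_out_of_range", "truncated")


def _corrupt_row(cells: List[str], rng) -> List[str]:
    kind = _CORRUPTIONS[int(rng.integers(0, len(_CORRUPTIONS)))]
    cells = list(cells)
    if kind == "bad_pos":
        cells[1] = "NaN"
    elif kind == "symbolic_allele":
        cells[2] = "I" if rng.random() < 0.5 else "D"
        cells[3] = "R"
    elif kind == "bad_beta":
        cells[4] = "not_a_number"
    elif kind == "p_out_of_range":
        cells[6] = "2.0"
    elif kind == "truncated":
        cells = cells[:4]
    return cells


def simulate_sumstats(
    config: SimulationConfig,
    reference: SyntheticReference,
    out_dir,
) -> SumstatsSim:
    """Emit per-trait summary-statistics tables plus the ground-truth ledger.

    All traits share the same variant loci (as in a multi-trait QTL dump);
    statistics, perturbation classes and row order are drawn independently
    per trait.  The ledger holds, for every emitted row, the trait, the
    0-based data-row index in that trait's table, the perturbation class,
    and the true harmonised form (chrom, pos, ref, alt, es, se, lp, af, ss,
    rsid) — corrupt rows record the class only.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_sites = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    sites = _draw_sites(config, reference, rng_sites)
    n = len(sites)
    seqs = {name: reference.sequence(name) for name in config.contig_names}

    tables: Dict[str, Path] = {}
    ledger_frames = []
    miss = config.missing
    for t_idx, trait in enumerate(config.trait_ids()):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2 + t_idx]))
        classes = _assign_classes(config, sites, rng)
        true_es = rng.normal(0.0, config.effect_sd, size=n) if config.effect_sd > 0 else np.zeros(n)
        se = np.abs(rng.normal(0.0, config.se_scale, size=n)) + config.se_floor
        beta = true_es + se * rng.standard_normal(n)
        pvals = 2.0 * norm.sf(np.abs(beta / se))
        af = rng.uniform(0.01, 0.99, size=n)
        order = rng.permutation(n)

        miss_draw = {
            key: rng.random(n) < miss.get(key, 0.0)
            for key in ("p", "af", "ss", "rsid")
        }

        rows: List[str] = []
        led = {k: [] for k in (
            "trait_id", "row", "klass", "chrom", "pos", "ref", "alt",
            "es", "se", "lp", "af", "ss", "rsid",
        )}
        for out_row, i in enumerate(order):
            s = sites[i]
            klass = classes[i]
            b, e_se, p, a_f = float(beta[i]), float(se[i]), float(pvals[i]), float(af[i])
            emit_pos, emit_ref, emit_alt = s.pos, s.ref, s.alt
            emit_beta, emit_af = b, a_f
            if klass == "respelled_indel":
                options = [
                    sp for sp in equivalent_spellings(seqs[s.chrom], s.pos, s.ref, s.alt)
                    if sp != (s.pos, s.ref, s.alt)
                    and len(sp[1]) + len(sp[2]) <= len(s.ref) + len(s.alt) + 6
                ]
                if options:
                    emit_pos, emit_ref, emit_alt = options[int(rng.integers(0, len(options)))]
                else:
                    klass = "clean"
            a1, a2 = emit_alt, emit_ref              # A1 = effect, A2 = other
            if klass == "swapped":
                a1, a2 = emit_ref, emit_alt
                emit_beta = -b
                emit_af = 1.0 - a_f
            elif klass == "incompatible":
                refb = seqs[s.chrom][s.pos - 1]
                wrong = [x for x in "ACGT" if x != refb]
                rng.shuffle(wrong)
                a2, a1 = wrong[0], wrong[1]

            p_txt = "NA" if miss_draw["p"][i] else repr(p)
            af_txt = "NA" if miss_draw["af"][i] else repr(emit_af)
            ss_txt = "NA" if miss_draw["ss"][i] else str(config.sample_size)
            rs_txt = "NA" if miss_draw["rsid"][i] else s.rsid
            cells = [
                s.chrom, str(emit_pos), a1, a2, repr(emit_beta), repr(e_se),
                p_txt, af_txt, ss_txt, rs_txt,
            ]
            if klass == "corrupt":
                cells = _corrupt_row(cells, rng)
            rows.append("\t".join(cells))

            led["trait_id"].append(trait)
            led["row"].append(out_row)
            led["klass"].append(klass)
            if klass == "corrupt":
                for k in ("chrom", "ref", "alt", "rsid"):
                    led[k].append("")
                for k in ("pos", "es", "se", "lp", "af", "ss"):
                    led[k].append(np.nan)
            else:
                led["chrom"].append(s.chrom)
                led["pos"].append(s.pos)
                led["ref"].append(s.ref)
                led["alt"].append(s.alt)
                led["es"].append(b)
                led["se"].append(e_se)
                led["lp"].append(np.nan if p_txt == "NA" else (999.0 if p == 0.0 else -math.log10(p)))
                led["af"].append(np.nan if af_txt == "NA" else a_f)
                led["ss"].append(np.nan if ss_txt == "NA" else config.sample_size)
                led["rsid"].append("" if rs_txt == "NA" else s.rsid)

        name = f"sumstats_{trait}.tsv" + (".gz" if config.gzip_output else "")
        path = out_dir / name
        text = "\t".join(TSV_COLUMNS) + "\n" + "\n".join(rows) + "\n"
        if config.gzip_output:
            with gzip.open(path, "wt") as fh:
                fh.write(text)
        else:
            path.write_text(text)
        tables[trait] = path
        ledger_frames.append(pd.DataFrame(led))

    ledger = pd.concat(ledger_frames, ignore_index=True)
    ledger_path = out_dir / "ledger.tsv"
    ledger.to_csv(ledger_path, sep="\t", index=False)
    schema_path = out_dir / "schema.json"
    schema_path.write_text(json.dumps(SCHEMA_DOC, indent=2) + "\n")

    metadata = [
        StudyMetadata(
            trait_id=trait,
            trait_label=f"Synthetic quantitative trait {i + 1}",
            study_id=f"SYNTH-{config.seed}-{i + 1}",
            sample_size=config.sample_size,
            ancestry="synthetic",
            units="SD",
            association_test="Wald",
            source_file=str(tables[trait].name),
            genome_assembly="synthetic-1",
            contigs=reference.contigs,
        )
        for i, trait in enumerate(config.trait_ids())
    ]
    return SumstatsSim(
        config=config,
        reference=reference,
        tables=tables,
        ledger=ledger,
        ledger_path=ledger_path,
        schema_path=schema_path,
        metadata=metadata,
    )


def write_rsid_map(sim: SumstatsSim, path) -> Path:
    """Write a dbSNP-like 3-column TSV (rsid, chrom, pos) for the simulated
    loci — the optional annotation source for tables lacking an rsid column."""
    path = Path(path)
    led = sim.ledger
    seen = set()
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\n")
        for rsid, chrom, pos in zip(led.rsid, led.chrom, led.pos):
            if not rsid or rsid in seen or not isinstance(chrom, str) or chrom == "":
                continue
            seen.add(rsid)
            fh.write(f"{rsid}\t{chrom}\t{int(pos)}\n")
    return path
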