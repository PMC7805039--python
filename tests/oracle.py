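"""Independent brute-force oracles used by the tests.

Deliberately naive: every function here works by exhaustive enumeration or
direct string editing over a whole (tiny) contig, so it can serve as ground
truth for the production implementations without sharing any code with
them.
"""

from collections import Counter


def apply_spelling(contig: str, pos: int, ref: str, alt: str) -> str:
    """Apply a 1-based (pos, ref, alt) edit to a contig string."""
    assert contig[pos - 1:pos - 1 + len(ref)] == ref, "spelling inconsistent with contig"
    return contig[:pos - 1] + alt + contig[pos - 1 + len(ref):]


def all_spellings(contig: str, edited: str):
    """Every (pos, ref, alt) spelling over the whole contig whose application
    reproduces ``edited``.  O(len^2) — tiny contigs only."""
    out = []
    for pos in range(1, len(contig) + 1):
        for lr in range(1, len(contig) - pos + 2):
            la = len(edited) - len(contig) + lr
            if la < 1:
                continue
            ref = contig[pos - 1:pos - 1 + lr]
            alt = edited[pos - 1:pos - 1 + la]
            if ref == alt:
                continue
            if contig[:pos - 1] + alt + contig[pos - 1 + lr:] == edited:
                out.append((pos, ref, alt))
    return out


def leftmost_minimal(contig: str, pos: int, ref: str, alt: str):
    """Canonical spelling: smallest total allele length, then leftmost."""
    edited = apply_spelling(contig, pos, ref, alt)
    spellings = all_spellings(contig, edited)
    return min(spellings, key=lambda s: (len(s[1]) + len(s[2]), s[0]))


def duplicated_ids(records):
    """Counting oracle for ID uniqueness (order-free)."""
    counts = Counter(r.ident for r in records if r.ident is not None)
    return {ident for ident, n in counts.items() if n > 1}


def scan_interval(records, chrom, start, end):
    return [r for r in records if r.chrom == chrom and start <= r.pos <= end]


def scan_rsid(records, rsid):
    return [r for r in records if r.info.get("rsid") == rsid]


def scan_pvalue(records, lp_min, trait_id=None):
    out = []
    for r in records:
        stats = [r.stats.get(trait_id)] if trait_id else list(r.stats.values())
        if any(s is not None and s.lp is not None and s.lp > lp_min for s in stats):
            out.append(r)
    return out


def record_key_set(records, with_trait=False):
    if not with_trait:
        return {(r.chrom, r.pos, r.ref_allele, r.alt_allele) for r in records}
    return {
        (r.chrom, r.pos, r.ref_allele, r.alt_allele, t)
        for r in records
        for t in r.stats
    }
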