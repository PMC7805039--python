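import subprocess

import pysam
import pytest

from gwasvcfkit.errors import MergeError, WriteError
from gwasvcfkit.model import GwasRecord, StudyMetadata, TraitStats
from gwasvcfkit.vcf_io import (
    build_header,
    export_tsv,
    index_positions,
    index_rsids,
    merge_traits,
    read_gwasvcf,
    rsid_lookup,
    validate_file,
    write_gwasvcf,
)

CONTIGS = (("1", 10_000), ("2", 5_000))


def meta(trait_id="bmi", **kw):
    base = dict(
        trait_label="Body mass index", study_id="PMID:12345",
        sample_size=1000, genome_assembly="GRCh37", contigs=CONTIGS,
        file_date="2024-01-01",
    )
    base.update(kw)
    return StudyMetadata(trait_id=trait_id, **base)


def rec(pos, chrom="1", ref="A", alt="G", ident=None, rsid=None, **stats):
    info = {} if rsid is None else {"rsid": rsid}
    traits = {
        t: TraitStats(**v) if isinstance(v, dict) else v for t, v in stats.items()
    } or {"bmi": TraitStats(es=0.1, se=0.05, lp=1.0)}
    return GwasRecord(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                      ident=ident, info=info, stats=traits)


class TestHeader:
    def test_single_trait_column_count(self):
        header = build_header([meta()])
        assert len(header.split("\n")[-1].split("\t")) == 10

    def test_five_traits_column_count(self):
        header = build_header([meta(trait_id=f"t{i}") for i in range(5)])
        assert len(header.split("\n")[-1].split("\t")) == 14

    def test_duplicate_trait_id_fatal(self):
        with pytest.raises(WriteError, match="duplicate trait ids"):
            build_header([meta(), meta()])

    def test_round_trip_through_independent_parser(self, tmp_path):
        header = build_header([meta()], format_fields=("ES", "SE", "LP", "SS"))
        path = tmp_path / "h.vcf.gz"
        write_gwasvcf([rec(100)], header, path)
        vf = pysam.VariantFile(str(path))
        fmts = {f.name: (f.number, f.type) for f in vf.header.formats.values()}
        assert fmts["ES"] == ("A", "Float")
        assert fmts["SS"] == ("A", "Integer")
        assert vf.header.info["RSID"].type == "String"
        assert [c for c in vf.header.contigs] == ["1", "2"]
        assert list(vf.header.samples) == ["bmi"]

    def test_sample_metadata_recovered(self, tmp_path):
        path = tmp_path / "m.vcf.gz"
        write_gwasvcf([rec(100)], build_header([meta()]), path)
        [m] = read_gwasvcf(path)[0]
        assert m.trait_label == "Body mass index"
        assert m.study_id == "PMID:12345"
        assert m.sample_size == 1000
        assert m.genome_assembly == "GRCh37"
        assert m.contigs == CONTIGS


class TestWriteRead:
    def test_write_read_fixpoint(self, tmp_path):
        records = [
            rec(100, rsid="rs1", bmi=dict(es=0.123456, se=0.05, lp=7.30103)),
            rec(250, ref="AT", alt="A", bmi=dict(es=-1.5, se=0.2, lp=0.301)),
            rec(30, chrom="2", bmi=dict(es=None, se=None, lp=None, af=0.25)),
        ]
        path = tmp_path / "x.vcf.gz"
        write_gwasvcf(records, build_header([meta()], format_fields=("ES", "SE", "LP", "AF")), path)
        _, back = read_gwasvcf(path)
        assert [r.key() for r in back] == [r.key() for r in records]
        for orig, rd in zip(records, back):
            so, sr = orig.stats["bmi"], rd.stats.get("bmi", TraitStats())
            for f in ("es", "se", "lp", "af"):
                a, b = getattr(so, f), getattr(sr, f)
                assert (a is None) == (b is None)
                if a is not None:
                    assert b == pytest.approx(a, rel=1e-5)  # 6 significant digits

    def test_missing_trait_cell_is_dot(self, tmp_path):
        metadata = [meta(trait_id="a"), meta(trait_id="b")]
        r = rec(100, a=dict(es=0.1, se=0.05, lp=1.0))
        path = tmp_path / "two.vcf.gz"
        write_gwasvcf([r], build_header(metadata), path)
        body = [l for l in pysam.BGZFile(str(path)).read().decode().splitlines()
                if not l.startswith("#")]
        assert body[0].split("\t")[10] == "."

    def test_lp_formatted_to_six_significant_digits(self, tmp_path):
        path = tmp_path / "lp.vcf.gz"
        write_gwasvcf([rec(100, bmi=dict(es=0.1, se=0.05, lp=7.301029995663981))],
                      build_header([meta()]), path)
        body = [l for l in pysam.BGZFile(str(path)).read().decode().splitlines()
                if not l.startswith("#")]
        assert body[0].split("\t")[9].split(":")[2] == "7.30103"

    @pytest.mark.parametrize(
        "records, match",
        [
            ([rec(200), rec(100)], "unsorted"),
            ([rec(100, ident="v1"), rec(200, ident="v1")], "duplicate variant ID"),
            ([rec(100, chrom="MT")], "not declared"),
            ([rec(100, other=dict(es=0.1))], "undeclared trait"),
            ([rec(100, bmi=dict(es=0.1, se=0.05, lp=1.0, ss=5))], "FORMAT field SS"),
        ],
    )
    def test_structural_guarantees_fatal(self, tmp_path, records, match):
        with pytest.raises(WriteError, match=match):
            write_gwasvcf(records, build_header([meta()]), tmp_path / "bad.vcf.gz")


class TestIndexes:
    def test_positional_index_readable_by_htslib(self, tmp_path):
        path = tmp_path / "i.vcf.gz"
        write_gwasvcf([rec(100), rec(250)], build_header([meta()]), path)
        tbi = index_positions(path)
        assert tbi.exists()
        with pysam.TabixFile(str(path)) as tb:
            assert len(list(tb.fetch("1", 0, 1000))) == 2
            assert "2" not in tb.contigs  # no records on contig 2

    def test_uncompressed_input_rejected_with_hint(self, tmp_path):
        path = tmp_path / "plain.vcf"
        write_gwasvcf([rec(100)], build_header([meta()]), path, bgzf=False)
        from gwasvcfkit.errors import IndexingError
        with pytest.raises(IndexingError, match="BGZF"):
            index_positions(path)

    def test_rsid_index_lookup_and_negatives(self, tmp_path):
        path = tmp_path / "r.vcf.gz"
        records = [rec(100, rsid="rs123"), rec(250, rsid="rs77"),
                   rec(400),  # no rsid
                   rec(500, rsid="rsBAD")]
        write_gwasvcf(records, build_header([meta()]), path)
        report = index_rsids(path)
        assert report.n_indexed == 2
        assert report.n_missing == 1
        assert report.n_malformed == 1
        assert rsid_lookup(report.db_path, "rs123") == ("1", 100)
        assert rsid_lookup(report.db_path, "rs999") is None

    def test_multiallelic_siblings_share_one_locus(self, tmp_path):
        path = tmp_path / "m.vcf.gz"
        records = [rec(100, alt="G", rsid="rs555"), rec(100, alt="T", rsid="rs555")]
        write_gwasvcf(records, build_header([meta()]), path)
        report = index_rsids(path)
        assert report.n_indexed == 1
        assert rsid_lookup(report.db_path, "rs555") == ("1", 100)


class TestExport:
    def test_gwas_catalog_projection(self):
        text = export_tsv([rec(1000, rsid="rs1", bmi=dict(es=0.12, se=0.03, lp=2.0))],
                          columns=["chromosome", "base_pair_location", "effect_allele",
                                   "other_allele", "beta", "standard_error", "p_value"])
        header, row = text.strip().split("\n")
        assert header.split("\t") == ["chromosome", "base_pair_location", "effect_allele",
                                      "other_allele", "beta", "standard_error", "p_value"]
        assert row.split("\t") == ["1", "1000", "G", "A", "0.12", "0.03", "0.01"]

    def test_p_recovered_exactly_from_integer_lp(self):
        text = export_tsv([rec(10, bmi=dict(es=0.1, se=0.05, lp=2.0))], columns=["p_value"])
        assert text.strip().split("\n")[1] == "0.01"

    def test_unknown_column_fatal_and_lists_available(self):
        with pytest.raises(WriteError, match="effect_allele"):
            export_tsv([rec(10)], columns=["wibble"])

    def test_wide_form_one_row_per_variant(self):
        records = [rec(10, a=dict(es=0.1, se=0.05, lp=1.0), b=dict(es=0.2, se=0.05, lp=1.0))]
        text = export_tsv(records, columns=["chromosome", "base_pair_location", "beta"], wide=True)
        header, row = text.strip().split("\n")
        assert header.split("\t") == ["chromosome", "base_pair_location", "beta_a", "beta_b"]
        assert row.split("\t") == ["1", "10", "0.1", "0.2"]


class TestMergeTraits:
    def _single(self, tmp_path, name, records):
        path = tmp_path / f"{name}.vcf.gz"
        write_gwasvcf(records, build_header([meta(trait_id=name)]), path)
        index_positions(path)
        return path

    def test_disjoint_union(self, tmp_path):
        a = self._single(tmp_path, "a", [rec(100, a=dict(es=0.1, se=0.05, lp=1.0))])
        b = self._single(tmp_path, "b", [rec(300, b=dict(es=0.2, se=0.05, lp=1.0))])
        out = tmp_path / "m.vcf.gz"
        report = merge_traits([a, b], out)
        assert report.n_records == 2
        _, records = read_gwasvcf(out)
        for r in records:
            assert len(r.stats) == 1  # null in exactly one sample column

    def test_self_merge_distinct_trait_ids(self, tmp_path):
        a = self._single(tmp_path, "a", [rec(100, a=dict(es=0.1, se=0.05, lp=1.0))])
        b = self._single(tmp_path, "b", [rec(100, b=dict(es=0.1, se=0.05, lp=1.0))])
        out = tmp_path / "m.vcf.gz"
        merge_traits([a, b], out)
        [r] = read_gwasvcf(out)[1]
        assert r.stats["a"] == r.stats["b"]

    def test_trait_collision_fatal(self, tmp_path):
        a = self._single(tmp_path, "a", [rec(100, a=dict(es=0.1, se=0.05, lp=1.0))])
        with pytest.raises(MergeError, match="more than one input"):
            merge_traits([a, a], tmp_path / "m.vcf.gz")

    def test_assembly_mismatch_fatal(self, tmp_path):
        a = self._single(tmp_path, "a", [rec(100, a=dict(es=0.1, se=0.05, lp=1.0))])
        pb = tmp_path / "b.vcf.gz"
        write_gwasvcf([rec(100, b=dict(es=0.1, se=0.05, lp=1.0))],
                      build_header([meta(trait_id="b", genome_assembly="GRCh38")]), pb)
        with pytest.raises(MergeError, match="assembly"):
            merge_traits([a, pb], tmp_path / "m.vcf.gz")

    def test_per_trait_extraction_inverts_merge(self, duo_vcf):
        merged, singles, _sim = duo_vcf
        _, merged_records = read_gwasvcf(merged)
        for single in singles:
            meta_s, records_s = read_gwasvcf(single)
            tid = meta_s[0].trait_id
            projected = {
                (r.key(), tuple(vars(r.stats[tid]).values()) if hasattr(r.stats[tid], "__dict__")
                 else (r.stats[tid].es, r.stats[tid].se, r.stats[tid].lp, r.stats[tid].af, r.stats[tid].ss))
                for r in merged_records if tid in r.stats
            }
            source = {
                (r.key(), (r.stats[tid].es, r.stats[tid].se, r.stats[tid].lp,
                           r.stats[tid].af, r.stats[tid].ss))
                for r in records_s
            }
            assert {k for k, _ in projected} == {k for k, _ in source}


class TestValidateFile:
    def test_all_checks_pass_on_conformant_file(self, small_vcf):
        path, _report, _sim = small_vcf
        assert all(c.passed for c in validate_file(path))

    def test_duplicate_id_detected(self, tmp_path):
        path = tmp_path / "dup.vcf"
        # hand-build an out-of-contract file (writer would refuse)
        header = build_header([meta()])
        lines = [header]
        for pos in (100, 200):
            lines.append(f"1\t{pos}\tvar_7\tA\tG\t.\t.\t.\tES:SE:LP\t0.1:0.05:1")
        gz = tmp_path / "dup.vcf.gz"
        import pysam as _p
        with _p.BGZFile(str(gz), "wb") as fh:
            fh.write(("\n".join(lines) + "\n").encode())
        results = {c.name: c.passed for c in validate_file(gz)}
        assert results["id_uniqueness"] is False
        assert results["sort_order"] is True


class TestInteroperability:
    def test_bcftools_parses_written_file(self, small_vcf):
        path, report, _sim = small_vcf
        out = subprocess.run(
            ["bcftools", "view", "-H", str(path)],
            capture_output=True, text=True, check=True,
        )
        assert len(out.stdout.splitlines()) == report.n_written

    def test_cyvcf2_parses_written_file(self, small_vcf):
        cyvcf2 = pytest.importorskip("cyvcf2")
        path, report, _sim = small_vcf
        vcf = cyvcf2.VCF(str(path))
        n = 0
        for v in vcf:
            assert v.INFO.get("RSID") is None or v.INFO["RSID"].startswith("rs")
            n += 1
        assert n == report.n_written
        assert set(vcf.samples) == {"trait_1"}
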