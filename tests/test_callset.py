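"""Variant parsing, left-normalization, key matching and the three filters."""
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelval.callset import (CallsetError, DictReference, VariantAnnotation,
                              VariantCall, apply_af_filter, apply_depth_filter,
                              apply_pass_filter, compute_gc_content,
                              left_normalize, normalize_clinvar_sig,
                              read_callset_tsv, read_callset_vcf,
                              restrict_to_targets, variant_key,
                              write_callset_tsv)
from panelval.intervals import GeneModel, GenomicInterval, build_targets


def call(chrom="chr1", pos=100, ref="C", alt="T", depth=50, af=0.5,
         filter_pass=True, platform="TS", sample_id="S1", **ann):
    return VariantCall(chrom, pos, ref, alt, depth, af, filter_pass, platform,
                       sample_id, VariantAnnotation(**ann))


def edited_haplotype(seq: str, pos_1based: int, ref: str, alt: str) -> str:
    """Apply a variant to a sequence string (the normalization oracle)."""
    i = pos_1based - 1
    assert seq[i:i + len(ref)] == ref
    return seq[:i] + alt + seq[i + len(ref):]


class TestLeftNormalize:
    def test_snv_fixed_point(self):
        ref = DictReference({"chr1": "A" * 99 + "C" + "A" * 20})
        v = call(pos=100, ref="C", alt="T")
        assert left_normalize(v, ref) is v

    def test_homopolymer_deletion_shifts_left(self):
        # sequence T A C C C G: one-C deletion written right-most must shift
        # to the left-most spelling
        seq = "TACCCGTTTT"
        ref = DictReference({"chr1": seq})
        v = call(pos=4, ref="CC", alt="C", depth=30)
        out = left_normalize(v, ref)
        assert (out.pos_1based, out.ref, out.alt) == (2, "AC", "A")
        assert edited_haplotype(seq, v.pos_1based, v.ref, v.alt) == \
            edited_haplotype(seq, out.pos_1based, out.ref, out.alt)

    def test_mnp_trimmed_to_snv(self):
        seq = "N" * 9 + "GCT" + "N" * 5
        seq = seq.replace("N", "A")
        ref = DictReference({"chr1": seq})
        v = call(pos=10, ref="GCT", alt="GAT")
        out = left_normalize(v, ref)
        assert (out.pos_1based, out.ref, out.alt) == (11, "C", "A")

    def test_ref_mismatch_raises(self):
        ref = DictReference({"chr1": "AAAA"})
        with pytest.raises(CallsetError, match="REF mismatch"):
            left_normalize(call(pos=2, ref="G", alt="T"), ref)

    @given(st.integers(0, 6), st.sampled_from(["A", "C"]), st.integers(1, 3))
    @settings(max_examples=150, deadline=None)
    def test_haplotype_equality_and_idempotence(self, offset, base, del_len):
        # random deletion spelled at a random offset within a homopolymer run
        seq = "GT" + base * 8 + "AGCA"
        ref = DictReference({"chr1": seq})
        pos = 3 + offset  # 1-based, inside the run
        ref_allele = seq[pos - 1: pos - 1 + del_len + 1]
        alt_allele = ref_allele[0]
        if ref_allele == alt_allele or len(ref_allele) != del_len + 1:
            return
        v = call(pos=pos, ref=ref_allele, alt=alt_allele)
        out = left_normalize(v, ref)
        # same base-level edit
        assert edited_haplotype(seq, v.pos_1based, v.ref, v.alt) == \
            edited_haplotype(seq, out.pos_1based, out.ref, out.alt)
        # idempotent
        again = left_normalize(out, ref)
        assert variant_key(again) == variant_key(out)
        # left-most: no equivalent minimal spelling exists further left
        for p in range(1, out.pos_1based):
            for rl in range(1, del_len + 2):
                r = seq[p - 1: p - 1 + rl]
                a = r[:1]
                if r and a != r and edited_haplotype(seq, p, r, a) == \
                        edited_haplotype(seq, v.pos_1based, v.ref, v.alt):
                    pytest.fail(f"found equivalent spelling further left at {p}")

    def test_equal_keys_after_normalizing_two_spellings(self):
        seq = "TACCCCGTTT"
        ref = DictReference({"chr1": seq})
        v1 = call(pos=3, ref="CC", alt="C")
        v2 = call(pos=5, ref="CC", alt="C")
        assert edited_haplotype(seq, 3, "CC", "C") == edited_haplotype(seq, 5, "CC", "C")
        assert variant_key(left_normalize(v1, ref)) == variant_key(left_normalize(v2, ref))


class TestVariantKey:
    def test_identical_records_match(self):
        assert variant_key(call()) == variant_key(call(depth=99, platform="WES"))

    def test_different_alt_distinct(self):
        assert variant_key(call(alt="G")) != variant_key(call(alt="T"))


class TestValidation:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(CallsetError):
            call(ref="C", alt="C")

    def test_bad_maf_rejected(self):
        with pytest.raises(CallsetError, match="MAF"):
            VariantAnnotation(maf_exac_nfe=1.5)

    def test_clinvar_synonyms(self):
        assert normalize_clinvar_sig("Likely pathogenic") == "Likely_pathogenic"
        assert normalize_clinvar_sig("Uncertain significance") == "Uncertain"
        assert normalize_clinvar_sig(
            "Conflicting interpretations of pathogenicity") == "Conflicting"
        with pytest.warns(UserWarning):
            assert normalize_clinvar_sig("weird_label") == "Not_found"


@pytest.fixture
def design():
    g = GeneModel("G1", "iron overload", [GenomicInterval("chr1", 999, 1200)])
    return build_targets([g], flank=0)  # target [999,1200) -> 1-based 1000..1200


class TestFilters:
    def test_target_restriction_boundaries(self, design):
        inside_first = call(pos=1000)
        outside = call(pos=999)
        kept = restrict_to_targets([inside_first, outside], design)
        assert kept == [inside_first]

    def test_target_restriction_matches_enumeration(self, design):
        calls = [call(pos=p) for p in range(990, 1215)]
        kept = restrict_to_targets(calls, design)
        expected = [c for c in calls if 1000 <= c.pos_1based <= 1200]
        assert kept == expected

    def test_depth_boundary(self):
        assert apply_depth_filter([call(depth=10)]) == [call(depth=10)]
        assert apply_depth_filter([call(depth=9)]) == []

    def test_af_boundary_scoped_to_wes(self):
        wes_low = call(platform="WES", af=0.19)
        wes_edge = call(platform="WES", af=0.20, pos=101)
        ts_low = call(platform="TS", af=0.10, pos=102)
        kept = apply_af_filter([wes_low, wes_edge, ts_low])
        assert kept == [wes_edge, ts_low]

    def test_pass_filter(self):
        bad = call(filter_pass=False)
        good = call(pos=101)
        assert apply_pass_filter([bad, good]) == [good]

    def test_filters_commute(self, design):
        calls = [
            call(pos=p, depth=d, af=a, platform=pl, filter_pass=fp)
            for p, d, a, pl, fp in itertools.product(
                [995, 1000, 1100, 1205], [5, 10, 50], [0.1, 0.2, 0.6],
                ["TS", "WES"], [True, False])
        ]
        filters = {
            "depth": lambda cs: apply_depth_filter(cs, 10),
            "af": apply_af_filter,
            "target": lambda cs: restrict_to_targets(cs, design),
            "pass": apply_pass_filter,
        }
        results = []
        for order in itertools.permutations(filters.values()):
            out = list(calls)
            for f in order:
                out = f(out)
            results.append({variant_key(c) + (c.platform, c.sample_id, c.depth,
                                              c.alt_fraction, c.filter_pass)
                            for c in out})
        assert all(r == results[0] for r in results)
        assert len(results[0]) <= len(calls)


class TestGcContent:
    def test_window_fraction(self):
        seq = "G" * 101 + "A" * 101
        ref = DictReference({"chr1": seq})
        assert compute_gc_content(ref, "chr1", 51) == pytest.approx(100.0)
        # centered at the G/A junction: 51 G (positions 51..101) + 50 A
        assert compute_gc_content(ref, "chr1", 101) == pytest.approx(100 * 51 / 101)


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        calls = [
            call(rsid="rs61733458", consequence="Exonic non-synonymous",
                 clinvar_sig="Benign", cadd=29.7, maf_exac_nfe=0.0301, gene="CP"),
            call(pos=200, alt="G", platform="WES", gc_content_pct=73.5,
                 repeat_flag=True),
        ]
        p = tmp_path / "calls.tsv"
        write_callset_tsv(calls, p)
        back = read_callset_tsv(p)
        assert back == calls

    def test_published_row_parses(self, tmp_path):
        calls = [call(rsid="rs61733458", consequence="Exonic non-synonymous",
                      clinvar_sig="Benign", cadd=29.7, maf_exac_nfe=0.0301)]
        p = tmp_path / "calls.tsv"
        write_callset_tsv(calls, p)
        a = read_callset_tsv(p)[0].annotation
        assert (a.rsid, a.clinvar_sig, a.cadd, a.maf_exac_nfe) == \
            ("rs61733458", "Benign", 29.7, 0.0301)

    def test_bad_maf_in_file_rejected(self, tmp_path):
        p = tmp_path / "calls.tsv"
        write_callset_tsv([call()], p)
        lines = p.read_text().splitlines()
        fields = lines[1].split("\t")
        fields[12] = "1.5"  # maf_exac_nfe column
        p.write_text(lines[0] + "\n" + "\t".join(fields) + "\n")
        with pytest.raises(CallsetError, match="line 2"):
            read_callset_tsv(p)

    def test_vcf_read_splits_multiallelic(self, tmp_path):
        vcf = tmp_path / "calls.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            '##INFO=<ID=AF,Number=A,Type=Float,Description="alt fraction">\n'
            '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="clinvar">\n'
            '##INFO=<ID=CADD,Number=1,Type=Float,Description="cadd">\n'
            '##INFO=<ID=MAF,Number=1,Type=Float,Description="maf">\n'
            '##INFO=<ID=CSQ,Number=1,Type=String,Description="csq">\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
            '##FILTER=<ID=q10,Description="low quality">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\trs1\tC\tT,G\t50\tPASS\t"
            "DP=80;AF=0.4,0.1;CLNSIG=Benign;CADD=25.0;MAF=0.01;"
            "CSQ=missense_variant;GENE=CP\n"
            "chr1\t200\t.\tA\tG\t50\tq10\tDP=30;AF=0.5;CSQ=synonymous_variant\n"
        )
        calls = read_callset_vcf(vcf, platform="WES", sample_id="S1")
        assert len(calls) == 3
        assert {(c.pos_1based, c.alt) for c in calls} == {(100, "T"), (100, "G"), (200, "G")}
        first = next(c for c in calls if c.alt == "T")
        assert first.depth == 80 and first.filter_pass
        assert first.annotation.clinvar_sig == "Benign"
        assert first.annotation.cadd == 25.0
        failed = next(c for c in calls if c.pos_1based == 200)
        assert not failed.filter_pass
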