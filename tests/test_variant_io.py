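"""Variant I/O: key normalization, VCF splitting, table round-trips, manifest."""

from __future__ import annotations

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_variant
from oracle_utils import respellings

from ctdna_concord.errors import InputError, UnsupportedAlleleError
from ctdna_concord.variant_io import (
    AnnotatedVariant,
    CallerMode,
    Consequence,
    SampleType,
    VariantKey,
    left_align,
    minimal_key,
    normalize_key,
    read_manifest,
    read_variant_table,
    read_vcf,
    trim_anchored,
    write_manifest,
    write_variant_table,
)


class TestNormalizeKey:
    @pytest.mark.parametrize(
        "spelling_a, spelling_b",
        [
            # same deletion written anchored vs shifted one base right
            (("chr1", 1000, "CAA", "CA"), ("chr1", 1001, "AA", "A")),
            # insertion padded on either side
            (("chr2", 500, "A", "AG"), ("chr2", 499, "TA", "TAG")),
            # deletion padded with trailing context
            (("chr3", 10, "AG", "A"), ("chr3", 10, "AGT", "AT")),
        ],
    )
    def test_equivalent_spellings_collapse(self, spelling_a, spelling_b):
        assert minimal_key(*spelling_a) == minimal_key(*spelling_b)

    def test_snv_is_fixed_point(self):
        key = minimal_key("chr17", 7578406, "C", "T")
        assert key == VariantKey("chr17", 7578406, "C", "T")
        assert minimal_key(*key) == key

    def test_variant_and_raw_key_agree(self):
        key = minimal_key("chr1", 1000, "CAA", "CA")
        assert normalize_key(
            make_variant(chrom="chr1", pos=1000, ref="CAA", alt="CA")
        ) == key

    @pytest.mark.parametrize("allele", ["<DEL>", "C[2:321682[", "*"])
    def test_symbolic_alleles_rejected(self, allele):
        with pytest.raises(UnsupportedAlleleError):
            minimal_key("chr1", 100, "C", allele)

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_respelled_indels_share_a_key(self, data):
        """All padded spellings of one indel on a 10-bp context agree."""
        context = "".join(
            data.draw(st.sampled_from("ACGT"), label=f"b{i}") for i in range(10)
        )
        start = 1001
        offset = data.draw(st.integers(3, 6), label="offset")
        pos = start + offset
        kind = data.draw(st.sampled_from(["ins", "del", "snv"]), label="kind")
        ref_base = context[offset]
        if kind == "ins":
            ref, alt = ref_base, ref_base + data.draw(
                st.text("ACGT", min_size=1, max_size=2), label="ins"
            )
        elif kind == "del":
            dlen = data.draw(st.integers(1, 2), label="dlen")
            ref = context[offset : offset + dlen + 1]
            alt = ref_base
        else:
            ref = ref_base
            alt = data.draw(
                st.sampled_from([b for b in "ACGT" if b != ref_base]), label="alt"
            )
        keys = {
            left_align(minimal_key("chrX", p, r, a), context, start)
            for p, r, a in respellings(context, start, pos, ref, alt)
        }
        assert len(keys) == 1
        # left-alignment is idempotent
        (key,) = keys
        assert left_align(key, context, start) == key

    def test_left_align_unifies_homopolymer_spellings(self):
        context, start = "CAAAAT", 999  # A-run at 1000..1003
        spellings = [("chr1", p, "AA", "A") for p in (1000, 1001, 1002)]
        aligned = {
            left_align(minimal_key(*s), context, start) for s in spellings
        }
        assert aligned == {VariantKey("chr1", 1000, "A", "")}

    def test_trim_anchored_keeps_vcf_style_anchor(self):
        assert trim_anchored("chr1", 1000, "CAA", "CA") == ("chr1", 1000, "CA", "C")


class TestVariantRecord:
    def test_alt_reads_cannot_exceed_depth(self):
        with pytest.raises(InputError):
            make_variant(vaf=0.9, depth=100, alt_reads=101)

    def test_vaf_must_match_read_support(self):
        with pytest.raises(InputError):
            make_variant(vaf=0.5, depth=1000, alt_reads=100)

    def test_multiallelic_alt_rejected(self):
        with pytest.raises(InputError):
            make_variant(alt="A,T")

    def test_mmaf_is_max_over_present_sources(self):
        v = make_variant(pop_af={"gnomad": 0.004, "exac": 0.009})
        assert v.mmaf == 0.009
        assert make_variant().mmaf is None


class TestTableRoundTrip:
    def test_round_trip_preserves_every_field(self, tmp_path):
        variants = [
            make_variant(),
            make_variant(
                chrom="chr3",
                pos=41194001,
                gene="CTNNB1",
                vaf=0.008,
                depth=4762,
                alt_reads=38,
                cadd=27.5,
                pop_af={"gnomad": 0.0001},
            ),
            make_variant(ref="AG", alt="A", consequence=Consequence.FRAMESHIFT,
                         vaf=None, alt_reads=None, depth=None),
        ]
        path = tmp_path / "t.tsv"
        write_variant_table(variants, path)
        back = read_variant_table(path)
        assert back == variants

    def test_high_depth_plasma_call_survives_round_trip(self, tmp_path):
        v = make_variant(gene="CTNNB1", vaf=0.008, depth=4762, alt_reads=38)
        path = tmp_path / "one.tsv"
        write_variant_table([v], path)
        assert read_variant_table(path)[0] == v

    def test_headerless_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chr1\t100\tC\tT\n")
        from ctdna_concord.errors import FormatError

        with pytest.raises(FormatError):
            read_variant_table(path)


VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1>
    ##contig=<ID=chr3>
    ##INFO=<ID=GENE,Number=1,Type=String,Description="g">
    ##INFO=<ID=CONSEQUENCE,Number=1,Type=String,Description="c">
    ##INFO=<ID=AF_GNOMAD,Number=A,Type=Float,Description="af">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    """
)


class TestReadVcf:
    def _read(self, tmp_path, body):
        path = tmp_path / "x.vcf"
        path.write_text(VCF_HEADER + body)
        return read_vcf(path, SampleType.PLASMA, CallerMode.CLC)

    def test_multiallelic_split_conserves_alt_count(self, tmp_path):
        table = self._read(
            tmp_path,
            "chr1\t1000\t.\tAC\tA,ACT\t.\t.\tGENE=TP53\tAD:DP\t10,5,3:18\n",
        )
        assert len(table.variants) == 2
        assert len({normalize_key(v) for v in table.variants}) == 2

    def test_ad_dp_yield_vaf(self, tmp_path):
        table = self._read(
            tmp_path, "chr1\t2000\t.\tC\tT\t.\t.\t.\tAD:DP\t10,90:100\n"
        )
        (v,) = table.variants
        assert v.alt_reads == 90 and v.depth == 100 and v.vaf == 0.9

    def test_missing_evidence_flags_not_drops(self, tmp_path):
        table = self._read(tmp_path, "chr1\t3000\t.\tC\tT\t.\t.\t.\tDP\t.\n")
        (v,) = table.variants
        assert v.vaf is None and "no_vaf_evidence" in v.flags

    def test_unparsable_file_names_the_problem(self, tmp_path):
        from ctdna_concord.errors import FormatError

        path = tmp_path / "junk.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises(FormatError):
            read_vcf(path, SampleType.PLASMA, CallerMode.CLC)


def _manifest_rows(n_naive=23, n_post=73):
    rows = []
    for i in range(n_naive + n_post):
        naive = i < n_naive
        rows.append(
            {
                "patient_id": f"P{i:03d}",
                "group": "treatment_naive" if naive else "post_treatment",
                "timing": "diagnosis" if naive else "on_chemo",
                "figo_stage": "III",
                "histology": "high_grade_serous",
                "tumor_path": "t.tsv",
                "plasma_path": "p.tsv",
                "germline_list_path": "",
                "outcome": "unknown",
                "tumor_qc_pass": "true",
            }
        )
    return rows


def _write_manifest_tsv(tmp_path, rows):
    cols = list(rows[0].keys()) if rows else ["patient_id"]
    lines = ["\t".join(cols)] + ["\t".join(r[c] for c in cols) for r in rows]
    path = tmp_path / "manifest.tsv"
    path.write_text("\n".join(lines) + "\n")
    # referenced sample tables must exist
    write_variant_table([], tmp_path / "t.tsv")
    write_variant_table([], tmp_path / "p.tsv")
    return path


class TestManifest:
    def test_group_counts(self, tmp_path):
        entries = read_manifest(_write_manifest_tsv(tmp_path, _manifest_rows()))
        assert len(entries) == 96
        naive = sum(1 for e in entries if e.group.value == "treatment_naive")
        assert (naive, 96 - naive) == (23, 73)

    def test_empty_manifest_is_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("patient_id\tgroup\ttiming\tfigo_stage\thistology\t"
                        "tumor_path\tplasma_path\n")
        assert read_manifest(path) == []

    def test_unknown_stage_rejected(self, tmp_path):
        rows = _manifest_rows(1, 0)
        rows[0]["figo_stage"] = "V"
        with pytest.raises(InputError, match="figo_stage"):
            read_manifest(_write_manifest_tsv(tmp_path, rows))

    def test_duplicate_patient_rejected(self, tmp_path):
        rows = _manifest_rows(2, 0)
        rows[1]["patient_id"] = rows[0]["patient_id"]
        with pytest.raises(InputError, match="duplicate"):
            read_manifest(_write_manifest_tsv(tmp_path, rows))

    def test_missing_file_names_patient(self, tmp_path):
        rows = _manifest_rows(1, 0)
        rows[0]["tumor_path"] = "nowhere.tsv"
        with pytest.raises(InputError, match="P000"):
            read_manifest(_write_manifest_tsv(tmp_path, rows))

    def test_round_trip(self, tmp_path):
        path = _write_manifest_tsv(tmp_path, _manifest_rows(2, 3))
        entries = read_manifest(path)
        out = tmp_path / "again.tsv"
        write_manifest(entries, out)
        assert read_manifest(out) == entries
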