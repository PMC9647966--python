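"""Data model and VCF/FASTA/GFF3/table round-trip behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpanel as sp
from snpanel.model import Call, GenotypeMatrix, MarkerRecord

from conftest import build_matrix

VCF_TOY = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\tm1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\tm2\tC\tT\t.\t.\t.\tGT\t./.\t1|0\t./1
chr1\t300\tm3\tC\tT,G\t.\t.\t.\tGT\t0/0\t1/2\t2/2
chr1\t400\tm4\tAT\tA\t.\t.\t.\tGT\t0/0\t0/1\t0/0
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TOY)
    return str(path)


class TestCallEncoding:
    @pytest.mark.parametrize(
        "gt,expected",
        [
            ("0/0", Call.HOM_REF),
            ("0/1", Call.HET),
            ("1/0", Call.HET),
            ("1|0", Call.HET),
            ("1/1", Call.HOM_ALT),
            ("./.", Call.MISSING),
            ("./1", Call.MISSING),
            ("1/.", Call.MISSING),
        ],
    )
    def test_gt_parsing_is_total(self, gt, expected):
        assert Call.from_gt_string(gt) is expected

    def test_four_states_round_trip_through_canonical_strings(self):
        for call in Call:
            assert Call.from_gt_string(call.to_gt_string()) is call


class TestReadVcf:
    def test_toy_vcf_calls(self, toy_vcf):
        m = sp.read_vcf(toy_vcf)
        assert m.samples == ["S1", "S2", "S3"]
        assert list(m.column("m1")) == [Call.HOM_REF, Call.HET, Call.HOM_ALT]

    def test_partial_and_full_missing_become_missing(self, toy_vcf):
        m = sp.read_vcf(toy_vcf)
        assert list(m.column("m2")) == [Call.MISSING, Call.HET, Call.MISSING]

    def test_multiallelic_and_indel_records_are_retained_flagged(self, toy_vcf):
        m = sp.read_vcf(toy_vcf)
        tri = m.marker("m3")
        assert not tri.is_biallelic and tri.is_snp
        indel = m.marker("m4")
        assert indel.is_biallelic and not indel.is_snp
        # a hom call in a non-ref alt is still HOM_ALT; mixed alts are HET
        assert list(m.column("m3")) == [Call.HOM_REF, Call.HET, Call.HOM_ALT]

    def test_region_subsetting(self, toy_vcf):
        m = sp.read_vcf(toy_vcf, region="chr1:150-350")
        assert m.marker_ids == ["m2", "m3"]

    def test_missing_gt_format_rejected(self, tmp_path):
        path = tmp_path / "nogt.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with pytest.raises(ValueError, match="GT"):
            sp.read_vcf(str(path))

    def test_malformed_vcf_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises(ValueError):
            sp.read_vcf(str(path))

    def test_duplicate_sample_names_rejected(self, tmp_path):
        path = tmp_path / "dup.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS1\n"
            "chr1\t1\tm\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\n"
        )
        with pytest.raises(ValueError):
            sp.read_vcf(str(path))


class TestWriteVcf:
    def test_empty_marker_list_gives_header_only_vcf(self, tmp_path):
        m = build_matrix(np.empty((2, 0), dtype=np.int8), ref_alts=[])
        out = tmp_path / "empty.vcf"
        sp.write_vcf(m, out)
        lines = out.read_text().splitlines()
        assert all(ln.startswith("#") for ln in lines)
        assert sp.read_vcf(str(out)).n_markers == 0

    def test_missing_serialized_as_dot_slash_dot(self, tmp_path):
        m = build_matrix([[Call.MISSING], [Call.HOM_REF]])
        out = tmp_path / "miss.vcf"
        sp.write_vcf(m, out)
        data = [ln for ln in out.read_text().splitlines() if not ln.startswith("#")]
        assert data[0].split("\t")[9] == "./."

    def test_records_sorted_by_chrom_then_pos(self, tmp_path):
        markers = [
            MarkerRecord("chr2", 50, "A", ("G",), id="b"),
            MarkerRecord("chr1", 900, "C", ("T",), id="a"),
        ]
        m = GenotypeMatrix(["s1"], markers, np.zeros((1, 2), dtype=np.int8))
        out = tmp_path / "sorted.vcf"
        sp.write_vcf(m, out)
        assert sp.read_vcf(str(out)).marker_ids == ["a", "b"]


@st.composite
def matrices(draw):
    n_samples = draw(st.integers(1, 6))
    n_markers = draw(st.integers(1, 6))
    positions = draw(
        st.lists(
            st.integers(1, 10_000),
            min_size=n_markers,
            max_size=n_markers,
            unique=True,
        )
    )
    ref_alt = [("A", "G"), ("C", "T"), ("G", "C"), ("T", "A")]
    markers = [
        MarkerRecord("chr1", pos, ref_alt[j % 4][0], (ref_alt[j % 4][1],),
                     id=f"m{j}")
        for j, pos in enumerate(sorted(positions))
    ]
    calls = np.array(
        draw(
            st.lists(
                st.lists(st.integers(0, 3), min_size=n_markers, max_size=n_markers),
                min_size=n_samples,
                max_size=n_samples,
            )
        ),
        dtype=np.int8,
    )
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples, markers, calls)


class TestRoundTrips:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(matrix=matrices())
    def test_vcf_round_trip_identity(self, matrix, tmp_path_factory):
        out = tmp_path_factory.mktemp("rt") / "rt.vcf"
        sp.write_vcf(matrix, out)
        assert sp.read_vcf(str(out)) == matrix.sorted_by_position()

    @pytest.mark.parametrize("orient", ["samples-rows", "markers-rows"])
    def test_genotype_table_round_trip(self, tmp_path, orient):
        m = build_matrix([[0, 1, 3], [2, 2, 0]], ref_alts=[("A", "G")] * 3)
        path = tmp_path / "table.tsv"
        sp.write_genotype_table(m, path, orient=orient)
        back = sp.read_genotype_table(path, markers=m.markers, orient=orient)
        assert back == m


class TestGenomeAnnotation:
    def test_fasta_fetch_1_based_inclusive(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nATGCCC\n")
        g = sp.read_genome(str(fa))
        assert g.fetch("chr1", 1, 3) == "ATG"
        assert g.fetch("chr1", 4, 6) == "CCC"
        with pytest.raises(ValueError):
            g.fetch("chr1", 0, 3)

    def test_gff3_cds_phase_and_strand(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\tCDS\t10\t20\t.\t-\t2\tID=c1;Parent=t1\n"
            "chr1\tx\tCDS\t30\t41\t.\t-\t0\tID=c2;Parent=t1\n"
        )
        segs = sp.read_cds(str(gff))
        assert [s.phase for s in segs] == [2, 0]
        assert all(s.strand == "-" for s in segs)
        grouped = sp.io.group_by_transcript(segs)
        assert [s.start for s in grouped["t1"]] == [10, 30]  # genomic order

    def test_chrom_name_mismatch_lists_offenders(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nATGCCC\n")
        from snpanel.model import CdsSegment
        segs = [CdsSegment("chrX", 1, 3, "+", 0, "t1")]
        with pytest.raises(ValueError, match="chrX"):
            sp.io.check_chrom_names(sp.read_genome(str(fa)), segs)


class TestMatrixModel:
    def test_duplicate_marker_ids_rejected(self):
        markers = [
            MarkerRecord("chr1", 1, "A", ("G",), id="m"),
            MarkerRecord("chr1", 2, "A", ("G",), id="m"),
        ]
        with pytest.raises(ValueError, match="duplicate marker"):
            GenotypeMatrix(["s1"], markers, np.zeros((1, 2), dtype=np.int8))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            build_matrix(np.zeros((2, 3), dtype=np.int8), ref_alts=[("A", "G")] * 2)

    def test_select_markers_preserves_order_given(self):
        m = build_matrix([[0, 1, 2]], ref_alts=[("A", "G")] * 3)
        sub = m.select_markers(["m3", "m1"])
        assert sub.marker_ids == ["m3", "m1"]
        assert list(sub.calls[0]) == [2, 0]
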