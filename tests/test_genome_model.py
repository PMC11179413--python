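"""Coordinate conventions, VCF round trips and breakend normalisation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from invkit.genome_model import (
    Breakend,
    GenomicInterval,
    InvalidIntervalError,
    SVCall,
    interval_size,
    normalize_bnd_inversion,
    read_gene_models,
    read_sv_vcf,
    revcomp,
    write_sv_vcf,
)


@pytest.mark.parametrize(
    "chrom, start, end, expected",
    [
        ("chr3", 6_352_714, 37_035_341, 30_682_627),  # 30.7-Mb clinical inversion
        ("chrX", 19_564_733, 22_210_246, 2_645_513),
        ("chr19", 35_717_427, 35_725_612, 8_185),  # complex deletion
        ("chr19", 35_717_452, 35_717_546, 94),  # retained internal segment
        ("chr10", 87_949_156, 87_963_156, 14_000),
        ("chr1", 100, 100, 0),
    ],
)
def test_interval_size_reproduces_reported_segment_sizes(chrom, start, end, expected):
    assert interval_size(GenomicInterval(chrom, start, end)) == expected


def test_invalid_intervals_rejected():
    with pytest.raises(InvalidIntervalError):
        GenomicInterval("chr1", 200, 100)
    with pytest.raises(InvalidIntervalError):
        GenomicInterval("chr1", 0, 10)


def test_chrom_names_normalized():
    assert GenomicInterval("2", 1, 10).chrom == "chr2"


@given(
    start=st.integers(1, 10**8),
    mid_off=st.integers(0, 10**6),
    end_off=st.integers(0, 10**6),
)
def test_interval_size_additive_under_abutment(start, mid_off, end_off):
    mid = start + mid_off
    end = mid + end_off
    a = GenomicInterval("chr1", start, mid)
    b = GenomicInterval("chr1", mid, end)
    whole = GenomicInterval("chr1", start, end)
    assert a.size() >= 0 and b.size() >= 0
    assert a.size() + b.size() == whole.size()


def _inv_call(call_id, sample, start, end, genotype="het", pr=7, fam="FAM001"):
    return SVCall(
        call_id=call_id, family_id=fam, sample_id=sample, svtype="INV",
        interval=GenomicInterval("chr2", start, end), pair_support=pr,
        split_support=3, genotype=genotype,
    )


class TestVcfRoundTrip:
    def test_fixture_vcf_read_field_by_field(self, tmp_path):
        calls = [
            _inv_call("inv1", "S1", 47_406_871, 47_425_914),
            SVCall(call_id="del1", family_id="FAM001", sample_id="S1", svtype="DEL",
                   interval=GenomicInterval("chr2", 1000, 2000), pair_support=4,
                   genotype="hom"),
            SVCall(call_id="bndA", family_id="FAM001", sample_id="S1", svtype="BND",
                   breakend=Breakend("chr2", 5000, "left"),
                   mate_breakend=Breakend("chr5", 9000, "right"),
                   mate_id="bndB", pair_support=5, genotype="het"),
            SVCall(call_id="bndB", family_id="FAM001", sample_id="S1", svtype="BND",
                   breakend=Breakend("chr5", 9000, "right"),
                   mate_breakend=Breakend("chr2", 5000, "left"),
                   mate_id="bndA", pair_support=5, genotype="het"),
        ]
        path = tmp_path / "fixture.vcf"
        write_sv_vcf(str(path), calls, contigs=[("chr2", 50_000_000), ("chr5", 10_000_000)])
        back = {c.call_id: c for c in read_sv_vcf(str(path), "FAM001")}
        assert len(back) == 4
        assert back["inv1"].interval == GenomicInterval("chr2", 47_406_871, 47_425_914)
        assert back["inv1"].pair_support == 7 and back["inv1"].split_support == 3
        assert back["inv1"].genotype == "het"
        assert back["del1"].genotype == "hom"
        assert back["bndA"].breakend == Breakend("chr2", 5000, "left")
        assert back["bndA"].mate_breakend == Breakend("chr5", 9000, "right")
        assert back["bndA"].mate_id == "bndB" and not back["bndA"].unpaired

    def test_empty_vcf_body(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_sv_vcf(str(path), [], samples=["S1"], contigs=[("chr1", 1000)])
        assert read_sv_vcf(str(path), "FAM001") == []

    def test_multisample_genotypes_assign_carriers(self, tmp_path):
        calls = [
            _inv_call("inv1", "kid", 10_000, 20_000),
            _inv_call("inv1", "mum", 10_000, 20_000),
        ]
        path = tmp_path / "trio.vcf"
        write_sv_vcf(str(path), calls, samples=["kid", "mum", "dad"],
                     contigs=[("chr2", 1_000_000)])
        back = read_sv_vcf(str(path), "FAM001")
        assert {c.sample_id for c in back} == {"kid", "mum"}


class TestBndInversionNormalization:
    def _quartet(self, s, e):
        """Breakend quartet a newer caller emits for an inversion of (s, e)."""
        mk = lambda cid, be, mate, mid: SVCall(
            call_id=cid, family_id="F", sample_id="S", svtype="BND",
            breakend=be, mate_breakend=mate, mate_id=mid, genotype="het",
        )
        return [
            mk("b1", Breakend("chr7", s, "left"), Breakend("chr7", e, "left"), "b2"),
            mk("b2", Breakend("chr7", e, "left"), Breakend("chr7", s, "left"), "b1"),
            mk("b3", Breakend("chr7", s + 1, "right"), Breakend("chr7", e + 1, "right"), "b4"),
            mk("b4", Breakend("chr7", e + 1, "right"), Breakend("chr7", s + 1, "right"), "b3"),
        ]

    def test_quartet_collapses_to_planted_interval(self):
        s, e = 1_000_000, 1_010_000
        out = normalize_bnd_inversion(self._quartet(s, e))
        assert all(c.svtype == "INV" for c in out)
        for c in out:
            assert abs(c.interval.start - s) <= 1 and abs(c.interval.end - e) <= 1

    def test_positions_preserved(self):
        s, e = 500, 900
        quartet = self._quartet(s, e)
        before = sorted(
            p for c in quartet for p in (c.breakend.pos, c.mate_breakend.pos)
        )
        out = normalize_bnd_inversion(quartet)
        after = sorted(p for c in out for p in (c.interval.start, c.interval.end))
        assert all(abs(x - y) <= 1 for x, y in zip(before, after))

    def test_interchromosomal_pair_passes_through(self):
        call = SVCall(
            call_id="t1", family_id="F", sample_id="S", svtype="BND",
            breakend=Breakend("chr1", 100, "left"),
            mate_breakend=Breakend("chr2", 200, "left"),
            mate_id="t2", genotype="het",
        )
        out = normalize_bnd_inversion([call])
        assert out == [call]

    def test_empty_input(self):
        assert normalize_bnd_inversion([]) == []


class TestGeneModels:
    TABLE = (
        "#gene\ttranscript\tchrom\tstrand\texon_starts\texon_ends\tcds_start\tcds_end\tcanonical\n"
        "PTN1\tPTN1.t1\tchr10\t+\t100,1000,2000\t200,1200,2400\t1000\t2300\t1\n"
        "PTN1\tPTN1.t2\tchr10\t+\t100,2000\t200,2400\t2000\t2300\t0\n"
        "MLX1\tMLX1.t1\tchr3\t-\t500,900\t600,1000\t520\t950\t1\n"
    )

    def test_two_gene_fixture(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(self.TABLE)
        genes = {g.gene_symbol: g for g in read_gene_models(str(path))}
        assert set(genes) == {"PTN1", "MLX1"}
        assert len(genes["PTN1"].transcripts) == 2
        assert len(genes["PTN1"].transcripts[0].exons) == 3

    def test_span_covers_all_transcripts(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(self.TABLE)
        genes = {g.gene_symbol: g for g in read_gene_models(str(path))}
        span = genes["PTN1"].span
        for t in genes["PTN1"].transcripts:
            for e in t.exons:
                assert span.contains(e)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("G1\tt1\tchr1\n")
        with pytest.raises(ValueError, match=":1:"):
            read_gene_models(str(path))

    def test_overlapping_exons_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "G1\tG1.t1\tchr1\t+\t100,150\t200,260\t.\t.\t0\n"
        )
        with pytest.raises(ValueError, match="overlap"):
            read_gene_models(str(path))

    def test_bed12_parsed(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text(
            "chr1\t999\t2400\tG2|G2.t1\t0\t+\t999\t2300\t0\t2\t201,400\t0,1001\n"
        )
        (gene,) = read_gene_models(str(path))
        assert gene.gene_symbol == "G2"
        t = gene.transcripts[0]
        assert t.exons[0].start == 1000 and t.cds_start == 1000 and t.cds_end == 2300


def test_revcomp():
    assert revcomp("ACGTN") == "NACGT"
    assert revcomp(revcomp("GATTACA")) == "GATTACA"
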