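"""Structure taxonomy, configuration enumeration and phasing."""

import pytest

from invkit.complex_sv import (
    Configuration,
    InsertedSequenceEvidence,
    Junction,
    RearrangementStructure,
    Segment,
    classify_structure,
    enumerate_configurations,
    flag_mobile_element_suspect,
    junctions_from_configuration,
    pair_inv_calls,
    phase_sv_by_informative_snps,
    reconstruct_derivatives,
    resolvable_by_technology,
    validate_configuration,
)
from invkit.genome_model import Breakend, GenomicInterval, SVCall
from invkit.synthetic_data import (
    PLANTABLE_CLASSES,
    CohortSimParams,
    simulate_cohort,
)


class TestPairInvCalls:
    def test_founder_event_offsets(self):
        # the intragenic mismatch-repair-gene founder inversion: 1.2-kb loss
        a = GenomicInterval("chr2", 47_406_871, 47_425_914)
        b = GenomicInterval("chr2", 47_408_111, 47_425_934)
        out = pair_inv_calls(a, b)
        assert out.start_offset == 1_240
        assert out.end_offset == 20
        assert out.loss_bp == 1_240
        assert out.loss_end == "proximal"
        assert out.outer_span == GenomicInterval("chr2", 47_406_871, 47_425_934)
        assert out.loss_fraction < 0.10

    def test_homeobox_cluster_offsets(self):
        a = GenomicInterval("chr2", 176_087_987, 176_110_607)
        b = GenomicInterval("chr2", 176_087_748, 176_110_599)
        out = pair_inv_calls(a, b)
        assert out.start_offset == 239 and out.end_offset == 8

    def test_identical_records_no_loss(self):
        a = GenomicInterval("chr1", 1000, 2000)
        out = pair_inv_calls(a, a)
        assert out.loss_end == "none" and out.loss_bp == 0

    def test_small_offsets_within_jitter_not_a_loss(self):
        a = GenomicInterval("chrX", 19_564_733, 22_210_246)
        b = GenomicInterval("chrX", 19_564_733 + 4, 22_210_246 - 3)
        assert pair_inv_calls(a, b).loss_end == "none"

    def test_different_chromosomes_error(self):
        with pytest.raises(ValueError):
            pair_inv_calls(GenomicInterval("chr1", 1, 10), GenomicInterval("chr2", 1, 10))


def _balanced_inv_structure():
    segs = [
        Segment("A", GenomicInterval("chr1", 1_000, 5_000)),
        Segment("B", GenomicInterval("chr1", 5_000, 9_000), orientation="-"),
        Segment("C", GenomicInterval("chr1", 9_000, 12_000)),
    ]
    st = RearrangementStructure(segments=segs, junctions=[])
    st.junctions = junctions_from_configuration(
        Configuration((("A+", "B-", "C+"),)), st
    )
    return st


class TestEnumeration:
    def test_balanced_inversion_single_configuration(self):
        st = _balanced_inv_structure()
        cfgs = enumerate_configurations(st)
        assert [c.derivatives for c in cfgs] == [(("A+", "B-", "C+"),)]

    def _dup_trp(self):
        from invkit.complex_sv import _build_dup_trp_structure

        return _build_dup_trp_structure(
            [GenomicInterval("chrX", 20_000, 27_000)],
            [GenomicInterval("chrX", 27_000, 40_000)],
            None,
        )

    def test_dup_trp_yields_four_configurations(self):
        st = self._dup_trp()
        cfgs = enumerate_configurations(st)
        assert len(cfgs) == 4
        assert all(validate_configuration(c, st) for c in cfgs)

    def test_dup_trp_spanned_collapses_to_one(self):
        st = self._dup_trp()
        j1, j2 = st.junctions
        ctx = ("T+", "S-", "T-", "D-", "T+")  # read across fold-back and dup copy
        st_spanned = RearrangementStructure(
            segments=st.segments,
            junctions=[j1, Junction(j2.breakend_1, j2.breakend_2,
                                    spanned=True, spanned_context=ctx)],
        )
        cfgs = enumerate_configurations(st_spanned)
        assert len(cfgs) == 1
        assert cfgs[0].derivatives == (
            ("L+", "D+", "T+", "S-", "T-", "D-", "T+", "S+", "R+"),
        )

    def _insertional(self):
        p = 50_000
        segs = [
            Segment("A1", GenomicInterval("chr5", 1_000, p)),
            Segment("A2", GenomicInterval("chr5", p, 90_000)),
            Segment("B1", GenomicInterval("chr19", 1_000, 30_000)),
            Segment("Bseg", GenomicInterval("chr19", 30_000, 44_500), copy_number=2),
            Segment("B2", GenomicInterval("chr19", 44_500, 80_000)),
        ]
        junctions = [
            Junction(Breakend("chr5", p, "left"), Breakend("chr19", 30_000, "right")),
            Junction(Breakend("chr19", 44_500, "left"), Breakend("chr5", p, "right")),
        ]
        return RearrangementStructure(segments=segs, junctions=junctions)

    def test_unspanned_duplicated_insertion_is_two_way_ambiguous(self):
        # insertion of the duplicated donor segment vs reciprocal
        # translocation with a duplication at the breakpoint
        st = self._insertional()
        cfgs = enumerate_configurations(st)
        assert len(cfgs) == 2
        derivative_sets = {c.derivatives for c in cfgs}
        assert (("A1+", "Bseg+", "A2+"), ("B1+", "Bseg+", "B2+")) in derivative_sets
        assert (("A1+", "Bseg+", "B2+"), ("B1+", "Bseg+", "A2+")) in derivative_sets

    def test_long_read_across_duplicated_copy_resolves_insertion(self):
        st = self._insertional()
        ctx = ("A1+", "Bseg+", "A2+")
        spanned = [
            Junction(j.breakend_1, j.breakend_2, spanned=True, spanned_context=ctx)
            for j in st.junctions
        ]
        cfgs = enumerate_configurations(
            RearrangementStructure(segments=st.segments, junctions=spanned)
        )
        assert [c.derivatives for c in cfgs] == [
            (("A1+", "Bseg+", "A2+"), ("B1+", "Bseg+", "B2+"))
        ]

    def test_spanning_never_increases_count(self):
        st = self._dup_trp()
        base = len(enumerate_configurations(st))
        j1, j2 = st.junctions
        for ctx_junctions in (
            [Junction(j1.breakend_1, j1.breakend_2, spanned=True,
                      spanned_context=("T+", "S-", "T-")), j2],
            [j1, Junction(j2.breakend_1, j2.breakend_2, spanned=True,
                          spanned_context=("T-", "D-", "T+"))],
        ):
            n = len(enumerate_configurations(
                RearrangementStructure(segments=st.segments, junctions=ctx_junctions)
            ))
            assert n <= base

    def test_count_invariant_under_translation_and_relabeling(self):
        from invkit.complex_sv import _build_dup_trp_structure

        st1 = self._dup_trp()
        st2 = _build_dup_trp_structure(
            [GenomicInterval("chr9", 1_020_000, 1_027_000)],
            [GenomicInterval("chr9", 1_027_000, 1_040_000)],
            None,
        )
        assert len(enumerate_configurations(st1)) == len(enumerate_configurations(st2))

    def test_combinatorial_bound(self):
        from invkit.complex_sv import CombinatorialLimitError

        segs = [Segment("L", GenomicInterval("chr1", 1, 1000))]
        pos = 1000
        for i in range(7):
            segs.append(Segment(f"M{i}", GenomicInterval("chr1", pos, pos + 100),
                                copy_number=2))
            pos += 100
        segs.append(Segment("R", GenomicInterval("chr1", pos, pos + 1000)))
        st = RearrangementStructure(segments=segs, junctions=[])
        with pytest.raises(CombinatorialLimitError):
            enumerate_configurations(st)


class TestReconstruction:
    def test_simple_inversion_derivative(self):
        st = _balanced_inv_structure()
        (der,) = reconstruct_derivatives(Configuration((("A+", "B-", "C+"),)), st)
        assert [p.signed_label for p in der.parts] == ["A+", "B-", "C+"]
        assert der.parts[0].der_start == 0
        assert der.parts[-1].der_end == 11_000  # total span under end-start sizing

    def test_gene_disruption_flagged_at_junctions(self):
        st = _balanced_inv_structure()
        genes = {"GENE1": GenomicInterval("chr1", 4_000, 6_000)}
        (der,) = reconstruct_derivatives(
            Configuration((("A+", "B-", "C+"),)), st, genes=genes
        )
        assert ("GENE1", 5_000) in der.disrupted_genes

    def test_invalid_configuration_rejected(self):
        st = _balanced_inv_structure()
        with pytest.raises(ValueError):
            reconstruct_derivatives(Configuration((("A+", "B+", "C+"),)), st)

    def test_round_trip_through_junction_validator(self):
        # a nine-segment two-chromosome configuration round-trips
        params = CohortSimParams(seed=2, n_families=5, n_planted_pathogenic=1,
                                 planted_classes=("COMPLEX_TRANSLOCATION",),
                                 n_common_polymorphic_inversions=0)
        event = simulate_cohort(params).truth.events[0]
        ders = reconstruct_derivatives(event.truth_configuration, event.structure)
        assert len(ders) == 2
        implied = junctions_from_configuration(event.truth_configuration, event.structure)
        assert len(implied) == len(event.structure.junctions)


class TestClassification:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("cls", PLANTABLE_CLASSES)
    def test_recovers_planted_class(self, cls, seed):
        params = CohortSimParams(seed=seed * 31 + 7, n_families=5,
                                 n_planted_pathogenic=1, planted_classes=(cls,),
                                 n_common_polymorphic_inversions=0)
        event = simulate_cohort(params).truth.events[0]
        templates = {}
        for c in event.calls:
            templates.setdefault(c.call_id, c)
        st = classify_structure(
            list(templates.values()), event.depth_profile,
            inserted_seq_evidence=event.evidence, enumerate_configs=False,
        )
        assert st.class_label == cls

    def test_retained_segment_deletion_signature(self):
        # deletion with a 94-bp retained/inverted internal segment
        del_iv = GenomicInterval("chr19", 35_717_427, 35_725_612)
        inv_iv = GenomicInterval("chr19", 35_717_452, 35_725_612)
        retained = GenomicInterval("chr19", 35_717_452, 35_717_546)
        calls = [
            SVCall(call_id="d", family_id="F", sample_id="S", svtype="DEL",
                   interval=del_iv, pair_support=9, genotype="het"),
            SVCall(call_id="i", family_id="F", sample_id="S", svtype="INV",
                   interval=inv_iv, pair_support=9, genotype="het"),
        ]
        depth = [
            (GenomicInterval("chr19", del_iv.start, retained.start), 0),
            (retained, 1),
            (GenomicInterval("chr19", retained.end, del_iv.end), 0),
        ]
        st = classify_structure(calls, depth)
        assert st.class_label == "DEL_WITH_RETAINED_SEGMENTS"
        assert st.configurations and st.configurations[0].derivatives == (
            ("A+", "X-", "C+"),
        )

    def test_paired_inv_with_small_loss_is_simple(self):
        # offsets 1,240 / 20 over a 19,063-bp span: loss fraction ~6.5%
        calls = [
            SVCall(call_id="a", family_id="F", sample_id="S", svtype="INV",
                   interval=GenomicInterval("chr2", 47_406_871, 47_425_914),
                   pair_support=9, genotype="het"),
            SVCall(call_id="b", family_id="F", sample_id="S", svtype="INV",
                   interval=GenomicInterval("chr2", 47_408_111, 47_425_934),
                   pair_support=9, genotype="het"),
        ]
        st = classify_structure(calls)
        assert st.class_label == "SIMPLE_INV"
        interp = st.evidence["pair_interpretation"]
        assert interp.loss_bp == 1_240 and 0.06 < interp.loss_fraction < 0.07

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            classify_structure([])


class TestMobileElementFlag:
    def _inv(self, size):
        return SVCall(call_id="i", family_id="F", sample_id="S", svtype="INV",
                      interval=GenomicInterval("chr12", 10_000, 10_000 + size),
                      pair_support=5, genotype="het")

    def test_alu_like_signature_flagged(self):
        ev = InsertedSequenceEvidence(clipped_seq_matches_insertion=True,
                                      spanning_pairs=0)
        assert flag_mobile_element_suspect(self._inv(300), ev)

    def test_genuine_small_inversion_with_spanning_pairs_not_flagged(self):
        ev = InsertedSequenceEvidence(clipped_seq_matches_insertion=False,
                                      spanning_pairs=4)
        assert not flag_mobile_element_suspect(self._inv(300), ev)

    def test_large_inversion_never_flagged(self):
        ev = InsertedSequenceEvidence(clipped_seq_matches_insertion=True,
                                      spanning_pairs=0)
        assert not flag_mobile_element_suspect(self._inv(50_000), ev)


class TestTechnologyThresholds:
    @pytest.mark.parametrize(
        "size, tech, expected",
        [
            (406, "short_read_150", True),
            (681, "short_read_150", False),
            (14_500, "hifi", True),
            (25_000, "hifi", False),
            (100_000, "ultralong", True),
        ],
    )
    def test_span_limits(self, size, tech, expected):
        assert resolvable_by_technology(size, tech) is expected

    def test_non_positive_size_error(self):
        with pytest.raises(ValueError):
            resolvable_by_technology(0, "hifi")


class TestPhasing:
    TRIO = {
        100: (("A", "G"), ("G", "G"), ("A", "A")),
        200: (("C", "T"), ("T", "T"), ("C", "C")),
        300: (("A", "C"), ("C", "C"), ("A", "A")),
        400: (("G", "T"), ("T", "T"), ("G", "G")),
    }

    def test_four_concordant_votes(self):
        reads = {100: "G", 200: "T", 300: "C", 400: "T"}
        out = phase_sv_by_informative_snps(reads, self.TRIO)
        assert out.origin == "maternal" and out.votes_maternal == 4

    def test_no_informative_snps(self):
        out = phase_sv_by_informative_snps({}, self.TRIO)
        assert out.origin == "undetermined" and not out.conflict

    def test_conflicting_votes_undetermined(self):
        reads = {100: "G", 200: "T", 300: "A"}  # two maternal, one paternal
        out = phase_sv_by_informative_snps(reads, self.TRIO)
        assert out.origin == "undetermined" and out.conflict

    def test_uninformative_snp_ignored(self):
        trio = dict(self.TRIO)
        trio[500] = (("A", "G"), ("A", "G"), ("A", "G"))  # everyone het
        out = phase_sv_by_informative_snps({500: "A"}, trio)
        assert out.origin == "undetermined"
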