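"""Conflicting-homozygosity scan, shared rare variants and mutation age."""

import numpy as np
import pytest

from invkit.founder_haplotype import (
    SampleObservation,
    VariantSite,
    baf,
    cm_from_bp,
    conflicting_homozygosity_scan,
    estimate_mutation_age,
    shared_rare_variants,
)
from invkit.genome_model import GenomicInterval
from invkit.synthetic_data import simulate_ancestral_lengths, simulate_founder_pair


def _site(pos, gt_a, gt_b, chrom="chr2"):
    s = VariantSite(chrom, pos, "A", "C")
    s.samples["S1"] = SampleObservation(genotype=gt_a)
    s.samples["S2"] = SampleObservation(genotype=gt_b)
    return s


class TestBaf:
    def test_fractions(self):
        s = VariantSite("chr1", 100, "A", "C")
        s.samples["S1"] = SampleObservation(ref_reads=5, alt_reads=5)
        s.samples["S2"] = SampleObservation(ref_reads=10, alt_reads=0)
        s.samples["S3"] = SampleObservation(ref_reads=3, alt_reads=7)
        assert baf(s, "S1") == 0.5
        assert baf(s, "S2") == 0.0
        assert baf(s, "S3") == 0.7

    def test_zero_depth_is_missing_not_error(self):
        s = VariantSite("chr1", 100, "A", "C")
        s.samples["S1"] = SampleObservation()
        assert baf(s, "S1") is None
        assert baf(s, "unseen") is None


class TestConflictScan:
    def test_identical_genotypes_span_whole_region(self):
        sites = [_site(p, "het", "het") for p in range(1_000, 10_000, 500)]
        hap = conflicting_homozygosity_scan(sites, "S1", "S2", 5_000)
        assert hap.interval.start == 1_000 and hap.interval.end == 9_500
        assert hap.left_flank_conflict_pos is None
        assert hap.right_flank_conflict_pos is None

    def test_planted_flanks_define_the_interval(self):
        sites = []
        for p in range(100, 10_001, 100):
            if p in (1_000, 9_000):
                sites.append(_site(p, "hom_ref", "hom_alt"))
            else:
                sites.append(_site(p, "het", "hom_ref"))
        hap = conflicting_homozygosity_scan(sites, "S1", "S2", 5_000)
        assert hap.interval == GenomicInterval("chr2", 1_000, 9_000)
        assert hap.left_flank_conflict_pos == 1_000
        assert hap.right_flank_conflict_pos == 9_000
        # the conflict sites themselves are excluded from the interior
        assert hap.n_sites_inside == len([p for p in range(100, 10_001, 100)
                                          if 1_000 < p < 9_000])

    def test_baf_proxy_used_when_genotypes_missing(self):
        sites = []
        for p in (100, 200, 300):
            s = VariantSite("chr2", p, "A", "C")
            s.samples["S1"] = SampleObservation(ref_reads=20, alt_reads=0)
            s.samples["S2"] = SampleObservation(
                ref_reads=0 if p == 300 else 20, alt_reads=20 if p == 300 else 0
            )
            sites.append(s)
        hap = conflicting_homozygosity_scan(sites, "S1", "S2", 200)
        assert hap.right_flank_conflict_pos == 300

    def test_target_outside_region_error(self):
        sites = [_site(100, "het", "het")]
        with pytest.raises(ValueError):
            conflicting_homozygosity_scan(sites, "S1", "S2", 999)

    def test_simulated_pair_recovers_planted_flanks_exactly(self):
        sim = simulate_founder_pair(
            region_bp=2_000_000, shared_len_bp=400_000, site_spacing_bp=2_000,
            depth=30, seed=42,
        )
        hap = conflicting_homozygosity_scan(
            sim.sites, *sim.carriers, target=sim.target
        )
        assert hap.left_flank_conflict_pos == sim.truth_left_flank
        assert hap.right_flank_conflict_pos == sim.truth_right_flank

    def test_fully_shared_region_returns_full_region(self):
        sim = simulate_founder_pair(
            region_bp=200_000, shared_len_bp=200_000, site_spacing_bp=2_000,
            depth=20, seed=1,
        )
        hap = conflicting_homozygosity_scan(sim.sites, *sim.carriers, target=sim.target)
        assert hap.left_flank_conflict_pos is None
        assert hap.right_flank_conflict_pos is None

    @pytest.mark.parametrize("seed", range(30))
    def test_unrelated_pair_shares_little(self, seed):
        # unrelated samples: shared interval far below the scanned region
        sim = simulate_founder_pair(
            region_bp=2_000_000, shared_len_bp=0, site_spacing_bp=1_000,
            depth=30, seed=seed,
        )
        hap = conflicting_homozygosity_scan(sim.sites, *sim.carriers, target=sim.target)
        assert hap.interval.size() < 2_000_000 * 0.5


class TestSharedRareVariants:
    def test_planted_thirteen_recovered(self):
        sim = simulate_founder_pair(
            region_bp=4_000_000, shared_len_bp=3_200_000, site_spacing_bp=10_000,
            depth=30, seed=7, n_shared_rare=13,
        )
        hap = conflicting_homozygosity_scan(sim.sites, *sim.carriers, target=sim.target)
        rare = shared_rare_variants(
            sim.sites, sim.carriers, sim.cohort_af, max_af=0.001, haplotype=hap
        )
        assert [s.pos for s in rare] == sim.shared_rare_positions
        assert len(rare) == 13

    def test_discordant_carrier_excluded(self):
        sites = [_site(500, "het", "hom_ref")]
        out = shared_rare_variants(sites, ["S1", "S2"], {500: 1e-4})
        assert out == []

    def test_monotone_in_max_af(self):
        sites = [_site(p, "het", "het") for p in (100, 200, 300)]
        af = {100: 1e-4, 200: 5e-3, 300: 0.2}
        small = shared_rare_variants(sites, ["S1", "S2"], af, max_af=1e-3)
        big = shared_rare_variants(sites, ["S1", "S2"], af, max_af=1e-2)
        assert {s.pos for s in small} <= {s.pos for s in big}


class TestAgeEstimator:
    def test_two_carrier_point_estimate(self):
        # two one-sided lengths summing 3.2 cM -> m/(2L) = 31.25 generations
        est = estimate_mutation_age([0.016, 0.016], genealogy="independent")
        assert est.tau_hat == pytest.approx(31.25)
        assert est.ci95[0] <= est.tau_hat <= est.ci95[1]

    def test_scaling(self):
        e1 = estimate_mutation_age([0.01, 0.02, 0.03])
        e2 = estimate_mutation_age([0.02, 0.04, 0.06])
        assert e2.tau_hat == pytest.approx(e1.tau_hat / 2)

    def test_correlated_mode_widens_interval(self):
        lengths = [0.016, 0.016, 0.02, 0.012]
        ind = estimate_mutation_age(lengths, genealogy="independent")
        cor = estimate_mutation_age(lengths, genealogy="correlated", correlation_rho=0.5)
        assert cor.ci95[1] - cor.ci95[0] > ind.ci95[1] - ind.ci95[0]
        assert cor.ci95[0] <= cor.tau_hat <= cor.ci95[1]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_mutation_age([])
        with pytest.raises(ValueError):
            estimate_mutation_age([0.0, 0.01])

    def test_simulation_recovery_median_and_coverage(self):
        tau, m, reps = 30.0, 4, 500
        rng = np.random.default_rng(123)
        taus, covered = [], 0
        for _ in range(reps):
            lengths = rng.exponential(1.0 / (2 * tau), size=m)
            est = estimate_mutation_age(lengths)
            taus.append(est.tau_hat)
            covered += est.ci95[0] <= tau <= est.ci95[1]
        assert abs(np.median(taus) - tau) / tau < 0.25
        assert covered / reps >= 0.90


class TestGeneticMap:
    def test_constant_rate(self):
        iv = GenomicInterval("chr2", 1, 3_200_001)
        assert cm_from_bp(iv) == pytest.approx(0.032)

    def test_piecewise_map(self):
        # rate doubles halfway: 1 cM/Mb then 2 cM/Mb
        gmap = [(0, 0.0), (1_000_000, 1.0), (2_000_000, 3.0)]
        iv = GenomicInterval("chr2", 500_000, 1_500_000)
        assert cm_from_bp(iv, genetic_map=gmap) == pytest.approx((2.0 - 0.5) / 100)

    def test_outside_map_error(self):
        gmap = [(1_000, 0.0), (2_000, 0.1)]
        with pytest.raises(ValueError):
            cm_from_bp(GenomicInterval("chr2", 500, 1_500), genetic_map=gmap)

    def test_no_map_no_rate_error(self):
        with pytest.raises(ValueError):
            cm_from_bp(GenomicInterval("chr2", 1, 100),
                       genetic_map=None, constant_rate_cm_per_mb=None)


def test_ancestral_length_generator_mean():
    lengths = simulate_ancestral_lengths(tau=30, n_lengths=10_000, seed=5)
    se = (1 / 60) / np.sqrt(10_000)
    assert abs(lengths.mean() - 1 / 60) < 3 * se
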