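"""Founder-haplotype detection and mutation age estimation.

Two apparently unrelated carriers of the same rare variant are tested for a
shared ancestral haplotype by scanning for *conflicting homozygosity*: a
site where one sample is homozygous reference and the other homozygous
alternate excludes recent co-inheritance of that region.  The interval
around the target locus free of such conflicts, together with ultra-rare
variants shared by all carriers, supports a founder origin.

The age of the founder mutation is estimated from the genetic lengths of
the shared one-sided haplotype segments: under recombination at rate 1 per
Morgan per meiosis, each one-sided shared length l between two carrier
lineages separated by 2*tau meioses is Exponential(2*tau), so the total
L = sum(l_i) over m lengths is Gamma(m, rate 2*tau), the MLE is
tau_hat = m / (2L) and the 95% CI follows from Gamma quantiles.  A
"correlated" genealogy (carriers sharing much of their pedigree back to the
founder) is handled by shrinking the effective number of lengths.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from .genome_model import GenomicInterval

__all__ = [
    "VariantSite",
    "SharedHaplotype",
    "AgeEstimate",
    "baf",
    "conflicting_homozygosity_scan",
    "shared_rare_variants",
    "estimate_mutation_age",
    "cm_from_bp",
]

GT = Literal["hom_ref", "het", "hom_alt", "missing"]


@dataclass
class SampleObservation:
    ref_reads: int = 0
    alt_reads: int = 0
    genotype: GT = "missing"


@dataclass
class VariantSite:
    """One biallelic SNV site with per-sample depths and genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    samples: dict[str, SampleObservation] = field(default_factory=dict)

    def gt(self, sample: str) -> GT:
        obs = self.samples.get(sample)
        return obs.genotype if obs is not None else "missing"


@dataclass
class SharedHaplotype:
    """Conflict-free interval around the target locus.

    The interval runs between the nearest conflicting-homozygosity sites on
    either side of the target (exclusive of the conflict positions
    themselves); a missing flank means no conflict inside the scanned
    region on that side.
    """

    interval: GenomicInterval
    left_flank_conflict_pos: int | None
    right_flank_conflict_pos: int | None
    n_sites_inside: int
    shared_rare_variants: list[VariantSite] = field(default_factory=list)


@dataclass
class AgeEstimate:
    tau_hat: float
    ci95: tuple[float, float]
    genealogy: Literal["independent", "correlated"]
    n_carriers: int | None
    total_shared_length_morgans: float
    n_lengths: int

    def __post_init__(self) -> None:
        low, high = self.ci95
        if not (low <= self.tau_hat <= high):
            raise ValueError("CI must bracket the point estimate")
        if self.tau_hat <= 0:
            raise ValueError("tau_hat must be positive")


def baf(site: VariantSite, sample: str) -> float | None:
    """B allele frequency: alt reads / total reads (None at zero depth)."""
    obs = site.samples.get(sample)
    if obs is None:
        return None
    total = obs.ref_reads + obs.alt_reads
    if total == 0:
        return None
    return obs.alt_reads / total


def _is_conflict(
    site: VariantSite, a: str, b: str, baf_conflict_threshold: float
) -> bool:
    ga, gb = site.gt(a), site.gt(b)
    if ga != "missing" and gb != "missing":
        return {ga, gb} == {"hom_ref", "hom_alt"}
    ba, bb = baf(site, a), baf(site, b)
    if ba is None or bb is None:
        return False
    return abs(ba - bb) >= baf_conflict_threshold


def conflicting_homozygosity_scan(
    sites: Sequence[VariantSite],
    sample_a: str,
    sample_b: str,
    target: int,
    baf_conflict_threshold: float = 0.9,
) -> SharedHaplotype:
    """Shared-haplotype interval around ``target`` for two carriers.

    A site is a conflict when the two samples are homozygous for opposite
    alleles — from hard genotypes when both are called, otherwise from the
    |dBAF| >= threshold proxy.  The returned interval spans from the nearest
    conflict left of the target to the nearest conflict on the right; when a
    side has no conflict the scanned-region bound is used and the flank is
    recorded as None.  Sites must be position-sorted, indel-free and
    quality-filtered upstream.
    """
    if not sites:
        raise ValueError("no sites to scan")
    positions = [s.pos for s in sites]
    if positions != sorted(positions):
        raise ValueError("sites must be sorted by position")
    if not (positions[0] <= target <= positions[-1]):
        raise ValueError(
            f"target {target} outside scanned region "
            f"[{positions[0]}, {positions[-1]}]"
        )
    chrom = sites[0].chrom
    # a conflict exactly at the target would contradict shared carriage of
    # the variant itself and is ignored rather than used as a flank
    conflicts = [
        s.pos
        for s in sites
        if s.pos != target and _is_conflict(s, sample_a, sample_b, baf_conflict_threshold)
    ]
    i = bisect_left(conflicts, target)
    left = conflicts[i - 1] if i > 0 else None
    right = conflicts[i] if i < len(conflicts) else None
    start = left if left is not None else positions[0]
    end = right if right is not None else positions[-1]
    inside = [
        s for s in sites
        if start < s.pos < end or (s.pos == start and left is None) or (s.pos == end and right is None)
    ]
    return SharedHaplotype(
        interval=GenomicInterval(chrom, start, end),
        left_flank_conflict_pos=left,
        right_flank_conflict_pos=right,
        n_sites_inside=len(inside),
    )


def shared_rare_variants(
    sites: Sequence[VariantSite],
    carriers: Sequence[str],
    cohort_af: Mapping[int, float],
    max_af: float = 0.001,
    haplotype: SharedHaplotype | None = None,
) -> list[VariantSite]:
    """Ultra-rare SNVs carried by every carrier inside the shared haplotype.

    A site qualifies when every carrier harbours the alternate allele
    (het or hom_alt), the cohort allele frequency is at most ``max_af``
    and (when a haplotype is given) the position lies strictly inside the
    shared interval.  Sorted by position.
    """
    out = []
    for s in sites:
        if haplotype is not None:
            iv = haplotype.interval
            lo = iv.start if haplotype.left_flank_conflict_pos is None else iv.start + 1
            hi = iv.end if haplotype.right_flank_conflict_pos is None else iv.end - 1
            if not (lo <= s.pos <= hi):
                continue
        af = cohort_af.get(s.pos)
        if af is None or af > max_af:
            continue
        if all(s.gt(c) in ("het", "hom_alt") for c in carriers):
            out.append(s)
    return sorted(out, key=lambda s: s.pos)


def estimate_mutation_age(
    one_sided_lengths_morgans: Sequence[float],
    genealogy: Literal["independent", "correlated"] = "independent",
    correlation_rho: float = 0.5,
    n_carriers: int | None = None,
) -> AgeEstimate:
    """Generations since the founder from shared haplotype lengths.

    ``one_sided_lengths_morgans`` are the genetic lengths (Morgans) of the
    shared segments on each side of the mutation for each independent
    carrier-pair comparison (two one-sided lengths per pair).  Independent
    genealogy: tau_hat = m / (2L) with a Gamma(m) quantile CI.  Correlated
    genealogy: the lengths are not independent, so the effective number of
    lengths is shrunk to m_eff = 1 + (m - 1)(1 - rho) before applying the
    same formulas.
    """
    lengths = np.asarray(one_sided_lengths_morgans, dtype=float)
    if lengths.size == 0:
        raise ValueError("need at least one shared length")
    if np.any(lengths <= 0):
        raise ValueError("shared lengths must be positive")
    m = float(lengths.size)
    L = float(lengths.sum())
    if genealogy == "correlated":
        if not (0 <= correlation_rho < 1):
            raise ValueError("correlation_rho must be in [0, 1)")
        m_eff = 1.0 + (m - 1.0) * (1.0 - correlation_rho)
        L = L * m_eff / m  # shrink total consistently with the effective count
    else:
        m_eff = m
    tau_hat = m_eff / (2.0 * L)
    low = float(gamma_dist.ppf(0.025, m_eff) / (2.0 * L))
    high = float(gamma_dist.ppf(0.975, m_eff) / (2.0 * L))
    return AgeEstimate(
        tau_hat=float(tau_hat),
        ci95=(low, high),
        genealogy=genealogy,
        n_carriers=n_carriers,
        total_shared_length_morgans=float(lengths.sum()),
        n_lengths=int(m),
    )


def cm_from_bp(
    interval: GenomicInterval,
    genetic_map: Sequence[tuple[int, float]] | None = None,
    constant_rate_cm_per_mb: float | None = 1.0,
) -> float:
    """Genetic length of an interval in Morgans.

    With a genetic map (monotone ``(pos, cM)`` points) the cM values at the
    interval ends are linearly interpolated; otherwise a constant rate is
    applied (default 1 cM/Mb).  An interval outside the map raises.
    """
    if genetic_map:
        pts = sorted(genetic_map)
        pos = np.array([p for p, _ in pts], dtype=float)
        cm = np.array([c for _, c in pts], dtype=float)
        if np.any(np.diff(cm) < 0):
            raise ValueError("genetic map must be monotone in cM")
        if interval.start < pos[0] or interval.end > pos[-1]:
            raise ValueError(f"interval {interval} outside genetic map range")
        c1, c2 = np.interp([interval.start, interval.end], pos, cm)
        return float(c2 - c1) / 100.0
    if constant_rate_cm_per_mb is None:
        raise ValueError("need a genetic map or a constant rate")
    return interval.size() / 1e6 * constant_rate_cm_per_mb / 100.0
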