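"""Transcript/protein consequence of an inversion and RNA-level support.

The transcript-level model follows what is observed in RNA for intragenic
inversions of coding exons: the inverted internal block is skipped from the
mature transcript, so the protein effect reduces to deletion arithmetic on
the block's CDS interval.  In-frame internal deletions are not expected to
trigger nonsense-mediated decay (NMD).  RNA support utilities cover allelic
imbalance at heterozygous coding SNPs (exact binomial test against 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from scipy.stats import binomtest

from .genome_model import GenomicInterval, TranscriptModel

__all__ = [
    "TranscriptConsequence",
    "AllelicExpression",
    "cds_del_to_protein",
    "inversion_consequence",
    "monoallelic_test",
    "genomic_to_cds",
]

FrameStatus = Literal["in_frame", "frameshift", "non_coding", "not_applicable"]
PositionEffect = Literal[
    "none", "utr_dislocation", "upstream_breakpoint", "downstream_breakpoint"
]
AllelicVerdict = Literal["monoallelic", "balanced", "imbalanced", "inconclusive"]


@dataclass
class TranscriptConsequence:
    transcript_id: str
    exons_overlapped: list[int]
    coding_overlap: bool
    frame_status: FrameStatus
    deleted_aa: int | None = None
    nmd_expected: bool = False
    position_effect_flag: PositionEffect = "none"
    breakpoint_distance_bp: int | None = None

    def __post_init__(self) -> None:
        if self.deleted_aa is not None and self.frame_status != "in_frame":
            raise ValueError("deleted_aa is defined only for in-frame events")
        if self.nmd_expected and self.frame_status == "in_frame":
            raise ValueError("in-frame events are not expected to trigger NMD")


@dataclass
class AllelicExpression:
    pos: int
    ref_count: int
    alt_count: int
    verdict: AllelicVerdict
    p_value: float | None


def cds_del_to_protein(c_start: int, c_end: int) -> tuple[FrameStatus, int | None]:
    """Protein effect of deleting CDS positions ``c_start..c_end`` (inclusive).

    The deletion is in frame when its length is a multiple of 3 *and* it
    starts at a codon boundary (c_start mod 3 == 1); the number of deleted
    amino acids is then length/3 (c.493_1026del -> 178 residues).  Deletions
    not aligned to codons are reported as frameshifts (splice-phase
    subtleties are deliberately not modelled).
    """
    if c_start < 1:
        raise ValueError("CDS coordinates are 1-based")
    if c_start > c_end:
        raise ValueError(f"c_start > c_end ({c_start} > {c_end})")
    length = c_end - c_start + 1
    if length % 3 == 0 and c_start % 3 == 1:
        return "in_frame", length // 3
    return "frameshift", None


def genomic_to_cds(transcript: TranscriptModel, pos: int) -> int | None:
    """1-based CDS coordinate of a genomic position (None if not in CDS).

    Counts coding bases 5' to 3' in transcript orientation using the
    1-based closed exon/CDS coordinates.
    """
    if not transcript.is_coding:
        return None
    coding = transcript.coding_exons()
    # coding_exons are size-convention intervals [start, end); coding bases
    # of exon e are positions start..end inclusive under 1-based closed
    # coords, i.e. e.end - e.start + 1 bases -- reconstruct closed bounds.
    blocks = [(e.start, e.end) for e in coding]
    inside = any(s <= pos <= t for s, t in blocks)
    if not inside:
        return None
    if transcript.strand == "+":
        c = 0
        for s, t in blocks:
            if pos > t:
                c += t - s + 1
            elif pos >= s:
                return c + (pos - s) + 1
        return None
    c = 0
    for s, t in reversed(blocks):
        if pos < s:
            c += t - s + 1
        elif pos <= t:
            return c + (t - pos) + 1
    return None


def inversion_consequence(
    inversion: GenomicInterval, transcript: TranscriptModel
) -> TranscriptConsequence:
    """Predicted effect of an inversion on one transcript.

    Rules, in order:

    * no contact with the transcript span: upstream/downstream position-
      effect flag with the distance to the nearest transcript edge;
    * a fully covered contiguous internal block of coding exons with both
      breakpoints outside the CDS of that block: modelled as skipping of the
      block, with frame logic delegated to :func:`cds_del_to_protein` on the
      block's CDS interval (in-frame skips are not NMD substrates);
    * a breakpoint that separates 5'-UTR-only exon(s) from the CDS without
      the inversion touching any coding base: ``utr_dislocation``;
    * wholly intronic: ``not_applicable``;
    * anything else touching coding sequence: frameshift-like disruption.
    """
    span = transcript.span
    if inversion.chrom != span.chrom or inversion.overlap_bp(span) == 0:
        if inversion.chrom == span.chrom:
            if inversion.end <= span.start:
                dist = span.start - inversion.end
                flag = "upstream_breakpoint" if transcript.strand == "+" else "downstream_breakpoint"
            else:
                dist = inversion.start - span.end
                flag = "downstream_breakpoint" if transcript.strand == "+" else "upstream_breakpoint"
        else:
            dist, flag = None, "none"
        return TranscriptConsequence(
            transcript_id=transcript.transcript_id,
            exons_overlapped=[],
            coding_overlap=False,
            frame_status="not_applicable",
            position_effect_flag=flag,  # type: ignore[arg-type]
            breakpoint_distance_bp=dist,
        )

    exons = transcript.exons
    overlapped = [i for i, e in enumerate(exons) if inversion.overlap_bp(e) > 0]
    coding = transcript.coding_exons()
    coding_overlap = any(inversion.overlap_bp(ce) > 0 for ce in coding)

    if not overlapped:
        # inside the transcript but exon-free: intronic, unless it detaches
        # UTR-only exons from the CDS.
        if _detaches_utr(inversion, transcript):
            return TranscriptConsequence(
                transcript_id=transcript.transcript_id,
                exons_overlapped=[],
                coding_overlap=False,
                frame_status="non_coding",
                position_effect_flag="utr_dislocation",
            )
        return TranscriptConsequence(
            transcript_id=transcript.transcript_id,
            exons_overlapped=[],
            coding_overlap=False,
            frame_status="not_applicable",
        )

    if not coding_overlap:
        flag = "utr_dislocation" if _detaches_utr(inversion, transcript) else "none"
        return TranscriptConsequence(
            transcript_id=transcript.transcript_id,
            exons_overlapped=overlapped,
            coding_overlap=False,
            frame_status="non_coding",
            position_effect_flag=flag,  # type: ignore[arg-type]
        )

    # contiguous internal block of fully covered exons -> exon-skipping model
    covered = [i for i in overlapped if inversion.contains(exons[i])]
    contiguous = covered and covered == list(range(covered[0], covered[-1] + 1))
    internal = covered and covered[0] > 0 and covered[-1] < len(exons) - 1
    clean_breakpoints = covered == overlapped  # breakpoints in introns
    if contiguous and internal and clean_breakpoints:
        block_cds = [
            genomic_to_cds(transcript, p)
            for i in covered
            for p in (exons[i].start, exons[i].end)
        ]
        block_cds = [c for c in block_cds if c is not None]
        if block_cds:
            frame, aa = cds_del_to_protein(min(block_cds), max(block_cds))
            return TranscriptConsequence(
                transcript_id=transcript.transcript_id,
                exons_overlapped=overlapped,
                coding_overlap=True,
                frame_status=frame,
                deleted_aa=aa,
                nmd_expected=frame == "frameshift",
            )

    # breakpoint inside coding sequence or partial exon coverage
    return TranscriptConsequence(
        transcript_id=transcript.transcript_id,
        exons_overlapped=overlapped,
        coding_overlap=True,
        frame_status="frameshift",
        nmd_expected=True,
    )


def _detaches_utr(inversion: GenomicInterval, transcript: TranscriptModel) -> bool:
    """True when a breakpoint separates UTR-only exons from the CDS."""
    if not transcript.is_coding:
        return False
    assert transcript.cds_start is not None and transcript.cds_end is not None
    utr_exons = [
        e for e in transcript.exons
        if e.end <= transcript.cds_start or e.start >= transcript.cds_end
    ]
    if not utr_exons:
        return False
    cds_iv = GenomicInterval(transcript.chrom, transcript.cds_start, transcript.cds_end)
    if inversion.overlap_bp(cds_iv) > 0:
        return False
    for bp in (inversion.start, inversion.end):
        if not transcript.span.contains_pos(bp):
            continue
        for e in utr_exons:
            # breakpoint falls between this UTR exon and the CDS
            if e.end <= bp <= transcript.cds_start or transcript.cds_end <= bp <= e.start:
                return True
    return False


def monoallelic_test(
    ref_count: int,
    alt_count: int,
    alpha: float = 0.05,
    min_depth: int = 10,
    pos: int = 0,
) -> AllelicExpression:
    """Allelic-expression verdict at one heterozygous site.

    Exact two-sided binomial test of the alt fraction against 0.5.
    Below ``min_depth`` total reads the verdict is inconclusive; complete
    absence of one allele with a significant test is monoallelic (e.g.
    47 vs 0 reads); a significant skew with both alleles present is reported
    as imbalanced with its p value.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_count + alt_count
    if total < max(min_depth, 1):
        return AllelicExpression(pos, ref_count, alt_count, "inconclusive", None)
    p = binomtest(alt_count, total, 0.5, alternative="two-sided").pvalue
    if p >= alpha:
        verdict: AllelicVerdict = "balanced"
    elif min(ref_count, alt_count) == 0:
        verdict = "monoallelic"
    else:
        verdict = "imbalanced"
    return AllelicExpression(pos, ref_count, alt_count, verdict, float(p))
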