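"""Dot-plot comparison of long reads against a reference window, and
junction-spanning assessment used to resolve ambiguous configurations.

Matching is exact k-mer identity at a configurable word size (default 50,
the setting used for HiFi reads in this pipeline); words containing N are
skipped.  Sense matches fall on diagonals of the read-vs-reference matrix,
matches to the reverse complement (inverted segments) on antidiagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .genome_model import revcomp

__all__ = [
    "DotPlotMatrix",
    "MatchRun",
    "SpanningAssessment",
    "ReadAlignment",
    "dotplot",
    "segment_runs",
    "count_spanning_reads",
]


@dataclass
class DotPlotMatrix:
    wordsize: int
    read_length: int
    ref_length: int
    sense_matches: set[tuple[int, int]] = field(default_factory=set)
    antisense_matches: set[tuple[int, int]] = field(default_factory=set)


@dataclass(frozen=True)
class MatchRun:
    """Maximal collinear run of word matches."""

    orientation: Literal["sense", "antisense"]
    read_start: int
    read_end: int  # offset of the last matching word
    ref_start: int
    ref_end: int

    @property
    def n_words(self) -> int:
        return abs(self.read_end - self.read_start) // 1 + 1


@dataclass(frozen=True)
class ReadAlignment:
    """Reference extent of one (possibly supplementary) alignment segment."""

    read_id: str
    chrom: str
    start: int
    end: int
    group: str | None = None  # supplementary-alignment group


@dataclass
class SpanningAssessment:
    n_spanning_reads: int
    min_flank_bp: int
    spanning_read_ids: list[str] = field(default_factory=list)

    @property
    def spanned(self) -> bool:
        return self.n_spanning_reads > 0


def dotplot(read_seq: str, ref_seq: str, wordsize: int = 50) -> DotPlotMatrix:
    """Exact-word dot plot of a read against a reference window.

    A sense match at ``(i, j)`` means ``read[i:i+w] == ref[j:j+w]``; an
    antisense match means the read word equals the reverse complement of the
    reference word starting at ``j`` (0-based offsets).  Sequences shorter
    than the word size give an empty matrix.
    """
    read_seq, ref_seq = read_seq.upper(), ref_seq.upper()
    w = wordsize
    mat = DotPlotMatrix(w, len(read_seq), len(ref_seq))
    if len(read_seq) < w or len(ref_seq) < w:
        return mat
    index: dict[str, list[int]] = {}
    for j in range(len(ref_seq) - w + 1):
        word = ref_seq[j : j + w]
        if "N" in word:
            continue
        index.setdefault(word, []).append(j)
    for i in range(len(read_seq) - w + 1):
        word = read_seq[i : i + w]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            mat.sense_matches.add((i, j))
        for j in index.get(revcomp(word), ()):
            mat.antisense_matches.add((i, j))
    return mat


def segment_runs(matrix: DotPlotMatrix, gap_words: int = 1) -> list[MatchRun]:
    """Maximal diagonal/antidiagonal runs of matches, ordered by read offset.

    Matches on the same (anti)diagonal belong to one run while consecutive
    read offsets differ by at most ``gap_words * wordsize`` (gap tolerance of
    one word by default).
    """
    max_step = (gap_words + 1) * matrix.wordsize
    runs: list[MatchRun] = []
    # sense: constant j - i
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for i, j in matrix.sense_matches:
        by_diag.setdefault(j - i, []).append((i, j))
    for diag in sorted(by_diag):
        pts = sorted(by_diag[diag])
        start = prev = pts[0]
        for pt in pts[1:]:
            if pt[0] - prev[0] <= max_step:
                prev = pt
            else:
                runs.append(MatchRun("sense", start[0], prev[0], start[1], prev[1]))
                start = prev = pt
        runs.append(MatchRun("sense", start[0], prev[0], start[1], prev[1]))
    # antisense: constant i + j
    by_anti: dict[int, list[tuple[int, int]]] = {}
    for i, j in matrix.antisense_matches:
        by_anti.setdefault(i + j, []).append((i, j))
    for anti in sorted(by_anti):
        pts = sorted(by_anti[anti])
        start = prev = pts[0]
        for pt in pts[1:]:
            if pt[0] - prev[0] <= max_step:
                prev = pt
            else:
                runs.append(MatchRun("antisense", start[0], prev[0], start[1], prev[1]))
                start = prev = pt
        runs.append(MatchRun("antisense", start[0], prev[0], start[1], prev[1]))
    runs.sort(key=lambda r: (r.read_start, r.read_end, r.ref_start))
    return _merge_colinear(runs, max_step)


def _merge_colinear(runs: list[MatchRun], max_step: int) -> list[MatchRun]:
    """Merge runs that continue each other on the same (anti)diagonal."""
    merged: list[MatchRun] = []
    for run in runs:
        if merged:
            last = merged[-1]
            same_diag = (
                last.orientation == run.orientation
                and (
                    (run.orientation == "sense" and run.ref_start - run.read_start == last.ref_start - last.read_start)
                    or (run.orientation == "antisense" and run.ref_start + run.read_start == last.ref_start + last.read_start)
                )
            )
            if same_diag and 0 < run.read_start - last.read_end <= max_step:
                merged[-1] = MatchRun(
                    last.orientation, last.read_start, run.read_end,
                    last.ref_start, run.ref_end,
                )
                continue
        merged.append(run)
    return merged


def count_spanning_reads(
    read_alignments: Iterable[ReadAlignment],
    junction,
    min_flank_bp: int = 500,
    attached_dup=None,
) -> SpanningAssessment:
    """Count reads whose aligned extent spans a junction.

    A read spans when its merged alignment extents (primary plus linked
    supplementary alignments) cover at least ``min_flank_bp`` beyond the
    junction on both sides, and additionally cover the full attached
    duplicated segment when one is given (the read must anchor in unique
    sequence on both flanks of the duplicated copy to be informative).
    ``junction`` needs ``breakend_1``/``breakend_2`` attributes (see
    :class:`invkit.complex_sv.Junction`).
    """
    by_read: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for aln in read_alignments:
        by_read.setdefault(aln.read_id, {}).setdefault(aln.chrom, []).append(
            (aln.start, aln.end)
        )

    b1, b2 = junction.breakend_1, junction.breakend_2
    required: list[tuple[str, int, int]] = []
    # flank on the retained side of each breakend
    for be in (b1, b2):
        if be.orientation == "left":
            required.append((be.chrom, be.pos - min_flank_bp, be.pos))
        else:
            required.append((be.chrom, be.pos, be.pos + min_flank_bp))
    if attached_dup is not None:
        required.append((attached_dup.chrom, attached_dup.start, attached_dup.end))

    spanning = []
    for read_id, per_chrom in sorted(by_read.items()):
        merged = {
            chrom: _merge_extents(extents) for chrom, extents in per_chrom.items()
        }
        if all(
            any(s <= lo and hi <= e for s, e in merged.get(chrom, []))
            for chrom, lo, hi in required
        ):
            spanning.append(read_id)
    return SpanningAssessment(
        n_spanning_reads=len(spanning),
        min_flank_bp=min_flank_bp,
        spanning_read_ids=spanning,
    )


def _merge_extents(extents: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(extents):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
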