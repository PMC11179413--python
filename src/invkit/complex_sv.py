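"""Interpretation of inversion-containing rearrangements.

A Manta inversion call is rarely the whole story: the same call signature
can arise from a balanced inversion, an inversion with terminal loss, a
deletion with small retained/inverted segments, a duplication-triplication
(DUP-TRP/INV-DUP), interlinked duplications, an insertional translocation,
a multi-chromosome balanced translocation or an inserted mobile element.
This module classifies the local call/depth signature into that taxonomy,
enumerates the derivative-chromosome configurations compatible with the
observed junctions (the source of clinical ambiguity when duplicated
segments cannot be spanned by reads), and reconstructs derivative
chromosomes for a chosen configuration.

Configurations are written as signed segment sequences per derivative
molecule, e.g. ``("A+", "X-", "C+")``.

Junction bookkeeping uses breakend orientation: ``left`` means reference
sequence to the left of the position is retained at the fusion.  A seam
between consecutive signed segments is *reference* when it fuses the left
and right sides of the same position; every other seam must account for an
observed junction.  An unspanned junction flagged imprecise carries a
position tolerance (its confidence interval); the micro-segment between the
two fold-back breakends of a duplication-triplication is modelled as a
"spacer" segment with unconstrained copy number, which is what makes the
classical four-configuration ambiguity of DUP-TRP signatures emerge from
the enumeration rather than being hard-coded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

from .genome_model import Breakend, GenomicInterval, SVCall
from .sv_cohort import reciprocal_overlap

__all__ = [
    "InversionPairInterpretation",
    "Segment",
    "Junction",
    "Configuration",
    "RearrangementStructure",
    "InsertedSequenceEvidence",
    "PhasingResult",
    "pair_inv_calls",
    "classify_structure",
    "enumerate_configurations",
    "validate_configuration",
    "reconstruct_derivatives",
    "phase_sv_by_informative_snps",
    "flag_mobile_element_suspect",
    "resolvable_by_technology",
    "CLASS_LABELS",
]

CLASS_LABELS = (
    "SIMPLE_INV",
    "INV_WITH_LOSS",
    "DEL_WITH_RETAINED_SEGMENTS",
    "DUP_TRP",
    "INTERLINKED_DUP",
    "INSERTIONAL",
    "COMPLEX_TRANSLOCATION",
    "MOBILE_ELEMENT_SUSPECT",
    "UNCLASSIFIED",
)

LOSS_FRACTION_THRESHOLD = 0.10  # simple inversion vs inversion-with-loss
OFFSET_TOLERANCE_BP = 5  # breakend microhomology jitter
MOBILE_ELEMENT_MAX_SPAN = 5_000

#: maximum duplicated-segment size spannable per technology (bp)
TECHNOLOGY_SPAN_LIMITS = {
    "short_read_150": 500,
    "hifi": 20_000,
    "ultralong": 500_000,
}


# ---------------------------------------------------------------------------
# Paired-inversion interpretation
# ---------------------------------------------------------------------------

@dataclass
class InversionPairInterpretation:
    outer_span: GenomicInterval
    start_offset: int
    end_offset: int
    loss_end: Literal["proximal", "distal", "none"]
    loss_bp: int
    loss_fraction: float


def pair_inv_calls(
    a: SVCall | GenomicInterval,
    b: SVCall | GenomicInterval,
    offset_tolerance: int = OFFSET_TOLERANCE_BP,
) -> InversionPairInterpretation:
    """Interpret the two Manta records typically emitted for one inversion.

    Manta reports an inversion as two overlapping INV records whose start
    (and end) coordinates differ by the number of bases lost at the
    corresponding end.  The outer span is (min start, max end); the side
    with the larger offset is called as a loss when it exceeds the
    breakend-jitter tolerance (default 5 bp).
    """
    iva = a.interval if isinstance(a, SVCall) else a
    ivb = b.interval if isinstance(b, SVCall) else b
    if iva is None or ivb is None:
        raise ValueError("paired interpretation needs interval-bearing calls")
    if iva.chrom != ivb.chrom:
        raise ValueError(f"records on different chromosomes: {iva} vs {ivb}")
    outer = GenomicInterval(iva.chrom, min(iva.start, ivb.start), max(iva.end, ivb.end))
    start_offset = abs(iva.start - ivb.start)
    end_offset = abs(iva.end - ivb.end)
    loss_bp = max(start_offset, end_offset)
    if loss_bp > offset_tolerance:
        loss_end: Literal["proximal", "distal", "none"] = (
            "proximal" if start_offset >= end_offset else "distal"
        )
    else:
        loss_end = "none"
    return InversionPairInterpretation(
        outer_span=outer,
        start_offset=start_offset,
        end_offset=end_offset,
        loss_end=loss_end,
        loss_bp=loss_bp,
        loss_fraction=loss_bp / outer.size() if outer.size() else 0.0,
    )


# ---------------------------------------------------------------------------
# Structure model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """A reference segment of the rearranged region.

    ``copy_number`` counts copies in the haploid derivative genome
    (0 = deleted, 1 = single copy, 2 = duplicated, 3 = triplicated);
    ``None`` marks an unconstrained copy count (used for the tiny
    fold-back spacer whose depth is unmeasurable).  ``foreign`` marks
    inserted non-reference sequence (e.g. a mobile element), which does not
    anchor a derivative molecule.
    """

    label: str
    interval: GenomicInterval
    copy_number: int | None = 1
    orientation: Literal["+", "-", "unknown"] = "unknown"
    spacer: bool = False
    foreign: bool = False

    def __post_init__(self) -> None:
        if self.copy_number is not None and self.copy_number < 0:
            raise ValueError(f"{self.label}: negative copy number")


@dataclass(frozen=True)
class Junction:
    """A novel adjacency observed between two breakends."""

    breakend_1: Breakend
    breakend_2: Breakend
    support: int = 0
    spanned: bool = False
    spanned_context: tuple[str, ...] | None = None
    tolerance_bp: int = 0

    def __post_init__(self) -> None:
        if self.support < 0:
            raise ValueError("junction support must be non-negative")

    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.breakend_1, self.breakend_2)


@dataclass(frozen=True)
class Configuration:
    """Signed segment sequences, one per derivative molecule."""

    derivatives: tuple[tuple[str, ...], ...]

    def __str__(self) -> str:
        return " | ".join("".join(d) for d in self.derivatives)


@dataclass
class RearrangementStructure:
    segments: list[Segment]
    junctions: list[Junction]
    class_label: str = "UNCLASSIFIED"
    configurations: list[Configuration] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)

    @property
    def ambiguous(self) -> bool:
        return len(self.configurations) > 1

    def segment(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass
class InsertedSequenceEvidence:
    """Summary of soft-clip/insertion evidence at a putative inversion."""

    clipped_seq_matches_insertion: bool
    spanning_pairs: int = 0
    element_name: str | None = None


# ---------------------------------------------------------------------------
# Signed-sequence plumbing
# ---------------------------------------------------------------------------

def _parse_signed(label: str) -> tuple[str, int]:
    if label.endswith("+"):
        return label[:-1], +1
    if label.endswith("-"):
        return label[:-1], -1
    raise ValueError(f"signed label must end with + or -: {label!r}")


def _signed(label: str, sign: int) -> str:
    return f"{label}{'+' if sign > 0 else '-'}"


def _revcomp_chain(chain: Sequence[str]) -> tuple[str, ...]:
    out = []
    for item in reversed(chain):
        lab, sign = _parse_signed(item)
        out.append(_signed(lab, -sign))
    return tuple(out)


def _trailing_breakend(seg: Segment, sign: int) -> Breakend:
    if sign > 0:
        return Breakend(seg.interval.chrom, seg.interval.end, "left")
    return Breakend(seg.interval.chrom, seg.interval.start, "right")


def _leading_breakend(seg: Segment, sign: int) -> Breakend:
    if sign > 0:
        return Breakend(seg.interval.chrom, seg.interval.start, "right")
    return Breakend(seg.interval.chrom, seg.interval.end, "left")


def _is_reference_seam(b1: Breakend, b2: Breakend) -> bool:
    # fusing the left and right side of one position is plain reference
    return (
        b1.chrom == b2.chrom
        and b1.pos == b2.pos
        and {b1.orientation, b2.orientation} == {"left", "right"}
    )


def _breakend_matches(a: Breakend, b: Breakend, tol: int) -> bool:
    return a.chrom == b.chrom and a.orientation == b.orientation and abs(a.pos - b.pos) <= tol


def _seam_matches_junction(b1: Breakend, b2: Breakend, j: Junction) -> bool:
    j1, j2 = j.breakends()
    t = j.tolerance_bp
    return (_breakend_matches(b1, j1, t) and _breakend_matches(b2, j2, t)) or (
        _breakend_matches(b1, j2, t) and _breakend_matches(b2, j1, t)
    )


def _contains_chain(molecule: Sequence[str], context: Sequence[str]) -> bool:
    mol = tuple(molecule)
    for probe in (tuple(context), _revcomp_chain(context)):
        n = len(probe)
        if any(mol[i : i + n] == probe for i in range(len(mol) - n + 1)):
            return True
    return False


# ---------------------------------------------------------------------------
# Configuration enumeration
# ---------------------------------------------------------------------------

class CombinatorialLimitError(RuntimeError):
    """Raised when a structure has too many segment copies to enumerate."""


def _chrom_key(chrom: str) -> tuple[int, str]:
    tail = chrom.removeprefix("chr")
    return (int(tail), "") if tail.isdigit() else (10**6, tail)


def _anchors(structure: RearrangementStructure) -> tuple[list[str], list[str]]:
    """Leftmost/rightmost (telomere-facing) segment labels per chromosome."""
    by_chrom: dict[str, list[Segment]] = {}
    for s in structure.segments:
        if not s.foreign:
            by_chrom.setdefault(s.interval.chrom, []).append(s)
    lefts, rights = [], []
    for chrom in sorted(by_chrom, key=_chrom_key):
        segs = sorted(by_chrom[chrom], key=lambda s: (s.interval.start, s.interval.end))
        lefts.append(segs[0].label)
        rights.append(segs[-1].label)
    return lefts, rights


def enumerate_configurations(
    structure: RearrangementStructure,
    max_copies: int = 12,
    max_spacer_copies: int = 2,
) -> list[Configuration]:
    """All derivative configurations compatible with the observed junctions.

    Exhaustive depth-first search over signed orderings of segment copies.
    Each derivative molecule runs from the leftmost (telomere-facing)
    segment of a chromosome to some rightmost segment; every seam between
    consecutive segments must either be reference continuity or consume
    exactly one observed junction (position within the junction's
    tolerance, breakend orientations matched).  Copy numbers are respected
    exactly, except spacer segments (``copy_number=None``) which may be
    used 0..``max_spacer_copies`` times.  Junctions flagged ``spanned``
    additionally require their recorded read-spanned segment chain to
    appear in a derivative.  Results are deduplicated up to
    whole-derivative reverse complement and sorted lexicographically.
    """
    segs = {s.label: s for s in structure.segments}
    lefts, rights = _anchors(structure)
    if not lefts:
        raise ValueError("structure has no non-foreign segments")
    required: dict[str, int] = {}
    spacer_limit: dict[str, int] = {}
    for s in structure.segments:
        if s.label in lefts or s.label in rights:
            continue
        if s.copy_number is None or s.spacer:
            spacer_limit[s.label] = max_spacer_copies
        else:
            required[s.label] = s.copy_number
    n_copies = sum(required.values()) + len(lefts) + len(rights)
    if n_copies > max_copies:
        raise CombinatorialLimitError(
            f"{n_copies} segment copies exceeds the enumeration bound of {max_copies}"
        )

    junctions = list(structure.junctions)
    results: set[tuple[tuple[str, ...], ...]] = set()

    def close_allowed(trailing: Breakend, right_label: str, used_j: list[bool]) -> int | None:
        lead = _leading_breakend(segs[right_label], +1)
        if _is_reference_seam(trailing, lead):
            return -1  # reference seam, no junction consumed
        for idx, j in enumerate(junctions):
            if not used_j[idx] and _seam_matches_junction(trailing, lead, j):
                return idx
        return None

    def dfs(
        mol_idx: int,
        current: list[str],
        molecules: list[tuple[str, ...]],
        pool: dict[str, int],
        spacers: dict[str, int],
        rights_left: list[str],
        used_j: list[bool],
    ) -> None:
        if mol_idx == len(lefts):
            if any(v for v in pool.values()):
                return
            if not all(used_j):
                return
            results.add(tuple(molecules))
            return
        if not current:
            current = [_signed(lefts[mol_idx], +1)]
        last_label, last_sign = _parse_signed(current[-1])
        trailing = _trailing_breakend(segs[last_label], last_sign)

        # option 1: close this molecule with an unused right anchor
        for r in list(rights_left):
            kind = close_allowed(trailing, r, used_j)
            if kind is None:
                continue
            if kind >= 0:
                used_j[kind] = True
            rights_left.remove(r)
            molecules.append(tuple(current + [_signed(r, +1)]))
            dfs(mol_idx + 1, [], molecules, pool, spacers, rights_left, used_j)
            molecules.pop()
            rights_left.append(r)
            if kind >= 0:
                used_j[kind] = False

        # option 2: extend with an internal copy
        candidates = [(lab, n) for lab, n in pool.items() if n > 0]
        candidates += [(lab, None) for lab, n in spacers.items() if n > 0]
        for lab, _n in candidates:
            for sign in (+1, -1):
                lead = _leading_breakend(segs[lab], sign)
                if _is_reference_seam(trailing, lead):
                    j_idx = -1
                else:
                    j_idx = None
                    for idx, j in enumerate(junctions):
                        if not used_j[idx] and _seam_matches_junction(trailing, lead, j):
                            j_idx = idx
                            break
                    if j_idx is None:
                        continue
                if j_idx >= 0:
                    used_j[j_idx] = True
                if lab in pool:
                    pool[lab] -= 1
                else:
                    spacers[lab] -= 1
                current.append(_signed(lab, sign))
                dfs(mol_idx, current, molecules, pool, spacers, rights_left, used_j)
                current.pop()
                if lab in pool:
                    pool[lab] += 1
                else:
                    spacers[lab] += 1
                if j_idx >= 0:
                    used_j[j_idx] = False

    dfs(0, [], [], dict(required), dict(spacer_limit), list(rights), [False] * len(junctions))

    configs = []
    for molecules in results:
        cfg = Configuration(derivatives=molecules)
        if _spanned_contexts_ok(cfg, structure):
            configs.append(cfg)
    # canonicalise up to whole-derivative reverse complement and sort
    seen: set[tuple[tuple[str, ...], ...]] = set()
    out = []
    for cfg in sorted(configs, key=lambda c: c.derivatives):
        canon = tuple(sorted(min(d, _revcomp_chain(d)) for d in cfg.derivatives))
        if canon not in seen:
            seen.add(canon)
            out.append(cfg)
    return out


def _spanned_contexts_ok(cfg: Configuration, structure: RearrangementStructure) -> bool:
    for j in structure.junctions:
        if j.spanned and j.spanned_context:
            if not any(_contains_chain(d, j.spanned_context) for d in cfg.derivatives):
                return False
    return True


def validate_configuration(
    configuration: Configuration, structure: RearrangementStructure
) -> bool:
    """Check a configuration against observed junctions and copy numbers.

    Every non-reference seam must consume exactly one observed junction
    (bijectively), segment usage must equal the stated copy numbers
    (spacers excepted) and spanned-junction contexts must be present.
    """
    segs = {s.label: s for s in structure.segments}
    lefts, rights = _anchors(structure)
    used = [False] * len(structure.junctions)
    counts: dict[str, int] = {}
    for derivative in configuration.derivatives:
        if not derivative:
            return False
        for item in derivative:
            lab, _ = _parse_signed(item)
            if lab not in segs:
                return False
            counts[lab] = counts.get(lab, 0) + 1
        for a, b in zip(derivative, derivative[1:]):
            la, sa = _parse_signed(a)
            lb, sb = _parse_signed(b)
            t = _trailing_breakend(segs[la], sa)
            l = _leading_breakend(segs[lb], sb)
            if _is_reference_seam(t, l):
                continue
            for idx, j in enumerate(structure.junctions):
                if not used[idx] and _seam_matches_junction(t, l, j):
                    used[idx] = True
                    break
            else:
                return False
    if not all(used):
        return False
    for s in structure.segments:
        got = counts.get(s.label, 0)
        if s.label in lefts or s.label in rights:
            if got != 1:
                return False
        elif s.copy_number is not None and not s.spacer:
            if got != s.copy_number:
                return False
    return _spanned_contexts_ok(configuration, structure)


# ---------------------------------------------------------------------------
# Derivative reconstruction
# ---------------------------------------------------------------------------

@dataclass
class DerivativePart:
    signed_label: str
    source: GenomicInterval
    der_start: int
    der_end: int


@dataclass
class DerivativeChromosome:
    name: str
    parts: list[DerivativePart]
    disrupted_genes: list[tuple[str, int]]  # (gene symbol, junction position)

    @property
    def length(self) -> int:
        return self.parts[-1].der_end if self.parts else 0


def reconstruct_derivatives(
    configuration: Configuration,
    structure: RearrangementStructure,
    genes: Mapping[str, GenomicInterval] | None = None,
) -> list[DerivativeChromosome]:
    """Build derivative chromosome descriptions for one configuration.

    The configuration is validated against the structure's junctions and
    copy numbers first.  Each derivative lists its ordered signed parts
    with cumulative coordinates; every novel seam falling inside a supplied
    gene span flags that gene as disrupted at that junction.
    """
    if not validate_configuration(configuration, structure):
        raise ValueError(
            f"configuration {configuration} does not satisfy the observed "
            "junctions/copy numbers of the structure"
        )
    segs = {s.label: s for s in structure.segments}
    derivatives = []
    for n, derivative in enumerate(configuration.derivatives, start=1):
        parts: list[DerivativePart] = []
        disrupted: list[tuple[str, int]] = []
        offset = 0
        for i, item in enumerate(derivative):
            lab, sign = _parse_signed(item)
            seg = segs[lab]
            size = seg.interval.size()
            parts.append(DerivativePart(item, seg.interval, offset, offset + size))
            offset += size
            if genes and i + 1 < len(derivative):
                nlab, nsign = _parse_signed(derivative[i + 1])
                t = _trailing_breakend(seg, sign)
                l = _leading_breakend(segs[nlab], nsign)
                if not _is_reference_seam(t, l):
                    for gene, span in genes.items():
                        for be in (t, l):
                            if span.chrom == be.chrom and span.contains_pos(be.pos):
                                disrupted.append((gene, be.pos))
        derivatives.append(
            DerivativeChromosome(name=f"der{n}", parts=parts, disrupted_genes=disrupted)
        )
    return derivatives


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def flag_mobile_element_suspect(
    inv_call: SVCall, evidence: InsertedSequenceEvidence | None
) -> bool:
    """Heuristic flag for inverted mobile-element integrations.

    A short putative inversion (< 5 kb) with no read pair spanning the full
    inverted segment, whose clipped bases match an inserted-sequence model
    better than the reference inversion, is more parsimoniously explained
    as an integrated (inverted) mobile element than as a genuine inversion.
    """
    if evidence is None or inv_call.interval is None:
        return False
    return (
        inv_call.interval.size() < MOBILE_ELEMENT_MAX_SPAN
        and evidence.spanning_pairs == 0
        and evidence.clipped_seq_matches_insertion
    )


def resolvable_by_technology(
    dup_segment_bp: int,
    technology: Literal["short_read_150", "hifi", "ultralong"],
) -> bool:
    """Whether a duplicated segment of this size can be spanned and resolved.

    Span limits: ~500 bp for 150-bp short-read pairs, ~20 kb for HiFi
    long reads, ~500 kb for ultra-long nanopore reads.
    """
    if dup_segment_bp <= 0:
        raise ValueError("duplicated-segment size must be positive")
    return dup_segment_bp < TECHNOLOGY_SPAN_LIMITS[technology]


def classify_structure(
    calls_near_locus: Sequence[SVCall],
    depth_profile: Sequence[tuple[GenomicInterval, int]] | None = None,
    inserted_seq_evidence: InsertedSequenceEvidence | None = None,
    window: GenomicInterval | None = None,
    enumerate_configs: bool = True,
) -> RearrangementStructure:
    """Classify the call/depth signature around a prioritized inversion.

    ``depth_profile`` holds derivative copy numbers per segment (0 deleted,
    1 normal, 2 duplicated, 3 triplicated).  Decision rules are applied in
    order; the first matching class wins:

    a. one or two overlapping INV calls, nothing else, loss fraction below
       10% of the outer span -> SIMPLE_INV (unless inserted-sequence
       evidence marks it a mobile-element suspect);
    b. as (a) with loss fraction >= 10% -> INV_WITH_LOSS;
    c. a DEL call with a retained (copy >= 1) segment strictly inside the
       deleted (copy 0) region -> DEL_WITH_RETAINED_SEGMENTS;
    d. an INV call over a duplicated segment adjacent to a triplicated
       segment -> DUP_TRP;
    e. two or more overlapping INV calls plus two or more non-adjacent
       duplicated segments -> INTERLINKED_DUP;
    f. junctions to a distant locus with a duplicated donor segment and
       copy-neutral acceptor -> INSERTIONAL;
    g. a junction graph connecting two or more chromosomes through three or
       more breakpoints, copy-balanced -> COMPLEX_TRANSLOCATION;
    h. a short unspanned INV with inserted-sequence evidence ->
       MOBILE_ELEMENT_SUSPECT; otherwise UNCLASSIFIED.
    """
    calls = list(calls_near_locus)
    if not calls:
        raise ValueError("no calls to classify")
    depth = list(depth_profile or [])
    inv = [c for c in calls if c.svtype == "INV" and c.interval is not None]
    dels = [c for c in calls if c.svtype == "DEL" and c.interval is not None]
    dups = [c for c in calls if c.svtype == "DUP" and c.interval is not None]
    bnds = [c for c in calls if c.svtype == "BND" and c.breakend is not None]

    dup_segs = [iv for iv, cn in depth if cn == 2]
    trp_segs = [iv for iv, cn in depth if cn >= 3]
    del_segs = [iv for iv, cn in depth if cn == 0]
    retained_segs = [iv for iv, cn in depth if cn >= 1]

    mobile = inv and flag_mobile_element_suspect(inv[0], inserted_seq_evidence)

    structure: RearrangementStructure | None = None

    # (a)/(b): pure paired (or single) inversion
    if (
        not mobile
        and inv
        and len(inv) <= 2
        and not dels and not dups and not bnds
        and not dup_segs and not trp_segs and not del_segs
    ):
        if len(inv) == 2:
            interp = pair_inv_calls(inv[0], inv[1])
        else:
            only = inv[0].interval
            assert only is not None
            interp = InversionPairInterpretation(only, 0, 0, "none", 0, 0.0)
        label = (
            "SIMPLE_INV"
            if interp.loss_fraction < LOSS_FRACTION_THRESHOLD
            else "INV_WITH_LOSS"
        )
        structure = _build_inversion_structure(interp, window)
        structure.class_label = label
        structure.evidence["pair_interpretation"] = interp

    # (c): deletion with retained internal segment(s)
    elif dels and _has_retained_internal(dels, del_segs, retained_segs):
        structure = _build_del_retained_structure(dels[0], del_segs, retained_segs, window)
        structure.class_label = "DEL_WITH_RETAINED_SEGMENTS"

    # (d): duplication-triplication
    elif inv and dup_segs and trp_segs and any(
        _adjacent(d, t) and any(reciprocal_overlap(c.interval, d) > 0.5 for c in inv if c.interval)
        for d in dup_segs
        for t in trp_segs
    ):
        structure = _build_dup_trp_structure(dup_segs, trp_segs, window)
        structure.class_label = "DUP_TRP"

    # (e): interlinked duplications
    elif len(inv) >= 2 and len(dup_segs) >= 2 and _nonadjacent_pairs(dup_segs):
        structure = _build_generic_structure(calls, depth, window)
        structure.class_label = "INTERLINKED_DUP"

    # (f): insertional (duplicated donor, distant acceptor)
    elif bnds and dup_segs and _has_distant_junction(bnds) and not del_segs:
        structure = _build_generic_structure(calls, depth, window)
        structure.class_label = "INSERTIONAL"

    # (g): multi-chromosome balanced translocation
    elif bnds and _junction_graph_complex(bnds):
        structure = _build_generic_structure(calls, depth, window)
        structure.class_label = "COMPLEX_TRANSLOCATION"

    # (h): mobile-element suspect
    elif mobile:
        assert inv[0].interval is not None
        structure = RearrangementStructure(
            segments=[], junctions=[], class_label="MOBILE_ELEMENT_SUSPECT"
        )
        structure.evidence["element"] = (
            inserted_seq_evidence.element_name if inserted_seq_evidence else None
        )

    if structure is None:
        structure = RearrangementStructure(segments=[], junctions=[])

    if enumerate_configs and structure.segments and structure.junctions:
        try:
            structure.configurations = enumerate_configurations(structure)
        except CombinatorialLimitError:
            structure.configurations = []
    return structure


def _adjacent(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and (a.end == b.start or b.end == a.start)


def _nonadjacent_pairs(segs: Sequence[GenomicInterval]) -> bool:
    return any(
        a.chrom == b.chrom and not _adjacent(a, b) and a.overlap_bp(b) == 0
        for a, b in itertools.combinations(segs, 2)
    )


def _has_retained_internal(
    dels: Sequence[SVCall],
    del_segs: Sequence[GenomicInterval],
    retained: Sequence[GenomicInterval],
) -> bool:
    for d in dels:
        assert d.interval is not None
        for r in retained:
            strictly_inside = (
                d.interval.chrom == r.chrom
                and d.interval.start < r.start
                and r.end < d.interval.end
            )
            if strictly_inside and any(d.interval.contains(z) for z in del_segs):
                return True
    return False


def _has_distant_junction(bnds: Sequence[SVCall], min_distance: int = 1_000_000) -> bool:
    for c in bnds:
        assert c.breakend is not None
        mate = c.mate_breakend
        if mate is None:
            continue
        if c.breakend.chrom != mate.chrom or abs(c.breakend.pos - mate.pos) >= min_distance:
            return True
    return False


def _junction_graph_complex(bnds: Sequence[SVCall]) -> bool:
    chroms = set()
    breakpoints = set()
    for c in bnds:
        assert c.breakend is not None
        chroms.add(c.breakend.chrom)
        breakpoints.add((c.breakend.chrom, c.breakend.pos))
        if c.mate_breakend is not None:
            chroms.add(c.mate_breakend.chrom)
            breakpoints.add((c.mate_breakend.chrom, c.mate_breakend.pos))
    return len(chroms) >= 2 and len(breakpoints) >= 3


# -- structure builders ------------------------------------------------------

def _window_for(iv: GenomicInterval, window: GenomicInterval | None, pad: int = 10_000) -> GenomicInterval:
    if window is not None:
        return window
    return GenomicInterval(iv.chrom, max(1, iv.start - pad), iv.end + pad)


def _build_inversion_structure(
    interp: InversionPairInterpretation, window: GenomicInterval | None
) -> RearrangementStructure:
    outer = interp.outer_span
    win = _window_for(outer, window)
    chrom = outer.chrom
    if interp.loss_bp > OFFSET_TOLERANCE_BP and interp.loss_end == "proximal":
        lost = GenomicInterval(chrom, outer.start, outer.start + interp.loss_bp)
        inv_seg = GenomicInterval(chrom, lost.end, outer.end)
        segments = [
            Segment("A", GenomicInterval(chrom, win.start, outer.start)),
            Segment("X", lost, copy_number=0),
            Segment("B", inv_seg, orientation="-"),
            Segment("C", GenomicInterval(chrom, outer.end, win.end)),
        ]
        truth = ("A+", "B-", "C+")
    elif interp.loss_bp > OFFSET_TOLERANCE_BP and interp.loss_end == "distal":
        lost = GenomicInterval(chrom, outer.end - interp.loss_bp, outer.end)
        inv_seg = GenomicInterval(chrom, outer.start, lost.start)
        segments = [
            Segment("A", GenomicInterval(chrom, win.start, outer.start)),
            Segment("B", inv_seg, orientation="-"),
            Segment("X", lost, copy_number=0),
            Segment("C", GenomicInterval(chrom, outer.end, win.end)),
        ]
        truth = ("A+", "B-", "C+")
    else:
        segments = [
            Segment("A", GenomicInterval(chrom, win.start, outer.start)),
            Segment("B", outer, orientation="-"),
            Segment("C", GenomicInterval(chrom, outer.end, win.end)),
        ]
        truth = ("A+", "B-", "C+")
    structure = RearrangementStructure(segments=segments, junctions=[])
    structure.junctions = junctions_from_configuration(
        Configuration((truth,)), structure
    )
    return structure


def _build_del_retained_structure(
    del_call: SVCall,
    del_segs: Sequence[GenomicInterval],
    retained: Sequence[GenomicInterval],
    window: GenomicInterval | None,
) -> RearrangementStructure:
    d = del_call.interval
    assert d is not None
    inner = next(
        r for r in retained if d.chrom == r.chrom and d.start < r.start and r.end < d.end
    )
    win = _window_for(d, window)
    chrom = d.chrom
    segments = [
        Segment("A", GenomicInterval(chrom, win.start, d.start)),
        Segment("P", GenomicInterval(chrom, d.start, inner.start), copy_number=0),
        Segment("X", inner, copy_number=1, orientation="-"),
        Segment("Q", GenomicInterval(chrom, inner.end, d.end), copy_number=0),
        Segment("C", GenomicInterval(chrom, d.end, win.end)),
    ]
    structure = RearrangementStructure(segments=segments, junctions=[])
    structure.junctions = junctions_from_configuration(
        Configuration((("A+", "X-", "C+"),)), structure
    )
    return structure


def _build_dup_trp_structure(
    dup_segs: Sequence[GenomicInterval],
    trp_segs: Sequence[GenomicInterval],
    window: GenomicInterval | None,
    spacer_bp: int = 50,
) -> RearrangementStructure:
    """Canonical dup-trp model: dup flank D, triplicated T, fold-back spacer S.

    The fold-back junction at the distal end of the triplication is
    imprecise; the micro-segment between its two breakend estimates is the
    spacer whose retention/orientation short reads cannot resolve.
    """
    dup = next(d for d in dup_segs if any(_adjacent(d, t) for t in trp_segs))
    trp = next(t for t in trp_segs if _adjacent(dup, t))
    chrom = dup.chrom
    lo = min(dup.start, trp.start)
    hi = max(dup.end, trp.end)
    win = _window_for(GenomicInterval(chrom, lo, hi), window)
    spacer = GenomicInterval(chrom, hi, hi + spacer_bp)
    segments = [
        Segment("L", GenomicInterval(chrom, win.start, lo)),
        Segment("D", dup, copy_number=2),
        Segment("T", trp, copy_number=3),
        Segment("S", spacer, copy_number=None, spacer=True),
        Segment("R", GenomicInterval(chrom, spacer.end, max(win.end, spacer.end + 1))),
    ]
    junctions = [
        Junction(  # fold-back at the distal end of the triplication
            Breakend(chrom, hi, "left"),
            Breakend(chrom, spacer.end, "left"),
        ),
        Junction(  # tail-to-tail junction joining dup 5' to trp 5'
            Breakend(chrom, dup.start, "right"),
            Breakend(chrom, trp.start, "right"),
        ),
    ]
    return RearrangementStructure(segments=segments, junctions=junctions)


def _build_generic_structure(
    calls: Sequence[SVCall],
    depth: Sequence[tuple[GenomicInterval, int]],
    window: GenomicInterval | None,
) -> RearrangementStructure:
    """Partition each involved chromosome at breakend positions.

    Copy numbers come from the depth profile (default 1).  Junctions come
    from BND mate pairs.
    """
    positions: dict[str, set[int]] = {}
    junctions: list[Junction] = []
    seen_pairs = set()
    for c in calls:
        if c.svtype == "BND" and c.breakend is not None and c.mate_breakend is not None:
            be, mate = c.breakend, c.mate_breakend
            key = tuple(sorted([(be.chrom, be.pos, be.orientation), (mate.chrom, mate.pos, mate.orientation)]))
            positions.setdefault(be.chrom, set()).add(be.pos)
            positions.setdefault(mate.chrom, set()).add(mate.pos)
            if key not in seen_pairs:
                seen_pairs.add(key)
                junctions.append(Junction(be, mate, support=c.pair_support))
    for iv, _cn in depth:
        positions.setdefault(iv.chrom, set()).update((iv.start, iv.end))

    segments: list[Segment] = []
    label_iter = iter(_label_names())
    for chrom in sorted(positions):
        pos = sorted(positions[chrom])
        lo = max(1, pos[0] - 10_000) if window is None else window.start
        hi = pos[-1] + 10_000
        bounds = [lo] + pos + [hi]
        for s, e in zip(bounds, bounds[1:]):
            if e <= s:
                continue
            iv = GenomicInterval(chrom, s, e)
            cn = 1
            for div, dcn in depth:
                if div.chrom == chrom and div.overlap_bp(iv) >= iv.size():
                    cn = dcn
                    break
            segments.append(Segment(next(label_iter), iv, copy_number=cn))
    return RearrangementStructure(segments=segments, junctions=junctions)


def _label_names() -> Iterable[str]:
    import string

    for letter in string.ascii_uppercase:
        yield letter
    for a, b in itertools.product(string.ascii_uppercase, repeat=2):
        yield a + b


def junctions_from_configuration(
    configuration: Configuration, structure: RearrangementStructure
) -> list[Junction]:
    """Novel junctions implied by a configuration (truth -> observation)."""
    segs = {s.label: s for s in structure.segments}
    out: list[Junction] = []
    for derivative in configuration.derivatives:
        for a, b in zip(derivative, derivative[1:]):
            la, sa = _parse_signed(a)
            lb, sb = _parse_signed(b)
            t = _trailing_breakend(segs[la], sa)
            l = _leading_breakend(segs[lb], sb)
            if not _is_reference_seam(t, l):
                out.append(Junction(t, l))
    return out


# ---------------------------------------------------------------------------
# Phasing by informative SNPs
# ---------------------------------------------------------------------------

@dataclass
class PhasingResult:
    origin: Literal["maternal", "paternal", "undetermined"]
    votes_maternal: int
    votes_paternal: int
    conflict: bool


def phase_sv_by_informative_snps(
    junction_read_alleles: Mapping[int, str],
    trio_genotypes: Mapping[int, tuple[Sequence[str], Sequence[str], Sequence[str]]],
) -> PhasingResult:
    """Parental origin of a de novo SV from SNPs on junction-supporting reads.

    ``junction_read_alleles`` maps SNP position to the allele observed on
    reads that support the SV junction; ``trio_genotypes`` maps position to
    (proband, mother, father) allele pairs.  A SNP is informative when the
    proband is heterozygous and the observed allele can be uniquely
    attributed to one parent.  The origin is returned when at least one
    informative SNP votes and no votes conflict.
    """
    votes_m = votes_p = 0
    for pos, allele in sorted(junction_read_alleles.items()):
        trio = trio_genotypes.get(pos)
        if trio is None:
            continue
        proband, mother, father = (set(g) for g in trio)
        if len(proband) != 2 or allele not in proband:
            continue  # not heterozygous in the proband, or inconsistent read
        in_m, in_f = allele in mother, allele in father
        if in_m and not in_f:
            votes_m += 1
        elif in_f and not in_m:
            votes_p += 1
    conflict = votes_m > 0 and votes_p > 0
    if conflict or (votes_m == 0 and votes_p == 0):
        return PhasingResult("undetermined", votes_m, votes_p, conflict)
    return PhasingResult(
        "maternal" if votes_m else "paternal", votes_m, votes_p, False
    )
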