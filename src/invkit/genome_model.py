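"""Core coordinate conventions, domain types and file readers.

Coordinates are stored 1-based as printed in clinical reports.  The size of a
segment is defined as ``end - start`` (the convention under which the segment
sizes quoted for large clinical inversions are exactly reproducible, e.g.
37,035,341 - 6,352,714 = 30,682,627).  Interval arithmetic throughout the
package (overlap, containment) therefore treats an interval as the half-open
set of inter-base positions ``[start, end)``.

Chromosome names are normalised to the ``chr``-prefixed GRCh38 style on read.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import pysam

__all__ = [
    "GenomicInterval",
    "Breakend",
    "SVCall",
    "TranscriptModel",
    "GeneRegion",
    "interval_size",
    "read_sv_vcf",
    "write_sv_vcf",
    "normalize_bnd_inversion",
    "read_gene_models",
    "read_fasta",
    "revcomp",
]

SVType = Literal["INV", "DEL", "DUP", "INS", "BND"]
Genotype = Literal["het", "hom", "unknown"]
Orientation = Literal["left", "right"]  # which side of pos is retained


class InvalidIntervalError(ValueError):
    """Raised for intervals with end < start or non-positive coordinates."""


def normalize_chrom(chrom: str) -> str:
    chrom = chrom.strip()
    if not chrom:
        raise ValueError("empty chromosome name")
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based genomic interval with ``size = end - start``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1 or self.end < 1:
            raise InvalidIntervalError(
                f"positions must be positive: {self.chrom}:{self.start}-{self.end}"
            )
        if self.end < self.start:
            raise InvalidIntervalError(
                f"end < start: {self.chrom}:{self.start}-{self.end}"
            )

    def size(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and self.end >= other.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __str__(self) -> str:  # chr2:47,406,871-47,425,914
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


def interval_size(iv: GenomicInterval) -> int:
    """Segment size in bp under the ``end - start`` convention."""
    return iv.size()


@dataclass(frozen=True)
class Breakend:
    """One side of a novel adjacency.

    ``orientation`` records which side of ``pos`` is retained in the
    derivative chromosome: ``"left"`` means reference sequence to the left of
    ``pos`` joins the partner; ``"right"`` means sequence to the right does.
    """

    chrom: str
    pos: int
    orientation: Orientation

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.orientation not in ("left", "right"):
            raise ValueError(f"orientation must be left/right, got {self.orientation}")


@dataclass
class SVCall:
    """One Manta-style SV record, keyed to a family and carrier sample."""

    call_id: str
    family_id: str
    sample_id: str
    svtype: SVType
    interval: GenomicInterval | None = None
    breakend: Breakend | None = None
    mate_breakend: Breakend | None = None
    mate_id: str | None = None
    pair_support: int = 0
    split_support: int = 0
    genotype: Genotype = "unknown"
    imprecise: bool = False
    unpaired: bool = False

    def __post_init__(self) -> None:
        if self.pair_support < 0 or self.split_support < 0:
            raise ValueError("read support counts must be non-negative")
        if self.svtype == "BND":
            if self.breakend is None:
                raise ValueError(f"{self.call_id}: BND call requires a breakend")
        elif self.interval is None:
            raise ValueError(f"{self.call_id}: non-BND call requires an interval")

    @property
    def chrom(self) -> str:
        if self.interval is not None:
            return self.interval.chrom
        assert self.breakend is not None
        return self.breakend.chrom


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    Exons are ordered by genomic position and must not overlap; the CDS span
    ``[cds_start, cds_end]`` (genomic, strand-independent) must fall inside
    the exon union.  A transcript with no CDS (non-coding) has
    ``cds_start = cds_end = None``.
    """

    gene_symbol: str
    transcript_id: str
    strand: Literal["+", "-"]
    exons: tuple[GenomicInterval, ...]
    cds_start: int | None = None
    cds_end: int | None = None
    canonical: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"{self.transcript_id}: exons on multiple chromosomes")
        ordered = sorted(self.exons, key=lambda e: e.start)
        object.__setattr__(self, "exons", tuple(ordered))
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {a} and {b}"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            assert self.cds_end is not None
            if self.cds_end < self.cds_start:
                raise ValueError(f"{self.transcript_id}: cds_end < cds_start")
            for pos in (self.cds_start, self.cds_end):
                if not any(e.start <= pos <= e.end for e in ordered):
                    raise ValueError(
                        f"{self.transcript_id}: CDS bound {pos} outside exons"
                    )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def coding_exons(self) -> list[GenomicInterval]:
        """Exons clipped to the CDS span (empty for non-coding transcripts)."""
        if self.cds_start is None or self.cds_end is None:
            return []
        out = []
        for e in self.exons:
            s, t = max(e.start, self.cds_start), min(e.end, self.cds_end)
            if t > s:
                out.append(GenomicInterval(e.chrom, s, t))
        return out


@dataclass(frozen=True)
class GeneRegion:
    """All transcripts of one gene; span = min exon start to max exon end."""

    gene_symbol: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_symbol}: gene needs >=1 transcript")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end)


# ---------------------------------------------------------------------------
# VCF reading / writing (Manta dialect)
# ---------------------------------------------------------------------------

_BND_ALT_RE = re.compile(
    r"^([ACGTNacgtn]*)([\[\]])([^\[\]:]+):(\d+)([\[\]])([ACGTNacgtn]*)$"
)


def _parse_bnd_alt(pos_chrom: str, pos: int, alt: str) -> tuple[Breakend, Breakend] | None:
    """Local and mate breakends from a VCF breakend ALT string.

    ``t[p[`` / ``t]p]`` keep the sequence left of the local position;
    ``]p]t`` / ``[p[t`` keep the right.  A ``]`` bracket means the mate keeps
    its left side, ``[`` its right.
    """
    m = _BND_ALT_RE.match(alt)
    if m is None:
        return None
    leading, b1, mate_chrom, mate_pos, b2, trailing = m.groups()
    if b1 != b2:
        return None
    local_orient: Orientation = "left" if leading else "right"
    mate_orient: Orientation = "left" if b1 == "]" else "right"
    return (
        Breakend(pos_chrom, pos, local_orient),
        Breakend(mate_chrom, int(mate_pos), mate_orient),
    )


def _genotype_from_gt(gt: tuple | None) -> Genotype:
    if gt is None:
        return "unknown"
    alleles = [a for a in gt if a is not None]
    if not alleles or all(a == 0 for a in alleles):
        return "unknown"
    if len(alleles) >= 2 and all(a >= 1 for a in alleles):
        return "hom"
    return "het"


def _support_from_format(sample, key: str) -> int:
    # Manta PR/SR are (ref, alt) tuples; missing field -> 0 (conservative).
    val = sample.get(key) if sample is not None else None
    if val is None:
        return 0
    if isinstance(val, (tuple, list)):
        return int(val[-1]) if val and val[-1] is not None else 0
    return int(val)


def read_sv_vcf(path: str, family_id: str) -> list[SVCall]:
    """Read a Manta-dialect SV VCF into :class:`SVCall` records.

    One call is emitted per (record, carrier sample); in a single-sample VCF
    without genotypes, one call per record attributed to the first sample (or
    the family id when the VCF has no sample columns).  BND mates are linked
    via MATEID; records without SVTYPE are skipped with a warning.
    """
    calls: list[SVCall] = []
    by_id: dict[str, list[SVCall]] = {}
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                warnings.warn(f"{path}: record {rec.id or rec.pos} lacks SVTYPE; skipped")
                continue
            svtype = str(svtype)
            rec_id = rec.id or f"{rec.chrom}_{rec.pos}_{svtype}"
            imprecise = bool(rec.info.get("IMPRECISE", False))
            mate_id = rec.info.get("MATEID")
            if isinstance(mate_id, (tuple, list)):
                mate_id = mate_id[0]

            interval = None
            breakend = mate_bnd = None
            if svtype == "BND":
                alt = rec.alts[0] if rec.alts else ""
                parsed = _parse_bnd_alt(rec.chrom, rec.pos, alt)
                if parsed is None:
                    warnings.warn(f"{path}: unparseable BND ALT {alt!r}; skipped")
                    continue
                breakend, mate_bnd = parsed
            else:
                interval = GenomicInterval(rec.chrom, rec.pos, int(rec.stop))

            def emit(sample_id: str, gt: Genotype, pr: int, sr: int, suffix: str = ""):
                calls.append(
                    SVCall(
                        call_id=rec_id + suffix,
                        family_id=family_id,
                        sample_id=sample_id,
                        svtype=svtype,  # type: ignore[arg-type]
                        interval=interval,
                        breakend=breakend,
                        mate_breakend=mate_bnd,
                        mate_id=str(mate_id) if mate_id else None,
                        pair_support=pr,
                        split_support=sr,
                        genotype=gt,
                        imprecise=imprecise,
                    )
                )
                by_id.setdefault(rec_id, []).append(calls[-1])

            if not samples:
                emit(family_id, "unknown", 0, 0)
                continue
            any_carrier = False
            for sample_id in samples:
                sample = rec.samples[sample_id]
                gt = _genotype_from_gt(sample.get("GT"))
                if gt == "unknown" and sample.get("GT") is not None and len(samples) > 1:
                    continue  # explicitly non-carrier in a multi-sample VCF
                any_carrier = True
                emit(
                    sample_id,
                    gt,
                    _support_from_format(sample, "PR"),
                    _support_from_format(sample, "SR"),
                    suffix=f"__{sample_id}" if len(samples) > 1 else "",
                )
            if not any_carrier:
                # keep the record visible (site-only evidence)
                emit(samples[0], "unknown", 0, 0)

    # link BND mates; flag unresolved ones
    for call in calls:
        if call.svtype != "BND":
            continue
        if call.mate_id is None or call.mate_id not in by_id:
            call.unpaired = True
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="Difference in length between REF and ALT alleles">
##INFO=<ID=MATEID,Number=.,Type=String,Description="ID of mate breakend">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise structural variation">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PR,Number=.,Type=Integer,Description="Spanning paired-read support (ref,alt)">
##FORMAT=<ID=SR,Number=.,Type=Integer,Description="Split-read support (ref,alt)">
"""


def write_sv_vcf(
    path: str,
    calls: Sequence[SVCall],
    samples: Sequence[str] | None = None,
    contigs: Sequence[tuple[str, int]] | None = None,
) -> None:
    """Write a minimal Manta-dialect VCF covering the fields the pipeline reads.

    Calls sharing a ``call_id`` (same record carried by several samples) are
    merged into one multi-sample row.  ``read_sv_vcf(write_sv_vcf(x))`` is the
    identity on the consumed fields.
    """
    if samples is None:
        samples = sorted({c.sample_id for c in calls})
    by_record: dict[str, list[SVCall]] = {}
    order: list[str] = []
    for c in calls:
        if c.call_id not in by_record:
            order.append(c.call_id)
        by_record.setdefault(c.call_id, []).append(c)

    def sort_key(rec_id: str):
        c = by_record[rec_id][0]
        pos = c.interval.start if c.interval else c.breakend.pos  # type: ignore[union-attr]
        return (c.chrom, pos, rec_id)

    lines = [_VCF_HEADER.rstrip("\n")]
    if contigs:
        for name, length in contigs:
            lines.append(f"##contig=<ID={normalize_chrom(name)},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))

    gt_str = {"het": "0/1", "hom": "1/1", "unknown": "./."}
    for rec_id in sorted(order, key=sort_key):
        group = by_record[rec_id]
        c0 = group[0]
        if c0.svtype == "BND":
            be, mate = c0.breakend, c0.mate_breakend
            assert be is not None and mate is not None
            bracket = "]" if mate.orientation == "left" else "["
            inner = f"{bracket}{mate.chrom}:{mate.pos}{bracket}"
            alt = f"N{inner}" if be.orientation == "left" else f"{inner}N"
            chrom, pos = be.chrom, be.pos
            info = ["SVTYPE=BND"]
            if c0.mate_id:
                info.append(f"MATEID={c0.mate_id}")
        else:
            assert c0.interval is not None
            chrom, pos = c0.interval.chrom, c0.interval.start
            alt = f"<{c0.svtype}>"
            svlen = c0.interval.size()
            if c0.svtype == "DEL":
                svlen = -svlen
            info = [f"SVTYPE={c0.svtype}", f"END={c0.interval.end}", f"SVLEN={svlen}"]
        if c0.imprecise:
            info.append("IMPRECISE")
        per_sample = {c.sample_id: c for c in group}
        cols = []
        for s in samples:
            c = per_sample.get(s)
            if c is None:
                cols.append("0/0:0,0:0,0")
            else:
                cols.append(
                    f"{gt_str[c.genotype]}:0,{c.pair_support}:0,{c.split_support}"
                )
        lines.append(
            "\t".join(
                [chrom, str(pos), rec_id, "N", alt, ".", "PASS",
                 ";".join(info), "GT:PR:SR"] + cols
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def normalize_bnd_inversion(bnd_calls: Iterable[SVCall]) -> list[SVCall]:
    """Collapse mate-linked BND pairs with inverted orientation into INV calls.

    Newer Manta emits an inversion as two reciprocal same-orientation breakend
    junctions (a head-head and a tail-tail pair).  Each same-chromosome mate
    pair whose two breakends retain the *same* side is rewritten as an INV
    record spanning min/max of the two positions; everything else (deletion- or
    duplication-type junctions, inter-chromosomal pairs, unpaired breakends)
    passes through unchanged.  Breakend positions are preserved exactly.
    """
    out: list[SVCall] = []
    for call in list(bnd_calls):
        if call.svtype != "BND" or call.breakend is None or call.mate_breakend is None:
            out.append(call)
            continue
        be, mate = call.breakend, call.mate_breakend
        if be.chrom != mate.chrom or be.orientation != mate.orientation:
            out.append(call)
            continue
        lo, hi = sorted((be.pos, mate.pos))
        if hi == lo:
            hi = lo + 1
        out.append(
            replace(
                call,
                svtype="INV",
                interval=GenomicInterval(be.chrom, lo, hi),
                breakend=None,
                mate_breakend=None,
                mate_id=None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str) -> list[GeneRegion]:
    """Read gene models from BED12 or the tabular exon/CDS format.

    Tabular format (TSV, ``#``-comments allowed)::

        gene  transcript  chrom  strand  exon_starts  exon_ends  cds_start  cds_end  canonical

    ``exon_starts``/``exon_ends`` are comma-separated 1-based coordinates;
    ``cds_start``/``cds_end`` may be ``.`` for non-coding transcripts.  BED12
    is detected by column count (12) and an integer in column 2; the BED name
    column holds ``gene|transcript``; thickStart==thickEnd marks non-coding.
    """
    transcripts: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 12 and fields[1].isdigit():
                    transcripts.append(_transcript_from_bed12(fields))
                elif len(fields) == 9:
                    transcripts.append(_transcript_from_table(fields))
                else:
                    raise ValueError(f"expected 9 (tabular) or 12 (BED12) columns, got {len(fields)}")
            except (ValueError, InvalidIntervalError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_symbol, []).append(t)
    return [GeneRegion(g, tuple(ts)) for g, ts in by_gene.items()]


def _transcript_from_table(fields: list[str]) -> TranscriptModel:
    gene, tx, chrom, strand, starts_s, ends_s, cds_s, cds_e, canonical = fields
    starts = [int(x) for x in starts_s.strip(",").split(",")]
    ends = [int(x) for x in ends_s.strip(",").split(",")]
    if len(starts) != len(ends):
        raise ValueError("exon_starts and exon_ends differ in length")
    exons = tuple(GenomicInterval(chrom, s, e) for s, e in zip(starts, ends))
    return TranscriptModel(
        gene_symbol=gene,
        transcript_id=tx,
        strand=strand,  # type: ignore[arg-type]
        exons=exons,
        cds_start=None if cds_s in (".", "") else int(cds_s),
        cds_end=None if cds_e in (".", "") else int(cds_e),
        canonical=canonical.lower() in ("1", "true", "yes"),
    )


def _transcript_from_bed12(fields: list[str]) -> TranscriptModel:
    chrom, chrom_start, _chrom_end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5]
    thick_start, thick_end = int(fields[6]), int(fields[7])
    count = int(fields[9])
    sizes = [int(x) for x in fields[10].strip(",").split(",")[:count]]
    offsets = [int(x) for x in fields[11].strip(",").split(",")[:count]]
    gene, _, tx = name.partition("|")
    exons = tuple(
        GenomicInterval(chrom, chrom_start + off + 1, chrom_start + off + size)
        for off, size in zip(offsets, sizes)
    )
    coding = thick_end > thick_start
    return TranscriptModel(
        gene_symbol=gene,
        transcript_id=tx or name,
        strand=strand,  # type: ignore[arg-type]
        exons=exons,
        cds_start=thick_start + 1 if coding else None,
        cds_end=thick_end if coding else None,
    )


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_fasta(path: str) -> dict[str, str]:
    """Plain FASTA reader returning {name: sequence} (uppercased)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs
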