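"""Synthetic cohorts with planted truth for every pipeline stage.

Real national-cohort SV data are access-controlled, so all testing runs on
generated inputs: a multi-family cohort of Manta-style calls containing
common polymorphic inversions and ultra-rare planted pathogenic events of
every structural class; trio genotypes around planted founder haplotypes
with binomial read-depth noise; exponential ancestral-haplotype lengths for
age-estimator recovery; and sequences rebuilt from derivative
configurations for dot plots.  Every generator is a pure function of its
parameters and seed, and written VCF output is byte-identical across runs.

The toy genome (three chromosomes of 15-30 Mb) stands in for GRCh38; all
coordinates are self-consistent within a run.  Sequencing error is not
simulated: the pipeline's claims concern interpretation of calls, not
calling.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .complex_sv import (
    Configuration,
    InsertedSequenceEvidence,
    Junction,
    RearrangementStructure,
    Segment,
    junctions_from_configuration,
)
from .genome_model import (
    Breakend,
    GeneRegion,
    GenomicInterval,
    SVCall,
    TranscriptModel,
    revcomp,
    write_sv_vcf,
)
from .founder_haplotype import SampleObservation, VariantSite
from .hi_prioritizer import Pedigree

__all__ = [
    "CohortSimParams",
    "PlantedEvent",
    "TruthTable",
    "SimulatedCohort",
    "SimulatedFounderPair",
    "simulate_cohort",
    "simulate_founder_pair",
    "simulate_ancestral_lengths",
    "simulate_read_from_configuration",
    "random_sequence",
    "PLANTABLE_CLASSES",
]

PLANTABLE_CLASSES = (
    "SIMPLE_INV",
    "INV_WITH_LOSS",
    "DEL_WITH_RETAINED_SEGMENTS",
    "DUP_TRP",
    "INTERLINKED_DUP",
    "INSERTIONAL",
    "COMPLEX_TRANSLOCATION",
    "MOBILE_ELEMENT_SUSPECT",
)

_DEFAULT_GENOME = (("chr1", 30_000_000), ("chr2", 20_000_000), ("chr3", 15_000_000))


@dataclass
class CohortSimParams:
    """Study conditions for a synthetic cohort run."""

    seed: int
    n_families: int = 50
    n_common_polymorphic_inversions: int = 5
    common_af_range: tuple[float, float] = (0.1, 0.3)
    n_planted_pathogenic: int = 1
    planted_classes: tuple[str, ...] = ("SIMPLE_INV",)
    genome: tuple[tuple[str, int], ...] = _DEFAULT_GENOME
    n_genes: int = 30
    n_hi_genes: int = 15
    pair_support: int = 10

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_common_polymorphic_inversions < 0:
            raise ValueError("counts must be non-negative (>=1 family)")
        for cls in self.planted_classes:
            if cls not in PLANTABLE_CLASSES:
                raise ValueError(f"unknown planted class {cls!r}")
        if len(self.planted_classes) < self.n_planted_pathogenic:
            raise ValueError("need one class per planted event")
        if self.n_planted_pathogenic > self.n_families:
            raise ValueError("planted events are one per family")
        if self.n_planted_pathogenic > self.n_hi_genes:
            raise ValueError("planted events need distinct HI genes")


@dataclass
class PlantedEvent:
    """Ground truth for one planted pathogenic rearrangement."""

    event_id: str
    family_id: str
    class_label: str
    gene: str
    inheritance: Literal["de_novo", "maternal", "paternal"]
    calls: list[SVCall]
    depth_profile: list[tuple[GenomicInterval, int]]
    structure: RearrangementStructure
    truth_configuration: Configuration
    evidence: InsertedSequenceEvidence | None = None


@dataclass
class TruthTable:
    events: list[PlantedEvent]

    def by_id(self, event_id: str) -> PlantedEvent:
        for e in self.events:
            if e.event_id == event_id:
                return e
        raise KeyError(event_id)


@dataclass
class SimulatedCohort:
    params: CohortSimParams
    families: list[Pedigree]
    calls_by_family: dict[str, list[SVCall]]
    gene_models: list[GeneRegion]
    hi_symbols: list[str]
    truth: TruthTable

    def all_calls(self) -> list[SVCall]:
        return [c for fam in sorted(self.calls_by_family) for c in self.calls_by_family[fam]]

    def write(self, outdir: str) -> str:
        """Write VCFs, gene table, HI list, manifest and truth; returns manifest path."""
        os.makedirs(outdir, exist_ok=True)
        contigs = list(self.params.genome)
        manifest_rows = []
        for ped in self.families:
            vcf_path = os.path.join(outdir, f"{ped.family_id}.vcf")
            samples = [ped.proband]
            if ped.mother:
                samples.append(ped.mother)
            if ped.father:
                samples.append(ped.father)
            write_sv_vcf(vcf_path, self.calls_by_family.get(ped.family_id, []),
                         samples=samples, contigs=contigs)
            # manifest stores paths relative to its own directory so that
            # the written tree is relocatable and byte-reproducible
            manifest_rows.append(
                f"{ped.family_id}\t{ped.family_id}.vcf\t{ped.proband}\t"
                f"{ped.mother or '-'}\t{ped.father or '-'}"
            )
        genes_path = os.path.join(outdir, "genes.tsv")
        with open(genes_path, "w") as fh:
            fh.write(_gene_table(self.gene_models))
        hi_path = os.path.join(outdir, "hi_genes.tsv")
        with open(hi_path, "w") as fh:
            fh.write("symbol\tchrom\tstart\tend\n")
            by_symbol = {g.gene_symbol: g for g in self.gene_models}
            for sym in self.hi_symbols:
                span = by_symbol[sym].span
                fh.write(f"{sym}\t{span.chrom}\t{span.start}\t{span.end}\n")
        depth_path = os.path.join(outdir, "depth.tsv")
        with open(depth_path, "w") as fh:
            fh.write("#family_id\tchrom\tstart\tend\tcopy_number\n")
            for e in self.truth.events:
                for iv, cn in e.depth_profile:
                    fh.write(f"{e.family_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{cn}\n")
        truth_path = os.path.join(outdir, "truth.json")
        with open(truth_path, "w") as fh:
            json.dump(
                [
                    {
                        "event_id": e.event_id,
                        "family_id": e.family_id,
                        "class": e.class_label,
                        "gene": e.gene,
                        "inheritance": e.inheritance,
                        "configuration": [list(d) for d in e.truth_configuration.derivatives],
                    }
                    for e in self.truth.events
                ],
                fh,
                indent=1,
            )
        manifest_path = os.path.join(outdir, "manifest.tsv")
        with open(manifest_path, "w") as fh:
            fh.write("\n".join(manifest_rows) + "\n")
        return manifest_path


def _gene_table(genes: Sequence[GeneRegion]) -> str:
    lines = ["#gene\ttranscript\tchrom\tstrand\texon_starts\texon_ends\tcds_start\tcds_end\tcanonical"]
    for g in genes:
        for t in g.transcripts:
            starts = ",".join(str(e.start) for e in t.exons)
            ends = ",".join(str(e.end) for e in t.exons)
            lines.append(
                "\t".join(
                    [g.gene_symbol, t.transcript_id, t.chrom, t.strand, starts, ends,
                     str(t.cds_start or "."), str(t.cds_end or "."),
                     "1" if t.canonical else "0"]
                )
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Gene model generation
# ---------------------------------------------------------------------------

def _make_genes(params: CohortSimParams) -> tuple[list[GeneRegion], list[str]]:
    """Deterministically placed 10-exon genes; the first n_hi_genes are HI."""
    genes = []
    n_per_chrom = -(-params.n_genes // len(params.genome))  # ceil
    idx = 0
    for chrom, length in params.genome:
        spacing = length // (n_per_chrom + 1)
        for k in range(n_per_chrom):
            if idx >= params.n_genes:
                break
            start = spacing * (k + 1)
            exons = []
            pos = start
            for _ in range(10):
                exons.append(GenomicInterval(chrom, pos, pos + 150))
                pos += 150 + 2000
            symbol = f"G{idx + 1:03d}"
            tx = TranscriptModel(
                gene_symbol=symbol,
                transcript_id=f"{symbol}.t1",
                strand="+",
                exons=tuple(exons),
                cds_start=exons[1].start,  # exon 1 is 5' UTR
                cds_end=exons[-1].start + 75,
                canonical=True,
            )
            genes.append(GeneRegion(symbol, (tx,)))
            idx += 1
    hi = [g.gene_symbol for g in genes[: params.n_hi_genes]]
    return genes, hi


# ---------------------------------------------------------------------------
# Planted pathogenic events
# ---------------------------------------------------------------------------

def _trio(family_id: str) -> Pedigree:
    return Pedigree(family_id, f"{family_id}_p", f"{family_id}_m", f"{family_id}_f")


def _carriers(ped: Pedigree, inheritance: str) -> list[str]:
    carriers = [ped.proband]
    if inheritance == "maternal":
        carriers.append(ped.mother)  # type: ignore[arg-type]
    elif inheritance == "paternal":
        carriers.append(ped.father)  # type: ignore[arg-type]
    return carriers


def _mk_calls(
    records: Sequence[tuple[str, SVCall]],
    carriers: Sequence[str],
) -> list[SVCall]:
    """Replicate template records across carrier samples (shared call ids)."""
    out = []
    for _rid, template in records:
        for sample in carriers:
            out.append(dataclasses.replace(template, sample_id=sample))
    return out


def _plant_event(
    cls: str,
    event_id: str,
    ped: Pedigree,
    gene: GeneRegion,
    genome: Mapping[str, int],
    rng: np.random.Generator,
    pair_support: int,
) -> PlantedEvent:
    inheritance = rng.choice(["de_novo", "maternal", "paternal"], p=[0.6, 0.2, 0.2])
    carriers = _carriers(ped, str(inheritance))
    builder = _EVENT_BUILDERS[cls]
    records, depth, structure, truth_cfg, evidence = builder(
        event_id, ped.family_id, gene, genome, rng, pair_support
    )
    calls = _mk_calls(records, carriers)
    return PlantedEvent(
        event_id=event_id,
        family_id=ped.family_id,
        class_label=cls,
        gene=gene.gene_symbol,
        inheritance=str(inheritance),  # type: ignore[arg-type]
        calls=calls,
        depth_profile=depth,
        structure=structure,
        truth_configuration=truth_cfg,
        evidence=evidence,
    )


def _inv_template(event_id: str, fam: str, iv: GenomicInterval, n: int, pr: int) -> tuple[str, SVCall]:
    rid = f"{event_id}:INV{n}"
    return rid, SVCall(
        call_id=rid, family_id=fam, sample_id="", svtype="INV",
        interval=iv, pair_support=pr, split_support=pr, genotype="het",
    )


def _intron_point(gene: GeneRegion, intron_idx: int, rng: np.random.Generator) -> int:
    """A position inside intron ``intron_idx`` (between exons idx and idx+1)."""
    exons = gene.transcripts[0].exons
    lo, hi = exons[intron_idx].end + 10, exons[intron_idx + 1].start - 10
    return int(rng.integers(lo, hi))


def _build_simple_inv(event_id, fam, gene, genome, rng, pr, loss_fraction=0.0):
    chrom = gene.chrom
    start = _intron_point(gene, 1, rng)
    end = _intron_point(gene, 6, rng)
    outer = GenomicInterval(chrom, start, end)
    jitter_s = int(rng.integers(0, 21))
    jitter_e = int(rng.integers(0, 21))
    if loss_fraction > 0:
        jitter_s = max(jitter_s, int(outer.size() * loss_fraction))
    a = GenomicInterval(chrom, start, end - jitter_e)
    b = GenomicInterval(chrom, start + jitter_s, end)
    records = [
        _inv_template(event_id, fam, a, 1, pr),
        _inv_template(event_id, fam, b, 2, pr),
    ]
    win = GenomicInterval(chrom, max(1, start - 10_000), end + 10_000)
    if jitter_s > 5:
        lost = GenomicInterval(chrom, start, start + jitter_s)
        segments = [
            Segment("A", GenomicInterval(chrom, win.start, start)),
            Segment("X", lost, copy_number=0),
            Segment("B", GenomicInterval(chrom, lost.end, end), orientation="-"),
            Segment("C", GenomicInterval(chrom, end, win.end)),
        ]
    else:
        segments = [
            Segment("A", GenomicInterval(chrom, win.start, start)),
            Segment("B", outer, orientation="-"),
            Segment("C", GenomicInterval(chrom, end, win.end)),
        ]
    truth = Configuration((("A+", "B-", "C+"),))
    structure = RearrangementStructure(segments=segments, junctions=[])
    structure.junctions = junctions_from_configuration(truth, structure)
    return records, [], structure, truth, None


def _build_inv_with_loss(event_id, fam, gene, genome, rng, pr):
    frac = float(rng.uniform(0.12, 0.25))
    return _build_simple_inv(event_id, fam, gene, genome, rng, pr, loss_fraction=frac)


def _build_del_retained(event_id, fam, gene, genome, rng, pr):
    chrom = gene.chrom
    d1 = _intron_point(gene, 2, rng)
    d2 = _intron_point(gene, 7, rng)
    x1 = d1 + 25
    x2 = x1 + int(rng.integers(80, 120))  # ~94 bp retained segment
    del_iv = GenomicInterval(chrom, d1, d2)
    inv_iv = GenomicInterval(chrom, x1, d2)  # Manta footprint: retained start to del end
    rid = f"{event_id}:DEL1"
    del_call = SVCall(call_id=rid, family_id=fam, sample_id="", svtype="DEL",
                      interval=del_iv, pair_support=pr, genotype="het")
    records = [
        (rid, del_call),
        _inv_template(event_id, fam, inv_iv, 1, pr),
    ]
    depth = [
        (GenomicInterval(chrom, d1, x1), 0),
        (GenomicInterval(chrom, x1, x2), 1),
        (GenomicInterval(chrom, x2, d2), 0),
    ]
    win = GenomicInterval(chrom, max(1, d1 - 10_000), d2 + 10_000)
    segments = [
        Segment("A", GenomicInterval(chrom, win.start, d1)),
        Segment("P", GenomicInterval(chrom, d1, x1), copy_number=0),
        Segment("X", GenomicInterval(chrom, x1, x2), copy_number=1, orientation="-"),
        Segment("Q", GenomicInterval(chrom, x2, d2), copy_number=0),
        Segment("C", GenomicInterval(chrom, d2, win.end)),
    ]
    truth = Configuration((("A+", "X-", "C+"),))
    structure = RearrangementStructure(segments=segments, junctions=[])
    structure.junctions = junctions_from_configuration(truth, structure)
    return records, depth, structure, truth, None


def _build_dup_trp(event_id, fam, gene, genome, rng, pr, spacer_bp=50):
    chrom = gene.chrom
    p0 = _intron_point(gene, 2, rng)
    p1 = _intron_point(gene, 5, rng)
    p2 = _intron_point(gene, 8, rng)
    dup = GenomicInterval(chrom, p0, p1)
    trp = GenomicInterval(chrom, p1, p2)
    spacer = GenomicInterval(chrom, p2, p2 + spacer_bp)
    records = [
        _inv_template(event_id, fam, dup, 1, pr),  # Manta INV over the dup flank
        (f"{event_id}:DUP1", SVCall(
            call_id=f"{event_id}:DUP1", family_id=fam, sample_id="", svtype="DUP",
            interval=GenomicInterval(chrom, p0, p2), pair_support=pr, genotype="het")),
    ]
    depth = [(dup, 2), (trp, 3)]
    win = GenomicInterval(chrom, max(1, p0 - 10_000), spacer.end + 10_000)
    segments = [
        Segment("L", GenomicInterval(chrom, win.start, p0)),
        Segment("D", dup, copy_number=2),
        Segment("T", trp, copy_number=3),
        Segment("S", spacer, copy_number=None, spacer=True),
        Segment("R", GenomicInterval(chrom, spacer.end, win.end)),
    ]
    junctions = [
        Junction(Breakend(chrom, p2, "left"), Breakend(chrom, spacer.end, "left")),
        Junction(Breakend(chrom, dup.start, "right"), Breakend(chrom, trp.start, "right")),
    ]
    truth = Configuration((("L+", "D+", "T+", "S-", "T-", "D-", "T+", "S+", "R+"),))
    structure = RearrangementStructure(segments=segments, junctions=junctions)
    return records, depth, structure, truth, None


def _build_interlinked_dup(event_id, fam, gene, genome, rng, pr):
    chrom = gene.chrom
    a1 = _intron_point(gene, 0, rng)
    a2 = _intron_point(gene, 2, rng)
    b1 = _intron_point(gene, 3, rng)
    b2 = _intron_point(gene, 5, rng)
    c1 = _intron_point(gene, 6, rng)
    c2 = _intron_point(gene, 8, rng)
    win = GenomicInterval(chrom, max(1, a1 - 10_000), c2 + 10_000)
    segments = [
        Segment("L", GenomicInterval(chrom, win.start, a1)),
        Segment("A", GenomicInterval(chrom, a1, a2), copy_number=2),
        Segment("g", GenomicInterval(chrom, a2, b1)),
        Segment("B", GenomicInterval(chrom, b1, b2), copy_number=2),
        Segment("h", GenomicInterval(chrom, b2, c1)),
        Segment("C", GenomicInterval(chrom, c1, c2), copy_number=2),
        Segment("R", GenomicInterval(chrom, c2, win.end)),
    ]
    truth = Configuration(
        (("L+", "A+", "g+", "B+", "B-", "A-", "h+", "C+", "C-", "R+"),)
    )
    structure = RearrangementStructure(segments=segments, junctions=[])
    structure.junctions = junctions_from_configuration(truth, structure)
    # Manta footprint: two overlapping INV calls + duplications + junction BNDs
    records = [
        _inv_template(event_id, fam, GenomicInterval(chrom, a1, b2), 1, pr),
        _inv_template(event_id, fam, GenomicInterval(chrom, b1, c2), 2, pr),
    ]
    for n, seg in enumerate(("A", "B", "C"), start=1):
        iv = structure.segment(seg).interval
        rid = f"{event_id}:DUP{n}"
        records.append((rid, SVCall(
            call_id=rid, family_id=fam, sample_id="", svtype="DUP",
            interval=iv, pair_support=pr, genotype="het")))
    records.extend(_bnd_records(event_id, fam, structure.junctions, pr))
    depth = [(structure.segment(s).interval, 2) for s in ("A", "B", "C")]
    return records, depth, structure, truth, None


def _build_insertional(event_id, fam, gene, genome, rng, pr):
    chrom = gene.chrom
    p = _intron_point(gene, 4, rng)
    donor_chrom = next(c for c in genome if c != chrom)
    q1 = int(genome[donor_chrom] * 0.4)
    q2 = q1 + 14_500
    win = GenomicInterval(chrom, max(1, gene.span.start - 10_000), gene.span.end + 10_000)
    dwin = GenomicInterval(donor_chrom, q1 - 30_000, q2 + 30_000)
    segments = [
        Segment("A1", GenomicInterval(chrom, win.start, p)),
        Segment("A2", GenomicInterval(chrom, p, win.end)),
        Segment("B1", GenomicInterval(donor_chrom, dwin.start, q1)),
        Segment("Bseg", GenomicInterval(donor_chrom, q1, q2), copy_number=2),
        Segment("B2", GenomicInterval(donor_chrom, q2, dwin.end)),
    ]
    junctions = [
        Junction(Breakend(chrom, p, "left"), Breakend(donor_chrom, q1, "right"),
                 support=pr),
        Junction(Breakend(donor_chrom, q2, "left"), Breakend(chrom, p, "right"),
                 support=pr),
    ]
    truth = Configuration((("A1+", "Bseg+", "A2+"), ("B1+", "Bseg+", "B2+")))
    structure = RearrangementStructure(segments=segments, junctions=junctions)
    # Manta footprint: small INV artifact at the acceptor + donor DUP + BNDs
    exons = gene.transcripts[0].exons
    small_inv = GenomicInterval(chrom, exons[4].start - 40, exons[4].end + 40)
    records = [_inv_template(event_id, fam, small_inv, 1, pr)]
    rid = f"{event_id}:DUP1"
    records.append((rid, SVCall(
        call_id=rid, family_id=fam, sample_id="", svtype="DUP",
        interval=GenomicInterval(donor_chrom, q1, q2), pair_support=pr, genotype="het")))
    records.extend(_bnd_records(event_id, fam, junctions, pr))
    depth = [(GenomicInterval(donor_chrom, q1, q2), 2)]
    return records, depth, structure, truth, None


def _build_complex_translocation(event_id, fam, gene, genome, rng, pr):
    chrom = gene.chrom
    other = next(c for c in genome if c != chrom)
    pa = [_intron_point(gene, i, rng) for i in (1, 4, 7)]
    base = int(genome[other] * 0.5)
    pb = [base, base + 200_000]
    win_a = GenomicInterval(chrom, max(1, pa[0] - 10_000), pa[-1] + 10_000)
    win_b = GenomicInterval(other, pb[0] - 10_000, pb[-1] + 10_000)
    segments = [
        Segment("L1", GenomicInterval(chrom, win_a.start, pa[0])),
        Segment("A", GenomicInterval(chrom, pa[0], pa[1])),
        Segment("B", GenomicInterval(chrom, pa[1], pa[2])),
        Segment("R1", GenomicInterval(chrom, pa[2], win_a.end)),
        Segment("L2", GenomicInterval(other, win_b.start, pb[0])),
        Segment("X", GenomicInterval(other, pb[0], pb[1])),
        Segment("R2", GenomicInterval(other, pb[1], win_b.end)),
    ]
    truth = Configuration(
        (("L1+", "B-", "X-", "R1+"), ("L2+", "A-", "R2+"))
    )
    structure = RearrangementStructure(segments=segments, junctions=[])
    structure.junctions = junctions_from_configuration(truth, structure)
    records = [
        _inv_template(event_id, fam, GenomicInterval(chrom, pa[1], pa[2]), 1, pr),
    ]
    records.extend(_bnd_records(event_id, fam, structure.junctions, pr))
    return records, [], structure, truth, None


def _build_mobile_element(event_id, fam, gene, genome, rng, pr):
    chrom = gene.chrom
    exons = gene.transcripts[0].exons
    # Manta footprint: ~300-bp INV spanning an exon edge, no spanning pairs
    start = exons[6].end - 60
    iv = GenomicInterval(chrom, start, start + 300)
    records = [_inv_template(event_id, fam, iv, 1, pr)]
    evidence = InsertedSequenceEvidence(
        clipped_seq_matches_insertion=True, spanning_pairs=0, element_name="AluSc"
    )
    insert_at = start
    win = GenomicInterval(chrom, max(1, insert_at - 10_000), insert_at + 10_000)
    segments = [
        Segment("A", GenomicInterval(chrom, win.start, insert_at)),
        Segment("ALU", GenomicInterval("chrALU", 1, 301), foreign=True),
        Segment("C", GenomicInterval(chrom, insert_at, win.end)),
    ]
    truth = Configuration((("A+", "ALU-", "C+"),))
    structure = RearrangementStructure(segments=segments, junctions=[])
    structure.junctions = junctions_from_configuration(truth, structure)
    return records, [], structure, truth, evidence


def _bnd_records(event_id, fam, junctions: Sequence[Junction], pr) -> list[tuple[str, SVCall]]:
    out = []
    for n, j in enumerate(junctions, start=1):
        rid_a, rid_b = f"{event_id}:BND{n}a", f"{event_id}:BND{n}b"
        out.append((rid_a, SVCall(
            call_id=rid_a, family_id=fam, sample_id="", svtype="BND",
            breakend=j.breakend_1, mate_breakend=j.breakend_2, mate_id=rid_b,
            pair_support=pr, genotype="het")))
        out.append((rid_b, SVCall(
            call_id=rid_b, family_id=fam, sample_id="", svtype="BND",
            breakend=j.breakend_2, mate_breakend=j.breakend_1, mate_id=rid_a,
            pair_support=pr, genotype="het")))
    return out


_EVENT_BUILDERS = {
    "SIMPLE_INV": _build_simple_inv,
    "INV_WITH_LOSS": _build_inv_with_loss,
    "DEL_WITH_RETAINED_SEGMENTS": _build_del_retained,
    "DUP_TRP": _build_dup_trp,
    "INTERLINKED_DUP": _build_interlinked_dup,
    "INSERTIONAL": _build_insertional,
    "COMPLEX_TRANSLOCATION": _build_complex_translocation,
    "MOBILE_ELEMENT_SUSPECT": _build_mobile_element,
}


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(params: CohortSimParams) -> SimulatedCohort:
    """Generate a multi-family cohort with planted truth.

    Common polymorphic inversions are placed where benign inversions live
    (intergenic space or wholly within one intron, spanning no coding
    exon), at allele frequencies drawn from ``common_af_range``; carriers
    follow binomial sampling per sample.  Planted pathogenic events are
    emitted as the Manta record pattern of their class in one trio family
    each, consistent with the assigned inheritance mode.
    """
    rng = np.random.default_rng(params.seed)
    genome = dict(params.genome)
    genes, hi_symbols = _make_genes(params)
    families = [_trio(f"FAM{k + 1:03d}") for k in range(params.n_families)]
    calls_by_family: dict[str, list[SVCall]] = {p.family_id: [] for p in families}

    # ---- planted pathogenic events, one per family, in distinct HI genes
    events: list[PlantedEvent] = []
    by_symbol = {g.gene_symbol: g for g in genes}
    target_families = list(rng.choice(len(families), size=params.n_planted_pathogenic, replace=False))
    target_genes = list(rng.choice(params.n_hi_genes, size=params.n_planted_pathogenic, replace=False))
    for k in range(params.n_planted_pathogenic):
        cls = params.planted_classes[k]
        ped = families[int(target_families[k])]
        gene = by_symbol[hi_symbols[int(target_genes[k])]]
        event = _plant_event(cls, f"EV{k + 1:02d}", ped, gene, genome, rng, params.pair_support)
        events.append(event)
        calls_by_family[ped.family_id].extend(event.calls)

    # ---- common polymorphic inversions (benign placement)
    lo_af, hi_af = params.common_af_range
    for k in range(params.n_common_polymorphic_inversions):
        af = float(rng.uniform(lo_af, hi_af))
        # placement alternates between an HI-gene intron (non exon-spanning)
        # and intergenic space — both are benign under the disruption rules
        if k % 2 == 0 and params.n_hi_genes:
            host = by_symbol[hi_symbols[k % params.n_hi_genes]]
            exons = host.transcripts[0].exons
            intron = 2 + (k % 5)
            lo = exons[intron].end + 20
            hi = exons[intron + 1].start - 20
            iv = GenomicInterval(host.chrom, lo, hi)
        else:
            chrom, length = params.genome[k % len(params.genome)]
            pos = int(length * 0.92) + k * 5_000
            iv = GenomicInterval(chrom, pos, pos + 3_000 + k * 100)
        for ped in families:
            for sample in (ped.proband, ped.mother, ped.father):
                n_alleles = int(rng.binomial(2, af))
                if n_alleles == 0 or sample is None:
                    continue
                rid = f"COMMON{k + 1:02d}:{ped.family_id}"
                calls_by_family[ped.family_id].append(SVCall(
                    call_id=rid, family_id=ped.family_id, sample_id=sample,
                    svtype="INV", interval=iv, pair_support=8, split_support=8,
                    genotype="hom" if n_alleles == 2 else "het",
                ))
    return SimulatedCohort(
        params=params,
        families=families,
        calls_by_family=calls_by_family,
        gene_models=genes,
        hi_symbols=hi_symbols,
        truth=TruthTable(events),
    )


# ---------------------------------------------------------------------------
# Founder pair simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedFounderPair:
    sites: list[VariantSite]
    carriers: tuple[str, str]
    target: int
    truth_left_flank: int | None
    truth_right_flank: int | None
    cohort_af: dict[int, float]
    shared_rare_positions: list[int]


def simulate_founder_pair(
    region_bp: int = 20_000_000,
    shared_len_bp: int = 3_200_000,
    site_spacing_bp: int = 10_000,
    depth: int = 30,
    seed: int = 0,
    n_shared_rare: int = 13,
    chrom: str = "chr2",
) -> SimulatedFounderPair:
    """Two unrelated carriers sharing one haplotype around a target locus.

    Inside the planted interval (centred on the target) both samples share
    one haplotype, so conflicting homozygosity cannot occur there; the
    nearest site on each side outside the interval is forced to a
    hom-ref/hom-alt conflict so the scan's truth flanks are exact.
    Genotypes elsewhere are drawn independently from per-site allele
    frequencies; allelic depths are binomial in the genotype fraction.
    ``n_shared_rare`` ultra-rare SNVs (cohort AF 5e-4) are planted on the
    shared haplotype.  With ``shared_len_bp >= region_bp`` the whole region
    is shared and there are no flanks.
    """
    if shared_len_bp > region_bp:
        raise ValueError("shared segment cannot exceed the region")
    rng = np.random.default_rng(seed)
    a, b = "S1", "S2"
    target = region_bp // 2
    sh_lo = target - shared_len_bp // 2
    sh_hi = target + shared_len_bp // 2
    positions = list(range(site_spacing_bp, region_bp, site_spacing_bp))
    inside = [p for p in positions if sh_lo <= p <= sh_hi]
    left_out = [p for p in positions if p < sh_lo]
    right_out = [p for p in positions if p > sh_hi]
    flank_l = left_out[-1] if left_out else None
    flank_r = right_out[0] if right_out else None

    rare_positions: list[int] = []
    candidates = [p for p in inside if p != target]
    if candidates and n_shared_rare:
        take = min(n_shared_rare, len(candidates))
        rare_positions = sorted(
            int(p) for p in rng.choice(candidates, size=take, replace=False)
        )

    sites: list[VariantSite] = []
    cohort_af: dict[int, float] = {}

    def obs(genotype: str) -> SampleObservation:
        frac = {"hom_ref": 0.0, "het": 0.5, "hom_alt": 1.0}[genotype]
        alt = int(rng.binomial(depth, frac)) if depth > 0 else 0
        ref = depth - alt
        return SampleObservation(ref_reads=ref, alt_reads=alt, genotype=genotype)  # type: ignore[arg-type]

    def gt_from_alleles(a1: int, a2: int) -> str:
        n = a1 + a2
        return ("hom_ref", "het", "hom_alt")[n]

    for pos in positions:
        af = float(rng.uniform(0.05, 0.95))
        cohort_af[pos] = af
        if pos in rare_positions:
            cohort_af[pos] = 5e-4
            site = VariantSite(chrom, pos, "A", "G")
            site.samples[a] = obs("het")
            site.samples[b] = obs("het")
            sites.append(site)
            continue
        if pos == flank_l or pos == flank_r:
            site = VariantSite(chrom, pos, "A", "C")
            site.samples[a] = obs("hom_ref")
            site.samples[b] = obs("hom_alt")
            sites.append(site)
            continue
        if sh_lo <= pos <= sh_hi:
            h = int(rng.random() < af)  # shared haplotype allele
            ga = gt_from_alleles(h, int(rng.random() < af))
            gb = gt_from_alleles(h, int(rng.random() < af))
        else:
            ga = gt_from_alleles(int(rng.random() < af), int(rng.random() < af))
            gb = gt_from_alleles(int(rng.random() < af), int(rng.random() < af))
        site = VariantSite(chrom, pos, "A", "C")
        site.samples[a] = obs(ga)
        site.samples[b] = obs(gb)
        sites.append(site)

    return SimulatedFounderPair(
        sites=sites,
        carriers=(a, b),
        target=target,
        truth_left_flank=flank_l,
        truth_right_flank=flank_r,
        cohort_af=cohort_af,
        shared_rare_positions=rare_positions,
    )


# ---------------------------------------------------------------------------
# Ancestral lengths and configuration reads
# ---------------------------------------------------------------------------

def simulate_ancestral_lengths(tau: float, n_lengths: int, seed: int = 0) -> np.ndarray:
    """i.i.d. Exponential(rate 2*tau) one-sided shared lengths (Morgans)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    return rng.exponential(scale=1.0 / (2.0 * tau), size=n_lengths)


def random_sequence(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_read_from_configuration(
    configuration: Configuration,
    segments: Mapping[str, GenomicInterval] | RearrangementStructure,
    ref_seqs: Mapping[str, str],
    derivative_index: int = 0,
    read_span: tuple[int, int] | None = None,
) -> str:
    """Error-free read along one derivative of a configuration.

    Concatenates reference pieces per the signed segment sequence (reverse
    complementing minus-orientation parts).  ``read_span`` optionally slices
    a window (0-based, derivative coordinates); a span beyond the
    derivative's extent raises.
    """
    if isinstance(segments, RearrangementStructure):
        seg_map = {s.label: s.interval for s in segments.segments}
    else:
        seg_map = dict(segments)
    derivative = configuration.derivatives[derivative_index]
    parts = []
    for item in derivative:
        label, sign = item[:-1], item[-1]
        iv = seg_map[label]
        seq = ref_seqs[iv.chrom][iv.start - 1 : iv.end - 1]
        parts.append(seq if sign == "+" else revcomp(seq))
    full = "".join(parts)
    if read_span is None:
        return full
    lo, hi = read_span
    if lo < 0 or hi > len(full) or lo >= hi:
        raise ValueError(f"read span {read_span} outside derivative of length {len(full)}")
    return full[lo:hi]
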