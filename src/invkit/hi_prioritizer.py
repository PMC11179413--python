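"""Haploinsufficiency-gene disruption rules and inheritance annotation.

Rare inversion clusters are kept when they plausibly disrupt a gene for
which haploinsufficiency (HI) is an established disease mechanism:

* at least one breakpoint must lie within the gene region (min exon start
  to max exon end over transcripts);
* when both breakpoints lie inside the same gene, the call must span at
  least one coding exon (an inversion confined to one intron rearranges
  nothing that matters);
* large inversions that contain an HI gene but leave it fully intact are
  deprioritized (the gene is moved, not broken).

Inheritance is annotated from family structure when relatives were
sequenced: de novo requires both parents assayed and non-carrying.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_model import GeneRegion, GenomicInterval, SVCall, normalize_chrom, read_sv_vcf, normalize_bnd_inversion, read_gene_models
from .sv_cohort import (
    CohortFilterParams,
    SVCluster,
    cluster_svs,
    filter_ultra_rare_inversions,
)

__all__ = [
    "HIGeneSet",
    "DisruptionAssessment",
    "InheritanceCall",
    "Pedigree",
    "assess_disruption",
    "infer_inheritance",
    "prioritize",
    "read_hi_list",
    "read_manifest",
]

Verdict = Literal[
    "PRIORITIZED",
    "DEPRIORITIZED_INTACT",
    "REJECTED_NO_CODING_EXON",
    "REJECTED_NO_BREAKPOINT",
]
InheritanceMode = Literal[
    "de_novo", "maternal", "paternal", "inherited_unphased", "unknown"
]


@dataclass
class HIGeneSet:
    """The curated HI gene list restricted to genes with models available."""

    entries: list[GeneRegion]
    source_label: str = "HI_list"

    def __post_init__(self) -> None:
        symbols = [g.gene_symbol for g in self.entries]
        if len(symbols) != len(set(symbols)):
            raise ValueError("HI gene symbols must be unique")

    def overlap_tree(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for gene in self.entries:
            span = gene.span
            trees.setdefault(span.chrom, IntervalTree()).addi(
                span.start, span.end, gene
            )
        return trees


@dataclass
class DisruptionAssessment:
    sv: SVCluster
    gene_symbol: str
    verdict: Verdict
    breakpoints_in_gene: int
    spans_coding_exon: bool


@dataclass
class InheritanceCall:
    mode: InheritanceMode
    carrier_parents: tuple[str, ...] = ()


@dataclass
class Pedigree:
    """Proband-centric trio/partial-trio structure for one family."""

    family_id: str
    proband: str
    mother: str | None = None
    father: str | None = None


def assess_disruption(sv: SVCluster, gene: GeneRegion) -> DisruptionAssessment:
    """Apply the breakpoint/coding-exon disruption rules to one (SV, gene).

    Uses the cluster's representative interval endpoints as the breakpoint
    estimates.  Rules in order: zero breakpoints inside the gene region
    means either a fully contained intact gene (deprioritized) or no
    contact (rejected); exactly one breakpoint inside always prioritizes;
    both inside prioritize only when the call overlaps at least one
    CDS-clipped exon of some transcript.
    """
    iv = sv.representative
    span = gene.span
    bps_inside = 0
    if iv.chrom == span.chrom:
        bps_inside = sum(1 for p in (iv.start, iv.end) if span.contains_pos(p))
    coding = [ce for t in gene.transcripts for ce in t.coding_exons()]
    spans_coding = any(iv.overlap_bp(ce) > 0 for ce in coding)

    if bps_inside == 0:
        if iv.chrom == span.chrom and iv.contains(span):
            verdict: Verdict = "DEPRIORITIZED_INTACT"
        else:
            verdict = "REJECTED_NO_BREAKPOINT"
    elif bps_inside == 1:
        verdict = "PRIORITIZED"
    else:
        verdict = "PRIORITIZED" if spans_coding else "REJECTED_NO_CODING_EXON"
    return DisruptionAssessment(
        sv=sv,
        gene_symbol=gene.gene_symbol,
        verdict=verdict,
        breakpoints_in_gene=bps_inside,
        spans_coding_exon=spans_coding,
    )


def infer_inheritance(cluster: SVCluster, pedigree: Pedigree) -> InheritanceCall:
    """Mode of inheritance of a cluster's variant within one family.

    Parent carrier status is read off the cluster membership: a parent
    carries the variant when one of the cluster's member calls belongs to
    that sample.  De novo is only assignable with both parents assayed.
    """
    carriers = {m.sample_id for m in cluster.members if m.family_id == pedigree.family_id}
    mother, father = pedigree.mother, pedigree.father
    if mother is None or father is None:
        known = [p for p in (mother, father) if p is not None]
        if known and known[0] in carriers:
            mode: InheritanceMode = "maternal" if known[0] == mother else "paternal"
            return InheritanceCall(mode, (known[0],))
        return InheritanceCall("unknown")
    in_m, in_f = mother in carriers, father in carriers
    if in_m and in_f:
        return InheritanceCall("inherited_unphased", (mother, father))
    if in_m:
        return InheritanceCall("maternal", (mother,))
    if in_f:
        return InheritanceCall("paternal", (father,))
    return InheritanceCall("de_novo")


# ---------------------------------------------------------------------------
# End-to-end prioritization
# ---------------------------------------------------------------------------

def read_manifest(path: str) -> list[tuple[Pedigree, str]]:
    """Manifest TSV: family_id, vcf_path, proband, mother, father ('-' = absent).

    Relative VCF paths are resolved against the manifest's directory.
    """
    import os

    base = os.path.dirname(os.path.abspath(path))
    out: list[tuple[Pedigree, str]] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            family_id, vcf_path, proband = row[0], row[1], row[2]
            if not os.path.isabs(vcf_path):
                vcf_path = os.path.join(base, vcf_path)
            mother = row[3] if len(row) > 3 and row[3] not in ("-", "") else None
            father = row[4] if len(row) > 4 and row[4] not in ("-", "") else None
            out.append((Pedigree(family_id, proband, mother, father), vcf_path))
    return out


def read_hi_list(path: str, gene_models: Sequence[GeneRegion]) -> HIGeneSet:
    """HI list TSV (symbol, chrom, start, end) joined to available gene models."""
    by_symbol = {g.gene_symbol: g for g in gene_models}
    entries = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "symbol":
                continue
            symbol = row[0]
            if symbol in by_symbol:
                entries.append(by_symbol[symbol])
    return HIGeneSet(entries=entries, source_label=path)


def prioritize(
    manifest: Sequence[tuple[Pedigree, str]] | str,
    gene_models: Sequence[GeneRegion] | str,
    hi_list: HIGeneSet | str,
    params: CohortFilterParams | None = None,
) -> pd.DataFrame:
    """Aggregate, filter and assess: the end-to-end prioritization report.

    Composition: read per-family VCFs -> normalise breakend-encoded
    inversions -> cluster cohort-wide -> retain ultra-rare supported INV
    clusters -> apply disruption rules against the HI gene set -> annotate
    inheritance.  One row per (cluster, gene) with verdict PRIORITIZED,
    sorted by allele count, then size, then (chrom, start) for determinism.
    """
    params = params or CohortFilterParams()
    if isinstance(manifest, str):
        manifest = read_manifest(manifest)
    if isinstance(gene_models, str):
        gene_models = read_gene_models(gene_models)
    if isinstance(hi_list, str):
        hi_list = read_hi_list(hi_list, gene_models)

    calls: list[SVCall] = []
    pedigrees: dict[str, Pedigree] = {}
    for pedigree, vcf_path in manifest:
        pedigrees[pedigree.family_id] = pedigree
        try:
            family_calls = read_sv_vcf(vcf_path, pedigree.family_id)
        except OSError as exc:
            raise OSError(f"manifest entry {pedigree.family_id}: {exc}") from exc
        calls.extend(normalize_bnd_inversion(family_calls))

    clusters = cluster_svs(calls, params)
    rare = filter_ultra_rare_inversions(clusters, params)
    trees = hi_list.overlap_tree()

    rows = []
    for cl in rare:
        iv = cl.representative
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = {h.data.gene_symbol: h.data for h in tree.overlap(iv.start, iv.end)}
        # one breakpoint inside a gene also counts when the call dwarfs it
        for gene in sorted(hits.values(), key=lambda g: g.gene_symbol):
            assessment = assess_disruption(cl, gene)
            if assessment.verdict != "PRIORITIZED":
                continue
            for family_id in sorted(cl.families):
                pedigree = pedigrees.get(family_id)
                inheritance = (
                    infer_inheritance(cl, pedigree)
                    if pedigree is not None
                    else InheritanceCall("unknown")
                )
                rows.append(
                    {
                        "cluster_id": cl.cluster_id,
                        "gene": gene.gene_symbol,
                        "family_id": family_id,
                        "chrom": iv.chrom,
                        "start": iv.start,
                        "end": iv.end,
                        "size_bp": iv.size(),
                        "allele_count": cl.allele_count,
                        "n_families": len(cl.families),
                        "breakpoints_in_gene": assessment.breakpoints_in_gene,
                        "spans_coding_exon": assessment.spans_coding_exon,
                        "inheritance": inheritance.mode,
                        "max_pair_support": cl.max_pair_support(),
                    }
                )
    report = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "gene", "family_id", "chrom", "start", "end",
            "size_bp", "allele_count", "n_families", "breakpoints_in_gene",
            "spans_coding_exon", "inheritance", "max_pair_support",
        ],
    )
    if not report.empty:
        report = report.sort_values(
            ["allele_count", "size_bp", "chrom", "start", "gene", "family_id"],
            kind="mergesort",
        ).reset_index(drop=True)
    return report
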