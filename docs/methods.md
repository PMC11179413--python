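# Methods

This note documents the models, conventions and numerical choices behind
`invkit`, and what its synthetic-data tests do and do not establish about
real cohort data.

## Coordinates and sizes

Positions are 1-based, chromosome names `chr`-prefixed (prefixless input is
normalised on read). The size of a segment is defined as `end − start`,
which treats an interval as the half-open set of inter-base positions
`[start, end)`. This is the convention under which the segment sizes quoted
in clinical reports of large inversions are exactly reproducible from their
printed coordinates (e.g. 37,035,341 − 6,352,714 = 30,682,627). Clinical
literature occasionally uses the inclusive convention (`end − start + 1`,
e.g. for a 24-bp micro-inversion); the two differ by 1 bp and `invkit`
standardises on the former everywhere. Reciprocal overlap, containment and
coding-exon spanning all use the same half-open arithmetic, so "spans a
coding exon" means ≥ 1 bp of half-open intersection with a CDS-clipped exon.

## Cohort clustering and the rarity filter

Calls are clustered per (SV type, chromosome) by single-linkage transitive
closure over the relation `RO(a,b) ≥ overlap_threshold` (default 0.80).
Single linkage is order-independent and matches how cohort SV databases
merge equivalent calls; the implementation is a sorted sweep with union-find
and is verified against a quadratic brute-force closure oracle in the test
suite. Inversions recovered from breakend (BND) notation are normalised
first: a mate-linked same-chromosome breakend pair whose two ends retain the
same side (head–head or tail–tail junction) is rewritten as an INV record
over min/max of the two positions, so BND-encoded inversions cluster with
directly-called ones. DEL/DUP/INS cluster only with their own type.

**Apparent allele count** sums, over distinct carrier samples, 2 for
homozygous calls and 1 otherwise; SV genotypes are unreliable, so unknown
genotypes conservatively contribute a single allele (a carrier-counting mode
is available). The default rarity cut is allele count ≤ 5 — in a national
cohort dominated by small families, a dominant pathogenic variant is
expected in very few carriers. The filter additionally requires ≥ 3
supporting discordant read pairs (`PR`) on at least one member; the
threshold is configurable and recorded in the run report, since discordant
pair support is a confidence signal rather than a published cutoff. Missing
PR/SR fields default to 0 so that absent evidence never passes a support
threshold.

## Haploinsufficiency disruption rules

The gene region is the min-to-max exon span over the supplied transcripts,
with no padding: regulatory-distance cases are handled by supplying longer
isoforms in the gene models rather than by a padding parameter. Rules, in
order, on the cluster's representative (member-median) interval:

1. zero breakpoints inside the gene: deprioritized as intact if the call
   contains the whole gene, otherwise rejected;
2. exactly one breakpoint inside: prioritized (the gene body is broken);
3. both breakpoints inside: prioritized only if the call spans ≥ 1 coding
   exon of any transcript — an inversion confined to one intron reorders
   nothing that matters.

Coding exons are exons intersected with `[cds_start, cds_end]`; a gene with
no CDS can never satisfy the coding-exon test (logged). Imprecise calls use
the same point-estimate breakpoints. De novo status requires both parents
assayed and non-carrying; a single sequenced carrier parent yields the
corresponding parental mode, a missing parent yields `unknown`.

## Rearrangement taxonomy

`classify_structure` applies decision rules in a fixed order to the calls
and a derivative copy-number profile (0 = deleted, 1 = single copy,
2 = duplicated, 3 = triplicated; i.e. copies on the rearranged haplotype,
total depth minus the intact homolog):

| order | class | signature |
|---|---|---|
| a | `SIMPLE_INV` | 1–2 INV calls only, loss fraction < 0.10 |
| b | `INV_WITH_LOSS` | as (a), loss fraction ≥ 0.10 |
| c | `DEL_WITH_RETAINED_SEGMENTS` | DEL call + copy ≥ 1 segment strictly inside the copy-0 region |
| d | `DUP_TRP` | INV call over a duplicated segment adjacent to a triplicated one |
| e | `INTERLINKED_DUP` | ≥ 2 INV calls + ≥ 2 non-adjacent duplicated segments |
| f | `INSERTIONAL` | junctions to a distant locus, duplicated donor, copy-neutral acceptor |
| g | `COMPLEX_TRANSLOCATION` | junction graph over ≥ 2 chromosomes, ≥ 3 breakpoints |
| h | `MOBILE_ELEMENT_SUSPECT` | short (< 5 kb) INV, no spanning pair, clipped bases match an inserted element |

The paired-record interpretation behind (a)/(b): Manta emits two INV records
for one event; the absolute start/end coordinate differences are the bases
lost at each end, a loss is called when the larger offset exceeds the 5-bp
breakend-jitter tolerance, and the loss fraction is taken against the outer
span. Small 11–12-bp end losses are therefore reported as losses while the
event remains a simple inversion by fraction. The 10% boundary between (a)
and (b) is the field's working definition of "relatively simple". The
mobile-element rule is a deliberately simple size + spanning-support
heuristic standing in for expert review of soft-clip alignments.

## Configuration enumeration

A *configuration* is a set of derivative molecules, each an ordered signed
sequence of reference segments (`A+`, `X-`, …). Enumeration is an exhaustive
depth-first search: each molecule runs from the leftmost (telomere-facing)
segment of a chromosome to some rightmost segment; every seam between
consecutive signed segments either fuses the left and right side of one
reference position (reference continuity, free) or must consume exactly one
observed junction, matched on breakend positions *and* orientations. Copy
numbers are respected exactly. Results are deduplicated up to
whole-derivative reverse complement and sorted; the search refuses
structures with more than 12 segment copies (exhaustive enumeration is
factorial; the bound is configurable).

Two modelling conventions matter:

* **Fold-back spacer.** The fold-back junction of a duplication–triplication
  has its two breakends a few tens of bp apart; the micro-segment between
  them (the "spacer") is too small for depth evidence and sits between two
  inverted copies of the same sequence, so short reads cannot establish its
  orientation — the local fragment sets of the two orientations are exact
  reverse complements of each other. The spacer is therefore a segment with
  unconstrained copy number, and its two orientations are enumerated as
  distinct configurations. Together with the unresolvable placement of the
  duplicated flank inside or outside the inverted block, this yields exactly
  the classical four configurations of an unspanned DUP-TRP/INV-DUP
  signature, as an emergent property of strict junction matching rather than
  a hard-coded count.
* **Spanned junctions.** A junction confirmed by a read that spans it *and*
  the adjacent duplicated copy records the observed segment chain; surviving
  configurations must contain that chain (or its reverse complement) in some
  derivative. Because of the palindrome above, a useful chain must extend
  beyond the inverted block — which is precisely why only reads longer than
  the duplicated segment are informative. Marking junctions spanned can only
  remove configurations, never add them.

An inter-chromosomal duplicated insertion with unspanned junctions
enumerates to exactly two configurations — insertion into the acceptor
chromosome versus a reciprocal translocation with the duplication at the
breakpoint — since both imply the identical junction multiset; one spanning
read collapses this to the insertion. `validate_configuration` re-derives
the implied junction multiset of any configuration and checks it
bijectively against the observations, and the truth configuration of every
synthetic signature is enumerated and validates (tested across all eight
classes and many seeds).

Phasing of de novo SVs uses SNPs carried on junction-supporting reads: a
SNP votes for a parent when the proband is heterozygous and the observed
allele occurs in exactly one parent's genotype; an origin is returned only
with ≥ 1 informative vote and no conflict.

## Founder haplotype and mutation age

A site is a *conflict* when the two samples are homozygous for opposite
alleles — from hard genotypes when both are called, otherwise via the
B-allele-frequency proxy `|ΔBAF| ≥ 0.9` (BAF = alt reads / total reads;
zero-depth sites are missing, not errors). Genotype conflicts are
phase-free, which is what single-proband-per-family data require. The
shared haplotype is the interval between the nearest conflicts on either
side of the target (exclusive); absent a conflict, the scanned-region bound
is used and the flank recorded as missing. Shared ultra-rare variants are
sites strictly inside that interval where every carrier has the alternate
allele and cohort AF ≤ 0.001.

Age model: a one-sided shared length between two carrier lineages separated
by 2τ meioses is `Exp(2τ)`; m independent lengths give
`L = Σℓᵢ ~ Gamma(m, 2τ)`, MLE `τ̂ = m/(2L)`, and the 95% CI is
`[q₀.₀₂₅(m), q₀.₉₇₅(m)]/(2L)` from Gamma quantiles (exact 95% coverage by
construction; verified ≥ 90% empirically at m = 4). For a *correlated*
genealogy — carriers sharing most of their pedigree back to the founder —
the lengths are positively correlated, carrying less information: the
effective number of lengths is shrunk to `m_eff = 1 + (m−1)(1−ρ)` (default
ρ = 0.5) and the total rescaled consistently, leaving the point estimate at
`m/(2L)` while widening the CI. This is a documented stand-in for the
correlated-genealogy machinery of dedicated age-estimation tools; only
order-of-magnitude agreement with published point estimates is claimed, and
the simulation recovery tests are the calibration evidence. Physical
lengths convert to genetic lengths by linear interpolation on a supplied
monotone genetic map, or at a constant 1 cM/Mb by default (map sources for
published estimates are typically unstated).

## Dot plots and spanning reads

Dot plots use exact k-mer identity at wordsize 50 (words containing N are
skipped): sense matches are read/reference word pairs that are equal,
antisense matches equal the reverse complement. Runs are maximal
(anti)diagonal chains with a one-word gap tolerance; a read synthesized from
p reference pieces (each ≥ 2 words) yields p runs on error-free sequence.
Error-tolerant matching is out of scope — long-read error is not simulated,
so tests use noise-free reads. A read *spans* a junction when its merged
alignment extents (supplementary alignments linked) cover ≥ 500 bp beyond
the junction on both retained sides and the whole attached duplicated copy
when one is present; 500 bp exceeds breakend jitter by two orders of
magnitude. Technology span limits used for resolvability verdicts: 500 bp
(150-bp paired short reads), 20 kb (HiFi), 500 kb (ultra-long).

## Transcript consequence and RNA support

An inversion that fully covers a contiguous internal block of coding exons,
with both breakpoints in introns, is modelled at the transcript level as
skipping of that block (the outcome observed in RNA for such events), so
the protein effect reduces to deletion arithmetic on the block's CDS
interval: in frame iff the length is a multiple of 3 *and* the start is
codon-aligned (`c_start mod 3 = 1`); splice-phase subtleties beyond this are
deliberately not modelled, and misaligned cases are reported as
frameshifts. In-frame internal deletions are not NMD substrates
(`nmd_expected` is never true for in-frame events). A breakpoint separating
5′-UTR-only exons from an untouched CDS is flagged `utr_dislocation`;
breakpoints outside the transcript yield upstream/downstream position-
effect flags with distances. Expression-outlier results are consumed as an
external table when provided, never fitted here.

Allelic imbalance at a heterozygous coding site is an exact two-sided
binomial test of the alt fraction against 0.5: below 10 total reads the
verdict is inconclusive (no published depth cutoff exists; 10 keeps the
binomial test meaningful), complete absence of one allele with p < 0.05 is
monoallelic, significant skew with both alleles present is reported as
imbalanced with its p value.

## Synthetic data: what it does and does not show

The generator emulates the *structure* of a national rare-disease cohort at
toy scale: a 3-chromosome (15–30 Mb) genome, 10-exon genes with a 5′-UTR
first exon, trio families, common polymorphic inversions (AF 0.1–0.3,
binomial carriers) placed where benign inversions live (intergenic or
intron-confined), and one planted pathogenic event per affected family
emitted as the Manta record pattern of its class — paired INV records with
0–20-bp breakend jitter and optional loss, DEL + retained-segment depth,
INV + DUP + depth for duplication–triplications, BND sets for insertional
and translocation events — with genotypes consistent with the assigned
inheritance. All generators are pure functions of (params, seed) and
written VCFs are byte-identical across runs.

Passing tests therefore establish the *interpretation logic*: that the
filters, rules, enumerator and estimators recover planted truth exactly
under noise-free calls. They do not establish robustness to caller error,
breakend imprecision beyond the modelled jitter, reference artefacts,
repeat-mediated mis-mapping or sequencing error — all of which real data
contain and which sat behind the manual-review stage of the original
analysis. Alignment, variant calling, liftover, expression-outlier model
fitting and phenotype matching are out of scope.

## Degenerate inputs and tie-breaks

Zero-size intervals are invalid for reciprocal overlap (undefined fraction)
and form singleton clusters when encountered. Cluster representatives are
member-wise median start/end (integer-truncated), and report rows are
ordered by (allele count, size, chromosome, start, gene, family) for
determinism. Identical paired INV records give offsets 0 and no loss call.
The enumerator's molecule order follows natural chromosome order; spacer
segments may be used 0–2 times. A conflict site exactly at the founder
target would contradict shared carriage and is ignored rather than used as
a flank.
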