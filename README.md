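# invkit

Discovery and interpretation of rare genomic **inversions** and
inversion-containing **complex rearrangements** in genome-sequenced
rare-disease cohorts.

Inversions are copy-neutral, so they are invisible to array-CGH and MLPA and
are routinely overlooked by CNV-centric clinical pipelines, yet they cause
disease by disrupting dosage-sensitive genes, dislocating regulatory
elements, or riding inside complex rearrangements whose true structure is
ambiguous from short reads alone. `invkit` implements, as a tested reusable
library plus CLI, the full analysis a cohort-scale inversion study needs:

1. **Cohort rarity filtering** — Manta-style SV calls from many families are
   merged by single-linkage clustering on reciprocal overlap
   `RO(a, b) = min(|a∩b|/|a|, |a∩b|/|b|) ≥ 0.80`, and clusters are kept when
   the apparent allele count is ≤ 5 (hom carriers count 2) with discordant
   pair support (`PR ≥ 3`) on at least one member.
2. **Haploinsufficiency (HI) prioritization** — a cluster is reported for an
   HI gene when at least one breakpoint lies within the gene region; with
   both breakpoints inside, it must span ≥ 1 coding (CDS-clipped) exon;
   inversions containing an intact gene are deprioritized. Inheritance
   (de novo / parental) is annotated from family structure.
3. **Structure taxonomy and configuration enumeration** — the local
   call/depth signature is classified as a simple inversion (< 10% loss at
   one end), inversion with loss, deletion with retained internal segments,
   duplication–triplication (DUP-TRP/INV-DUP), interlinked duplications,
   insertional translocation, multi-chromosome complex translocation or a
   mobile-element suspect. All derivative-chromosome configurations
   compatible with the observed junction set are enumerated exhaustively:
   an unspanned DUP-TRP signature admits 4, a duplicated inter-chromosomal
   insertion 2 (insertion vs reciprocal translocation); a long read spanning
   the duplicated copy collapses each to 1.
4. **Founder-haplotype analysis** — shared haplotypes between unrelated
   carriers are delimited by absence of *conflicting homozygosity*
   (opposite-homozygote sites), supported by shared ultra-rare SNVs, and the
   mutation age is estimated from the genetic lengths of the shared
   segments: each one-sided length is `ℓ ~ Exp(2τ)`, so
   `τ̂ = m / (2 Σℓᵢ)` with a Gamma-quantile 95% CI.
5. **Long-read support** — FlexiDot-style exact k-mer dot plots
   (wordsize 50) and junction-spanning read counts used to resolve
   configuration ambiguity (≈ 500 bp spannable with 150-bp short-read
   pairs, ≈ 20 kb with HiFi).
6. **Synthetic cohorts with planted truth** — real national-cohort data are
   access-controlled, so a first-class generator emits per-family VCFs, gene
   models, HI lists, trio genotypes and truth tables for every structural
   class, making the whole pipeline testable end to end.

## Worked example

Interpreting the paired records Manta emits for one inversion — here the
coordinates of an intragenic founder inversion in a mismatch-repair gene —
and dating the founder event from 3.2 cM of shared haplotype:

```python
from invkit.genome_model import GenomicInterval
from invkit.complex_sv import pair_inv_calls
from invkit.founder_haplotype import estimate_mutation_age

interp = pair_inv_calls(
    GenomicInterval("chr2", 47_406_871, 47_425_914),
    GenomicInterval("chr2", 47_408_111, 47_425_934),
)
print(f"outer span : {interp.outer_span} ({interp.outer_span.size():,} bp)")
print(f"offsets    : start {interp.start_offset} bp, end {interp.end_offset} bp")
print(f"loss       : {interp.loss_bp} bp at the {interp.loss_end} end "
      f"({100*interp.loss_fraction:.1f}% of the span)")

age = estimate_mutation_age([0.016, 0.016], genealogy="independent", n_carriers=2)
print(f"mutation age: {age.tau_hat:.2f} generations "
      f"(95% CI {age.ci95[0]:.1f}-{age.ci95[1]:.1f})")
```

```
outer span : chr2:47,406,871-47,425,934 (19,063 bp)
offsets    : start 1240 bp, end 20 bp
loss       : 1240 bp at the proximal end (6.5% of the span)
mutation age: 31.25 generations (95% CI 3.8-87.1)
```

The two records differ by 1,240 bp at the proximal end — an inversion with a
1.2-kb deletion at one breakpoint, still a "simple" inversion at 6.5% loss —
and a carrier pair sharing 3.2 cM around the variant dates the founder event
to roughly 31 generations ago.

End to end on a synthetic cohort, from the shell:

```console
$ invkit simulate --seed 11 --n-families 40 --planted DUP_TRP --out demo
wrote cohort under demo (manifest: demo/manifest.tsv)
$ invkit prioritize --manifest demo/manifest.tsv --genes demo/genes.tsv \
      --hi-list demo/hi_genes.tsv --out demo/report.tsv
1 prioritized rows -> demo/report.tsv
$ invkit classify --vcf demo/FAM006.vcf --family-id FAM006 \
      --region chr1:5410172-5516644 --depth demo/depth.tsv --out demo/classified.json
DUP_TRP (4 configurations) -> demo/classified.json
```

The planted duplication–triplication is the only prioritized row in a
40-family cohort seeded with common polymorphic inversions (allele count 1,
de novo, both breakpoints in the HI gene, coding exon spanned), and its
classification reports the four derivative configurations that short-read
data cannot distinguish — the reason such events need long-read follow-up.

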