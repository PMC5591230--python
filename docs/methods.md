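# Methods

## The question the package answers

Short-read SNV discovery in a diploid genome can proceed two ways:

* **alignment-based** — map reads to a reference, tally a per-position
  pileup, and genotype sites from allele fractions;
* **assembly-based** — assemble reads de novo into contigs, align the
  contigs to the reference, and read SNVs off the mismatch columns.

The assembly route has an intrinsic failure mode for heterozygous
variants.  A de Bruijn assembler that wants long contigs must merge the
two parallel paths ("bubbles") that a heterozygous SNV creates in the
graph; whichever allele is kept, the other is erased before calling even
begins.  With balanced allele coverage the alternate allele survives in
roughly half the bubbles, so heterozygous recall from collapsed contigs
is capped near 50% while homozygous recall is essentially unharmed.
`asmbench` builds the entire comparison at desk scale — genome
simulation, read simulation, a deliberately haplotype-collapsing
assembler, one shared aligner, both callers, assembly QC and the
evaluation layer — so the cap and its downstream signatures (recall
gap, zygosity skew of missed variants, low recovery of alignment-arm
misses) can be measured rather than asserted.

## Synthetic data model

`simgenome` draws an i.i.d. random chromosome (length `L`, GC content
`gc`), places non-overlapping multi-exon genes (exons 150–400 bp,
introns 100–800 bp, CDS flanked by 20–100 bp UTR margins inside the
terminal exons), and spikes `n_snv` SNVs plus `n_indel` 1–10 bp indels
at uniform positions subject to a minimum pairwise spacing.  Each
variant is heterozygous with probability `het_fraction` (default 0.6;
field-typical for a human-like het/hom mix) and heterozygous alleles are
assigned to a uniformly chosen haplotype, with the assignment recorded.
Defaults that matter:

| parameter | default | why |
|---|---|---|
| `min_spacing` | 150 bp | longer than a read and far longer than k, so every het SNV forms an isolated, simple de Bruijn bubble — the mechanism under study in its cleanest form |
| `het_fraction` | 0.6 | typical het share of a human-like SNV set; every experiment states its own value explicitly |
| indel lengths | 1–10 bp | confounders for the aligner and assembler; indel calling itself is out of scope |
| confidence BED | 80% high, 10 blocks | synthetic analogue of high-confidence region masks used with real truth sets |

`readsim` draws fragments of Normal(350, 50) bp length (clamped to
[read length, 700]), each from a uniformly chosen haplotype, and reports
both 100 bp ends with mate 2 reverse-complemented.  The pair count is
`round(coverage x L / (2 x 100))`, so "30X" is quoted against the
haploid reference, as read coverages conventionally are.  Sequencing
noise is a uniform per-base substitution process (default 0.002, about
Q27) with constant quality strings and no indel errors: instrument
error profiles are irrelevant to the collapse mechanism, and keeping
errors substitution-only makes every indel in the data a true variant.

What the generator does *not* emulate — GC-dependent coverage bias,
repeat structure beyond what an i.i.d. sequence contains, structural
variants, mapping ambiguity from paralogy — limits what passing tests
say about real genomes: the benchmark isolates the diploidy mechanism,
it does not certify callers for production use.

## Assembler

`dbgasm` is a minimal canonical-k-mer de Bruijn assembler (default
k = 31, suited to 100 bp reads on megabase-scale toys; k must be odd so
no k-mer equals its own reverse complement).  Pipeline:

1. **count** — every k-window of every mate, canonicalised (packed
   2-bit integers, numpy; a per-window fallback covers 31 < k <= 63);
2. **filter** — nodes need `min_count` >= 2 occurrences, which removes
   nearly all singleton error k-mers at >= 10X;
3. **clip tips** — dead-end branches shorter than `2k` bases hanging
   off a junction that keeps another continuation, iterated to fixpoint;
4. **pop bubbles** — for every simple two-branch bubble (common source
   and sink, equal-length simple internal paths) the branch with lower
   mean node count is deleted; exact ties keep the branch spelling the
   lexicographically smaller added sequence.  For an isolated het SNV
   the two branch spellings differ only at the variant base, so the tie
   rule is allele-symmetric across random sites and the surviving allele
   is a fair coin overall.  Complex or unequal-length bubbles (e.g. het
   indels) are left intact — contigs simply break there, which mimics
   real assembly fragmentation;
5. **spell contigs** — maximal non-branching paths, normalised to the
   lexicographically smaller strand, ordered by length then sequence,
   filtered at 100 bp.  Traversal order is sorted, so assemblies are
   bit-reproducible without a seed.

This collapse-by-majority consensus is the point of the module: it is
the behaviour that caps heterozygous recall, implemented explicitly
rather than inherited as a side effect of a production assembler.

## Aligner

`seedalign` serves both arms.  A 15-mer exact index of the reference
forward strand (k-mers above 100 occurrences masked as repetitive)
seeds both strands of a query; hits are clustered by diagonal, chained
greedily, and inter-anchor segments are closed with a banded global
affine-gap DP (match +1, mismatch -1, gap open -2, gap extend -1 — one
mismatch is cheaper than opening a gap).  Reads are aligned end-to-end
in the query with a 12 bp band; contigs use the same machinery with a
50 bp band and sparser seeds.  Each query keeps at most its single
best-scoring placement across strands and chromosomes; a score tie with
any other placement flags the record non-unique, and non-unique records
are excluded from the pileup, from contig calling and from coverage —
the usual MAPQ-0 convention and the best-match-per-chromosome rule in
one policy.  Candidate chains that leave more than 2 kb of query
without an anchor are discarded: genuine placements always seed densely,
and closing such a gap by DP would be quadratic.

The reported score always equals re-scoring the returned CIGAR, and the
banded DP equals an unbanded affine Needleman–Wunsch whenever the band
covers the optimum (both are tested against an independent oracle).

## Callers

*Alignment arm.*  The pileup counts bases from uniquely mapped reads
(insertions skipped, deletions contribute nothing).  At each site with
depth >= 4, let `f` be the top non-reference allele fraction: HOM-alt
when `f >= 0.8`, HET when `0.2 <= f < 0.8`, and the alt count must be
>= 2.  The thresholds are deliberately simple (the production
genotypers they stand in for are black boxes) and are chosen so a
balanced het at 15X is called reliably: P(alt count < 2 or f < 0.2 at
depth 15, p = 0.5) is below half a percent.

*Assembly arm.*  Every mismatch column inside the aligned blocks of a
contig's best unique alignment becomes a call — unless it lies within
5 bp (on the reference) of an indel edit, a conservative buffer against
alignment-artifact SNVs.  Overlapping contigs that agree yield one
call; conflicts yield none.  Calls carry genotype UNKNOWN: a collapsed
haplotype cannot express zygosity, which is itself part of the finding,
so all zygosity analysis uses the truth annotations of matched and
missed sites, never called genotypes.

## Evaluation

Calls match truth on (chrom, pos, alt) — site and allele, genotype
ignored.  Recall = TP/(TP+FN), precision = TP/(TP+FP); empty call sets
report 0.0 with an explicit flag so sweep tables stay rectangular.
Recovery takes caller A's false-negative set and intersects it with
caller B's calls; the rate is an integer percent.  Region strata follow
the precedence CDS > UTR > intron > intergenic; the high/low-confidence
2x2 table of TP vs FP uses Pearson's chi-square without continuity
correction (1 df), skipped with a flag when a margin is zero.  All
presentation rounding is decimal half-away-from-zero, separate from the
exact internal ratios.

Nx follows the standard definition: sort contigs descending and report
the length at which the cumulative sum first reaches x% of the total
(N0 = maximum, N100 = minimum).  "Covered" means under an aligned
match/mismatch block of any contig's best unique alignment, counted
once.

## Problem sizes and numerical choices

The default sweep runs a 200 kb genome, 1,000 SNVs + 50 indels,
coverages 2–50X — the whole experiment finishes in about two minutes
on one CPU, and the suite's larger mechanism runs (500 kb, 2,500
isolated hets, error-free 50X) in about one more.  These sizes are
chosen so every claim that survives scaling — the recall plateau by
30X, the assembly-arm gap, the het-collapse cap, the zygosity skew —
is measured on thousands of variants while iteration stays interactive.

Numerical conventions worth stating: VCF positions are 1-based, BED and
all internal intervals 0-based half-open; alt-allele ties in the
genotyper resolve alphabetically; contig order and graph traversal are
sorted, so reruns are byte-identical under a fixed seed; desk-scale
assemblies saturate by ~10X, after which totals can wobble below 1%
(the plateau noise any assembly sweep shows), and monotonicity checks
allow exactly that slack.

## Known limitations

* Heterozygous recall from the assembly arm is a statistical coin flip:
  with 2,500 isolated hets its standard deviation is about one
  percentage point, so individual runs can land slightly above 50%.
* Precision of the alignment arm on clean synthetic data sits near
  93–97%, higher than production pipelines report on real genomes —
  the stand-in genotyper has no mapping-quality model, no duplicates
  and no systematic error modes, so precision values are not
  benchmark targets here; recall values are.
* Recovery of alignment-arm misses is only observable at low coverage:
  at >= 15X on clean data the alignment arm misses almost nothing.
* Indels are simulated strictly as confounders; neither arm calls them.
* Single synthetic chromosome by default; multi-chromosome inputs are
  supported (the best-match-per-chromosome rule needs them) but the
  generators emit one chromosome.
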