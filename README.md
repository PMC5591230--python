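# asmbench

**Alignment-based vs assembly-based SNV calling, benchmarked on
synthetic diploid genomes.**

Calling single-nucleotide variants from short reads is usually done by
aligning reads to a reference and genotyping a pileup.  An attractive
alternative is to assemble the reads de novo and read variants off the
contig-to-reference alignment — but a de Bruijn assembler that merges
the two parallel graph paths created by a heterozygous site ("bubble
popping") erases one allele before calling even starts.  `asmbench`
builds both pipelines at desk scale, on simulated diploid genomes with
a known truth set, so the consequences of that *haplotype collapse* can
be measured directly:

* recall/precision of each arm across a read-coverage sweep,
* the fraction of one arm's misses the other arm recovers,
* the homozygous/heterozygous composition of recalled vs missed SNVs,
* assembly quality (Nx curves, genome/gene/exon coverage) per coverage.

It is aimed at people teaching or studying variant-calling methodology
who want the mechanism reproducible in minutes on a laptop, not after a
cluster-scale assembly.

## The quantities at the core

With TP/FP/FN from matching calls to truth on (chrom, pos, alt):

```
recall    = TP / (TP + FN)
precision = TP / (TP + FP)
recovery  = |missed_by_A ∩ called_by_B| / |missed_by_A|
Nx        = length of the shortest contig among the largest contigs
            jointly holding ≥ x% of the assembly (N50 at x = 50)
```

For an isolated heterozygous SNV the assembler keeps the branch with
higher mean k-mer count; with balanced allele coverage the alternate
allele survives with probability ~1/2, so assembly-arm heterozygous
recall is capped near 50% while homozygous recall stays near 100%.

## Worked example

```python
from asmbench.sweeprunner import SweepConfig, run_sweep

cfg = SweepConfig(outdir="sweep_out", coverages=[10, 15, 20, 30, 50])
results = run_sweep(cfg)   # 200 kb genome, 1,000 SNVs + 50 indels, ~2 min
for cov in cfg.coverages:
    r = results[cov]
    print(f"{cov:>3}X  alignment recall {r['alignment_eval'].recall:.3f}"
          f"  assembly recall {r['assembly_eval'].recall:.3f}"
          f"  recalled hom/het {r['zygosity_recalled'].n_hom}"
          f"/{r['zygosity_recalled'].n_het}"
          f"  missed hom/het {r['zygosity_missed'].n_hom}"
          f"/{r['zygosity_missed'].n_het}")
```

prints (seed 42, the default):

```
 10X  alignment recall 0.957  assembly recall 0.701  recalled hom/het 416/285  missed hom/het 0/299
 15X  alignment recall 0.993  assembly recall 0.694  recalled hom/het 416/278  missed hom/het 0/306
 20X  alignment recall 0.998  assembly recall 0.691  recalled hom/het 416/275  missed hom/het 0/309
 30X  alignment recall 1.000  assembly recall 0.696  recalled hom/het 416/280  missed hom/het 0/304
 50X  alignment recall 1.000  assembly recall 0.714  recalled hom/het 416/298  missed hom/het 0/286
```

Read it off directly: the alignment arm plateaus above 99% recall by
15–30X; the assembly arm never beats ~70% — it finds all 416 recalled
homozygous sites but only about half of the heterozygous ones, and
every single missed SNV is heterozygous.  That is haplotype collapse.

The same experiment is scriptable from the shell:

```
asmbench sweep --out sweep_out --seed 42
asmbench simulate --length 200000 --n-snv 1000 --coverage 30 --out sim/
asmbench assemble --reads1 sim/reads_1.fq --reads2 sim/reads_2.fq --out contigs.fa
asmbench call-contigs --reference sim/reference.fa --contigs contigs.fa --out asm.vcf
asmbench evaluate --truth sim/truth.vcf --calls asm.vcf
```

All artifacts are plain text: FASTA references and contigs, paired
FASTQ, VCF v4.2 truth and call sets, BED gene models and confidence
regions, TSV reports.

## Layout

| module | role |
|---|---|
| `asmbench.simgenome` | reference, gene model, truth variants, diploid template, confidence BED |
| `asmbench.readsim` | paired-end read simulation from the diploid template |
| `asmbench.dbgasm` | de Bruijn assembler: counting, tip clipping, bubble popping, contigs |
| `asmbench.seedalign` | shared seed-and-extend aligner (reads and contigs) |
| `asmbench.callers` | pileup genotyper and contig-mismatch caller |
| `asmbench.asmqc` | Nx statistics, assembly summary, genome/gene/exon coverage |
| `asmbench.evalkit` | truth matching, recall/precision, recovery, zygosity, stratification |
| `asmbench.sweeprunner` | config, end-to-end sweep orchestration, CLI |

See `docs/methods.md` for the model, parameter rationale and known
limitations.
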