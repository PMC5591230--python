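"""Synthetic diploid genome construction.

This module builds the ground-truth side of the benchmark: a random
reference chromosome, a non-overlapping gene model (for region-stratified
evaluation and assembly QC), a spiked set of truth variants with a known
het/hom mix, the diploid template genome obtained by applying those
variants to the reference, and a synthetic high/low-confidence region BED.

Coordinate conventions
----------------------
* ``TruthVariant.pos`` is 1-based (VCF style); indels are left-anchored on
  a shared reference base, as in VCF.
* All interval containers (exons, confidence regions) are 0-based
  half-open, as in BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seqs import BASES, decode
from .errors import CapacityError, ConsistencyError, InputError

REGION_INTERGENIC = 0
REGION_INTRON = 1
REGION_UTR = 2
REGION_CDS = 3
REGION_NAMES = {
    REGION_INTERGENIC: "intergenic",
    REGION_INTRON: "intron",
    REGION_UTR: "UTR",
    REGION_CDS: "CDS",
}


@dataclass
class ReferenceGenome:
    """A single synthetic chromosome over the ACGT alphabet."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Gene:
    id: str
    strand: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    exons: list[tuple[int, int]]  # disjoint, sorted, within [start, end)
    cds: tuple[int, int]  # genomic span of the coding region

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GeneModel:
    """Ordered, non-overlapping genes on one chromosome.

    Positions are classified with the precedence CDS > UTR > intron >
    intergenic; because genes never overlap the classification is a total
    function of position.
    """

    genes: list[Gene]

    def region_array(self, genome_length: int) -> np.ndarray:
        """Per-position region code for the whole chromosome."""
        arr = np.zeros(genome_length, dtype=np.uint8)
        for g in self.genes:
            arr[g.start : g.end] = REGION_INTRON
            cs, ce = g.cds
            for es, ee in g.exons:
                arr[es:ee] = REGION_UTR
            for es, ee in g.exons:
                s, e = max(es, cs), min(ee, ce)
                if s < e:
                    arr[s:e] = REGION_CDS
        return arr

    def classify(self, pos0: int, genome_length: int | None = None) -> str:
        for g in self.genes:
            if g.start <= pos0 < g.end:
                in_exon = any(es <= pos0 < ee for es, ee in g.exons)
                if not in_exon:
                    return "intron"
                cs, ce = g.cds
                return "CDS" if cs <= pos0 < ce else "UTR"
        return "intergenic"


@dataclass(frozen=True)
class TruthVariant:
    """A spiked variant forming part of the ground-truth set."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str  # SNV | INS | DEL
    genotype: str  # HET | HOM

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


@dataclass
class DiploidTemplate:
    """Two haplotype sequences plus coordinate maps back to the reference.

    ``hap2ref[h][i]`` gives the 0-based reference position of haplotype
    ``h`` base ``i`` (-1 for inserted bases); ``ref2hap[h][p]`` is the
    inverse (-1 for deleted reference bases).  ``carriers`` records, per
    truth variant position, which haplotypes carry the alternate allele.
    """

    reference: ReferenceGenome
    hap1: str
    hap2: str
    hap2ref: tuple[np.ndarray, np.ndarray]
    ref2hap: tuple[np.ndarray, np.ndarray]
    carriers: dict[int, tuple[bool, bool]] = field(default_factory=dict)

    @property
    def haplotypes(self) -> tuple[str, str]:
        return (self.hap1, self.hap2)


@dataclass
class ConfidenceRegions:
    """High-confidence intervals (0-based half-open); the complement is low."""

    high: list[tuple[int, int]]
    genome_length: int

    def high_mask(self) -> np.ndarray:
        mask = np.zeros(self.genome_length, dtype=bool)
        for s, e in self.high:
            mask[s:e] = True
        return mask

    def is_high(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.high)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_reference(
    length: int, gc: float = 0.5, seed: int = 0, name: str = "chr1"
) -> ReferenceGenome:
    """Draw an i.i.d. random chromosome with the requested GC content."""
    if length < 1000:
        raise InputError("reference length must be >= 1000")
    if not 0.0 <= gc <= 1.0:
        raise InputError("gc must be within [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return ReferenceGenome(name=name, sequence=decode(codes))


def generate_gene_model(
    genome: ReferenceGenome,
    n_genes: int,
    mean_exons: float = 4.0,
    seed: int = 0,
) -> GeneModel:
    """Place non-overlapping multi-exon genes on the reference.

    Each gene alternates exons (150-400 bp) and introns (100-800 bp); the
    CDS is the exon union minus short UTR margins inside the terminal
    exons.  Raises :class:`CapacityError` when the requested genes do not
    fit with at least 200 bp of intergenic spacing.
    """
    if n_genes < 0:
        raise InputError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    if n_genes == 0:
        return GeneModel(genes=[])

    layouts = []
    for _ in range(n_genes):
        n_ex = max(1, rng.poisson(mean_exons))
        ex_lens = rng.integers(150, 401, size=n_ex)
        in_lens = rng.integers(100, 801, size=max(0, n_ex - 1))
        layouts.append((ex_lens, in_lens))
    spans = [int(e.sum() + i.sum()) for e, i in layouts]
    gap = 200
    total = sum(spans) + gap * (n_genes + 1)
    if total > genome.length:
        raise CapacityError(
            f"{n_genes} genes need {total} bp but genome has {genome.length}"
        )

    # distribute the free space uniformly among the n_genes + 1 gaps
    free = genome.length - sum(spans) - gap * (n_genes + 1)
    cuts = np.sort(rng.integers(0, free + 1, size=n_genes))
    extra = np.diff(np.concatenate([[0], cuts]))
    cursor = 0
    for gi, ((ex_lens, in_lens), span) in enumerate(zip(layouts, spans)):
        cursor += gap + int(extra[gi])
        start = cursor
        exons = []
        p = start
        for i, el in enumerate(ex_lens):
            exons.append((p, p + int(el)))
            p += int(el)
            if i < len(in_lens):
                p += int(in_lens[i])
        end = p
        utr5 = int(rng.integers(20, max(21, min(100, int(ex_lens[0]) // 3))))
        utr3 = int(rng.integers(20, max(21, min(100, int(ex_lens[-1]) // 3))))
        cds = (exons[0][0] + utr5, exons[-1][1] - utr3)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            Gene(id=f"gene_{gi + 1}", strand=strand, start=start, end=end,
                 exons=exons, cds=cds)
        )
        cursor = end
    return GeneModel(genes=genes)


def sample_truth_variants(
    genome: ReferenceGenome,
    gene_model: GeneModel | None = None,
    n_snv: int = 0,
    n_indel: int = 0,
    het_fraction: float = 0.6,
    min_spacing: int = 150,
    seed: int = 0,
) -> list[TruthVariant]:
    """Spike ``n_snv`` SNVs and ``n_indel`` 1-10 bp indels into the genome.

    Positions are uniform subject to a minimum pairwise spacing (default
    150 bp, longer than a read, so each heterozygous SNV forms an isolated
    de Bruijn bubble).  Each variant is heterozygous with probability
    ``het_fraction``.  ``gene_model`` is accepted for interface symmetry;
    placement is region-agnostic.
    """
    n = n_snv + n_indel
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    margin = 60  # keep variants away from chromosome ends
    usable = genome.length - 2 * margin - 12  # room for the longest DEL
    slack = usable - (n - 1) * min_spacing
    if slack < n:
        raise CapacityError(
            f"cannot place {n} variants with spacing {min_spacing} "
            f"in {genome.length} bp"
        )
    offsets = np.sort(rng.choice(slack, size=n, replace=False))
    pos0 = margin + offsets + min_spacing * np.arange(n)

    vtypes = np.array(["SNV"] * n_snv + ["INDEL"] * n_indel)
    rng.shuffle(vtypes)
    seq = genome.sequence
    out: list[TruthVariant] = []
    for p, vt in zip(pos0.tolist(), vtypes):
        genotype = "HET" if rng.random() < het_fraction else "HOM"
        if vt == "SNV":
            ref = seq[p]
            alt = rng.choice([b for b in BASES if b != ref])
            out.append(TruthVariant(genome.name, p + 1, ref, str(alt), "SNV", genotype))
        else:
            ell = int(rng.integers(1, 11))
            if rng.random() < 0.5:  # deletion
                ref = seq[p : p + ell + 1]
                out.append(
                    TruthVariant(genome.name, p + 1, ref, ref[0], "DEL", genotype)
                )
            else:  # insertion
                ins = "".join(rng.choice(list(BASES), size=ell))
                ref = seq[p]
                out.append(
                    TruthVariant(genome.name, p + 1, ref, ref + ins, "INS", genotype)
                )
    return out


def build_diploid_template(
    genome: ReferenceGenome,
    variants: list[TruthVariant],
    seed: int = 0,
) -> DiploidTemplate:
    """Apply truth variants to the reference to obtain the two haplotypes.

    HOM variants land on both haplotypes; each HET variant lands on one
    haplotype chosen uniformly (seeded) — the assignment is recorded in
    ``carriers``.  Coordinate maps between haplotype and reference
    positions are built alongside.
    """
    rng = np.random.default_rng(seed)
    seq = genome.sequence
    L = genome.length
    variants = sorted(variants, key=lambda v: v.pos)
    last_end = -1
    for v in variants:
        if seq[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
            raise ConsistencyError(
                f"variant at {v.pos} REF={v.ref!r} does not match the reference"
            )
        if v.pos - 1 <= last_end:
            raise ConsistencyError(f"overlapping variants near position {v.pos}")
        last_end = v.pos - 1 + len(v.ref) - 1

    carriers: dict[int, tuple[bool, bool]] = {}
    plans: list[tuple[TruthVariant, tuple[bool, bool]]] = []
    for v in variants:
        if v.genotype == "HOM":
            c = (True, True)
        else:
            h = int(rng.integers(2))
            c = (h == 0, h == 1)
        carriers[v.pos] = c
        plans.append((v, c))

    haps: list[str] = []
    h2r: list[np.ndarray] = []
    r2h: list[np.ndarray] = []
    for h in range(2):
        parts: list[str] = []
        maps: list[np.ndarray] = []
        cursor = 0
        for v, c in plans:
            p0 = v.pos - 1
            if not c[h]:
                continue
            parts.append(seq[cursor:p0])
            maps.append(np.arange(cursor, p0))
            if v.vtype == "SNV":
                parts.append(v.alt)
                maps.append(np.array([p0]))
                cursor = p0 + 1
            elif v.vtype == "DEL":
                parts.append(v.alt)  # the anchor base
                maps.append(np.array([p0]))
                cursor = p0 + len(v.ref)
            else:  # INS
                parts.append(v.alt)
                maps.append(
                    np.concatenate([[p0], np.full(len(v.alt) - 1, -1, dtype=np.int64)])
                )
                cursor = p0 + 1
        parts.append(seq[cursor:L])
        maps.append(np.arange(cursor, L))
        hap = "".join(parts)
        hap2ref = np.concatenate(maps).astype(np.int64)
        ref2hap = np.full(L, -1, dtype=np.int64)
        mapped = hap2ref >= 0
        ref2hap[hap2ref[mapped]] = np.nonzero(mapped)[0]
        haps.append(hap)
        h2r.append(hap2ref)
        r2h.append(ref2hap)

    return DiploidTemplate(
        reference=genome,
        hap1=haps[0],
        hap2=haps[1],
        hap2ref=(h2r[0], h2r[1]),
        ref2hap=(r2h[0], r2h[1]),
        carriers=carriers,
    )


def make_confidence_bed(
    genome: ReferenceGenome,
    high_fraction: float = 0.8,
    n_blocks: int = 10,
    seed: int = 0,
) -> ConfidenceRegions:
    """Synthesise disjoint high-confidence blocks covering ``high_fraction``."""
    if not 0.0 < high_fraction <= 1.0:
        raise InputError("high_fraction must be in (0, 1]")
    L = genome.length
    if high_fraction == 1.0:
        return ConfidenceRegions(high=[(0, L)], genome_length=L)
    rng = np.random.default_rng(seed)
    total_high = int(round(L * high_fraction))
    n_blocks = max(1, min(n_blocks, total_high))
    base = total_high // n_blocks
    sizes = [base] * n_blocks
    sizes[-1] += total_high - base * n_blocks
    free = L - total_high
    cuts = np.sort(rng.integers(0, free + 1, size=n_blocks))
    gaps = np.diff(np.concatenate([[0], cuts]))
    intervals = []
    cursor = 0
    for sz, gp in zip(sizes, gaps):
        cursor += int(gp)
        intervals.append((cursor, cursor + sz))
        cursor += sz
    # merge any blocks that ended up adjacent
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return ConfidenceRegions(high=merged, genome_length=L)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str] | ReferenceGenome, path, width: int = 60):
    if isinstance(sequences, ReferenceGenome):
        sequences = {sequences.name: sequences.sequence}
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=asmbench
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_truth_vcf(variants: list[TruthVariant], path, sample: str = "TRUTH"):
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(sample=sample))
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            gt = "0/1" if v.genotype == "HET" else "1/1"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_truth_vcf(path) -> list[TruthVariant]:
    """Read a single-sample VCF back into TruthVariant records (via pysam)."""
    import pysam

    out: list[TruthVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) == 1 and len(alt) == 1:
                vtype = "SNV"
            elif len(ref) > len(alt):
                vtype = "DEL"
            else:
                vtype = "INS"
            gt = rec.samples[sample]["GT"]
            genotype = "HOM" if gt == (1, 1) else "HET"
            out.append(TruthVariant(rec.chrom, rec.pos, ref, alt, vtype, genotype))
    return out


def write_gene_bed12(model: GeneModel, chrom: str, path):
    with open(path, "w") as fh:
        for g in model.genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\t"
                f"{g.cds[0]}\t{g.cds[1]}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
            )


def read_gene_bed12(path) -> GeneModel:
    genes = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            genes.append(
                Gene(id=f[3], strand=f[5], start=start, end=end, exons=exons,
                     cds=(int(f[6]), int(f[7])))
            )
    return GeneModel(genes=genes)


def write_bed(regions: ConfidenceRegions, chrom: str, path):
    with open(path, "w") as fh:
        for s, e in regions.high:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path, genome_length: int) -> ConfidenceRegions:
    high = []
    with open(path) as fh:
        for line in fh:
            f = line.split("\t")
            high.append((int(f[1]), int(f[2])))
    return ConfidenceRegions(high=sorted(high), genome_length=genome_length)
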