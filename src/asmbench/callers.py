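"""The two SNV-calling arms compared by the benchmark.

* ``pileup`` + ``call_snvs_from_pileup``: a diploid genotyper over
  per-position base counts from uniquely mapped reads — the
  alignment-based arm.
* ``call_snvs_from_contigs``: a contig-mismatch extractor over the best
  unique alignment of each contig — the assembly-based arm.  It emits
  genotype ``UNKNOWN`` because a collapsed haplotype cannot express
  zygosity; that inability is itself part of the phenomenon under study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seqs import BASES, encode, revcomp
from .errors import InputError

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=asmbench-{source}
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


@dataclass
class PileupColumn:
    chrom: str
    pos: int  # 1-based
    ref_base: str
    base_counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass(frozen=True)
class Call:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str  # HET | HOM | UNKNOWN
    source: str  # alignment | assembly

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


class Pileup:
    """Per-chromosome (L, 4) base-count matrices from unique alignments."""

    def __init__(self, references: dict[str, str]):
        self.references = references
        self.counts = {
            name: np.zeros((len(seq), 4), dtype=np.int32)
            for name, seq in references.items()
        }

    def column(self, chrom: str, pos: int) -> PileupColumn:
        row = self.counts[chrom][pos - 1]
        return PileupColumn(
            chrom=chrom,
            pos=pos,
            ref_base=self.references[chrom][pos - 1],
            base_counts={b: int(row[i]) for i, b in enumerate(BASES)},
        )

    def columns(self, min_depth: int = 1):
        """Yield PileupColumn for every position at or above ``min_depth``."""
        for chrom, mat in self.counts.items():
            for pos0 in np.nonzero(mat.sum(axis=1) >= min_depth)[0].tolist():
                yield self.column(chrom, pos0 + 1)


def pileup(alignments, reads_by_id: dict[str, str], references) -> Pileup:
    """Tally read bases per reference position from unique alignments.

    Insertions contribute nothing; deleted reference positions get no
    count.  ``reads_by_id`` holds read sequences as simulated (the pileup
    reorients '-' strand records internally).
    """
    if hasattr(references, "sequence"):
        references = {references.name: references.sequence}
    pile = Pileup(references)
    idx_parts: dict[str, list[np.ndarray]] = {name: [] for name in references}
    for rec in alignments:
        if not rec.unique:
            continue
        seq = reads_by_id[rec.query_id]
        if rec.strand == "-":
            seq = revcomp(seq)
        codes = encode(seq)
        q = 0
        r = rec.ref_start - 1
        for op, n in rec.cigar:
            if op in "=X":
                idx_parts[rec.chrom].append(
                    np.arange(r, r + n, dtype=np.int64) * 4 + codes[q : q + n]
                )
                q += n
                r += n
            elif op == "I":
                q += n
            else:  # D
                r += n
    for chrom, parts in idx_parts.items():
        if not parts:
            continue
        flat = np.concatenate(parts)
        L = len(references[chrom])
        pile.counts[chrom] += np.bincount(flat, minlength=L * 4).reshape(L, 4).astype(
            np.int32
        )
    return pile


def call_snvs_from_pileup(
    pile: Pileup,
    min_depth: int = 4,
    min_alt_count: int = 2,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> list[Call]:
    """Threshold genotyper: HET when the top non-reference allele fraction
    falls in ``het_band``, HOM-alt at or above the upper bound, no call
    otherwise.  Ties between alternate bases resolve to the
    alphabetically first, so calls are deterministic.
    """
    if min_depth < 1 or min_alt_count < 1:
        raise InputError("thresholds must be positive")
    lo, hi = het_band
    if not 0.0 < lo < hi < 1.0:
        raise InputError("het_band must satisfy 0 < lo < hi < 1")
    calls: list[Call] = []
    for chrom, mat in pile.counts.items():
        ref_codes = encode(pile.references[chrom])
        depth = mat.sum(axis=1)
        nonref = mat.copy()
        valid = ref_codes < 4
        nonref[np.arange(len(ref_codes))[valid], ref_codes[valid]] = 0
        alt_code = nonref.argmax(axis=1)
        alt_count = nonref.max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(depth > 0, alt_count / np.maximum(depth, 1), 0.0)
        mask = (depth >= min_depth) & (alt_count >= min_alt_count) & (f >= lo)
        for pos0 in np.nonzero(mask)[0].tolist():
            genotype = "HOM" if f[pos0] >= hi else "HET"
            calls.append(
                Call(
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref=pile.references[chrom][pos0],
                    alt=BASES[int(alt_code[pos0])],
                    genotype=genotype,
                    source="alignment",
                )
            )
    return calls


def call_snvs_from_contigs(
    contig_alignments,
    contigs_by_id: dict[str, str],
    references,
    indel_exclusion_radius: int = 5,
) -> list[Call]:
    """Emit every mismatch column of the best unique contig alignments.

    Mismatches within ``indel_exclusion_radius`` bp (on the reference) of
    an indel edit are suppressed as likely alignment artifacts.  When two
    contigs overlap a position, agreeing claims are emitted once and
    conflicting claims are dropped.
    """
    if hasattr(references, "sequence"):
        references = {references.name: references.sequence}
    claims: dict[tuple[str, int], set[tuple[str, str]]] = {}
    for rec in contig_alignments:
        if not rec.unique:
            continue
        seq = contigs_by_id[rec.query_id]
        if rec.strand == "-":
            seq = revcomp(seq)
        ref = references[rec.chrom]
        q = 0
        r = rec.ref_start - 1
        mismatches: list[tuple[int, str, str]] = []
        indel_points: list[int] = []
        for op, n in rec.cigar:
            if op == "=":
                q += n
                r += n
            elif op == "X":
                for t in range(n):
                    mismatches.append((r + t, ref[r + t], seq[q + t]))
                q += n
                r += n
            elif op == "I":
                indel_points.append(r)
                q += n
            else:  # D
                indel_points.extend([r, r + n])
                r += n
        for pos0, rb, ab in mismatches:
            if rb == ab or ab not in BASES or rb not in BASES:
                continue
            if any(abs(pos0 - ip) <= indel_exclusion_radius for ip in indel_points):
                continue
            claims.setdefault((rec.chrom, pos0), set()).add((rb, ab))
    calls: list[Call] = []
    for (chrom, pos0), alleles in sorted(claims.items()):
        if len(alleles) != 1:
            continue  # overlapping contigs disagree
        rb, ab = next(iter(alleles))
        calls.append(
            Call(chrom=chrom, pos=pos0 + 1, ref=rb, alt=ab, genotype="UNKNOWN",
                 source="assembly")
        )
    return calls


def write_calls_vcf(calls: list[Call], path, source: str = "alignment",
                    sample: str = "SAMPLE"):
    """VCF v4.2 output; the assembly arm writes GT as '.'."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(source=source, sample=sample))
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
            gt = {"HET": "0/1", "HOM": "1/1"}.get(c.genotype, ".")
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t.\tGT\t{gt}\n")


def read_calls_vcf(path, source: str = "alignment") -> list[Call]:
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            genotype = "UNKNOWN"
            if samples:
                gt = rec.samples[samples[0]].get("GT")
                if gt == (0, 1) or gt == (1, 0):
                    genotype = "HET"
                elif gt == (1, 1):
                    genotype = "HOM"
            calls.append(
                Call(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                     genotype=genotype, source=source)
            )
    return calls
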