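"""Assembly quality assessment: Nx statistics and coverage reports.

"Covered" throughout means covered by an aligned block (match or
mismatch columns, not deletions) of the best unique alignment of any
contig; overlapping placements count once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .simgenome import GeneModel


@dataclass
class NxCurve:
    """Nx(x) for x in 0..100: a non-increasing step function of contig length."""

    points: list[tuple[int, int]]  # (x percent, length)
    total_length: int


@dataclass
class CoverageReport:
    genome_fraction: float
    gene_status: dict[str, str]  # gene id -> FULL | PARTIAL | UNCOVERED
    exon_status: dict[str, str]  # "<gene>:<i>" -> status
    gene_counts: dict[str, int]
    exon_counts: dict[str, int]


def _lengths(contigs) -> list[int]:
    return [c.length if hasattr(c, "length") else int(c) for c in contigs]


def nx_statistic(lengths, x: float) -> int:
    """Length of the shortest contig among the largest contigs jointly
    holding at least x% of the assembly; Nx(0) is the maximum length."""
    lens = sorted(_lengths(lengths), reverse=True)
    if not lens:
        raise InputError("Nx of an empty length set is undefined")
    if not 0 <= x <= 100:
        raise InputError("x must be within [0, 100]")
    if x == 0:
        return lens[0]
    target = x / 100.0 * sum(lens)
    acc = 0
    for ln in lens:
        acc += ln
        if acc >= target:
            return ln
    return lens[-1]


def nx_curve(lengths) -> NxCurve:
    lens = _lengths(lengths)
    return NxCurve(
        points=[(x, nx_statistic(lens, x)) for x in range(101)],
        total_length=sum(lens),
    )


def assembly_summary(contigs) -> dict[str, int]:
    lens = _lengths(contigs)
    if not lens:
        return {"n_contigs": 0, "total_length": 0, "max_length": 0, "n50": 0}
    return {
        "n_contigs": len(lens),
        "total_length": sum(lens),
        "max_length": max(lens),
        "n50": nx_statistic(lens, 50),
    }


def _covered_mask(contig_alignments, length: int, chrom: str) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for rec in contig_alignments:
        if not rec.unique or rec.chrom != chrom:
            continue
        r = rec.ref_start - 1
        for op, n in rec.cigar:
            if op in "=X":
                mask[r : r + n] = True
                r += n
            elif op == "D":
                r += n
    return mask


def genome_coverage(contig_alignments, reference) -> float:
    """Fraction of reference bases under at least one aligned contig block."""
    mask = _covered_mask(contig_alignments, reference.length, reference.name)
    return float(mask.sum()) / reference.length


def feature_coverage(
    contig_alignments, gene_model: GeneModel, reference
) -> CoverageReport:
    """Classify each gene span and exon as FULL, PARTIAL or UNCOVERED."""
    mask = _covered_mask(contig_alignments, reference.length, reference.name)

    def status(s: int, e: int) -> str:
        n = int(mask[s:e].sum())
        if n == e - s:
            return "FULL"
        return "PARTIAL" if n > 0 else "UNCOVERED"

    gene_status = {g.id: status(g.start, g.end) for g in gene_model.genes}
    exon_status = {
        f"{g.id}:{i}": status(es, ee)
        for g in gene_model.genes
        for i, (es, ee) in enumerate(g.exons)
    }

    def tally(d):
        out = {"FULL": 0, "PARTIAL": 0, "UNCOVERED": 0}
        for v in d.values():
            out[v] += 1
        return out

    return CoverageReport(
        genome_fraction=float(mask.sum()) / reference.length,
        gene_status=gene_status,
        exon_status=exon_status,
        gene_counts=tally(gene_status),
        exon_counts=tally(exon_status),
    )


def contig_duplication(contig_alignments) -> float:
    """Fraction of aligned contigs whose best placement overlaps a
    higher-scoring contig's aligned span by more than 50%."""
    recs = [r for r in contig_alignments if r.unique]
    if not recs:
        return 0.0
    recs = sorted(recs, key=lambda r: -r.score)
    dup = 0
    placed: dict[str, list[tuple[int, int]]] = {}
    for r in recs:
        s, e = r.ref_start, r.ref_end
        span = e - s + 1
        overlap = 0
        for ps, pe in placed.get(r.chrom, []):
            overlap += max(0, min(e, pe) - max(s, ps) + 1)
        if overlap > 0.5 * span:
            dup += 1
        placed.setdefault(r.chrom, []).append((s, e))
    return dup / len(recs)


def write_nx_tsv(curve: NxCurve, path):
    with open(path, "w") as fh:
        fh.write("x\tlength\n")
        for x, ln in curve.points:
            fh.write(f"{x}\t{ln}\n")
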