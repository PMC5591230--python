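"""Truth-set comparison and the benchmark's summary statistics.

Calls match truth on (chrom, pos, alt) — site and allele, genotype
ignored.  The assembly arm cannot express zygosity, so the hom/het
composition of recalled and missed variants is always computed from the
truth annotations of the matched keys, never from called genotypes.

Presentation rounding is decimal half-away-from-zero (``round_half_up``),
separate from the exact internal ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats

from .errors import InputError
from .simgenome import GeneModel, REGION_NAMES, TruthVariant

Key = tuple[str, int, str]


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    tp_set: frozenset[Key]
    fp_set: frozenset[Key]
    fn_set: frozenset[Key]
    no_calls: bool = False

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0


@dataclass
class RecoveryResult:
    missed: frozenset[Key]
    recovered: frozenset[Key]
    rate: int  # integer percent, half-up
    no_missed: bool = False


@dataclass
class ZygosityRatio:
    n_hom: int
    n_het: int

    @property
    def ratio(self) -> float:
        if self.n_het == 0:
            raise InputError("hom/het ratio undefined with zero heterozygotes")
        return self.n_hom / self.n_het


def round_half_up(value: float, digits: int = 0) -> float:
    """Decimal round-half-away-from-zero at ``digits`` decimal places."""
    if digits < 0:
        raise InputError("digits must be >= 0")
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def match_calls(truth: list[TruthVariant], calls) -> EvalResult:
    """Partition truth vs calls into TP/FP/FN on (chrom, pos, alt) keys."""
    truth_keys = [v.key for v in truth]
    call_keys = [c.key for c in calls]
    if len(set(truth_keys)) != len(truth_keys):
        raise InputError("duplicate keys in the truth set")
    if len(set(call_keys)) != len(call_keys):
        raise InputError("duplicate keys in the call set")
    t, c = set(truth_keys), set(call_keys)
    tp = t & c
    return EvalResult(
        tp=len(tp),
        fp=len(c - t),
        fn=len(t - c),
        tp_set=frozenset(tp),
        fp_set=frozenset(c - t),
        fn_set=frozenset(t - c),
        no_calls=not c,
    )


def recall(ev: EvalResult) -> float:
    return ev.recall


def precision(ev: EvalResult) -> float:
    return ev.precision


def recovery(truth, eval_a: EvalResult, calls_b) -> RecoveryResult:
    """Of the truth variants caller A missed, how many did caller B call?"""
    missed = eval_a.fn_set
    b_keys = {c.key for c in calls_b}
    recovered = frozenset(missed & b_keys)
    if not missed:
        return RecoveryResult(frozenset(), frozenset(), 0, no_missed=True)
    rate = int(round_half_up(100.0 * len(recovered) / len(missed), 0))
    return RecoveryResult(frozenset(missed), recovered, rate)


def zygosity_ratio(variant_subset: list[TruthVariant]) -> ZygosityRatio:
    n_hom = sum(1 for v in variant_subset if v.genotype == "HOM")
    n_het = sum(1 for v in variant_subset if v.genotype == "HET")
    return ZygosityRatio(n_hom=n_hom, n_het=n_het)


def stratify_by_region(
    ev: EvalResult, gene_model: GeneModel, genome_length: int
) -> dict[str, dict[str, float]]:
    """Per-region TP/FP/FN and rates (CDS > UTR > intron > intergenic)."""
    region = gene_model.region_array(genome_length)

    def name_of(key: Key) -> str:
        return REGION_NAMES[int(region[key[1] - 1])]

    out = {
        name: {"tp": 0, "fp": 0, "fn": 0}
        for name in ("CDS", "UTR", "intron", "intergenic")
    }
    for attr, keys in (("tp", ev.tp_set), ("fp", ev.fp_set), ("fn", ev.fn_set)):
        for key in keys:
            out[name_of(key)][attr] += 1
    for name, d in out.items():
        d["recall"] = d["tp"] / (d["tp"] + d["fn"]) if d["tp"] + d["fn"] else 0.0
        d["precision"] = d["tp"] / (d["tp"] + d["fp"]) if d["tp"] + d["fp"] else 0.0
    return out


def stratify_by_confidence(ev: EvalResult, regions) -> dict:
    """2x2 {TP,FP} x {high,low} with Pearson's chi-square (no continuity
    correction, 1 df).  Any zero margin skips the test with a flag."""
    def split(keys):
        hi = sum(1 for k in keys if regions.is_high(k[1] - 1))
        return hi, len(keys) - hi

    tp_hi, tp_lo = split(ev.tp_set)
    fp_hi, fp_lo = split(ev.fp_set)
    table = [[tp_hi, tp_lo], [fp_hi, fp_lo]]
    margins = [tp_hi + tp_lo, fp_hi + fp_lo, tp_hi + fp_hi, tp_lo + fp_lo]
    if any(m == 0 for m in margins):
        return {"table": table, "chi2": None, "p": None, "tested": False}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"table": table, "chi2": float(chi2), "p": float(p), "tested": True}


def venn_counts(truth_keys, a_keys, b_keys) -> dict[str, int]:
    """Disjoint three-set decomposition (call-set comparison logic)."""
    t, a, b = set(truth_keys), set(a_keys), set(b_keys)
    return {
        "truth_only": len(t - a - b),
        "a_only": len(a - t - b),
        "b_only": len(b - t - a),
        "truth_a": len((t & a) - b),
        "truth_b": len((t & b) - a),
        "a_b": len((a & b) - t),
        "truth_a_b": len(t & a & b),
    }


# ---------------------------------------------------------------------------
# report emission
# ---------------------------------------------------------------------------


def report_tables(sweep_results: dict, outdir):
    """Write the four sweep TSVs: assembly summaries, calling metrics,
    zygosity ratios and Nx curves (one row per x per coverage)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    covs = sorted(sweep_results)

    with open(os.path.join(outdir, "assembly_summary.tsv"), "w") as fh:
        fh.write("coverage\tn_contigs\ttotal_length\tmax_length\tn50\t"
                 "genome_fraction\tgenes_full\tgenes_partial\tgenes_uncovered\n")
        for cov in covs:
            r = sweep_results[cov]
            s = r["assembly_summary"]
            gc = r["gene_counts"]
            fh.write(
                f"{cov}\t{s['n_contigs']}\t{s['total_length']}\t{s['max_length']}\t"
                f"{s['n50']}\t{r['genome_fraction']:.4f}\t{gc['FULL']}\t"
                f"{gc['PARTIAL']}\t{gc['UNCOVERED']}\n"
            )

    with open(os.path.join(outdir, "calling_metrics.tsv"), "w") as fh:
        fh.write("coverage\tarm\ttp\tfp\tfn\trecall\tprecision\t"
                 "missed\trecovered\trecovery_rate\n")
        for cov in covs:
            r = sweep_results[cov]
            for arm in ("alignment", "assembly"):
                ev = r[f"{arm}_eval"]
                rec = r["recovery"] if arm == "assembly" else None
                missed = len(r["alignment_eval"].fn_set)
                fh.write(
                    f"{cov}\t{arm}\t{ev.tp}\t{ev.fp}\t{ev.fn}\t"
                    f"{round_half_up(ev.recall, 2):.2f}\t"
                    f"{round_half_up(ev.precision, 2):.2f}\t"
                    + (f"{missed}\t{len(rec.recovered)}\t{rec.rate}\n"
                       if rec else "\t\t\n")
                )

    with open(os.path.join(outdir, "zygosity_ratios.tsv"), "w") as fh:
        fh.write("coverage\tsubset\tn_hom\tn_het\tratio\n")
        for cov in covs:
            r = sweep_results[cov]
            for subset in ("recalled", "missed"):
                z = r[f"zygosity_{subset}"]
                ratio = f"{z.n_hom / z.n_het:.2f}" if z.n_het else "NA"
                fh.write(f"{cov}\t{subset}\t{z.n_hom}\t{z.n_het}\t{ratio}\n")

    with open(os.path.join(outdir, "nx_curves.tsv"), "w") as fh:
        fh.write("coverage\tx\tlength\n")
        for cov in covs:
            for x, ln in sweep_results[cov]["nx_curve"].points:
                fh.write(f"{cov}\t{x}\t{ln}\n")
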