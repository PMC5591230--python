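"""End-to-end orchestration of the coverage-sweep experiment, plus the CLI.

``run_sweep`` drives the whole benchmark from one config: generate the
synthetic diploid genome once, then for each read coverage simulate one
read set, run the alignment arm (map reads, pileup, genotype) and the
assembly arm (assemble, map contigs, extract mismatches) on the *same*
reads, and evaluate both call sets against the same truth — the paired
design that makes the two arms directly comparable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
from dataclasses import dataclass, field

from . import asmqc, callers, dbgasm, evalkit, readsim, seedalign, simgenome
from .errors import AsmbenchError

log = logging.getLogger("asmbench")


@dataclass
class SweepConfig:
    """Desk-scale defaults: a 200 kb diploid genome with 1,000 spiked SNVs
    and 50 indel confounders, swept from 2X to 50X read coverage."""

    genome_length: int = 200_000
    gc: float = 0.5
    n_genes: int = 20
    mean_exons: float = 4.0
    n_snv: int = 1000
    n_indel: int = 50
    het_fraction: float = 0.6
    min_spacing: int = 150
    coverages: list[float] = field(default_factory=lambda: [2, 5, 10, 15, 20, 30, 50])
    read_length: int = 100
    frag_mean: int = 350
    frag_sd: int = 50
    error_rate: float = 0.002
    k: int = 31
    min_count: int = 2
    max_tip_length: int | None = None  # defaults to 2k
    min_contig_length: int = 100
    k_seed: int = 15
    read_band: int = 12
    contig_band: int = 50
    min_depth: int = 4
    min_alt_count: int = 2
    het_band: tuple[float, float] = (0.2, 0.8)
    high_fraction: float = 0.8
    n_confidence_blocks: int = 10
    seed: int = 42
    outdir: str = "sweep_out"
    write_fastq: bool = True

    @classmethod
    def from_file(cls, path) -> "SweepConfig":
        """Flat key=value config file; '#' starts a comment."""
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in fields:
                    raise AsmbenchError(f"unknown config key: {key}")
                if key == "coverages":
                    kwargs[key] = [float(x) for x in val.split(",")]
                elif key == "het_band":
                    lo, hi = val.split(",")
                    kwargs[key] = (float(lo), float(hi))
                elif key in ("outdir",):
                    kwargs[key] = val
                elif key == "write_fastq":
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                elif key == "max_tip_length":
                    kwargs[key] = None if val.lower() == "none" else int(val)
                else:
                    typ = type(getattr(cls(), key))
                    kwargs[key] = typ(val)
        return cls(**kwargs)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except AsmbenchError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise AsmbenchError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def reads_by_id(pairs) -> dict[str, str]:
    """Mate sequences keyed the way the mapper names them."""
    out = {}
    for p in pairs:
        out[f"{p.id}/1"] = p.mate1_seq
        out[f"{p.id}/2"] = p.mate2_seq
    return out


def run_alignment_arm(index, pairs, reference, cfg: SweepConfig):
    """Map reads, pile up, genotype: the alignment-based call set."""
    alignments = seedalign.map_read_pairs(index, pairs, band=cfg.read_band)
    pile = callers.pileup(alignments, reads_by_id(pairs), reference)
    calls = callers.call_snvs_from_pileup(
        pile,
        min_depth=cfg.min_depth,
        min_alt_count=cfg.min_alt_count,
        het_band=cfg.het_band,
    )
    return alignments, calls


def run_assembly_arm(index, pairs, reference, cfg: SweepConfig):
    """Assemble, map contigs, extract mismatches: the assembly call set."""
    reads = [m for p in pairs for m in (p.mate1_seq, p.mate2_seq)]
    contigs = dbgasm.assemble(
        reads,
        k=cfg.k,
        min_count=cfg.min_count,
        max_tip_length=cfg.max_tip_length,
        min_contig_length=cfg.min_contig_length,
    )
    contig_alignments = seedalign.map_contigs(index, contigs, band=cfg.contig_band)
    calls = callers.call_snvs_from_contigs(
        contig_alignments, {c.id: c.sequence for c in contigs}, reference
    )
    return contigs, contig_alignments, calls


def run_sweep(cfg: SweepConfig) -> dict:
    """Run the full experiment; returns per-coverage results and writes
    all artifacts (FASTA/FASTQ/VCF/TSV plus a run log) under cfg.outdir."""
    os.makedirs(cfg.outdir, exist_ok=True)
    run_log = os.path.join(cfg.outdir, "run.log")
    handler = logging.FileHandler(run_log, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_sweep_inner(cfg)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_sweep_inner(cfg: SweepConfig) -> dict:
    from . import __version__

    log.info("asmbench %s", __version__)
    log.info("config: %s", json.dumps(dataclasses.asdict(cfg), default=str))

    genome = simgenome.generate_reference(cfg.genome_length, cfg.gc, seed=cfg.seed)
    gene_model = simgenome.generate_gene_model(
        genome, cfg.n_genes, cfg.mean_exons, seed=cfg.seed + 1
    )
    truth = simgenome.sample_truth_variants(
        genome,
        gene_model,
        n_snv=cfg.n_snv,
        n_indel=cfg.n_indel,
        het_fraction=cfg.het_fraction,
        min_spacing=cfg.min_spacing,
        seed=cfg.seed + 2,
    )
    template = simgenome.build_diploid_template(genome, truth, seed=cfg.seed + 3)
    confidence = simgenome.make_confidence_bed(
        genome, cfg.high_fraction, cfg.n_confidence_blocks, seed=cfg.seed + 4
    )
    truth_snvs = [v for v in truth if v.vtype == "SNV"]

    simgenome.write_fasta(genome, os.path.join(cfg.outdir, "reference.fa"))
    simgenome.write_truth_vcf(truth, os.path.join(cfg.outdir, "truth.vcf"))
    simgenome.write_gene_bed12(
        gene_model, genome.name, os.path.join(cfg.outdir, "genes.bed")
    )
    simgenome.write_bed(
        confidence, genome.name, os.path.join(cfg.outdir, "confidence.bed")
    )

    index = seedalign.build_index(genome, k_seed=cfg.k_seed)
    by_pos = {v.pos: v for v in truth_snvs}
    results: dict = {}

    for cov in cfg.coverages:
        log.info("coverage %sX: simulating reads", cov)
        pairs = readsim.simulate_read_pairs(
            template,
            coverage=cov,
            read_length=cfg.read_length,
            frag_mean=cfg.frag_mean,
            frag_sd=cfg.frag_sd,
            error_rate=cfg.error_rate,
            seed=cfg.seed + 100 + int(cov * 10),
        )
        tag = f"cov{cov:g}x"
        if cfg.write_fastq:
            readsim.write_fastq_pair(
                pairs,
                os.path.join(cfg.outdir, f"reads_{tag}_1.fq"),
                os.path.join(cfg.outdir, f"reads_{tag}_2.fq"),
            )

        log.info("coverage %sX: alignment arm", cov)
        _, aln_calls = run_alignment_arm(index, pairs, genome, cfg)
        callers.write_calls_vcf(
            aln_calls, os.path.join(cfg.outdir, f"calls_alignment_{tag}.vcf"),
            source="alignment",
        )

        log.info("coverage %sX: assembly arm", cov)
        contigs, contig_alignments, asm_calls = run_assembly_arm(
            index, pairs, genome, cfg
        )
        dbgasm.write_contigs_fasta(
            contigs, os.path.join(cfg.outdir, f"contigs_{tag}.fa")
        )
        callers.write_calls_vcf(
            asm_calls, os.path.join(cfg.outdir, f"calls_assembly_{tag}.vcf"),
            source="assembly",
        )

        log.info("coverage %sX: evaluation", cov)
        aln_eval = evalkit.match_calls(truth_snvs, aln_calls)
        asm_eval = evalkit.match_calls(truth_snvs, asm_calls)
        rec = evalkit.recovery(truth_snvs, aln_eval, asm_calls)
        recalled = [by_pos[k[1]] for k in asm_eval.tp_set]
        missed = [by_pos[k[1]] for k in asm_eval.fn_set]
        report = asmqc.feature_coverage(contig_alignments, gene_model, genome)
        results[cov] = {
            "alignment_eval": aln_eval,
            "assembly_eval": asm_eval,
            "recovery": rec,
            "zygosity_recalled": evalkit.zygosity_ratio(recalled),
            "zygosity_missed": evalkit.zygosity_ratio(missed),
            "assembly_summary": asmqc.assembly_summary(contigs),
            "genome_fraction": report.genome_fraction,
            "gene_counts": report.gene_counts,
            "exon_counts": report.exon_counts,
            "nx_curve": asmqc.nx_curve(contigs) if contigs else asmqc.NxCurve([], 0),
            "region_strata": evalkit.stratify_by_region(
                aln_eval, gene_model, genome.length
            ),
            "confidence": evalkit.stratify_by_confidence(aln_eval, confidence),
        }
        log.info(
            "coverage %sX: alignment recall %.4f, assembly recall %.4f",
            cov, aln_eval.recall, asm_eval.recall,
        )

    evalkit.report_tables(results, cfg.outdir)
    results["_meta"] = {
        "genome": genome,
        "gene_model": gene_model,
        "truth": truth,
        "template": template,
        "confidence": confidence,
    }
    return results


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

import click  # noqa: E402


@click.group()
def main():
    """Alignment-based vs assembly-based SNV calling benchmark."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(message)s")


@main.command()
@click.option("--length", default=200_000, show_default=True)
@click.option("--gc", default=0.5, show_default=True)
@click.option("--n-genes", default=20, show_default=True)
@click.option("--n-snv", default=1000, show_default=True)
@click.option("--n-indel", default=50, show_default=True)
@click.option("--het-fraction", default=0.6, show_default=True)
@click.option("--min-spacing", default=150, show_default=True)
@click.option("--coverage", default=30.0, show_default=True)
@click.option("--read-length", default=100, show_default=True)
@click.option("--frag-mean", default=350, show_default=True)
@click.option("--frag-sd", default=50, show_default=True)
@click.option("--error-rate", default=0.002, show_default=True)
@click.option("--seed", default=42, show_default=True)
@click.option("--out", required=True, type=click.Path())
def simulate(length, gc, n_genes, n_snv, n_indel, het_fraction, min_spacing,
             coverage, read_length, frag_mean, frag_sd, error_rate, seed, out):
    """Generate reference, truth set, diploid template and paired FASTQ."""
    os.makedirs(out, exist_ok=True)
    genome = simgenome.generate_reference(length, gc, seed=seed)
    gene_model = simgenome.generate_gene_model(genome, n_genes, seed=seed + 1)
    truth = simgenome.sample_truth_variants(
        genome, gene_model, n_snv=n_snv, n_indel=n_indel,
        het_fraction=het_fraction, min_spacing=min_spacing, seed=seed + 2,
    )
    template = simgenome.build_diploid_template(genome, truth, seed=seed + 3)
    confidence = simgenome.make_confidence_bed(genome, seed=seed + 4)
    pairs = readsim.simulate_read_pairs(
        template, coverage, read_length=read_length, frag_mean=frag_mean,
        frag_sd=frag_sd, error_rate=error_rate, seed=seed + 5,
    )
    simgenome.write_fasta(genome, os.path.join(out, "reference.fa"))
    simgenome.write_truth_vcf(truth, os.path.join(out, "truth.vcf"))
    simgenome.write_gene_bed12(gene_model, genome.name, os.path.join(out, "genes.bed"))
    simgenome.write_bed(confidence, genome.name, os.path.join(out, "confidence.bed"))
    readsim.write_fastq_pair(
        pairs, os.path.join(out, "reads_1.fq"), os.path.join(out, "reads_2.fq")
    )
    click.echo(f"wrote {len(pairs)} read pairs to {out}")


@main.command()
@click.option("--reads1", required=True, type=click.Path(exists=True))
@click.option("--reads2", required=True, type=click.Path(exists=True))
@click.option("-k", default=31, show_default=True)
@click.option("--min-count", default=2, show_default=True)
@click.option("--max-tip-length", default=None, type=int)
@click.option("--min-contig-length", default=100, show_default=True)
@click.option("--out", required=True, type=click.Path())
def assemble(reads1, reads2, k, min_count, max_tip_length, min_contig_length, out):
    """Assemble paired FASTQ into contigs (FASTA)."""
    reads = [s for _, s in readsim.read_fastq(reads1)]
    reads += [s for _, s in readsim.read_fastq(reads2)]
    contigs = dbgasm.assemble(
        reads, k=k, min_count=min_count, max_tip_length=max_tip_length,
        min_contig_length=min_contig_length,
    )
    dbgasm.write_contigs_fasta(contigs, out)
    s = asmqc.assembly_summary(contigs)
    click.echo(f"{s['n_contigs']} contigs, total {s['total_length']} bp, "
               f"N50 {s['n50']}")


@main.command("map")
@click.option("--reference", "ref_path", required=True, type=click.Path(exists=True))
@click.option("--query", required=True, type=click.Path(exists=True),
              help="FASTA or FASTQ of queries")
@click.option("--mode", type=click.Choice(["reads", "contigs"]), default="reads",
              show_default=True)
@click.option("--out", required=True, type=click.Path())
def map_cmd(ref_path, query, mode, out):
    """Map reads or contigs to the reference; writes an alignment TSV."""
    refs = simgenome.read_fasta(ref_path)
    index = seedalign.build_index(refs)
    if query.endswith((".fq", ".fastq")):
        queries = readsim.read_fastq(query)
    else:
        queries = list(simgenome.read_fasta(query).items())
    band = 12 if mode == "reads" else 50
    records = []
    for qid, seq in queries:
        records.extend(seedalign.map_sequence(index, seq, query_id=qid, band=band))
    seedalign.write_alignments_tsv(records, out)
    click.echo(f"mapped {len(records)}/{len(queries)} queries")


@main.command("call-pileup")
@click.option("--reference", "ref_path", required=True, type=click.Path(exists=True))
@click.option("--reads1", required=True, type=click.Path(exists=True))
@click.option("--reads2", required=True, type=click.Path(exists=True))
@click.option("--min-depth", default=4, show_default=True)
@click.option("--min-alt-count", default=2, show_default=True)
@click.option("--out", required=True, type=click.Path())
def call_pileup(ref_path, reads1, reads2, min_depth, min_alt_count, out):
    """Alignment arm: map reads and genotype from the pileup."""
    refs = simgenome.read_fasta(ref_path)
    index = seedalign.build_index(refs)
    seqs = {}
    records = []
    for path, mate in ((reads1, 1), (reads2, 2)):
        for qid, seq in readsim.read_fastq(path):
            qid = qid if qid.endswith(f"/{mate}") else f"{qid}/{mate}"
            seqs[qid] = seq
            records.extend(seedalign.map_sequence(index, seq, query_id=qid))
    pile = callers.pileup(records, seqs, refs)
    calls = callers.call_snvs_from_pileup(
        pile, min_depth=min_depth, min_alt_count=min_alt_count
    )
    callers.write_calls_vcf(calls, out, source="alignment")
    click.echo(f"{len(calls)} SNV calls")


@main.command("call-contigs")
@click.option("--reference", "ref_path", required=True, type=click.Path(exists=True))
@click.option("--contigs", "contig_path", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def call_contigs(ref_path, contig_path, out):
    """Assembly arm: map contigs and extract mismatch SNVs."""
    refs = simgenome.read_fasta(ref_path)
    index = seedalign.build_index(refs)
    contigs = simgenome.read_fasta(contig_path)
    records = []
    for cid, seq in contigs.items():
        records.extend(
            seedalign.map_sequence(index, seq, query_id=cid, band=50, stride=30)
        )
    calls = callers.call_snvs_from_contigs(records, contigs, refs)
    callers.write_calls_vcf(calls, out, source="assembly")
    click.echo(f"{len(calls)} SNV calls")


@main.command()
@click.option("--reference", "ref_path", required=True, type=click.Path(exists=True))
@click.option("--contigs", "contig_path", required=True, type=click.Path(exists=True))
@click.option("--genes", "genes_path", type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def qc(ref_path, contig_path, genes_path, out):
    """Assembly QC: Nx curve, summary, genome/gene coverage."""
    refs = simgenome.read_fasta(ref_path)
    name, seq = next(iter(refs.items()))
    genome = simgenome.ReferenceGenome(name, seq)
    contigs = simgenome.read_fasta(contig_path)
    index = seedalign.build_index(refs)
    records = []
    for cid, cseq in contigs.items():
        records.extend(
            seedalign.map_sequence(index, cseq, query_id=cid, band=50, stride=30)
        )
    lens = [len(s) for s in contigs.values()]
    s = asmqc.assembly_summary(lens)
    frac = asmqc.genome_coverage(records, genome)
    os.makedirs(out, exist_ok=True)
    asmqc.write_nx_tsv(asmqc.nx_curve(lens), os.path.join(out, "nx_curve.tsv"))
    with open(os.path.join(out, "qc_summary.tsv"), "w") as fh:
        fh.write("n_contigs\ttotal_length\tmax_length\tn50\tgenome_fraction\n")
        fh.write(f"{s['n_contigs']}\t{s['total_length']}\t{s['max_length']}\t"
                 f"{s['n50']}\t{frac:.4f}\n")
    if genes_path:
        model = simgenome.read_gene_bed12(genes_path)
        rep = asmqc.feature_coverage(records, model, genome)
        with open(os.path.join(out, "gene_coverage.tsv"), "w") as fh:
            fh.write("gene\tstatus\n")
            for gid, st in rep.gene_status.items():
                fh.write(f"{gid}\t{st}\n")
    click.echo(f"genome fraction covered: {frac:.4f}")


@main.command()
@click.option("--truth", "truth_path", required=True, type=click.Path(exists=True))
@click.option("--calls", "calls_path", required=True, type=click.Path(exists=True))
@click.option("--calls-b", "calls_b_path", type=click.Path(exists=True),
              help="second call set for recovery analysis")
@click.option("--out", type=click.Path())
def evaluate(truth_path, calls_path, calls_b_path, out):
    """Compare a call set (and optionally a second) against the truth VCF."""
    truth = [v for v in simgenome.read_truth_vcf(truth_path) if v.vtype == "SNV"]
    calls = callers.read_calls_vcf(calls_path)
    ev = evalkit.match_calls(truth, calls)
    lines = [
        f"tp\t{ev.tp}", f"fp\t{ev.fp}", f"fn\t{ev.fn}",
        f"recall\t{evalkit.round_half_up(ev.recall, 2):.2f}",
        f"precision\t{evalkit.round_half_up(ev.precision, 2):.2f}",
    ]
    if calls_b_path:
        calls_b = callers.read_calls_vcf(calls_b_path, source="assembly")
        rec = evalkit.recovery(truth, ev, calls_b)
        lines += [f"missed\t{len(rec.missed)}", f"recovered\t{len(rec.recovered)}",
                  f"recovery_rate\t{rec.rate}%"]
    text = "\n".join(lines) + "\n"
    if out:
        with open(out, "w") as fh:
            fh.write(text)
    click.echo(text, nl=False)


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--seed", default=None, type=int, help="override the config seed")
@click.option("--out", default=None, type=click.Path(), help="override outdir")
@click.option("--threads", default=1, show_default=True,
              help="accepted for interface compatibility; execution is "
                   "single-threaded and results never depend on it")
def sweep(config_path, seed, out, threads):
    """Run the full coverage-sweep experiment."""
    cfg = SweepConfig.from_file(config_path) if config_path else SweepConfig()
    if seed is not None:
        cfg.seed = seed
    if out is not None:
        cfg.outdir = out
    results = run_sweep(cfg)
    for cov in cfg.coverages:
        r = results[cov]
        click.echo(
            f"{cov:g}X: alignment recall "
            f"{evalkit.round_half_up(r['alignment_eval'].recall, 2):.2f}, "
            f"assembly recall "
            f"{evalkit.round_half_up(r['assembly_eval'].recall, 2):.2f}, "
            f"recovery {r['recovery'].rate}%"
        )


if __name__ == "__main__":
    main()
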