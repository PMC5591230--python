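"""Minimal haplotype-collapsing de Bruijn assembler.

The assembler deliberately implements the consensus behaviour that makes
contig-level SNV calling lose heterozygous sites: after k-mer counting,
weak-node filtering and tip clipping, every simple two-branch bubble —
the graph signature of an isolated heterozygous SNV (or a recurrent
sequencing error) — is *popped*: the branch with the lower mean k-mer
count is deleted, ties broken lexicographically.  With balanced allele
coverage the alternate allele therefore survives in only about half the
bubbles, which is exactly the collapse mechanism whose downstream
consequences this package measures.

Graph representation: nodes are canonical k-mers (lexicographic min of a
k-mer and its reverse complement; k must be odd so no k-mer is its own
reverse complement).  Edges are implicit — two oriented k-mers are
adjacent when they overlap by k-1 bases and both endpoints survive in the
node set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seqs import BASES, decode_kmer_values, encode, kmer_values, revcomp
from .errors import InputError


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerTable:
    """Canonical k-mer occurrence counts."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class Contig:
    id: str
    sequence: str
    mean_kmer_coverage: float

    @property
    def length(self) -> int:
        return len(self.sequence)


class DBGraph:
    """de Bruijn graph over surviving canonical k-mers.

    Adjacency is evaluated on demand: ``successors(s)`` returns the
    spelled (oriented, possibly non-canonical) k-mers reachable from the
    oriented k-mer ``s`` by a one-base extension whose canonical form is
    present in the node set.
    """

    def __init__(self, k: int, nodes: dict[str, int]):
        self.k = k
        self.nodes = nodes  # canonical k-mer -> count

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.nodes

    def count_of(self, kmer: str) -> int:
        return self.nodes[canonical(kmer)]

    def successors(self, kmer: str) -> list[str]:
        suf = kmer[1:]
        return [suf + b for b in BASES if canonical(suf + b) in self.nodes]

    def predecessors(self, kmer: str) -> list[str]:
        pre = kmer[:-1]
        return [b + pre for b in BASES if canonical(b + pre) in self.nodes]

    def edges(self):
        """Yield oriented (u, v) pairs with exact (k-1)-overlap, u canonical."""
        for u in self.nodes:
            for v in self.successors(u):
                yield (u, v)

    def copy(self) -> "DBGraph":
        return DBGraph(self.k, dict(self.nodes))


def count_kmers(reads, k: int = 31) -> KmerTable:
    """Count every length-k window of every read under canonical form.

    ``reads`` is any iterable of ACGT strings (individual mates, not
    pairs).  k must be odd; the packed fast path supports k <= 31, longer
    odd k fall back to per-window counting.
    """
    if k % 2 == 0:
        raise InputError("k must be odd (canonical form is ill-defined otherwise)")
    if not 3 <= k <= 63:
        raise InputError("k must be within [3, 63]")
    if k > 31:
        return _count_kmers_slow(reads, k)

    chunk: list[str] = []
    chunk_bases = 0
    all_vals: list[np.ndarray] = []
    all_cnts: list[np.ndarray] = []

    def flush():
        nonlocal chunk, chunk_bases
        if not chunk:
            return
        blob = "N".join(chunk)
        fwd, rev, valid = kmer_values(encode(blob), k)
        canon = np.minimum(fwd, rev)[valid]
        vals, cnts = np.unique(canon, return_counts=True)
        all_vals.append(vals)
        all_cnts.append(cnts)
        chunk = []
        chunk_bases = 0

    for r in reads:
        if len(r) < k:
            continue
        chunk.append(r)
        chunk_bases += len(r)
        if chunk_bases >= 8_000_000:
            flush()
    flush()
    if not all_vals:
        return KmerTable(k=k, counts={})
    vals = np.concatenate(all_vals)
    cnts = np.concatenate(all_cnts)
    uvals, inv = np.unique(vals, return_inverse=True)
    ucnts = np.bincount(inv, weights=cnts).astype(np.int64)
    keys = decode_kmer_values(uvals, k)
    return KmerTable(k=k, counts=dict(zip(keys, ucnts.tolist())))


def _count_kmers_slow(reads, k: int) -> KmerTable:
    counts: dict[str, int] = {}
    for r in reads:
        for i in range(len(r) - k + 1):
            c = canonical(r[i : i + k])
            counts[c] = counts.get(c, 0) + 1
    return KmerTable(k=k, counts=counts)


def build_graph(table: KmerTable, min_count: int = 2) -> DBGraph:
    """Keep k-mers seen at least ``min_count`` times as graph nodes."""
    if min_count < 1:
        raise InputError("min_count must be >= 1")
    nodes = {km: c for km, c in table.counts.items() if c >= min_count}
    return DBGraph(table.k, nodes)


# ---------------------------------------------------------------------------
# graph cleanup
# ---------------------------------------------------------------------------


def _unitigs(graph: DBGraph) -> list[list[str]]:
    """Maximal non-branching oriented chains, deterministically ordered.

    Every node appears in exactly one chain.  Cycles without a junction
    are broken at their smallest canonical k-mer.
    """
    visited: set[str] = set()
    chains: list[list[str]] = []
    for key in sorted(graph.nodes):
        if key in visited:
            continue
        chain = [key]
        members = {key}
        # extend right
        while True:
            succ = graph.successors(chain[-1])
            if len(succ) != 1:
                break
            nxt = succ[0]
            if canonical(nxt) in members or len(graph.predecessors(nxt)) != 1:
                break
            chain.append(nxt)
            members.add(canonical(nxt))
        # extend left
        while True:
            pred = graph.predecessors(chain[0])
            if len(pred) != 1:
                break
            prv = pred[0]
            if canonical(prv) in members or len(graph.successors(prv)) != 1:
                break
            chain.insert(0, prv)
            members.add(canonical(prv))
        visited |= members
        chains.append(chain)
    return chains


def clip_tips(graph: DBGraph, max_tip_length: int | None = None) -> DBGraph:
    """Remove short dead-end branches (tips), iterated to fixpoint.

    A chain is a tip when one end has no continuation, its length in
    bases (k + nodes - 1) is below ``max_tip_length`` (default 2k), and
    the junction it hangs off retains another continuation — so genuine
    chromosome ends are never clipped.
    """
    if max_tip_length is None:
        max_tip_length = 2 * graph.k
    if max_tip_length < graph.k:
        raise InputError("max_tip_length must be >= k")
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        for chain in _unitigs(g):
            if canonical(chain[0]) not in g.nodes:
                continue  # removed earlier in this pass
            length = g.k + len(chain) - 1
            if length >= max_tip_length:
                continue
            preds = g.predecessors(chain[0])
            succs = g.successors(chain[-1])
            dangling = None
            if not succs and preds:
                dangling = preds
            elif not preds and succs:
                dangling = [revcomp(s) for s in succs]
            if dangling is None:
                continue
            # attachment must keep an alternative branch
            if any(len(g.successors(p)) >= 2 for p in dangling):
                for km in chain:
                    g.nodes.pop(canonical(km), None)
                changed = True
    return g


def _walk_branch(graph: DBGraph, start: str, limit: int):
    """Follow a simple (in=out=1) chain from ``start``; return (internal, sink)."""
    internal = []
    cur = start
    seen = set()
    while (
        len(graph.predecessors(cur)) == 1
        and len(graph.successors(cur)) == 1
        and len(internal) < limit
    ):
        key = canonical(cur)
        if key in seen:
            return None, None  # cycle
        seen.add(key)
        internal.append(cur)
        cur = graph.successors(cur)[0]
    if not internal:
        return None, None
    if len(graph.predecessors(cur)) < 2:
        return None, None
    return internal, cur


def pop_bubbles(graph: DBGraph, max_branch: int | None = None) -> DBGraph:
    """Collapse simple two-branch bubbles onto their majority branch.

    For every oriented junction with exactly two outgoing branches whose
    internal paths are simple, equal-length and reconvergent on the same
    sink, the branch with the lower mean node count is deleted; on ties
    the branch spelling the lexicographically smaller added sequence
    survives.  Iterated to fixpoint.  An isolated heterozygous SNV forms
    exactly such a bubble with k internal nodes per branch.
    """
    if max_branch is None:
        max_branch = 3 * graph.k
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        for key in sorted(g.nodes):
            if key not in g.nodes:
                continue
            for src in (key, revcomp(key)):
                succs = sorted(g.successors(src))
                if len(succs) != 2:
                    continue
                walks = [_walk_branch(g, s, max_branch) for s in succs]
                (ia, sa), (ib, sb) = walks
                if ia is None or ib is None:
                    continue
                if sa != sb or len(ia) != len(ib):
                    continue
                keys_a = {canonical(x) for x in ia}
                keys_b = {canonical(x) for x in ib}
                if keys_a & keys_b:
                    continue
                sink_key = canonical(sa)
                if sink_key in keys_a or sink_key in keys_b or canonical(src) in (
                    keys_a | keys_b
                ):
                    continue
                mean_a = sum(g.nodes[x] for x in keys_a) / len(keys_a)
                mean_b = sum(g.nodes[x] for x in keys_b) / len(keys_b)
                seq_a = "".join(x[-1] for x in ia)
                seq_b = "".join(x[-1] for x in ib)
                if mean_a > mean_b:
                    loser = keys_b
                elif mean_b > mean_a:
                    loser = keys_a
                else:
                    loser = keys_b if seq_a <= seq_b else keys_a
                for km in loser:
                    g.nodes.pop(km, None)
                changed = True
                break  # re-examine this node's neighbourhood fresh
    return g


def extract_contigs(graph: DBGraph, min_contig_length: int = 100) -> list[Contig]:
    """Spell maximal non-branching paths into contigs.

    Contig sequences are normalised to the lexicographically smaller of
    the two strands, then ordered by length (descending) and sequence, so
    assemblies are reproducible without a seed.
    """
    out = []
    for chain in _unitigs(graph):
        seq = chain[0] + "".join(km[-1] for km in chain[1:])
        seq = min(seq, revcomp(seq))
        if len(seq) < min_contig_length:
            continue
        cov = float(np.mean([graph.nodes[canonical(km)] for km in chain]))
        out.append((seq, cov))
    out.sort(key=lambda t: (-len(t[0]), t[0]))
    return [
        Contig(id=f"contig_{i + 1}", sequence=seq, mean_kmer_coverage=cov)
        for i, (seq, cov) in enumerate(out)
    ]


def assemble(
    reads,
    k: int = 31,
    min_count: int = 2,
    max_tip_length: int | None = None,
    min_contig_length: int = 100,
) -> list[Contig]:
    """Full pipeline: count, filter, clip tips, pop bubbles, spell contigs."""
    table = count_kmers(reads, k=k)
    g = build_graph(table, min_count=min_count)
    g = clip_tips(g, max_tip_length=max_tip_length)
    g = pop_bubbles(g)
    return extract_contigs(g, min_contig_length=min_contig_length)


def write_contigs_fasta(contigs: list[Contig], path, width: int = 60):
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id} len={c.length} cov={c.mean_kmer_coverage:.2f}\n")
            for i in range(0, c.length, width):
                fh.write(c.sequence[i : i + width] + "\n")
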