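"""Shared seed-and-extend aligner for reads and contigs.

One engine serves both arms of the benchmark: short reads are mapped
end-to-end against the reference (the alignment-calling substrate) and
assembled contigs are mapped with a wider band (the contig-calling
substrate).  Seeds come from an exact k-mer index of the reference
forward strand; queries are tried on both strands, seed hits are
clustered by diagonal, chained, and the inter-anchor segments are closed
with a banded affine-gap dynamic program.

The ambiguity policy mirrors common MAPQ-0 handling and the
best-match-per-chromosome rule used for contigs: every query gets at
most one record, flagged ``unique=False`` when a different placement
ties the best score; non-unique records are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seqs import encode, kmer_values, revcomp
from .errors import InputError

SCORING = {"match": 1, "mismatch": -1, "gap_open": -2, "gap_extend": -1}
_NEG = -(10**9)

Cigar = tuple[tuple[str, int], ...]


@dataclass
class AlignmentRecord:
    query_id: str
    chrom: str
    ref_start: int  # 1-based
    strand: str  # '+' | '-'
    cigar: Cigar
    score: int
    unique: bool

    @property
    def ref_end(self) -> int:
        """1-based inclusive end on the reference."""
        return self.ref_start + cigar_ref_len(self.cigar) - 1


def cigar_query_len(cigar: Cigar) -> int:
    return sum(n for op, n in cigar if op in "=XI")


def cigar_ref_len(cigar: Cigar) -> int:
    return sum(n for op, n in cigar if op in "=XD")


def cigar_to_string(cigar: Cigar) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def score_cigar(cigar: Cigar, scoring=None) -> int:
    sc = scoring or SCORING
    total = 0
    for op, n in cigar:
        if op == "=":
            total += sc["match"] * n
        elif op == "X":
            total += sc["mismatch"] * n
        else:
            total += sc["gap_open"] + sc["gap_extend"] * (n - 1)
    return total


def _merge_ops(ops: list[tuple[str, int]]) -> Cigar:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return tuple(merged)


def banded_align(a: str, b: str, band: int, scoring=None) -> tuple[int, Cigar]:
    """Optimal global alignment of ``a`` vs ``b`` within a diagonal band.

    Gap costs are affine: the first base of a gap costs ``gap_open`` and
    each further base ``gap_extend``.  With ``band >= max(len(a),
    len(b))`` the result equals the unrestricted optimum.
    """
    sc = scoring or SCORING
    n, m = len(a), len(b)
    if band < abs(n - m):
        raise InputError("band narrower than the sequence length difference")
    if n == 0 and m == 0:
        return 0, ()
    W = 2 * band + 1
    off0 = band  # offset of j == i

    def row_arrays():
        return [_NEG] * W, [_NEG] * W, [_NEG] * W

    M_rows, E_rows, F_rows = [], [], []
    go, ge, sm, sx = sc["gap_open"], sc["gap_extend"], sc["match"], sc["mismatch"]

    for i in range(n + 1):
        M, E, F = row_arrays()
        lo = max(0, i - band)
        hi = min(m, i + band)
        for j in range(lo, hi + 1):
            o = j - i + off0
            if i == 0 and j == 0:
                M[o] = 0
                continue
            if i == 0:
                E[o] = go + ge * (j - 1)
                continue
            if j == 0:
                F[o] = go + ge * (i - 1)
                continue
            # E: gap consuming b ('D'), from (i, j-1) -> offset o-1 this row
            if o - 1 >= 0:
                h_left = max(M[o - 1], E[o - 1], F[o - 1])
                e_ext = E[o - 1] + ge if E[o - 1] > _NEG else _NEG
                e_open = h_left + go if h_left > _NEG else _NEG
                E[o] = max(e_open, e_ext)
            # F: gap consuming a ('I'), from (i-1, j) -> offset o+1 previous row
            if o + 1 < W:
                pM, pE, pF = M_rows[i - 1][o + 1], E_rows[i - 1][o + 1], F_rows[i - 1][o + 1]
                h_up = max(pM, pE, pF)
                f_ext = pF + ge if pF > _NEG else _NEG
                f_open = h_up + go if h_up > _NEG else _NEG
                F[o] = max(f_open, f_ext)
            # M: diagonal, from (i-1, j-1) -> same offset previous row
            dM, dE, dF = M_rows[i - 1][o], E_rows[i - 1][o], F_rows[i - 1][o]
            h_diag = max(dM, dE, dF)
            if h_diag > _NEG:
                M[o] = h_diag + (sm if a[i - 1] == b[j - 1] else sx)
        M_rows.append(M)
        E_rows.append(E)
        F_rows.append(F)

    o_end = m - n + off0
    finals = {
        "M": M_rows[n][o_end],
        "E": E_rows[n][o_end],
        "F": F_rows[n][o_end],
    }
    state = max(finals, key=lambda s: (finals[s], s))
    score = finals[state]
    if score <= _NEG:
        raise InputError("no alignment within the band")

    # traceback
    ops: list[tuple[str, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        o = j - i + off0
        if state == "M":
            ops.append(("=" if a[i - 1] == b[j - 1] else "X", 1))
            i, j = i - 1, j - 1
            o = j - i + off0
            vals = (M_rows[i][o], E_rows[i][o], F_rows[i][o])
            state = "MEF"[int(np.argmax(vals))]
        elif state == "E":
            ops.append(("D", 1))
            cur = E_rows[i][j - i + off0]
            j -= 1
            o = j - i + off0
            if E_rows[i][o] > _NEG and E_rows[i][o] + sc["gap_extend"] == cur:
                state = "E"
            else:
                vals = (M_rows[i][o], E_rows[i][o], F_rows[i][o])
                state = "MEF"[int(np.argmax(vals))]
        else:  # F
            cur = F_rows[i][j - i + off0]
            ops.append(("I", 1))
            i -= 1
            o = j - i + off0
            if F_rows[i][o] > _NEG and F_rows[i][o] + sc["gap_extend"] == cur:
                state = "F"
            else:
                vals = (M_rows[i][o], E_rows[i][o], F_rows[i][o])
                state = "MEF"[int(np.argmax(vals))]
        if i == 0 and j == 0:
            break
    ops.reverse()
    return score, _merge_ops(ops)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


class SeedIndex:
    """Exact k-mer index of the reference forward strand.

    k-mers occurring more than ``max_occ`` times across all chromosomes
    are masked as repetitive and never seed an alignment.
    """

    def __init__(self, references: dict[str, str], k_seed: int, max_occ: int = 100):
        if not 11 <= k_seed <= 31:
            raise InputError("k_seed must be within [11, 31]")
        self.k_seed = k_seed
        self.max_occ = max_occ
        self.references = references
        self.positions: dict[int, list[tuple[str, int]]] = {}
        self.n_windows = 0

        vals_all, chrom_ids, pos_all = [], [], []
        names = list(references)
        for ci, name in enumerate(names):
            seq = references[name]
            fwd, _, valid = kmer_values(encode(seq), k_seed)
            idx = np.nonzero(valid)[0]
            vals_all.append(fwd[idx])
            chrom_ids.append(np.full(idx.size, ci, dtype=np.int32))
            pos_all.append(idx.astype(np.int64))
            self.n_windows += int(idx.size)
        if not vals_all:
            return
        vals = np.concatenate(vals_all)
        cids = np.concatenate(chrom_ids)
        poss = np.concatenate(pos_all)
        order = np.argsort(vals, kind="stable")
        vals, cids, poss = vals[order], cids[order], poss[order]
        bounds = np.nonzero(np.diff(vals))[0] + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [vals.size]])
        for s, e in zip(starts.tolist(), ends.tolist()):
            if e - s > self.max_occ:
                continue
            self.positions[int(vals[s])] = [
                (names[int(cids[t])], int(poss[t])) for t in range(s, e)
            ]

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        codes = encode(kmer)
        if (codes >= 4).any():
            return []
        val = 0
        for c in codes.tolist():
            val = (val << 2) | c
        return self.positions.get(val, [])


def build_index(reference, k_seed: int = 15, max_occ: int = 100) -> SeedIndex:
    """Index a ReferenceGenome or a {name: sequence} mapping."""
    if hasattr(reference, "sequence"):
        refs = {reference.name: reference.sequence}
    else:
        refs = dict(reference)
    return SeedIndex(refs, k_seed=k_seed, max_occ=max_occ)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def _chain_cluster(cluster: list[tuple[int, int, int]], k: int):
    """Greedy collinear chain: anchors strictly ordered, non-overlapping."""
    chain = []
    prev_off = prev_pos = -(10**9)
    for diag, off, pos in sorted(cluster, key=lambda t: (t[1], t[2])):
        if off >= prev_off + k and pos >= prev_pos + k:
            chain.append((off, pos))
            prev_off, prev_pos = off, pos
    return chain


def _stitch(qs: str, ref: str, chain, k: int, pad: int, scoring):
    """Spell the full-query alignment through the anchor chain."""
    ops: list[tuple[str, int]] = []
    off0, pos0 = chain[0]
    r_start = max(0, pos0 - off0)

    def seg(qseg: str, rseg: str):
        if qseg == rseg:
            if qseg:
                ops.append(("=", len(qseg)))
            return
        band = abs(len(qseg) - len(rseg)) + pad
        _, cig = banded_align(qseg, rseg, band, scoring)
        ops.extend(cig)

    seg(qs[:off0], ref[r_start:pos0])
    ops.append(("=", k))
    prev_off, prev_pos = off0, pos0
    for off, pos in chain[1:]:
        seg(qs[prev_off + k : off], ref[prev_pos + k : pos])
        ops.append(("=", k))
        prev_off, prev_pos = off, pos
    tail_q = qs[prev_off + k :]
    r_end = min(len(ref), prev_pos + k + len(tail_q))
    seg(tail_q, ref[prev_pos + k : r_end])
    return r_start, _merge_ops(ops)


def map_sequence(
    index: SeedIndex,
    query: str,
    query_id: str = "query",
    min_seed_hits: int = 1,
    band: int = 12,
    stride: int | None = None,
    max_clusters: int = 8,
    max_unanchored: int = 2000,
    scoring=None,
) -> list[AlignmentRecord]:
    """Map one query; return [] (unmapped) or a single best record.

    The best-scoring placement across strands and chromosomes wins; a
    score tie with any other placement marks the record non-unique.
    Candidate chains leaving more than ``max_unanchored`` consecutive
    query bases without a seed anchor are discarded — a placement that
    sparse is never genuine and closing it by dynamic programming would
    be quadratic in the gap.
    """
    sc = scoring or SCORING
    k = index.k_seed
    if len(query) < k:
        return []
    if stride is None:
        stride = k
    offs = list(range(0, len(query) - k + 1, stride))
    if offs[-1] != len(query) - k:
        offs.append(len(query) - k)

    candidates = []
    for strand in "+-":
        qs = query if strand == "+" else revcomp(query)
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for off in offs:
            for chrom, pos in index.lookup(qs[off : off + k]):
                by_chrom.setdefault(chrom, []).append((pos - off, off, pos))
        for chrom, hits in by_chrom.items():
            hits.sort()
            clusters: list[list[tuple[int, int, int]]] = [[hits[0]]]
            for h in hits[1:]:
                if h[0] - clusters[-1][-1][0] > band:
                    clusters.append([h])
                else:
                    clusters[-1].append(h)
            for cl in clusters:
                chain = _chain_cluster(cl, k)
                if len(chain) < min_seed_hits:
                    continue
                gaps = [chain[0][0], len(qs) - (chain[-1][0] + k)]
                gaps += [b[0] - (a[0] + k) for a, b in zip(chain, chain[1:])]
                if max(gaps) > max_unanchored:
                    continue
                candidates.append((len(chain), strand, chrom, chain, qs))

    if not candidates:
        return []
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3][0]))
    ref_band = band
    results = {}
    for _, strand, chrom, chain, qs in candidates[:max_clusters]:
        ref = index.references[chrom]
        # fast path: the whole query matches on one diagonal
        off0, pos0 = chain[0]
        start = pos0 - off0
        if 0 <= start and start + len(qs) <= len(ref) and ref[start : start + len(qs)] == qs:
            cigar: Cigar = (("=", len(qs)),)
            r_start = start
        else:
            try:
                r_start, cigar = _stitch(qs, ref, chain, k, pad=6, scoring=sc)
            except InputError:
                continue
        if cigar_query_len(cigar) != len(qs):
            continue
        key = (chrom, r_start, strand)
        results[key] = (score_cigar(cigar, sc), cigar)

    if not results:
        return []
    best_key = max(results, key=lambda kk: (results[kk][0], kk))
    best_score = results[best_key][0]
    ties = [kk for kk, (s, _) in results.items() if s == best_score]
    unique = len(ties) == 1
    kk = min(ties)
    score, cigar = results[kk]
    return [
        AlignmentRecord(
            query_id=query_id,
            chrom=kk[0],
            ref_start=kk[1] + 1,
            strand=kk[2],
            cigar=cigar,
            score=score,
            unique=unique,
        )
    ]


def map_read_pairs(index: SeedIndex, pairs, band: int = 12) -> list[AlignmentRecord]:
    """Map both mates of every pair independently (end-to-end in query)."""
    records = []
    for p in pairs:
        for mate, seq in ((1, p.mate1_seq), (2, p.mate2_seq)):
            recs = map_sequence(index, seq, query_id=f"{p.id}/{mate}", band=band)
            records.extend(recs)
    return records


def map_contigs(index: SeedIndex, contigs, band: int = 50) -> list[AlignmentRecord]:
    """Map contigs with a wider band; one best record per contig."""
    records = []
    for c in contigs:
        recs = map_sequence(
            index, c.sequence, query_id=c.id, band=band, stride=2 * index.k_seed
        )
        records.extend(recs)
    return records


def write_alignments_tsv(records: list[AlignmentRecord], path):
    """SAM-flavoured TSV export for inspection."""
    with open(path, "w") as fh:
        fh.write("QNAME\tSTRAND\tRNAME\tPOS\tCIGAR\tSCORE\tUNIQUE\n")
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.strand}\t{r.chrom}\t{r.ref_start}\t"
                f"{cigar_to_string(r.cigar)}\t{r.score}\t{int(r.unique)}\n"
            )
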