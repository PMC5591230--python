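"""Paired-end short-read simulation from a diploid template.

Fragments are drawn from a normal length distribution (default
350 +/- 50 bp), each from a uniformly chosen haplotype, with mate 2
reverse-complemented — the standard FR library layout.  Sequencing noise
is a uniform per-base substitution process (no indel errors, constant
base quality); that is deliberately simpler than a real instrument
profile because only substitution noise matters to the mechanisms this
package studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seqs import BASES, revcomp
from .errors import InputError


@dataclass
class ReadPair:
    """One simulated fragment with its diagnostic truth origin."""

    id: str
    mate1_seq: str
    mate2_seq: str
    qual: str
    haplotype: int  # 0 or 1
    frag_start: int  # 0-based start on the source haplotype
    frag_len: int
    strand: str  # '+': mate1 is the forward end of the fragment


def simulate_read_pairs(
    template,
    coverage: float,
    read_length: int = 100,
    frag_mean: int = 350,
    frag_sd: int = 50,
    error_rate: float = 0.002,
    seed: int = 0,
    id_prefix: str = "sim",
) -> list[ReadPair]:
    """Simulate paired reads at ``coverage`` fold over the haploid reference.

    The pair count is ``round(coverage * reference_length / (2 * read_length))``
    so total sequenced bases match the quoted depth.  Fragment lengths are
    clamped to ``[read_length, 2 * frag_mean]``; fragments overhanging the
    haplotype end are re-drawn uniformly within bounds.
    """
    if coverage <= 0:
        raise InputError("coverage must be positive")
    haps = template.haplotypes
    if min(len(h) for h in haps) < read_length:
        raise InputError("template shorter than read length")
    ref_len = template.reference.length
    n_pairs = int(round(coverage * ref_len / (2 * read_length)))
    rng = np.random.default_rng(seed)

    hap_idx = rng.integers(0, 2, size=n_pairs)
    frag_lens = np.clip(
        np.rint(rng.normal(frag_mean, frag_sd, size=n_pairs)).astype(np.int64),
        read_length,
        2 * frag_mean,
    )
    # cap at haplotype length, then draw starts uniformly in the valid range
    hap_lens = np.array([len(haps[0]), len(haps[1])])
    frag_lens = np.minimum(frag_lens, hap_lens[hap_idx])
    starts = rng.integers(0, hap_lens[hap_idx] - frag_lens + 1)
    strands = rng.integers(0, 2, size=n_pairs)
    n_err = rng.binomial(read_length, error_rate, size=(n_pairs, 2))

    qual = "I" * read_length
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        h = int(hap_idx[i])
        s = int(starts[i])
        fl = int(frag_lens[i])
        frag = haps[h][s : s + fl]
        fwd = frag[:read_length]
        rev = revcomp(frag[fl - read_length :])
        if strands[i] == 0:
            m1, m2, strand = fwd, rev, "+"
        else:
            m1, m2, strand = rev, fwd, "-"
        if n_err[i, 0]:
            m1 = _inject_errors(m1, int(n_err[i, 0]), rng)
        if n_err[i, 1]:
            m2 = _inject_errors(m2, int(n_err[i, 1]), rng)
        pairs.append(
            ReadPair(
                id=f"{id_prefix}_{i}",
                mate1_seq=m1,
                mate2_seq=m2,
                qual=qual,
                haplotype=h,
                frag_start=s,
                frag_len=fl,
                strand=strand,
            )
        )
    return pairs


def _inject_errors(seq: str, n: int, rng) -> str:
    pos = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for p in pos:
        chars[p] = rng.choice([b for b in BASES if b != chars[p]])
    return "".join(chars)


def write_fastq_pair(pairs: list[ReadPair], path1, path2, embed_truth: bool = False):
    """Write the two mate files; ids get /1 and /2 suffixes.

    With ``embed_truth`` the source haplotype and fragment start are
    appended to the read name for downstream diagnostics.
    """
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            name = p.id
            if embed_truth:
                name = f"{p.id}|hap={p.haplotype}|start={p.frag_start}|strand={p.strand}"
            f1.write(f"@{name}/1\n{p.mate1_seq}\n+\n{p.qual}\n")
            f2.write(f"@{name}/2\n{p.mate2_seq}\n+\n{p.qual}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    """Plain FASTQ reader returning (id, sequence) tuples."""
    out = []
    with open(path) as fh:
        while True:
            h = fh.readline()
            if not h:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((h[1:].strip(), seq))
    return out
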