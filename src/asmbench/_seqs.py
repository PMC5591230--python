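"""Low-level sequence utilities shared across modules.

All heavy per-base work (k-mer extraction, base counting) runs on numpy
2-bit code arrays; strings are only materialised at module boundaries.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence to 2-bit codes (A=0, C=1, G=2, T=3); other bytes -> 4."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASE_BYTES[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def kmer_values(codes: np.ndarray, k: int):
    """Integer values of every k-window of ``codes`` on both strands.

    Returns ``(fwd, rev, valid)`` where ``fwd[i]`` packs
    ``codes[i:i+k]`` big-endian 2 bits per base, ``rev[i]`` is the value of
    the reverse complement of the same window, and ``valid[i]`` is False
    for windows containing a non-ACGT code.  Requires ``k <= 31`` so values
    fit in uint64.
    """
    if k > 31:
        raise ValueError("packed k-mer values support k <= 31")
    c = codes.astype(np.uint64)
    n = c.size - k + 1
    if n <= 0:
        e = np.empty(0, np.uint64)
        return e, e.copy(), np.empty(0, bool)
    fwd = np.zeros(n, np.uint64)
    rev = np.zeros(n, np.uint64)
    three = np.uint64(3)
    for j in range(k):
        w = c[j : j + n] & three
        fwd = (fwd << np.uint64(2)) | w
        rev |= (three - w) << np.uint64(2 * j)
    bad = (codes >= 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return fwd, rev, valid


def decode_kmer_values(vals: np.ndarray, k: int) -> list[str]:
    """Unpack uint64 k-mer values back to strings (vectorised)."""
    vals = np.asarray(vals, dtype=np.uint64)
    out = np.empty((vals.size, k), dtype=np.uint8)
    for j in range(k):
        shift = np.uint64(2 * (k - 1 - j))
        out[:, j] = _BASE_BYTES[((vals >> shift) & np.uint64(3)).astype(np.uint8)]
    flat = out.tobytes().decode("ascii")
    return [flat[i * k : (i + 1) * k] for i in range(vals.size)]
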