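"""Sequence utilities: encoding, reverse complement and k-mer indexing."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0,C=1,G=2,T=3; anything else -1."""
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(codes), -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        out[codes == ord(b)] = i
    return out


def kmer_ids(seq: str, k: int) -> np.ndarray:
    """ID of the k-mer starting at each position (base-4 big-endian);
    -1 where the k-mer contains a non-ACGT base.

    Length of the result is len(seq) - k + 1.
    """
    codes = encode_sequence(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for off in range(k):
        c = codes[off : off + n]
        valid &= c >= 0
        ids = ids * 4 + np.where(c >= 0, c, 0)
    ids[~valid] = -1
    return ids


def revcomp_id_table(k: int) -> np.ndarray:
    """Lookup table mapping each k-mer ID to its reverse complement's ID."""
    ids = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(ids)
    tmp = ids.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return rc


def id_to_kmer(kid: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[kid % 4])
        kid //= 4
    return "".join(reversed(out))


def kmer_to_id(kmer: str) -> int:
    kid = 0
    for b in kmer.upper():
        kid = kid * 4 + BASES.index(b)
    return kid
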