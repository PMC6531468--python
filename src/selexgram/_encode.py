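"""Integer encoding of RNA sequences and vectorized k-mer indexing.

Internal alphabet is A=0, C=1, G=2, U=3 (DNA input is canonicalized, T -> U).
A k-mer is addressed by its base-4 integer in [0, 4**k); because the base
order is alphabetical, k-mer indices sort lexicographically.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGU"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["T"] = _CODE["U"]

# byte-level lookup used for fast encoding; 255 marks non-ACGUT characters
_BYTE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _CODE.items():
    _BYTE_LUT[ord(_b)] = _i
    _BYTE_LUT[ord(_b.lower())] = _i


def canonicalize(seq: str) -> str:
    """Uppercase and convert T to U. Raises on characters outside {A,C,G,T,U,N}."""
    s = seq.upper().replace("T", "U")
    if set(s) - set("ACGUN"):
        bad = sorted(set(s) - set("ACGUN"))
        raise ValueError(f"sequence contains invalid characters: {bad}")
    return s


def encode(seq: str) -> np.ndarray:
    """Encode one sequence to a uint8 code vector; non-ACGU positions become 255."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _BYTE_LUT[arr]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _BYTE_LUT[buf.reshape(len(seqs), L)]


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for b in kmer.upper().replace("T", "U"):
        idx = idx * 4 + _CODE[b]
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def kmer_index_matrix(mat: np.ndarray, k: int) -> np.ndarray:
    """Sliding k-mer indices for every row of an (n, L) code matrix.

    Returns an (n, L-k+1) int32 matrix; windows touching an ambiguous
    position (code 255) get index -1.
    """
    n, L = mat.shape
    w = L - k + 1
    if w <= 0:
        return np.empty((n, 0), dtype=np.int32)
    ids = np.zeros((n, w), dtype=np.int32)
    bad = np.zeros((n, w), dtype=bool)
    for j in range(k):
        col = mat[:, j : j + w]
        bad |= col == 255
        ids = ids * 4 + np.where(col == 255, 0, col).astype(np.int32)
    ids[bad] = -1
    return ids


def row_presence_counts(ids: np.ndarray, universe: int) -> np.ndarray:
    """Count, per k-mer index, the number of rows containing it at least once.

    ``ids`` is an (n, w) matrix of k-mer indices (−1 = ignore). Each row
    contributes at most one count to each index (presence, not occurrences).
    """
    if ids.size == 0:
        return np.zeros(universe, dtype=np.int64)
    srt = np.sort(ids, axis=1)
    first = np.ones_like(srt, dtype=bool)
    first[:, 1:] = srt[:, 1:] != srt[:, :-1]
    vals = srt[first & (srt >= 0)]
    return np.bincount(vals, minlength=universe).astype(np.int64)


def group_by_length(seqs: list[str]) -> dict[int, list[str]]:
    groups: dict[int, list[str]] = {}
    for s in seqs:
        groups.setdefault(len(s), []).append(s)
    return groups
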