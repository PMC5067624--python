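"""2-bit k-mer encoding helpers shared by the read filter and the survey index.

k is limited to 31 so a k-mer packs into a uint64. Canonical form is the
numeric minimum of a k-mer and its reverse complement, which collapses
strand without caring which strand a read was sequenced from.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to 2-bit codes; non-ACGT bases get code 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_ints(seq: str, k: int) -> np.ndarray:
    """All forward k-mers of `seq` as uint64, windows containing N dropped."""
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    codes = encode_bases(seq)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    vals = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        vals = (vals << np.uint64(2)) | c.astype(np.uint64)
        bad |= c == 255
    vals[bad] = np.uint64(0)
    return np.where(bad, np.uint64(2**63), vals)  # sentinel never canonical-min


def revcomp_ints(kmers: np.ndarray, k: int) -> np.ndarray:
    """Reverse complement of packed k-mers."""
    out = np.zeros_like(kmers)
    v = kmers.copy()
    for _ in range(k):
        out = (out << np.uint64(2)) | (~v & np.uint64(3))
        v >>= np.uint64(2)
    return out


def canonical_ints(kmers: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(kmers, revcomp_ints(kmers, k))


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-collapsed) k-mers of a sequence."""
    fwd = kmer_ints(seq, k)
    good = fwd != np.uint64(2**63)
    return canonical_ints(fwd[good], k)


def canonical_spectrum(seqs, k: int) -> np.ndarray:
    """Sorted unique canonical k-mers across several sequences."""
    parts = [canonical_kmers(s, k) for s in seqs]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def shared_count(kmers: np.ndarray, spectrum: np.ndarray) -> int:
    """How many of `kmers` are present in a sorted `spectrum`."""
    if kmers.size == 0 or spectrum.size == 0:
        return 0
    idx = np.searchsorted(spectrum, kmers)
    idx[idx == spectrum.size] = spectrum.size - 1
    return int(np.count_nonzero(spectrum[idx] == kmers))
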