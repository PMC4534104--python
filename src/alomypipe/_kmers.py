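"""Low-level nucleotide utilities shared across modules.

2-bit k-mer packing (k <= 32) into uint64 keys and a sorted-array k-mer
position index over a set of sequences. Sequences are concatenated with
sentinel bytes so that windows spanning two sequences are never valid keys.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A,C,G,T -> 0..3; anything else 255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def pack_windows(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every length-k window of a code array into uint64 keys.

    Returns (keys, valid) where valid marks windows containing only ACGT.
    """
    if not 1 <= k <= 32:
        raise ValueError("k must be in 1..32 for 2-bit packing")
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    c = codes.astype(np.uint64)
    keys = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        keys = (keys << np.uint64(2)) | (c[j : j + n] & np.uint64(3))
    bad = (codes > 3).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return keys, valid


def pack_points(codes2d: np.ndarray, positions: np.ndarray, k: int) -> np.ndarray:
    """Pack k-mers starting at the given columns of a (n, L) code matrix.

    Returns a (n, len(positions)) uint64 array.
    """
    c = codes2d.astype(np.uint64)
    out = np.zeros((codes2d.shape[0], len(positions)), dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | (c[:, positions + j] & np.uint64(3))
    return out


class SeqIndex:
    """Sorted k-mer position index over named sequences.

    Positions are global offsets into the concatenation of all sequences,
    separated by `gap` sentinel bytes (value 255).
    """

    def __init__(self, seqs: dict[str, str], k: int, gap: int = 1):
        self.k = k
        self.gap = gap
        self.names = list(seqs)
        self.lengths = np.array([len(seqs[n]) for n in self.names], dtype=np.int64)
        parts = []
        starts = []
        pos = 0
        sep = np.full(gap, 255, dtype=np.uint8)
        for name in self.names:
            starts.append(pos)
            parts.append(encode(seqs[name]))
            pos += len(seqs[name]) + gap
            parts.append(sep)
        self.starts = np.array(starts, dtype=np.int64)
        self.codes = (
            np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        )
        keys, valid = pack_windows(self.codes, k)
        idx = np.nonzero(valid)[0]
        order = np.argsort(keys[idx], kind="stable")
        self._keys = keys[idx][order]
        self._pos = idx[order].astype(np.int64)

    def __len__(self) -> int:
        return len(self.names)

    def locate(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Global positions -> (sequence index, offset within sequence)."""
        si = np.searchsorted(self.starts, gpos, side="right") - 1
        return si, gpos - self.starts[si]

    def lookup_many(self, keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For each query key return [lo, hi) into the sorted position array."""
        lo = np.searchsorted(self._keys, keys, side="left")
        hi = np.searchsorted(self._keys, keys, side="right")
        return lo, hi

    def positions_slice(self, lo: int, hi: int) -> np.ndarray:
        return self._pos[lo:hi]

    def candidates(self, keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query index, global position) hits for an array of keys."""
        lo, hi = self.lookup_many(keys)
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        qi = np.repeat(np.arange(len(keys)), counts)
        # flat indices into self._pos for every hit of every query
        offsets = np.arange(total) - np.repeat(
            np.concatenate([[0], np.cumsum(counts)[:-1]]), counts
        )
        flat = np.repeat(lo, counts) + offsets
        return qi, self._pos[flat]


def shared_kmer_offsets(
    index: SeqIndex, query: str, step: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Candidate (target index, diagonal offset, query position) triples.

    The diagonal offset is target_offset - query_position: the position the
    query's first base would take on the target under an ungapped alignment.
    """
    k = index.k
    codes = encode(query)
    keys, valid = pack_windows(codes, k)
    qpos = np.arange(len(keys))[valid][::step]
    if len(qpos) == 0:
        return (
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
        )
    qi, gpos = index.candidates(keys[qpos])
    si, off = index.locate(gpos)
    qp = qpos[qi]
    return si, off - qp, qp
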