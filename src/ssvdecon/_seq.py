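"""Sequence encoding helpers shared across the package."""

from __future__ import annotations

import numpy as np

from ._kernels import kmer_codes

BASES = "ACGTN"

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_arr(encode(seq)))


def random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8)


class KmerIndex:
    """Exact k-mer lookup over a set of encoded sequences.

    Windows containing N (e.g. homology-masked panel bases) are never
    indexed, which is what makes competitive mapping deterministic: masked
    copies of a shared segment simply do not exist in the index.
    """

    def __init__(self, arrays: list[np.ndarray], k: int):
        self.k = int(k)
        self.arrays = arrays
        codes_all = []
        recs_all = []
        pos_all = []
        for rec_idx, arr in enumerate(arrays):
            codes, valid = kmer_codes(arr, self.k)
            if codes.size == 0:
                continue
            idx = np.nonzero(valid)[0]
            codes_all.append(codes[idx])
            pos_all.append(idx.astype(np.int64))
            recs_all.append(np.full(idx.size, rec_idx, dtype=np.int64))
        if codes_all:
            codes = np.concatenate(codes_all)
            pos = np.concatenate(pos_all)
            recs = np.concatenate(recs_all)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._pos = pos[order]
            self._recs = recs[order]
        else:
            self._codes = np.empty(0, np.int64)
            self._pos = np.empty(0, np.int64)
            self._recs = np.empty(0, np.int64)
        # code -> (start, stop) slice into the sorted arrays
        self._map: dict[int, tuple[int, int]] = {}
        if self._codes.size:
            uniq, starts = np.unique(self._codes, return_index=True)
            stops = np.append(starts[1:], self._codes.size)
            self._map = {
                int(c): (int(s), int(e))
                for c, s, e in zip(uniq.tolist(), starts.tolist(), stops.tolist())
            }

    def lookup(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (record_indices, positions) of every occurrence of ``code``."""
        span = self._map.get(int(code))
        if span is None:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        s, e = span
        return self._recs[s:e], self._pos[s:e]
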