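"""Coverage normalization and SNV aggregation over the vector genome.

Coverage is reported per base and normalized per 1,000: each base's read
count divided by the total coverage summed over the whole vector genome,
times 1,000 — so the normalized track always sums to 1,000 and is invariant
to sequencing depth. SNVs are aggregated by summing all alternative alleles
at a position (the combined variant contribution) and reported only when
present in at least half of the experimental samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np

from ._seq import encode


@dataclass
class CoverageTrack:
    ref_id: str
    raw: np.ndarray         # per-base read counts
    normalized: np.ndarray  # per-base, sums to 1000 when any read maps


@dataclass
class SNVCall:
    ref_id: str
    pos: int
    ref_base: str
    alt_fraction_combined: float
    per_sample_present: dict[str, bool]


def coverage(
    alignments: list[tuple[int, np.ndarray]] | list[tuple[int, int]],
    ref_len: int,
    ref_id: str = "rAAV_genome",
) -> CoverageTrack:
    """Per-base coverage from deduplicated alignments on the vector genome.

    ``alignments`` holds (ref_start, aligned segment) pairs — the segment may
    be the aligned read array or simply its length. raw[i] counts the
    alignments whose span covers base i; normalized[i] = 1000 * raw[i] / sum(raw).
    """
    diff = np.zeros(ref_len + 1, dtype=np.int64)
    for start, seg in alignments:
        length = seg if isinstance(seg, (int, np.integer)) else len(seg)
        lo = max(0, int(start))
        hi = min(ref_len, int(start) + int(length))
        if hi > lo:
            diff[lo] += 1
            diff[hi] -= 1
    raw = np.cumsum(diff[:-1])
    total = raw.sum()
    if total == 0:
        warnings.warn("zero total coverage; normalized track is all-zero", stacklevel=2)
        normalized = np.zeros(ref_len, dtype=float)
    else:
        normalized = 1000.0 * raw / total
    return CoverageTrack(ref_id=ref_id, raw=raw, normalized=normalized)


def pileup(
    alignments: list[tuple[int, np.ndarray]], ref_len: int
) -> np.ndarray:
    """(ref_len, 4) base-count matrix from ungapped aligned segments."""
    counts = np.zeros((ref_len, 4), dtype=np.int64)
    for start, seg in alignments:
        start = int(start)
        seg = np.asarray(seg)
        lo = max(0, start)
        hi = min(ref_len, start + seg.shape[0])
        sub = seg[lo - start : hi - start]
        ok = sub <= 3
        np.add.at(counts, (np.arange(lo, hi)[ok], sub[ok].astype(np.int64)), 1)
    return counts


def call_snvs(
    pileups: dict[str, np.ndarray],
    ref_seq: str,
    min_depth: int = 20,
    min_alt_fraction: float = 0.01,
    ref_id: str = "rAAV_genome",
) -> list[SNVCall]:
    """Aggregate SNVs across samples with the combined-alternative rule.

    Per sample and position with depth >= ``min_depth``, the alt fraction is
    (depth - ref-base count) / depth — all alternative alleles summed. A
    position is present in a sample when that fraction >= ``min_alt_fraction``;
    it is reported when present in >= ceil(S/2) of the S samples, with
    ``alt_fraction_combined`` the mean over the samples where it is present.
    """
    ref_arr = encode(ref_seq)
    L = ref_arr.shape[0]
    samples = list(pileups)
    S = len(samples)
    if S == 0:
        return []
    for sid, p in pileups.items():
        if p.shape != (L, 4):
            raise ValueError(f"pileup for {sid} has shape {p.shape}, expected ({L}, 4)")
    need = ceil(S / 2)
    present = np.zeros((S, L), dtype=bool)
    altfrac = np.zeros((S, L), dtype=float)
    valid_ref = ref_arr <= 3
    for si, sid in enumerate(samples):
        p = pileups[sid]
        depth = p.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            refc = np.where(valid_ref, p[np.arange(L), np.minimum(ref_arr, 3)], 0)
            af = np.where(depth > 0, (depth - refc) / np.maximum(depth, 1), 0.0)
        altfrac[si] = af
        present[si] = (depth >= min_depth) & (af >= min_alt_fraction) & valid_ref
    n_present = present.sum(axis=0)
    calls = []
    for pos in np.nonzero(n_present >= need)[0].tolist():
        mask = present[:, pos]
        combined = float(altfrac[mask, pos].mean())
        calls.append(
            SNVCall(
                ref_id=ref_id,
                pos=int(pos),
                ref_base="ACGTN"[ref_arr[pos]],
                alt_fraction_combined=combined,
                per_sample_present={s: bool(present[si, pos]) for si, s in enumerate(samples)},
            )
        )
    return calls


def read_density_by_reference(profile_counts: dict[str, int], ref_lengths: dict[str, int]) -> dict[str, float]:
    """Read density per reference segment, normalized to segment length and
    to the mean density across segments (a per-chromosome density stand-in
    when the producer genome is represented by a single segment)."""
    dens = {
        r: profile_counts.get(r, 0) / ref_lengths[r] for r in ref_lengths if ref_lengths[r] > 0
    }
    mean = np.mean(list(dens.values())) if dens else 0.0
    if mean == 0:
        return {r: 0.0 for r in dens}
    return {r: d / mean for r, d in dens.items()}
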