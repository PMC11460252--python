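"""Competitive read classification against the masked reference panel.

The pipeline mirrors a standard contamination-quantification workflow:
quality control (adapter trimming + length/quality filter), seed-and-extend
local alignment of each mate against every panel record, a species
assignment rule with an explicit ambiguity margin, UMI deduplication to
molecule counts, and the species percentage profile.

The aligner is an internal k-mer seed-and-extend implementation: exact
k-mer seeds against the unmasked panel grouped per diagonal, ungapped
extension scored match +1 / mismatch -4, and an affine-gap (open -6,
extend -1) local-alignment fallback when the ungapped window fails the
identity or length thresholds. Masked (N) panel bases are never seeded and
never match, so each homologous segment has exactly one competitive owner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import diag_best_window, gotoh_local, sw_locate
from ._seq import KmerIndex, encode, revcomp_arr
from .refpanel import ReferencePanel
from .simulate import DEFAULT_ADAPTER, ReadPair

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -4, -6, -1
ADAPTER_MATCH, ADAPTER_MISMATCH, ADAPTER_GAP = 1, -1, -2
ADAPTER_MIN_SCORE = 10

QC_REJECTED = "qc_rejected"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class AlignmentHit:
    ref_id: str
    pos: int          # 0-based leftmost ref coordinate of the aligned span
    strand: str       # '+' read aligns forward, '-' reverse-complemented
    score: int
    identity: float
    aln_len: int
    read_start: int   # on the oriented read
    read_end: int


@dataclass
class SpeciesProfile:
    """Percentage decomposition of one prep x DNase condition."""

    prep_id: str
    dnase: bool
    percentages: dict[str, float]
    n_total_dedup: int
    n_ambiguous: int

    def __post_init__(self):
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"percentages sum to {total}, expected 100")


class PanelIndex:
    """K-mer index over an (already masked) reference panel."""

    def __init__(self, panel: ReferencePanel):
        self.panel = panel
        self.k = panel.kmer_size
        self.arrays = [encode(r.sequence) for r in panel.records]
        self.ref_ids = [r.ref_id for r in panel.records]
        self.species = [r.species_label for r in panel.records]
        self.index = KmerIndex(self.arrays, self.k)


def trim_and_filter(
    pair: ReadPair,
    adapter_seq: str = DEFAULT_ADAPTER,
    min_len: int = 30,
    min_mean_q: float = 20.0,
) -> ReadPair | None:
    """3' adapter trim (local alignment) + length/quality filter.

    The adapter is located by Smith-Waterman (match 1, mismatch -1, gap -2);
    alignments scoring >= 10 are removed together with everything downstream.
    Returns None when either trimmed mate is shorter than ``min_len`` or has
    mean Phred quality below ``min_mean_q``.
    """
    if not adapter_seq:
        raise ValueError("adapter_seq must be non-empty")
    adapter_arr = encode(adapter_seq)

    def trim(seq: str, qual: str) -> tuple[str, str]:
        score, start, _end = sw_locate(
            encode(seq), adapter_arr, ADAPTER_MATCH, ADAPTER_MISMATCH, ADAPTER_GAP
        )
        if score >= ADAPTER_MIN_SCORE:
            return seq[:start], qual[:start]
        return seq, qual

    s1, q1 = trim(pair.seq1, pair.qual1)
    s2, q2 = trim(pair.seq2, pair.qual2)
    for s, q in ((s1, q1), (s2, q2)):
        if len(s) < min_len:
            return None
        mean_q = np.mean([ord(c) - 33 for c in q])
        if mean_q < min_mean_q:
            return None
    return ReadPair(pair.read_id, pair.umi, s1, s2, q1, q2, pair.truth_species)


def _align_oriented(
    arr: np.ndarray,
    pidx: PanelIndex,
    strand: str,
    min_identity: float,
    min_aln_len: int,
    seed_stride: int,
    max_candidates: int,
) -> list[AlignmentHit]:
    from ._kernels import kmer_codes

    k = pidx.k
    n = arr.shape[0]
    if n < k:
        return []
    codes, valid = kmer_codes(arr, k)
    offsets = list(range(0, n - k + 1, seed_stride))
    if offsets[-1] != n - k:
        offsets.append(n - k)
    votes: dict[tuple[int, int], int] = {}
    for off in offsets:
        if not valid[off]:
            continue
        recs, positions = pidx.index.lookup(int(codes[off]))
        for rec, pos in zip(recs.tolist(), positions.tolist()):
            key = (rec, pos - off)
            votes[key] = votes.get(key, 0) + 1
    if not votes:
        return []
    cands = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[:max_candidates]
    hits: list[AlignmentHit] = []
    for (rec, diag), _v in cands:
        ref_arr = pidx.arrays[rec]
        score, rs, re_, matches = diag_best_window(arr, ref_arr, diag, MATCH, MISMATCH)
        aln_len = re_ - rs
        if aln_len > 0 and aln_len >= min_aln_len and matches / aln_len >= min_identity:
            hits.append(
                AlignmentHit(
                    pidx.ref_ids[rec], diag + rs, strand, int(score),
                    matches / aln_len, aln_len, rs, re_,
                )
            )
            continue
        # gapped fallback on a banded segment around the seeded diagonal
        margin = 8
        seg_lo = max(0, diag - margin)
        seg_hi = min(ref_arr.shape[0], diag + n + margin)
        if seg_hi - seg_lo < min_aln_len:
            continue
        g = gotoh_local(arr, ref_arr[seg_lo:seg_hi], MATCH, MISMATCH, GAP_OPEN, GAP_EXT)
        gscore, a_s, a_e, b_s, _b_e, gmatches, galn = g
        if galn >= min_aln_len and galn > 0 and gmatches / galn >= min_identity:
            hits.append(
                AlignmentHit(
                    pidx.ref_ids[rec], seg_lo + b_s, strand, int(gscore),
                    gmatches / galn, galn, a_s, a_e,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.ref_id, h.pos))
    return hits


def align_read(
    seq: str,
    pidx: PanelIndex,
    min_identity: float = 0.90,
    min_aln_len: int = 50,
    seed_stride: int = 16,
    max_candidates: int = 8,
) -> list[AlignmentHit]:
    """Best local alignment hits of one read (both strands) per reference.

    Hits below ``min_identity`` or ``min_aln_len`` are discarded; at most one
    hit (the best) is kept per reference; the list is sorted by score
    descending. Reads shorter than the panel k-mer size return an empty list.
    """
    arr = encode(seq)
    hits = _align_oriented(
        arr, pidx, "+", min_identity, min_aln_len, seed_stride, max_candidates
    )
    hits += _align_oriented(
        revcomp_arr(arr), pidx, "-", min_identity, min_aln_len, seed_stride, max_candidates
    )
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.ref_id)
        if cur is None or (h.score, -h.pos) > (cur.score, -cur.pos):
            best[h.ref_id] = h
    return sorted(best.values(), key=lambda h: (-h.score, h.ref_id, h.pos))


def assign_pair(
    hits1: list[AlignmentHit],
    hits2: list[AlignmentHit],
    pidx: PanelIndex,
    score_margin: int = 5,
) -> tuple[str, str | None, int | None]:
    """Species assignment for one pair: (category, best_ref_id, position).

    The pair score per reference is the best mate-1 hit score plus the best
    mate-2 hit score (0 when a mate has no hit). The top species wins if it
    beats the runner-up species by at least ``score_margin``; within the
    margin the pair is ``ambiguous``; with no hit at all it is ``unmapped``.
    """
    by_ref1 = {h.ref_id: h for h in hits1}
    by_ref2 = {h.ref_id: h for h in hits2}
    refs = set(by_ref1) | set(by_ref2)
    if not refs:
        return UNMAPPED, None, None
    species_of = dict(zip(pidx.ref_ids, pidx.species))
    scores: dict[str, tuple[int, str]] = {}
    for ref in refs:
        sc = (by_ref1[ref].score if ref in by_ref1 else 0) + (
            by_ref2[ref].score if ref in by_ref2 else 0
        )
        sp = species_of[ref]
        if sp not in scores or sc > scores[sp][0]:
            scores[sp] = (sc, ref)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1][0], kv[0]))
    top_sp, (top_score, top_ref) = ranked[0]
    runner = ranked[1][1][0] if len(ranked) > 1 else 0
    if top_score - runner < score_margin:
        return AMBIGUOUS, None, None
    pos_cands = [h.pos for h in (by_ref1.get(top_ref), by_ref2.get(top_ref)) if h]
    return top_sp, top_ref, min(pos_cands)


def dedup_umi(assignments: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates to molecules.

    Mapped pairs identical in (UMI, category) with positions within 2 bp
    collapse to one record; UMIs within Hamming distance 1 at the same
    position also collapse. Unmapped/ambiguous pairs deduplicate on
    (UMI, first 30 nt of mate 1). Returns the surviving rows.
    """
    keep = np.zeros(len(assignments), dtype=bool)
    idx_of = {rid: i for i, rid in enumerate(assignments.index)}
    mapped = assignments[~assignments["category"].isin((UNMAPPED, AMBIGUOUS))]
    for (_cat, _umi), grp in mapped.groupby(["category", "umi"], sort=False):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        prev_pos = None
        for row_i in order:
            pos = int(grp["pos"].iloc[row_i])
            if prev_pos is None or pos - prev_pos > 2:
                keep[idx_of[grp.index[row_i]]] = True
            prev_pos = pos

    # Hamming-1 UMI merge among surviving molecules at (nearly) the same position
    surv = assignments[keep & ~assignments["category"].isin((UNMAPPED, AMBIGUOUS))]
    for _cat, grp in surv.groupby("category", sort=False):
        pos_arr = grp["pos"].to_numpy(dtype=np.int64)
        umis = grp["umi"].to_numpy()
        order = np.argsort(pos_arr, kind="stable")
        kept_window: list[tuple[int, str, object]] = []  # (pos, umi, row_label)
        for oi in order:
            p, u = int(pos_arr[oi]), umis[oi]
            kept_window = [(kp, ku, kr) for kp, ku, kr in kept_window if p - kp <= 2]
            merged = False
            for _kp, ku, _kr in kept_window:
                if len(ku) == len(u) and sum(a != b for a, b in zip(ku, u)) <= 1:
                    keep[idx_of[grp.index[oi]]] = False
                    merged = True
                    break
            if not merged:
                kept_window.append((p, u, grp.index[oi]))

    rest = assignments[assignments["category"].isin((UNMAPPED, AMBIGUOUS))]
    seen: set[tuple] = set()
    for rid, row in rest.iterrows():
        key = (row["umi"], row["category"], row["seq1"][:30])
        if key not in seen:
            seen.add(key)
            keep[idx_of[rid]] = True
    return assignments[keep]


def profile(
    assignments: pd.DataFrame,
    panel: ReferencePanel,
    prep_id: str,
    dnase: bool,
) -> SpeciesProfile:
    """Species percentage table from deduplicated assignments.

    Ambiguous pairs are folded into ``unmapped`` for the headline table (the
    count is retained in ``n_ambiguous``); QC-rejected pairs are expected to
    have been removed before alignment and are not in the denominator.
    """
    if len(assignments) == 0:
        raise ValueError("no assignments to profile")
    counts = assignments["category"].value_counts().to_dict()
    n_ambiguous = counts.pop(AMBIGUOUS, 0)
    counts[UNMAPPED] = counts.get(UNMAPPED, 0) + n_ambiguous
    total = len(assignments)
    categories = list(dict.fromkeys(panel.species_labels)) + [UNMAPPED]
    percentages = {c: 100.0 * counts.get(c, 0) / total for c in categories}
    return SpeciesProfile(
        prep_id=prep_id,
        dnase=dnase,
        percentages=percentages,
        n_total_dedup=total,
        n_ambiguous=int(n_ambiguous),
    )


@dataclass
class ClassificationResult:
    profile: SpeciesProfile
    assignments: pd.DataFrame          # post-dedup
    qc: dict[str, int]
    raav_alignments: list[tuple[int, np.ndarray]] = field(default_factory=list)
    annex: pd.DataFrame | None = None  # secondary-panel triage of unmapped reads


def classify_read_pairs(
    pairs: list[ReadPair],
    panel: ReferencePanel,
    prep_id: str = "prep",
    dnase: bool = False,
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = 30,
    min_mean_q: float = 20.0,
    min_identity: float = 0.90,
    min_aln_len: int = 50,
    score_margin: int = 5,
    secondary: list | None = None,
) -> ClassificationResult:
    """Full pipeline: QC -> align -> assign -> UMI dedup -> profile.

    ``raav_alignments`` collects, for every surviving molecule assigned to
    the vector genome, the (ref_start, oriented read segment) of each mate's
    accepted alignment — the input for coverage and SNV aggregation.
    """
    pidx = PanelIndex(panel)
    rows = []
    aln_store: dict[str, list[tuple[int, np.ndarray]]] = {}
    n_qc_rejected = 0
    raav_id = None
    for rec, sp in zip(pidx.ref_ids, pidx.species):
        if sp == "rAAV_genome":
            raav_id = rec
    for pair in pairs:
        trimmed = trim_and_filter(pair, adapter, min_len, min_mean_q)
        if trimmed is None:
            n_qc_rejected += 1
            continue
        hits1 = align_read(trimmed.seq1, pidx, min_identity, min_aln_len)
        hits2 = align_read(trimmed.seq2, pidx, min_identity, min_aln_len)
        category, ref_id, pos = assign_pair(hits1, hits2, pidx, score_margin)
        rows.append(
            (pair.read_id, pair.umi, category, ref_id, -1 if pos is None else pos,
             trimmed.seq1)
        )
        if ref_id == raav_id:
            segs = []
            for seq, hits in ((trimmed.seq1, hits1), (trimmed.seq2, hits2)):
                h = next((x for x in hits if x.ref_id == raav_id), None)
                if h is None:
                    continue
                arr = encode(seq)
                if h.strand == "-":
                    arr = revcomp_arr(arr)
                segs.append((h.pos, arr[h.read_start : h.read_end]))
            aln_store[pair.read_id] = segs

    assignments = pd.DataFrame(
        rows, columns=["read_id", "umi", "category", "ref_id", "pos", "seq1"]
    )
    if len(assignments) == 0:
        raise ValueError("all read pairs were rejected by QC")
    deduped = dedup_umi(assignments)
    prof = profile(deduped, panel, prep_id, dnase)
    raav_alignments = [
        seg for rid in deduped["read_id"] for seg in aln_store.get(rid, ())
    ]
    qc = {
        "n_input": len(pairs),
        "n_qc_rejected": n_qc_rejected,
        "n_aligned_pairs": len(assignments),
        "n_dedup": len(deduped),
        "n_ambiguous": prof.n_ambiguous,
        "n_unmapped": int((deduped["category"] == UNMAPPED).sum()),
    }
    annex = None
    if secondary:
        unmapped_seqs = deduped.loc[
            deduped["category"].isin((UNMAPPED, AMBIGUOUS)), "seq1"
        ].tolist()
        annex = triage_unmapped(unmapped_seqs, secondary, min_identity, min_aln_len)
    return ClassificationResult(
        profile=prof, assignments=deduped, qc=qc,
        raav_alignments=raav_alignments, annex=annex,
    )


def triage_unmapped(
    seqs: list[str],
    secondary_records,
    min_identity: float = 0.90,
    min_aln_len: int = 50,
) -> pd.DataFrame:
    """Re-search unmapped reads against a secondary reference panel.

    Stand-in for a database search of the unmapped bucket: reports, per
    secondary reference, how many unmapped reads align to it. The annex never
    moves reads between headline categories.
    """
    from .refpanel import ReferencePanel

    sec_panel = ReferencePanel(records=list(secondary_records))
    pidx = PanelIndex(sec_panel)
    counts: dict[str, int] = {r.ref_id: 0 for r in sec_panel.records}
    n_hit = 0
    for seq in seqs:
        hits = align_read(seq, pidx, min_identity, min_aln_len)
        if hits:
            counts[hits[0].ref_id] += 1
            n_hit += 1
    rows = [(ref, c, 100.0 * c / len(seqs) if seqs else 0.0) for ref, c in counts.items()]
    return pd.DataFrame(rows, columns=["ref_id", "n_reads", "percent_of_unmapped"])
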