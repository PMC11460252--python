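"""Multi-species reference panel with cross-reference homology masking.

A vector prep is decomposed against a panel of candidate DNA sources: the
rAAV genome itself, the producer-cell genome, the packaging plasmids,
bacterial carryover, and controls. Several of these legitimately share
sequence — ITRs occur in both the vector genome and the vector plasmid
backbone, and homology arms are copied from the producer genome — so a read
from a shared segment would otherwise map equally well to several species.
The panel resolves this up front: every homologous segment is detected and
hard-masked (to N) in all but the highest-priority owner, so competitive
mapping has exactly one unmasked copy of every shared region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._kernels import diag_all_windows, kmer_codes
from ._seq import decode, encode, revcomp_arr

SPECIES_LABELS = (
    "rAAV_genome",
    "producer_genome",
    "helper_plasmid",
    "plasmid_backbone",
    "repcap_plasmid",
    "ecoli_genome",
    "baculovirus",
    "lambda_spike",
    "foreign",
)

#: Default priority ranks (1 = highest). Shared ITR/cassette sequence counts
#: toward the vector genome — the purity quantity of interest — and the
#: producer genome is ranked last so homology arms count as vector sequence.
DEFAULT_PRIORITY = {
    "rAAV_genome": 1,
    "plasmid_backbone": 2,
    "helper_plasmid": 3,
    "repcap_plasmid": 4,
    "lambda_spike": 5,
    "baculovirus": 6,
    "ecoli_genome": 7,
    "producer_genome": 8,
    "foreign": 9,
}

DEFAULT_KMER_SIZE = 21
MASK_SEED_K = 15
DEFAULT_MASK_MIN_LEN = 50
DEFAULT_MASK_MIN_IDENTITY = 0.90

# mismatch penalty for the ungapped mask extension; -9 against +1 makes a
# window score-positive exactly when its identity exceeds 0.9
_MASK_MISMATCH = -9


@dataclass(frozen=True)
class ReferenceRecord:
    """One species-labelled reference sequence with its priority rank."""

    ref_id: str
    species_label: str
    sequence: str
    priority: int

    def __post_init__(self):
        if self.species_label not in SPECIES_LABELS:
            raise ValueError(f"unknown species_label {self.species_label!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.ref_id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MaskInterval:
    """Homologous segment masked on the lower-priority record.

    Coordinates are 0-based half-open on ``target_ref``.
    """

    target_ref: str
    start: int
    end: int
    source_ref: str
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferencePanel:
    """Post-masking panel: records with masked bases set to N."""

    records: list[ReferenceRecord]
    masks: list[MaskInterval] = field(default_factory=list)
    kmer_size: int = DEFAULT_KMER_SIZE

    def record(self, ref_id: str) -> ReferenceRecord:
        for r in self.records:
            if r.ref_id == ref_id:
                return r
        raise KeyError(ref_id)

    def by_species(self, species_label: str) -> ReferenceRecord:
        hits = [r for r in self.records if r.species_label == species_label]
        if len(hits) != 1:
            raise KeyError(f"{len(hits)} records with species {species_label}")
        return hits[0]

    @property
    def species_labels(self) -> list[str]:
        return [r.species_label for r in self.records]


def _check_records(records: list[ReferenceRecord]) -> None:
    ids = [r.ref_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ref_ids: {dup}")


def find_shared_regions(
    records: list[ReferenceRecord],
    mask_min_len: int = DEFAULT_MASK_MIN_LEN,
    mask_min_identity: float = DEFAULT_MASK_MIN_IDENTITY,
) -> list[MaskInterval]:
    """Detect homologous segments between distinct records.

    Shared-k-mer seeding (k=15, both strands) followed by ungapped extension
    along each seeded diagonal; windows of aligned length >= mask_min_len and
    identity >= mask_min_identity are reported on the LOWER-priority record
    of each pair, merged per (target, source) when overlapping.
    """
    _check_records(records)
    if mask_min_len < MASK_SEED_K:
        raise ValueError(f"mask_min_len must be >= seed size {MASK_SEED_K}")
    usable = []
    for r in records:
        if len(r) < mask_min_len:
            warnings.warn(
                f"record {r.ref_id} shorter than mask_min_len; skipped", stacklevel=2
            )
        else:
            usable.append(r)

    arrs = {r.ref_id: encode(r.sequence) for r in usable}
    kdata = {}
    for r in usable:
        codes, valid = kmer_codes(arrs[r.ref_id], MASK_SEED_K)
        idx = np.nonzero(valid)[0]
        c = codes[idx]
        order = np.argsort(c, kind="stable")
        kdata[r.ref_id] = (c[order], idx[order].astype(np.int64))

    intervals: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    buf = np.empty((256, 3), dtype=np.int64)
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            if a.priority == b.priority:
                # deterministic tie-break: lexicographically smaller id wins
                source, target = sorted((a, b), key=lambda r: r.ref_id)
            elif a.priority < b.priority:
                source, target = a, b
            else:
                source, target = b, a
            t_arr = arrs[target.ref_id]
            t_codes, t_pos = kdata[target.ref_id]
            for oriented in (arrs[source.ref_id], revcomp_arr(arrs[source.ref_id])):
                s_codes, s_valid = kmer_codes(oriented, MASK_SEED_K)
                s_idx = np.nonzero(s_valid)[0]
                sc = s_codes[s_idx]
                so = np.argsort(sc, kind="stable")
                sc, sp = sc[so], s_idx[so].astype(np.int64)
                shared = np.intersect1d(t_codes, sc, assume_unique=False)
                if shared.size == 0:
                    continue
                diags: set[int] = set()
                for code in shared.tolist():
                    tl = np.searchsorted(t_codes, code, side="left")
                    tr = np.searchsorted(t_codes, code, side="right")
                    sl = np.searchsorted(sc, code, side="left")
                    sr = np.searchsorted(sc, code, side="right")
                    for tp in t_pos[tl:tr].tolist():
                        for spp in sp[sl:sr].tolist():
                            diags.add(spp - tp)
                for d in sorted(diags):
                    n = diag_all_windows(
                        t_arr, oriented, d, 1, _MASK_MISMATCH, mask_min_len, buf
                    )
                    for w in range(n):
                        ws, we, wm = int(buf[w, 0]), int(buf[w, 1]), int(buf[w, 2])
                        ident = wm / (we - ws)
                        if ident >= mask_min_identity:
                            intervals.setdefault(
                                (target.ref_id, source.ref_id), []
                            ).append((ws, we, wm))

    out: list[MaskInterval] = []
    for (target_id, source_id), wins in intervals.items():
        wins.sort()
        merged: list[list[int]] = []
        for ws, we, wm in wins:
            if merged and ws <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], we)
                merged[-1][2] = max(merged[-1][2], wm)
            else:
                merged.append([ws, we, wm])
        for ws, we, wm in merged:
            out.append(
                MaskInterval(
                    target_ref=target_id,
                    start=ws,
                    end=we,
                    source_ref=source_id,
                    identity=round(min(1.0, wm / (we - ws)), 4),
                )
            )
    out.sort(key=lambda m: (m.target_ref, m.start, m.end, m.source_ref))
    return out


def apply_masks(
    records: list[ReferenceRecord],
    masks: list[MaskInterval],
    kmer_size: int = DEFAULT_KMER_SIZE,
) -> ReferencePanel:
    """Replace masked positions by N on each interval's target record."""
    _check_records(records)
    by_id = {r.ref_id: r for r in records}
    arrays = {r.ref_id: bytearray(r.sequence, "ascii") for r in records}
    for m in masks:
        if m.target_ref not in by_id:
            raise ValueError(f"mask targets unknown record {m.target_ref}")
        L = len(by_id[m.target_ref])
        if not (0 <= m.start < m.end <= L):
            raise ValueError(
                f"mask [{m.start}, {m.end}) out of bounds for "
                f"{m.target_ref} (length {L})"
            )
        arrays[m.target_ref][m.start : m.end] = b"N" * (m.end - m.start)
    masked = [
        replace(r, sequence=arrays[r.ref_id].decode("ascii")) for r in records
    ]
    return ReferencePanel(records=masked, masks=list(masks), kmer_size=kmer_size)


def build_panel(
    records: list[ReferenceRecord],
    kmer_size: int = DEFAULT_KMER_SIZE,
    mask_min_len: int = DEFAULT_MASK_MIN_LEN,
    mask_min_identity: float = DEFAULT_MASK_MIN_IDENTITY,
) -> ReferencePanel:
    """find_shared_regions + apply_masks in one step."""
    masks = find_shared_regions(records, mask_min_len, mask_min_identity)
    return apply_masks(records, masks, kmer_size=kmer_size)


# ---------------------------------------------------------------------------
# on-disk representation: FASTA (with species=/priority= tags) + BED-like TSV

_BED_HEADER = "#target_ref\tstart\tend\tattributes"


def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=r.ref_id,
            description=f"species={r.species_label} priority={r.priority}",
        )
        for r in panel.records
    ]
    SeqIO.write(seqs, str(path / "panel.fasta"), "fasta")
    with open(path / "masks.bed", "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for m in panel.masks:
            fh.write(
                f"{m.target_ref}\t{m.start}\t{m.end}\t"
                f"mask_from={m.source_ref};id={m.identity:.2f}\n"
            )


def _parse_bed_line(line: str, lineno: int) -> MaskInterval:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 4:
        raise ValueError(f"masks.bed line {lineno}: expected 4 fields, got {len(parts)}")
    target, start_s, end_s, attrs = parts
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"masks.bed line {lineno}: non-integer coordinates") from exc
    source = ""
    identity = float("nan")
    for kv in attrs.split(";"):
        if "=" not in kv:
            raise ValueError(f"masks.bed line {lineno}: malformed attribute {kv!r}")
        key, val = kv.split("=", 1)
        if key == "mask_from":
            source = val
        elif key == "id":
            identity = float(val)
    if not source:
        raise ValueError(f"masks.bed line {lineno}: missing mask_from attribute")
    return MaskInterval(target, start, end, source, identity)


def read_panel(path: str | Path) -> ReferencePanel:
    path = Path(path)
    records = []
    for lineno, rec in enumerate(SeqIO.parse(str(path / "panel.fasta"), "fasta"), 1):
        tags = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        if "species" not in tags or "priority" not in tags:
            raise ValueError(
                f"panel.fasta record {lineno} ({rec.id}): missing species=/priority= tags"
            )
        records.append(
            ReferenceRecord(
                ref_id=rec.id,
                species_label=tags["species"],
                sequence=str(rec.seq).upper(),
                priority=int(tags["priority"]),
            )
        )
    masks = []
    with open(path / "masks.bed") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            masks.append(_parse_bed_line(line, lineno))
    panel = ReferencePanel(records=records, masks=masks)
    for m in masks:
        rec = panel.record(m.target_ref)
        if set(rec.sequence[m.start : m.end]) - {"N"}:
            raise ValueError(
                f"mask [{m.start}, {m.end}) on {m.target_ref} is not N in panel.fasta"
            )
    return panel


def validate_panel(panel: ReferencePanel) -> None:
    """Self-consistency: masked bases are N and no unmasked homology remains."""
    for m in panel.masks:
        rec = panel.record(m.target_ref)
        if set(rec.sequence[m.start : m.end]) - {"N"}:
            raise AssertionError(f"mask on {m.target_ref} not applied")
    leftover = find_shared_regions(panel.records)
    if leftover:
        raise AssertionError(f"unmasked homology remains: {leftover}")
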