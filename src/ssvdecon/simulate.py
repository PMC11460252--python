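"""Synthetic-data generator with known ground truth.

Three generators cover the whole study design:

* :func:`build_synthetic_references` — a reference set with deliberate
  cross-species homology (shared ITRs between vector genome and plasmid
  backbone, homology arms copied from the producer genome), the masking
  hazards the reference panel exists to solve.
* :func:`simulate_prep_reads` / :func:`simulate_spike_control` — paired-end
  reads with UMIs from a prep modelled as a mixture of DNA species, a
  per-species encapsidation fraction, and a DNase step that destroys
  extra-capsid molecules. Sonication fragments are ~300 bp; substitution
  errors are i.i.d.; a truth table records every read's source molecule.
* :func:`simulate_phenotypes` — CFU plate counts, viability trajectories and
  qPCR Ct values with planted effect sizes for the downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import decode, encode, revcomp_arr
from .refpanel import DEFAULT_PRIORITY, ReferenceRecord

#: Illumina TruSeq read-through adapter observed when a fragment is shorter
#: than the read length.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

ITR_LEN = 145
ARM_LEN = 800

DEFAULT_SIZES = {
    "producer_genome": 200_000,
    "rAAV_genome": 4_700,
    "plasmid_backbone": 3_000,
    "helper_plasmid": 10_000,
    "repcap_plasmid": 7_000,
    "ecoli_genome": 50_000,
    "baculovirus": 20_000,
    "lambda_spike": 48_500,
    "foreign": 20_000,
}

#: Flat Phred quality (Q30) written for every base.
QUAL_CHAR = chr(30 + 33)


@dataclass
class PrepSpec:
    """Ground truth for one prep: composition, encapsidation, DNase model.

    ``fractions`` are fractions of DNA molecules per species (must sum to 1;
    include ``foreign`` for the unmapped bucket). ``encapsidated[s]`` is the
    fraction of species ``s`` packaged inside capsids and hence protected
    from DNase; ``dnase_efficiency`` is the fraction of extra-capsid
    molecules a DNase treatment destroys.
    """

    prep_id: str
    fractions: dict[str, float]
    encapsidated: dict[str, float] = field(default_factory=dict)
    dnase_efficiency: float = 0.99

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        for s, f in self.fractions.items():
            if f < 0:
                raise ValueError(f"negative fraction for {s}")
        enc = {"rAAV_genome": 1.0, "lambda_spike": 0.0}
        enc.update(self.encapsidated)
        self.encapsidated = enc
        if not 0.0 <= self.dnase_efficiency <= 1.0:
            raise ValueError("dnase_efficiency must be in [0, 1]")


def effective_fractions(prep: PrepSpec, dnase: bool) -> dict[str, float]:
    """Species fractions among surviving molecules after (optional) DNase.

    Without DNase these equal ``prep.fractions`` exactly. With DNase, species
    ``s`` keeps weight ``f_s * (enc_s + (1 - enc_s) * (1 - efficiency))``,
    renormalized over the survivors.
    """
    if not dnase:
        return dict(prep.fractions)
    eff = {}
    for s, f in prep.fractions.items():
        enc = prep.encapsidated.get(s, 0.0)
        eff[s] = f * (enc + (1.0 - enc) * (1.0 - prep.dnase_efficiency))
    total = sum(eff.values())
    if total <= 0:
        raise ValueError("all effective weights are zero after DNase")
    return {s: w / total for s, w in eff.items()}


@dataclass
class ReadPair:
    read_id: str
    umi: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    truth_species: str


@dataclass
class SimulatedReadSet:
    pairs: list[ReadPair]
    truth: pd.DataFrame  # read_id, molecule_id, species, ref_id, pos, strand, is_duplicate

    def write(self, out_prefix: str | Path) -> None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        write_fastq(self.pairs, f"{out_prefix}_R1.fastq", f"{out_prefix}_R2.fastq")
        self.truth.to_csv(f"{out_prefix}_truth.tsv", sep="\t", index=False)


def write_fastq(pairs: list[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id} UMI:{p.umi}\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id} UMI:{p.umi}\n{p.seq2}\n+\n{p.qual2}\n")


def build_synthetic_references(
    seed: int, sizes: dict[str, int] | None = None
) -> list[ReferenceRecord]:
    """Construct the reference set with deliberate cross-species homology.

    The rAAV genome is ITR + left homology arm + cassette + right arm +
    reverse-complemented ITR; both arms are verbatim copies of producer-genome
    loci and the plasmid backbone carries both ITRs. All other records are
    i.i.d. uniform DNA. Byte-deterministic under ``seed``.
    """
    sizes = {**DEFAULT_SIZES, **(sizes or {})}
    raav_len = sizes["rAAV_genome"]
    if raav_len < 2 * ITR_LEN + 2 * ARM_LEN:
        raise ValueError(
            f"rAAV length {raav_len} < {2 * ITR_LEN + 2 * ARM_LEN} "
            "(two ITRs plus two homology arms)"
        )
    rng = np.random.default_rng(seed)

    def rand(n):
        return rng.integers(0, 4, size=n, dtype=np.int64).astype(np.uint8)

    producer = rand(sizes["producer_genome"])
    itr = rand(ITR_LEN)
    # two distinct producer loci provide the homology arms
    lo = int(rng.integers(0, sizes["producer_genome"] // 2 - ARM_LEN))
    hi = int(rng.integers(sizes["producer_genome"] // 2, sizes["producer_genome"] - ARM_LEN))
    arm_left = producer[lo : lo + ARM_LEN].copy()
    arm_right = producer[hi : hi + ARM_LEN].copy()
    cassette = rand(raav_len - 2 * ITR_LEN - 2 * ARM_LEN)
    raav = np.concatenate([itr, arm_left, cassette, arm_right, revcomp_arr(itr)])
    backbone = np.concatenate(
        [itr, rand(sizes["plasmid_backbone"] - 2 * ITR_LEN), revcomp_arr(itr)]
    )
    arrays = {
        "rAAV_genome": raav,
        "producer_genome": producer,
        "plasmid_backbone": backbone,
        "helper_plasmid": rand(sizes["helper_plasmid"]),
        "repcap_plasmid": rand(sizes["repcap_plasmid"]),
        "ecoli_genome": rand(sizes["ecoli_genome"]),
        "baculovirus": rand(sizes["baculovirus"]),
        "lambda_spike": rand(sizes["lambda_spike"]),
        "foreign": rand(sizes["foreign"]),
    }
    return [
        ReferenceRecord(
            ref_id=label,
            species_label=label,
            sequence=decode(arr),
            priority=DEFAULT_PRIORITY[label],
        )
        for label, arr in arrays.items()
    ]


def _make_mate_pair(
    frag: np.ndarray,
    read_len: int,
    adapter_arr: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the two mate arrays from an (already oriented) fragment."""

    def one_end(oriented):
        if oriented.shape[0] >= read_len:
            return oriented[:read_len].copy()
        # read-through: fragment, then adapter, then random bases
        fill = read_len - oriented.shape[0] - adapter_arr.shape[0]
        parts = [oriented, adapter_arr]
        if fill > 0:
            parts.append(rng.integers(0, 4, size=fill, dtype=np.int64).astype(np.uint8))
        return np.concatenate(parts)[:read_len]

    return one_end(frag), one_end(revcomp_arr(frag))


def _inject_errors(arr: np.ndarray, n_err: int, rng: np.random.Generator) -> None:
    if n_err <= 0:
        return
    pos = rng.integers(0, arr.shape[0], size=n_err)
    shift = rng.integers(1, 4, size=n_err)
    arr[pos] = (arr[pos] + shift) % 4


def simulate_prep_reads(
    refs: list[ReferenceRecord],
    prep: PrepSpec,
    dnase: bool,
    n_pairs: int,
    frag_mean: float = 300.0,
    frag_sd: float = 60.0,
    read_len: int = 150,
    err_rate: float = 0.001,
    dup_rate: float = 0.05,
    umi_len: int = 8,
    adapter: str = DEFAULT_ADAPTER,
    variants: list[tuple[int, str, float]] | None = None,
    seed: int = 0,
) -> SimulatedReadSet:
    """Simulate ``n_pairs`` sequenced molecules from one prep.

    Per molecule: species drawn from the DNase-adjusted effective fractions,
    fragment start uniform, length ~ Normal(frag_mean, frag_sd) truncated to
    [50, 2*read_len + 200], strand uniform, substitution errors i.i.d. at
    ``err_rate``. A fraction ``dup_rate`` of molecules additionally emits a
    PCR duplicate (same fragment and UMI, fresh errors). ``variants`` plants
    SNVs on rAAV molecules as (0-based position, alt base, allele fraction).
    The truth table records the pre-error species of every read_id.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    eff = effective_fractions(prep, dnase)
    species = sorted(eff)
    weights = np.array([eff[s] for s in species])
    if weights.sum() <= 0:
        raise ValueError("all effective weights are zero")
    weights = weights / weights.sum()

    by_label = {r.species_label: r for r in refs}
    for s in species:
        if eff[s] > 0 and s not in by_label:
            raise ValueError(f"no reference record for species {s}")
    arrs = {s: encode(by_label[s].sequence) for s in species if eff[s] > 0}
    adapter_arr = encode(adapter)
    variants = variants or []

    rng = np.random.default_rng(seed)
    spec_idx = rng.choice(len(species), size=n_pairs, p=weights)
    frag_lens = np.clip(
        np.rint(rng.normal(frag_mean, frag_sd, size=n_pairs)), 50, 2 * read_len + 200
    ).astype(np.int64)
    start_u = rng.random(n_pairs)
    strands = rng.integers(0, 2, size=n_pairs)
    umi_mat = rng.integers(0, 4, size=(n_pairs, umi_len), dtype=np.int64).astype(np.uint8)
    dup_flags = rng.random(n_pairs) < dup_rate
    err_counts = rng.binomial(read_len, err_rate, size=(n_pairs, 2))
    var_draws = rng.random((n_pairs, len(variants))) if variants else None

    pairs: list[ReadPair] = []
    truth_rows: list[tuple] = []
    dup_jobs: list[tuple[int, np.ndarray]] = []

    for m in range(n_pairs):
        s = species[spec_idx[m]]
        ref_arr = arrs[s]
        L = ref_arr.shape[0]
        flen = int(min(frag_lens[m], L))
        start = int(start_u[m] * (L - flen + 1))
        frag = ref_arr[start : start + flen].copy()
        if s == "rAAV_genome" and variants:
            for vi, (vpos, valt, _vaf) in enumerate(variants):
                if start <= vpos < start + flen and var_draws[m, vi] < variants[vi][2]:
                    frag[vpos - start] = encode(valt)[0]
        if strands[m] == 1:
            frag = revcomp_arr(frag)
        umi = decode(umi_mat[m])
        read_id = f"{prep.prep_id}:{m:07d}"
        s1, s2 = _make_mate_pair(frag, read_len, adapter_arr, rng)
        _inject_errors(s1, int(err_counts[m, 0]), rng)
        _inject_errors(s2, int(err_counts[m, 1]), rng)
        qual = QUAL_CHAR * read_len
        pairs.append(ReadPair(read_id, umi, decode(s1), decode(s2), qual, qual, s))
        truth_rows.append(
            (read_id, m, s, by_label[s].ref_id, start, "-" if strands[m] else "+", False)
        )
        if dup_flags[m]:
            dup_jobs.append((m, frag))

    for m, frag in dup_jobs:
        s = species[spec_idx[m]]
        umi = decode(umi_mat[m])
        read_id = f"{prep.prep_id}:{m:07d}:d1"
        s1, s2 = _make_mate_pair(frag, read_len, adapter_arr, rng)
        _inject_errors(s1, int(rng.binomial(read_len, err_rate)), rng)
        _inject_errors(s2, int(rng.binomial(read_len, err_rate)), rng)
        qual = QUAL_CHAR * read_len
        pairs.append(ReadPair(read_id, umi, decode(s1), decode(s2), qual, qual, s))
        start = truth_rows[m][4]
        truth_rows.append((read_id, m, s, by_label[s].ref_id, start, truth_rows[m][5], True))

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "molecule_id", "species", "ref_id", "pos", "strand", "is_duplicate"],
    )
    return SimulatedReadSet(pairs=pairs, truth=truth)


def simulate_spike_control(
    refs: list[ReferenceRecord],
    with_dnase: bool,
    n_pairs: int = 10_000,
    dnase_efficiency: float = 0.999,
    seed: int = 0,
    **read_kwargs,
) -> SimulatedReadSet:
    """Lambda-phage-only digestion control.

    Lambda DNA is never encapsidated, so with DNase each of the ``n_pairs``
    requested molecules survives independently with probability
    ``1 - dnase_efficiency`` (binomial thinning, not renormalization); the
    surviving molecules are then sequenced. Without DNase all molecules
    survive.
    """
    rng = np.random.default_rng(seed)
    n_surv = int(rng.binomial(n_pairs, 1.0 - dnase_efficiency)) if with_dnase else n_pairs
    prep = PrepSpec(
        prep_id="lambda_control_plus" if with_dnase else "lambda_control_minus",
        fractions={"lambda_spike": 1.0},
        dnase_efficiency=dnase_efficiency,
    )
    if n_surv == 0:
        truth = pd.DataFrame(
            columns=["read_id", "molecule_id", "species", "ref_id", "pos", "strand", "is_duplicate"]
        )
        return SimulatedReadSet(pairs=[], truth=truth)
    return simulate_prep_reads(
        refs, prep, dnase=False, n_pairs=n_surv,
        seed=int(rng.integers(0, 2**31 - 1)), **read_kwargs,
    )


# ---------------------------------------------------------------------------
# phenotype simulation

GENE_PANEL = (
    "FAS", "CDKN1A", "BAX", "TNFA", "TP53", "IFNB1",
    "IL6", "CXCL10", "CASP3", "MX1", "MYC",
)
REFERENCE_GENE = "ACTB"

MORPHOLOGY_CLASSES = ("BFU-E", "CFU-E", "CFU-GM", "CFU-G", "CFU-M", "CFU-GEMM")

#: log2 fold change per percentage point of contaminant DNA (100 - purity),
#: loosely mirroring the stress/apoptosis/inflammation panel behaviour:
#: positive coefficients are induced by contamination.
DEFAULT_GENE_COEF = {
    "FAS": 0.012, "CDKN1A": 0.015, "BAX": 0.012, "TNFA": 0.018,
    "TP53": 0.006, "IFNB1": 0.020, "IL6": 0.015, "CXCL10": 0.020,
    "CASP3": 0.008, "MX1": 0.015, "MYC": -0.004,
}


@dataclass
class EffectModel:
    """Planted effect sizes for the phenotype generator.

    %CFU per condition follows ``cfu_intercept + cfu_slope * purity`` with
    donor-level Gaussian noise; plate counts are Poisson. Gene expression is
    planted as log2 fold changes vs mock, either via the per-contamination
    coefficients or explicit overrides in ``planted_log2fc``.
    """

    cfu_slope: float = 0.2          # %CFU per % rAAV purity
    cfu_intercept: float = 5.0      # %CFU at 0% purity
    cfu_noise_sd: float = 2.0       # donor-level sd of %CFU
    cells_plated: tuple[int, ...] = (300, 100, 25)
    n_plate_replicates: int = 2
    erythroid_frac: float = 0.6
    gemm_frac: float = 0.03
    n_donors: int = 3
    gene_coef: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GENE_COEF))
    planted_log2fc: dict[tuple[str, str], float] = field(default_factory=dict)
    actb_ct: float = 18.0
    base_delta_ct: float = 6.0      # mock Ct offset of every panel gene vs ACTB
    ct_noise_sd: float = 0.15
    n_tech_reps: int = 3
    viability_base: float = 92.0    # mock viability, %
    viability_aav_drop: float = 18.0
    viability_contamination_coef: float = 0.08  # extra % drop per % contaminant
    viability_recovery_per_day: float = 2.0
    viability_noise_sd: float = 2.0

    def log2fc(self, gene: str, condition_id: str, purity: float) -> float:
        if (gene, condition_id) in self.planted_log2fc:
            return self.planted_log2fc[(gene, condition_id)]
        return self.gene_coef.get(gene, 0.0) * (100.0 - purity)


@dataclass
class PhenotypeTables:
    cfu: pd.DataFrame
    viability: pd.DataFrame
    ct: pd.DataFrame
    truth: dict


def simulate_phenotypes(
    purity_by_prep: dict[str, float],
    effect_model: EffectModel | None = None,
    seed: int = 0,
) -> PhenotypeTables:
    """Synthetic CFU, viability and Ct tables with known ground truth.

    ``purity_by_prep`` maps condition_id -> %rAAV genome of the transducing
    prep. A ``mock`` condition (no AAV) is always appended; its Ct values
    anchor the ddCT normalization and its viability has no AAV drop.
    """
    em = effect_model or EffectModel()
    rng = np.random.default_rng(seed)
    class_probs = _class_probs(em)

    cfu_rows = []
    via_rows = []
    ct_rows = []
    truth_pct = {}
    for cond, purity in purity_by_prep.items():
        for donor in range(1, em.n_donors + 1):
            pct = em.cfu_intercept + em.cfu_slope * purity
            if em.cfu_noise_sd > 0:
                pct += rng.normal(0.0, em.cfu_noise_sd)
            if pct < 0:
                warnings.warn(
                    f"negative expected %CFU for {cond} donor {donor}; clipped to 0",
                    stacklevel=2,
                )
                pct = 0.0
            truth_pct[(cond, donor)] = pct
            for cells in em.cells_plated:
                for rep in range(1, em.n_plate_replicates + 1):
                    lam = cells * pct / 100.0
                    total = int(rng.poisson(lam))
                    counts = rng.multinomial(total, class_probs)
                    cfu_rows.append((cond, donor, cells, rep, *counts))

    conditions_ct = list(purity_by_prep) + ["mock"]
    for cond in conditions_ct:
        purity = purity_by_prep.get(cond, 100.0)
        for donor in range(1, em.n_donors + 1):
            # viability trajectory
            aav = cond != "mock"
            for day in (1, 3, 5):
                v = em.viability_base
                if aav:
                    v -= em.viability_aav_drop
                    v -= em.viability_contamination_coef * (100.0 - purity)
                    v += em.viability_recovery_per_day * (day - 1)
                v += rng.normal(0.0, em.viability_noise_sd)
                via_rows.append((cond, donor, day, float(np.clip(v, 0.0, 100.0))))
            # Ct values
            sample_id = f"donor{donor}"
            for gene in GENE_PANEL + (REFERENCE_GENE,):
                if gene == REFERENCE_GENE:
                    mean_ct = em.actb_ct
                elif cond == "mock":
                    mean_ct = em.actb_ct + em.base_delta_ct
                else:
                    mean_ct = em.actb_ct + em.base_delta_ct - em.log2fc(gene, cond, purity)
                for rep in range(1, em.n_tech_reps + 1):
                    ct = mean_ct + rng.normal(0.0, em.ct_noise_sd)
                    ct_rows.append((sample_id, cond, gene, rep, float(ct)))

    cfu = pd.DataFrame(
        cfu_rows,
        columns=["condition_id", "donor", "cells_plated", "replicate", *MORPHOLOGY_CLASSES],
    )
    viability = pd.DataFrame(via_rows, columns=["condition_id", "donor", "day", "viability"])
    ct = pd.DataFrame(ct_rows, columns=["sample_id", "condition_id", "gene", "replicate", "ct"])
    truth = {
        "cfu_slope": em.cfu_slope,
        "cfu_intercept": em.cfu_intercept,
        "expected_pct_cfu": truth_pct,
        "log2fc": {
            (g, c): em.log2fc(g, c, purity_by_prep[c])
            for c in purity_by_prep
            for g in GENE_PANEL
        },
        "erythroid_frac": em.erythroid_frac,
    }
    return PhenotypeTables(cfu=cfu, viability=viability, ct=ct, truth=truth)


def _class_probs(em: EffectModel) -> np.ndarray:
    ery = em.erythroid_frac * (1.0 - em.gemm_frac)
    mye = (1.0 - em.erythroid_frac) * (1.0 - em.gemm_frac)
    return np.array(
        [0.6 * ery, 0.4 * ery, 0.5 * mye, 0.25 * mye, 0.25 * mye, em.gemm_frac]
    )
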