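"""Downstream phenotype statistics for transduced CD34+ HSPCs.

Clonogenic potential (CFU per plated cell), erythroid/myeloid lineage
proportions, the purity-clonogenicity regression, ddCT expression fold
changes, and starred pairwise group comparisons (Welch's t-test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MORPHOLOGY_CLASSES

ERYTHROID_CLASSES = ("BFU-E", "CFU-E")
MYELOID_CLASSES = ("CFU-GM", "CFU-G", "CFU-M")

#: significance thresholds -> star annotation
STAR_THRESHOLDS = ((0.0001, "****"), (0.0005, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class CFUPlate:
    condition_id: str
    cells_plated: int
    replicate: int
    counts: dict[str, int]

    def __post_init__(self):
        if self.cells_plated <= 0:
            raise ValueError("cells_plated must be positive")
        for k, v in self.counts.items():
            if k not in MORPHOLOGY_CLASSES:
                raise ValueError(f"unknown morphology class {k!r}")
            if v < 0:
                raise ValueError("colony counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CtRecord:
    sample_id: str
    condition_id: str
    gene: str
    ct_values: list[float]

    def __post_init__(self):
        if not self.ct_values:
            raise ValueError("ct_values must be non-empty")
        if any(ct <= 0 for ct in self.ct_values):
            raise ValueError("Ct values must be positive")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_values))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_se: float
    n: int

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        t = stats.t.ppf(1 - alpha / 2, self.n - 2)
        return self.slope - t * self.slope_se, self.slope + t * self.slope_se


def plates_from_frame(cfu: pd.DataFrame) -> list[CFUPlate]:
    """Convert a CFU table (one row per plate) to CFUPlate objects."""
    plates = []
    for _, row in cfu.iterrows():
        plates.append(
            CFUPlate(
                condition_id=str(row["condition_id"]),
                cells_plated=int(row["cells_plated"]),
                replicate=int(row["replicate"]),
                counts={c: int(row[c]) for c in MORPHOLOGY_CLASSES if c in row},
            )
        )
    return plates


def cfu_percent(plates: list[CFUPlate]) -> tuple[float, list[float]]:
    """%CFU per plated cell: per-plate values and their mean.

    Per plate: 100 * total colonies / cells plated; the condition value is
    the mean across plates.
    """
    if not plates:
        raise ValueError("need at least one plate")
    per_plate = [100.0 * p.total / p.cells_plated for p in plates]
    return float(np.mean(per_plate)), per_plate


def lineage_proportions(plates: list[CFUPlate]) -> dict[str, float]:
    """Erythroid vs myeloid percentage split of classified colonies.

    Erythroid = BFU-E + CFU-E; myeloid = CFU-GM + CFU-G + CFU-M. Mixed
    CFU-GEMM colonies belong to neither dichotomy arm and are reported
    separately as a percentage of all colonies.
    """
    ery = sum(p.counts.get(c, 0) for p in plates for c in ERYTHROID_CLASSES)
    mye = sum(p.counts.get(c, 0) for p in plates for c in MYELOID_CLASSES)
    gemm = sum(p.counts.get("CFU-GEMM", 0) for p in plates)
    classified = ery + mye
    if classified == 0:
        raise ValueError("zero classified (erythroid/myeloid) colonies")
    total = classified + gemm
    return {
        "erythroid": 100.0 * ery / classified,
        "myeloid": 100.0 * mye / classified,
        "gemm_of_total": 100.0 * gemm / total,
    }


def purity_cfu_regression(points: list[tuple[float, float]]) -> RegressionResult:
    """OLS of %CFU on %rAAV genome purity.

    p-value is the two-sided t-test on the slope; r_squared is the squared
    Pearson correlation of fitted vs observed values.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("purity values are constant; regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope_se=float(res.stderr),
        n=len(points),
    )


def ddct_fold_change(
    target: CtRecord,
    reference: CtRecord,
    mock_target: CtRecord,
    mock_reference: CtRecord,
) -> float:
    """Standard ddCT: fold change vs a housekeeping gene and a mock control.

    dCt = Ct_target - Ct_reference per condition (technical replicates
    averaged first); ddCt = dCt_condition - dCt_mock; fold = 2^(-ddCt).
    """
    for rec, role in ((reference, "reference"), (mock_reference, "mock reference")):
        if rec is None:
            raise ValueError(f"missing {role} (housekeeping) record")
    d_cond = target.mean_ct - reference.mean_ct
    d_mock = mock_target.mean_ct - mock_reference.mean_ct
    return float(2.0 ** (-(d_cond - d_mock)))


def stars(p_value: float) -> str:
    for thr, sym in STAR_THRESHOLDS:
        if p_value < thr:
            return sym
    return "ns"


def group_compare(values_a, values_b) -> tuple[float, str]:
    """Welch two-sample t-test with star annotation.

    Degenerate case: zero variance in both groups with equal means gives
    p = 1 (no evidence of a difference).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return p, stars(p)
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return p, stars(p)


def expression_heatmap_table(
    fold_changes: dict[tuple[str, str], float],
    genes: list[str],
    conditions: list[str],
) -> pd.DataFrame:
    """log2 fold-change matrix (genes x conditions) for heatmap rendering.

    Requires a complete grid; missing cells raise an error listing their
    (gene, condition) coordinates.
    """
    missing = [(g, c) for g in genes for c in conditions if (g, c) not in fold_changes]
    if missing:
        raise ValueError(f"missing fold changes for cells: {missing}")
    data = {
        c: [float(np.log2(fold_changes[(g, c)])) for g in genes] for c in conditions
    }
    return pd.DataFrame(data, index=genes, columns=conditions)


def viability_summary(viability: pd.DataFrame) -> pd.DataFrame:
    """Descriptive mean +/- sd viability per condition and day."""
    return (
        viability.groupby(["condition_id", "day"])["viability"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


def ct_records_from_frame(ct: pd.DataFrame) -> dict[tuple[str, str, str], CtRecord]:
    """Index a long-format Ct table by (sample_id, condition_id, gene)."""
    out = {}
    for (sid, cond, gene), grp in ct.groupby(["sample_id", "condition_id", "gene"]):
        out[(sid, cond, gene)] = CtRecord(
            sample_id=sid, condition_id=cond, gene=gene,
            ct_values=grp["ct"].tolist(),
        )
    return out
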