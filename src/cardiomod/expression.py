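"""Expression follow-up statistics for candidate modifier genes.

Covers qPCR relative quantification by the delta-delta-Ct method with
BH-corrected unpaired t-tests, the FPKM > 1 expressed-gene filter, log2 fold
differences between experiment arms, and the treated-vs-sham fold-ratio
contrast used to separate a treatment response from culture drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CtMeasurement",
    "ExpressionMatrix",
    "FoldChangeResult",
    "delta_delta_ct",
    "expressed_filter",
    "log2_fold_difference",
    "treatment_ratio_analysis",
    "bh_correction",
]

ARM_LABELS = ("pre", "treated", "sham", "wildtype", "mutant", "case", "control")


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR well: target and housekeeping Ct for a sample."""

    sample: str
    group: str  # case | control
    gene: str
    ct_target: float
    ct_housekeeping: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_housekeeping):
            if not 0 < v < 50:
                raise ValueError(f"Ct value {v} outside (0, 50)")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_housekeeping


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM/RPKM matrix with an arm label per sample."""

    values: pd.DataFrame  # index: genes; columns: samples
    arms: Mapping[str, str]  # sample -> arm label

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.arms)
        if missing:
            raise ValueError(f"samples without arm label: {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be >= 0")

    def arm_samples(self, arm: str) -> list[str]:
        return [s for s in self.values.columns if self.arms[s] == arm]

    def arm_mean(self, arm: str) -> pd.Series:
        cols = self.arm_samples(arm)
        if not cols:
            raise ValueError(f"no samples in arm {arm!r}")
        return self.values[cols].mean(axis=1)

    @property
    def arm_labels(self) -> set[str]:
        return set(self.arms.values())


@dataclass
class FoldChangeResult:
    gene: str
    fold: float
    log2fd: float
    p_raw: float
    q_bh: float = np.nan
    expressed: bool = True
    n_case: int = 0
    n_control: int = 0


def delta_delta_ct(
    measurements: Sequence[CtMeasurement] | pd.DataFrame,
    reference_group: str = "control",
) -> pd.DataFrame:
    """Per-gene relative expression by the delta-delta-Ct method.

    Per sample, dCt = Ct(target) - Ct(housekeeping); per gene, ddCt is the
    mean dCt of the comparison group minus the mean dCt of the reference
    group, and the fold change is 2**(-ddCt).  Groups are compared by a Welch
    unpaired two-sided t-test on dCt (the log-scale quantity), with BH
    correction across genes.  Genes with fewer than two samples in either
    group are skipped with a warning.
    """
    if isinstance(measurements, pd.DataFrame):
        measurements = [
            CtMeasurement(
                str(r.sample), str(r.group), str(r.gene),
                float(r.ct_target), float(r.ct_housekeeping),
            )
            for r in measurements.itertuples()
        ]
    by_gene: dict[str, dict[str, list[float]]] = {}
    for m in measurements:
        by_gene.setdefault(m.gene, {}).setdefault(m.group, []).append(m.delta_ct)

    rows: list[FoldChangeResult] = []
    for gene in sorted(by_gene):
        groups = by_gene[gene]
        other = [g for g in groups if g != reference_group]
        if reference_group not in groups or len(other) != 1:
            warnings.warn(f"gene {gene}: need reference and one comparison group")
            continue
        ref = np.asarray(groups[reference_group])
        cmp_ = np.asarray(groups[other[0]])
        if len(ref) < 2 or len(cmp_) < 2:
            warnings.warn(f"gene {gene}: fewer than 2 samples in a group; skipped")
            continue
        ddct = cmp_.mean() - ref.mean()
        if np.allclose(ref.var(ddof=1) + cmp_.var(ddof=1), 0):
            p = 1.0 if np.isclose(ddct, 0) else 0.0
        else:
            p = float(stats.ttest_ind(cmp_, ref, equal_var=False).pvalue)
        rows.append(
            FoldChangeResult(
                gene=gene,
                fold=float(2.0 ** (-ddct)),
                log2fd=float(-ddct),
                p_raw=max(p, np.finfo(float).tiny),
                n_case=len(cmp_),
                n_control=len(ref),
            )
        )
    out = pd.DataFrame([vars(r) for r in rows])
    if len(out):
        out["q_bh"] = bh_correction(out["p_raw"].to_numpy())
    return out


def expressed_filter(matrix: ExpressionMatrix, threshold: float = 1.0) -> list[str]:
    """Genes whose mean expression exceeds the threshold in at least one arm."""
    arm_means = pd.DataFrame(
        {arm: matrix.arm_mean(arm) for arm in sorted(matrix.arm_labels)}
    )
    keep = arm_means.max(axis=1) > threshold
    return list(arm_means.index[keep])


def log2_fold_difference(
    matrix: ExpressionMatrix,
    arm_a: str,
    arm_b: str,
    pseudocount: float = 0.1,
) -> pd.Series:
    """Per-gene log2((mean_a + eps) / (mean_b + eps)); antisymmetric in arms."""
    ma = matrix.arm_mean(arm_a) + pseudocount
    mb = matrix.arm_mean(arm_b) + pseudocount
    return np.log2(ma) - np.log2(mb)


def treatment_ratio_analysis(
    matrix: ExpressionMatrix, pseudocount: float = 0.1
) -> pd.Series:
    """log2 of (treated/pre) over (sham/pre) per gene.

    Isolates the treatment response from shared culture drift; when the
    pre-treatment means cancel this equals the treated-vs-sham log2 fold
    difference.
    """
    for arm in ("pre", "treated", "sham"):
        if arm not in matrix.arm_labels:
            raise ValueError(f"missing experiment arm {arm!r}")
    pre = matrix.arm_mean("pre") + pseudocount
    treated = matrix.arm_mean("treated") + pseudocount
    sham = matrix.arm_mean("sham") + pseudocount
    return np.log2(treated / pre) - np.log2(sham / pre)


def bh_correction(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
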