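"""Multi-evidence modifier-gene scoring.

Each gene is scored on a 12-point scale combining gene-based rare-variant
association with external priors:

=====================================  ======
criterion                              points
=====================================  ======
LVWT association p < 0.05                 +2
EF association p < 0.05                   +1
LVOTG association p < 0.05                +1
case-control association p < 0.05         +1
left-ventricle expression RPKM > 10       +1
LoF constraint z > 3                      +1
missense constraint z > 3                 +1
hypertrophy coexpression Q < 0.01         +1
heart-failure coexpression Q < 0.01       +1
curated candidate cardiac gene            +2
flagged (UDP blacklist/paralog prefix)    -2
=====================================  ======

Per trait, the smallest p-value over all tests and variant sets is used.  All
comparisons are strict and absent evidence earns no points, so totals lie in
[-2, 12].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneEvidence",
    "ScoreBreakdown",
    "ScoreThresholds",
    "collect_gene_evidence",
    "score_gene",
    "rank_genes",
]

TRAIT_POINTS = {"lvwt": 2, "ef": 1, "lvotg": 1, "case_control": 1}


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class GeneEvidence:
    """Per-gene inputs to the scoring algorithm; ``None`` means absent."""

    gene: str
    p_lvwt: float | None = None
    p_ef: float | None = None
    p_lvotg: float | None = None
    p_cc: float | None = None
    rpkm_lv: float | None = None
    lof_z: float | None = None
    mis_z: float | None = None
    q_hypertrophy: float | None = None
    q_heart_failure: float | None = None
    is_candidate: bool = False
    is_flagged: bool = False

    def __post_init__(self) -> None:
        self.gene = _norm(self.gene)
        for name in ("p_lvwt", "p_ef", "p_lvotg", "p_cc",
                     "q_hypertrophy", "q_heart_failure"):
            v = getattr(self, name)
            if v is not None and not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.rpkm_lv is not None and self.rpkm_lv < 0:
            raise ValueError("rpkm_lv must be >= 0")

    @property
    def best_p(self) -> float:
        """Smallest per-trait association p (inf when no trait was tested)."""
        ps = [p for p in (self.p_lvwt, self.p_ef, self.p_lvotg, self.p_cc)
              if p is not None]
        return min(ps) if ps else np.inf


@dataclass
class ScoreThresholds:
    p_max: float = 0.05
    rpkm_min: float = 10.0
    z_min: float = 3.0
    q_max: float = 0.01


@dataclass
class ScoreBreakdown:
    gene: str
    points: dict[str, int] = field(default_factory=dict)
    total: int = 0
    best_p: float = np.inf

    def __post_init__(self) -> None:
        if self.total != sum(self.points.values()):
            raise ValueError("total does not equal the sum of itemized points")


def score_gene(
    evidence: GeneEvidence, thresholds: ScoreThresholds | None = None
) -> ScoreBreakdown:
    """Apply the point schedule to one gene's evidence."""
    t = thresholds or ScoreThresholds()
    pts: dict[str, int] = {}

    def lt(value: float | None, bound: float) -> bool:
        return value is not None and value < bound

    def gt(value: float | None, bound: float) -> bool:
        return value is not None and value > bound

    if lt(evidence.p_lvwt, t.p_max):
        pts["lvwt"] = TRAIT_POINTS["lvwt"]
    if lt(evidence.p_ef, t.p_max):
        pts["ef"] = TRAIT_POINTS["ef"]
    if lt(evidence.p_lvotg, t.p_max):
        pts["lvotg"] = TRAIT_POINTS["lvotg"]
    if lt(evidence.p_cc, t.p_max):
        pts["case_control"] = TRAIT_POINTS["case_control"]
    if gt(evidence.rpkm_lv, t.rpkm_min):
        pts["expression"] = 1
    if gt(evidence.lof_z, t.z_min):
        pts["lof"] = 1
    if gt(evidence.mis_z, t.z_min):
        pts["mis"] = 1
    if lt(evidence.q_hypertrophy, t.q_max):
        pts["hypertrophy_network"] = 1
    if lt(evidence.q_heart_failure, t.q_max):
        pts["hf_network"] = 1
    if evidence.is_candidate:
        pts["candidate"] = 2
    if evidence.is_flagged:
        pts["flagged"] = -2
    return ScoreBreakdown(
        gene=evidence.gene,
        points=pts,
        total=sum(pts.values()),
        best_p=evidence.best_p,
    )


_TRAIT_COLUMN = {
    "LVWT": "p_lvwt",
    "EF": "p_ef",
    "LVOTG": "p_lvotg",
    "CASE_CONTROL": "p_cc",
}


def collect_gene_evidence(
    assoc_results: pd.DataFrame,
    expression_table: pd.DataFrame | None = None,
    constraint_table: pd.DataFrame | None = None,
    network_table: pd.DataFrame | None = None,
    candidate_list: Iterable[str] = (),
    flag_list: Iterable[str] = (),
) -> list[GeneEvidence]:
    """Assemble one evidence record per gene appearing in any source.

    ``assoc_results`` needs columns ``region_id, trait`` plus any of
    ``p_skat, p_skato, p_fisher``; the per-trait evidence p is the minimum over
    all rows and test types for that gene and trait.  ``expression_table``:
    ``gene, rpkm_lv``; ``constraint_table``: ``gene, lof_z, mis_z``;
    ``network_table``: ``gene, q_hypertrophy, q_heart_failure``.  Gene symbols
    are case-normalized; duplicate conflicting rows in an evidence table raise.
    """
    best: dict[str, dict[str, float]] = {}
    p_cols = [c for c in ("p_skat", "p_skato", "p_fisher")
              if c in assoc_results.columns]
    for row in assoc_results.itertuples():
        gene = _norm(row.region_id)
        col = _TRAIT_COLUMN.get(str(row.trait).upper())
        if col is None:
            raise ValueError(f"unknown trait {row.trait!r} in association results")
        ps = [getattr(row, c) for c in p_cols]
        ps = [float(p) for p in ps if p is not None and np.isfinite(p)]
        if not ps:
            continue
        entry = best.setdefault(gene, {})
        entry[col] = min(min(ps), entry.get(col, np.inf))

    def table_lookup(
        table: pd.DataFrame | None, columns: Sequence[str], source: str
    ) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        if table is None:
            return out
        for row in table.itertuples():
            gene = _norm(row.gene)
            vals = {c: float(getattr(row, c)) for c in columns
                    if pd.notna(getattr(row, c))}
            if gene in out and out[gene] != vals:
                raise ValueError(f"conflicting rows for gene {gene} in {source}")
            out[gene] = vals
        return out

    expr = table_lookup(expression_table, ["rpkm_lv"], "expression table")
    constraint = table_lookup(constraint_table, ["lof_z", "mis_z"],
                              "constraint table")
    network = table_lookup(network_table, ["q_hypertrophy", "q_heart_failure"],
                           "network table")
    candidates = {_norm(g) for g in candidate_list}
    flagged = {_norm(g) for g in flag_list}

    genes = sorted(set(best) | set(expr) | set(constraint) | set(network)
                   | candidates)
    out = []
    for gene in genes:
        fields: dict = {"gene": gene}
        fields.update(best.get(gene, {}))
        fields.update(expr.get(gene, {}))
        fields.update(constraint.get(gene, {}))
        fields.update(network.get(gene, {}))
        fields["is_candidate"] = gene in candidates
        fields["is_flagged"] = gene in flagged
        out.append(GeneEvidence(**fields))
    return out


def rank_genes(
    breakdowns: Sequence[ScoreBreakdown],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank genes by total score.

    Ties break by smallest per-trait association p (ascending), then gene
    symbol.  Returns the ranked table and a threshold summary counting genes
    with total >= each observed score level.
    """
    if not breakdowns:
        empty = pd.DataFrame()
        return empty, empty
    rows = []
    for b in sorted(breakdowns, key=lambda b: (-b.total, b.best_p, b.gene)):
        row = {"gene": b.gene, "total": b.total, "best_p": b.best_p}
        row.update({f"pts_{k}": v for k, v in sorted(b.points.items())})
        rows.append(row)
    table = pd.DataFrame(rows).fillna(0)
    pts_cols = [c for c in table.columns if c.startswith("pts_")]
    table[pts_cols] = table[pts_cols].astype(int)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    totals = table["total"].to_numpy()
    levels = sorted(set(totals), reverse=True)
    summary = pd.DataFrame(
        {"score_at_least": levels,
         "n_genes": [int(np.sum(totals >= lv)) for lv in levels]}
    )
    return table, summary
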