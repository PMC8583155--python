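"""Expression-side numeric rules.

Relative qPCR expression by the 2^-ΔΔCt method with two reference genes,
the differential-response call (fold change > 2 in either direction and
p < 0.01 from a Welch t-test on per-replicate ΔCt), the RNA-seq DEG
threshold filter (TMM expression sum, |log2FC|, FDR), and
stress-responsiveness summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

QPCR_COLUMNS = ("gene", "condition", "replicate", "ct")


@dataclass(frozen=True)
class DiffCallConfig:
    fold_threshold: float = 2.0
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class DEGCriteria:
    """The three-way DEG filter: TMM expression sum, |log2FC|, and FDR."""

    tmm_sum_min: float = 5.0
    log2fc_abs_min: float = 1.0
    fdr_max: float = 0.05

    def __post_init__(self) -> None:
        if min(self.tmm_sum_min, self.log2fc_abs_min, self.fdr_max) <= 0:
            raise ValueError("all criteria must be positive")


@dataclass
class QpcrTable:
    """Long-format Ct table with two designated reference genes and a control.

    ``data`` columns: gene, condition, replicate, ct. Every (gene,
    condition) needs at least two replicates, and both reference genes must
    be measured in every condition.
    """

    data: pd.DataFrame
    reference_genes: tuple[str, str]
    control_condition: str

    def __post_init__(self) -> None:
        missing = set(QPCR_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"qPCR table lacks columns {sorted(missing)}")
        if len(self.reference_genes) != 2:
            raise ValueError("exactly two reference genes are required")
        conditions = set(self.data["condition"])
        if self.control_condition not in conditions:
            raise ValueError(f"control condition {self.control_condition!r} absent")
        for ref in self.reference_genes:
            have = set(self.data.loc[self.data["gene"] == ref, "condition"])
            if conditions - have:
                raise ValueError(
                    f"reference gene {ref!r} missing in condition(s) "
                    f"{sorted(conditions - have)}"
                )
        counts = self.data.groupby(["gene", "condition"])["ct"].count()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"fewer than 2 replicates for {bad}")

    @classmethod
    def read_tsv(
        cls, path, reference_genes: tuple[str, str], control_condition: str
    ) -> "QpcrTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df, tuple(reference_genes), control_condition)

    def conditions(self) -> list[str]:
        return sorted(set(self.data["condition"]))

    def genes(self) -> list[str]:
        refs = set(self.reference_genes)
        return sorted(g for g in set(self.data["gene"]) if g not in refs)


def _reference_mean(table: QpcrTable, condition: str) -> float:
    """Arithmetic mean of the two reference genes' mean Cts in a condition.

    Equivalent to a geometric mean of the reference expression levels.
    """
    sub = table.data[table.data["condition"] == condition]
    means = [
        sub.loc[sub["gene"] == ref, "ct"].mean() for ref in table.reference_genes
    ]
    return float(np.mean(means))


def replicate_delta_ct(table: QpcrTable, gene: str, condition: str) -> np.ndarray:
    """Per-replicate ΔCt of a gene in a condition (reference-corrected)."""
    sub = table.data[
        (table.data["condition"] == condition) & (table.data["gene"] == gene)
    ]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent in condition {condition!r}")
    return sub["ct"].to_numpy(dtype=float) - _reference_mean(table, condition)


def delta_delta_ct(
    table: QpcrTable, gene: str, condition: str
) -> tuple[float, float]:
    """Relative expression 2^-ΔΔCt of ``gene`` in ``condition`` vs the control.

    Returns ``(fold, sd)``; the SD is that of the per-replicate 2^-ΔΔCt
    values, propagating the replicate spread onto the fold scale.
    """
    dct_cond = replicate_delta_ct(table, gene, condition)
    dct_ctrl = replicate_delta_ct(table, gene, table.control_condition)
    ddct = dct_cond.mean() - dct_ctrl.mean()
    fold = float(2.0 ** (-ddct))
    per_replicate = 2.0 ** (-(dct_cond - dct_ctrl.mean()))
    sd = float(per_replicate.std(ddof=1)) if len(per_replicate) > 1 else 0.0
    return fold, sd


def differential_pvalue(table: QpcrTable, gene: str, condition: str) -> float:
    """Two-sided Welch t-test on per-replicate ΔCt, treatment vs control."""
    dct_cond = replicate_delta_ct(table, gene, condition)
    dct_ctrl = replicate_delta_ct(table, gene, table.control_condition)
    return float(stats.ttest_ind(dct_cond, dct_ctrl, equal_var=False).pvalue)


def call_differential(
    fold: float, pvalue: float, config: DiffCallConfig = DiffCallConfig()
) -> bool:
    """True iff the fold change exceeds the threshold in either direction
    and the p-value beats alpha."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    changed = fold > config.fold_threshold or fold < 1.0 / config.fold_threshold
    return changed and pvalue < config.alpha


def deg_filter(
    expr_table: pd.DataFrame, criteria: DEGCriteria = DEGCriteria()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three-way DEG filter; returns survivors and per-criterion counts.

    The table must carry ``tmm_sum``, ``log2fc`` and ``fdr`` columns. A row
    survives iff tmm_sum >= tmm_sum_min AND |log2fc| > log2fc_abs_min AND
    fdr < fdr_max.
    """
    required = {"tmm_sum", "log2fc", "fdr"}
    missing = required - set(expr_table.columns)
    if missing:
        raise ValueError(f"expression table lacks columns {sorted(missing)}")
    pass_tmm = expr_table["tmm_sum"] >= criteria.tmm_sum_min
    pass_fc = expr_table["log2fc"].abs() > criteria.log2fc_abs_min
    pass_fdr = expr_table["fdr"] < criteria.fdr_max
    audit = {
        "pass_tmm": int(pass_tmm.sum()),
        "pass_log2fc": int(pass_fc.sum()),
        "pass_fdr": int(pass_fdr.sum()),
        "pass_all": int((pass_tmm & pass_fc & pass_fdr).sum()),
    }
    return expr_table[pass_tmm & pass_fc & pass_fdr], audit


@dataclass(frozen=True)
class StressSummary:
    responding: int
    total: int
    fraction: float
    per_stress: dict


def stress_response_summary(calls: pd.DataFrame) -> StressSummary:
    """Summarise a gene x stress boolean matrix of differential-response calls."""
    if calls.empty:
        return StressSummary(0, 0, 0.0, {})
    any_stress = calls.any(axis=1)
    responding = int(any_stress.sum())
    total = int(len(calls))
    per_stress = {col: int(calls[col].sum()) for col in calls.columns}
    return StressSummary(responding, total, responding / total, per_stress)
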