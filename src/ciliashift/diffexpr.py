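"""Genome-wide differential-expression screen.

For every gene: arithmetic means of log2 expression within the case and
control groups, the log2 fold change on the control−case convention
(``down`` = lower in cases), the fold change 2^log2FC (a ratio of
geometric means of intensities), and a two-sample t-test.  The screen
keeps genes with fold change ≥ ``fc_min`` in either direction and raw
t-test p < ``p_max`` — a fold-change floor on an uncorrected t-test, the
classic reproducible screen for small-sample microarray comparisons.
An optional Benjamini–Hochberg FDR column is attached for information
only; it takes no part in the filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, GroupDesign, ValidationError

__all__ = [
    "DERecord",
    "group_stats",
    "fold_change",
    "two_sample_ttest",
    "de_table",
    "de_screen",
    "screen_records",
]


@dataclass
class DERecord:
    """Screening result for one gene."""

    gene_id: str
    mean_log2_case: float
    mean_log2_control: float
    log2_fc: float          # control − case
    fold_change: float      # 2 ** log2_fc
    t_pvalue: float
    direction: str          # "down" = lower in cases


def group_stats(m: ExpressionMatrix, d: GroupDesign, gene: str) -> tuple[float, float]:
    """Arithmetic means of the log2 values over case and control samples."""
    if not m.is_log2:
        raise ValidationError("group statistics are defined on the log2 scale")
    if gene not in m.data.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    row = m.data.loc[gene]
    return (
        float(row[d.case_samples].mean()),
        float(row[d.control_samples].mean()),
    )


def fold_change(mean_log2_case: float, mean_log2_control: float) -> tuple[float, float]:
    """(log2FC, FC) on the control-over-case convention."""
    log2_fc = mean_log2_control - mean_log2_case
    return log2_fc, float(2.0 ** log2_fc)


def two_sample_ttest(case_values, control_values, equal_var: bool = False) -> float:
    """Two-sided two-sample t-test p-value (Welch by default).

    Degenerate inputs with zero variance in both groups return p = 1 when
    the means agree (no evidence of a difference) and p ≈ 0 otherwise.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValidationError("t-test needs at least two values per group")
    if case.std() == 0.0 and control.std() == 0.0:
        return 1.0 if case.mean() == control.mean() else 0.0
    res = stats.ttest_ind(case, control, equal_var=equal_var)
    return float(res.pvalue)


def de_table(
    m: ExpressionMatrix,
    d: GroupDesign,
    equal_var: bool = False,
    add_fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene screen statistics for every row of the matrix (vectorized)."""
    if not m.is_log2:
        raise ValidationError("screen the log2-scaled matrix")
    d.validate_against(m)
    case = m.data[d.case_samples].to_numpy(dtype=float)
    control = m.data[d.control_samples].to_numpy(dtype=float)
    mean_case = case.mean(axis=1)
    mean_control = control.mean(axis=1)
    log2_fc = mean_control - mean_case
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # floor-saturated genes have near-identical values; handled below
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        t_p = stats.ttest_ind(case, control, axis=1, equal_var=equal_var).pvalue
    # zero variance in both groups: no evidence (p=1) unless means differ
    degenerate = (case.std(axis=1) == 0) & (control.std(axis=1) == 0)
    t_p = np.where(degenerate, np.where(mean_case == mean_control, 1.0, 0.0), t_p)
    out = pd.DataFrame(
        {
            "mean_log2_case": mean_case,
            "mean_log2_control": mean_control,
            "log2_fc": log2_fc,
            "fold_change": 2.0 ** log2_fc,
            "t_pvalue": t_p,
            "direction": np.where(log2_fc > 0, "down", "up"),
        },
        index=m.data.index,
    )
    if add_fdr:
        out["fdr_bh"] = _bh_fdr(out["t_pvalue"].to_numpy())
    return out


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = p.size
    adjusted = np.empty(n)
    adjusted[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adjusted, 0, 1)


def screen_records(
    table: pd.DataFrame, fc_min: float = 2.0, p_max: float = 0.05,
    p_column: str = "t_pvalue",
) -> tuple[list[DERecord], list[DERecord]]:
    """Partition pre-computed per-gene rows into (down, up) screen hits.

    ``down`` rows have fold_change ≥ fc_min (lower in cases), ``up`` rows
    have fold_change ≤ 1/fc_min; both require p < p_max.  Each list is
    sorted by p-value ascending.  Accepts both the screen's own column
    names and the fixture tables' ``log2_case``/``log2_control``.
    """
    table = table.rename(
        columns={"log2_case": "mean_log2_case", "log2_control": "mean_log2_control"}
    )
    p = table[p_column]
    fc = table["fold_change"]
    down = table[(fc >= fc_min) & (p < p_max)].sort_values(p_column)
    up = table[(fc <= 1.0 / fc_min) & (p < p_max)].sort_values(p_column)

    def _records(sub: pd.DataFrame) -> list[DERecord]:
        return [
            DERecord(
                gene_id=str(g),
                mean_log2_case=float(r["mean_log2_case"]),
                mean_log2_control=float(r["mean_log2_control"]),
                log2_fc=float(r["log2_fc"]),
                fold_change=float(r["fold_change"]),
                t_pvalue=float(r[p_column]),
                direction="down" if r["log2_fc"] > 0 else "up",
            )
            for g, r in sub.iterrows()
        ]

    return _records(down), _records(up)


def de_screen(
    m: ExpressionMatrix,
    d: GroupDesign,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    equal_var: bool = False,
) -> tuple[list[DERecord], list[DERecord]]:
    """Run the fold-change + t-test screen on a preprocessed matrix.

    Returns (down-regulated, up-regulated) records, each list sorted by
    p-value.  ``fc_min=inf`` yields two empty lists.
    """
    if m.n_rows == 0:
        return [], []
    return screen_records(de_table(m, d, equal_var=equal_var), fc_min, p_max)
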