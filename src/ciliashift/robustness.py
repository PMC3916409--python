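"""Leave-one-out robustness of the set tests and the screen.

Small case groups make any single sample influential; the check here
re-runs the whole analysis with each case sample removed in turn.  The
operational criterion for "the result is stable" is that every gene set
significant in the full design stays below the chosen significance level
in every drop.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import ExpressionMatrix, GeneSet, GroupDesign, ValidationError
from .diffexpr import de_screen
from .setstats import SetTestResult, set_downregulation_test

__all__ = ["LooResult", "leave_one_out", "stability_summary"]


@dataclass
class LooResult:
    """One re-analysis with a single sample removed."""

    dropped_sample: str
    set_results: dict[str, SetTestResult]
    n_down: int
    n_up: int


def leave_one_out(
    m: ExpressionMatrix,
    d: GroupDesign,
    sets: list[GeneSet],
    drop_controls: bool = False,
    fc_min: float = 2.0,
    p_max: float = 0.05,
) -> list[LooResult]:
    """Re-run the screen and every set test once per dropped sample.

    By default only case samples are dropped; ``drop_controls=True``
    extends the loop to control samples.  Deterministic given inputs.
    """
    if d.n_case < 2:
        raise ValidationError("leave-one-out needs at least two case samples")
    to_drop = list(d.case_samples)
    if drop_controls:
        to_drop += list(d.control_samples)
    results = []
    for sample in to_drop:
        sub_design = d.drop_sample(sample)
        sub_matrix = m.subset_samples(list(sub_design.labels))
        down, up = de_screen(sub_matrix, sub_design, fc_min=fc_min, p_max=p_max)
        set_results = {
            s.name: set_downregulation_test(sub_matrix, sub_design, s) for s in sets
        }
        results.append(
            LooResult(
                dropped_sample=sample,
                set_results=set_results,
                n_down=len(down),
                n_up=len(up),
            )
        )
    return results


def stability_summary(results: list[LooResult], alpha: float = 0.01) -> pd.DataFrame:
    """Order statistics of the combined p-value per set across the drops.

    Returns one row per set with min/median/max p_combined and a flag
    ``all_significant`` that is true when every drop stays below
    ``alpha``.  Flags are monotone in alpha.
    """
    if not results:
        raise ValidationError("no leave-one-out results to summarize")
    set_names = list(results[0].set_results)
    rows = []
    for name in set_names:
        p = pd.Series([r.set_results[name].p_combined for r in results])
        rows.append(
            {
                "set_name": name,
                "p_min": p.min(),
                "p_median": p.median(),
                "p_max": p.max(),
                "all_significant": bool((p < alpha).all()),
            }
        )
    columns = ["set_name", "p_min", "p_median", "p_max", "all_significant"]
    return pd.DataFrame(rows, columns=columns).set_index("set_name")
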