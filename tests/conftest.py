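"""Shared fixtures and the brute-force rank-sum oracle."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from ciliashift import ExpressionMatrix, GroupDesign


def enumeration_rank_sum_p(case, control, alternative="case_less", mid_p=False):
    """Exact one-tailed rank-sum p by complete enumeration.

    Walks every C(n1+n2, n1) assignment of the pooled midranks to the
    case group and counts assignments with rank sum at or beyond the
    observed one (half-weight on exact ties of the statistic for mid-p).
    Independent of the package's dynamic-programming implementation.
    """
    pooled = np.concatenate([np.asarray(case, float), np.asarray(control, float)])
    n1, n = len(case), len(pooled)
    r2 = np.rint(2.0 * rankdata(pooled)).astype(int)  # doubled midranks
    w_obs = r2[:n1].sum()
    sums = np.array([sum(r2[list(idx)]) for idx in combinations(range(n), n1)])
    n_total = comb(n, n1)
    n_eq = int((sums == w_obs).sum())
    if alternative == "case_less":
        extreme = int((sums < w_obs).sum())
    else:
        extreme = int((sums > w_obs).sum())
    weight_eq = 0.5 if mid_p else 1.0
    return (extreme + weight_eq * n_eq) / n_total


@pytest.fixture
def small_design():
    return GroupDesign(
        {"c1": "case", "c2": "case", "c3": "case", "k1": "control", "k2": "control"}
    )


@pytest.fixture
def small_matrix():
    """3 genes × 5 samples, log2 scale, one clearly down-shifted gene."""
    data = pd.DataFrame(
        {
            "c1": [1.0, 7.0, 5.0],
            "c2": [2.0, 7.0, 5.5],
            "c3": [3.0, 7.0, 4.5],
            "k1": [8.0, 7.0, 5.2],
            "k2": [9.0, 7.0, 4.8],
        },
        index=["down_gene", "flat_gene", "noise_gene"],
    )
    return ExpressionMatrix(data, is_log2=True)
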