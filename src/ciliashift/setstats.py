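"""Directional gene-set statistics.

The central question: does a predefined set of genes shift coordinately
downward in cases?  Per gene, a one-tailed Wilcoxon–Mann–Whitney rank-sum
test compares case against control expression.  The k per-gene one-tailed
p-values are then combined with the unweighted Z-method (Stouffer): each
p_i becomes a standard normal deviate Z_i = Φ⁻¹(1 − p_i); under the joint
null of independent tests, (ΣZ_i)/√k is standard normal, and the combined
p-value is its upper-tail probability.  Independence across genes is an
assumption, not a theorem — co-regulated sets inflate the type-I error,
which the simulation harness quantifies rather than hides.

The rank-sum test is exact for small samples: the null distribution of
the case rank sum is computed by dynamic programming over all
C(n₁+n₂, n₁) group assignments, with midranks for ties, so the p-value is
the exact tail probability of the observed rank sum (observed value
included).  Above ``exact_threshold`` pooled samples it switches to the
normal approximation with tie correction and continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.stats import norm, rankdata

from .datamodel import ExpressionMatrix, GeneSet, GroupDesign, ValidationError

__all__ = [
    "SetTestResult",
    "wilcoxon_one_tailed",
    "rank_sum_null",
    "combine_z",
    "set_downregulation_test",
    "binomial_set_enrichment",
    "DEFAULT_EXACT_THRESHOLD",
    "CLIP_EPSILON",
]

logger = logging.getLogger(__name__)

DEFAULT_EXACT_THRESHOLD = 25  # pooled-sample cutoff for the exact null
CLIP_EPSILON = 1e-16          # p clipped to [eps, 1-eps] before Φ⁻¹


@dataclass
class SetTestResult:
    """Combined down-regulation evidence for one gene set."""

    set_name: str
    genes: list[str]
    per_gene_p: list[float]
    per_gene_z: list[float]
    z_combined: float
    p_combined: float

    @property
    def k(self) -> int:
        return len(self.per_gene_p)


# ---------------------------------------------------------------------------
# exact Wilcoxon–Mann–Whitney


@lru_cache(maxsize=4096)
def rank_sum_null(n1: int, doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Exact pmf of the case rank sum over all C(N, n1) assignments.

    ``doubled_ranks`` are the pooled midranks times two (integers even with
    ties), sorted.  Returns an array ``pmf`` where ``pmf[s]`` is the
    probability that twice the case rank sum equals ``s``.
    """
    total = sum(doubled_ranks)
    # ways[j, s] = number of j-subsets of the ranks with doubled sum s
    ways = np.zeros((n1 + 1, total + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in doubled_ranks:
        ways[1:, r:] += ways[:-1, : total + 1 - r]
    return ways[n1] / comb(len(doubled_ranks), n1)


def _doubled_midranks(pooled: np.ndarray) -> np.ndarray:
    ranks2 = 2.0 * rankdata(pooled)
    out = np.rint(ranks2).astype(int)
    if not np.allclose(ranks2, out):
        raise AssertionError("midranks should be multiples of 1/2")
    return out


def wilcoxon_one_tailed(
    case_values: Sequence[float],
    control_values: Sequence[float],
    alternative: str = "case_less",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
    mid_p: bool = False,
) -> float:
    """One-tailed rank-sum p-value for a directional location shift.

    ``case_less`` asks whether case values sit below control values (the
    down-regulation direction); ``case_greater`` the reverse.  Exact tail
    probabilities (inclusive of the observed rank sum) are returned when
    the pooled sample size is at most ``exact_threshold``; otherwise the
    normal approximation with tie correction and continuity correction.
    When every pooled value is identical the test carries no evidence and
    returns 1 for either direction.

    ``mid_p=True`` returns the mid-p variant P(W < w) + P(W = w)/2
    (Lancaster's correction): the inclusive p of a discrete statistic is
    stochastically larger than uniform, which biases downstream Z-method
    combination toward conservatism; the mid-p restores a mean of 1/2
    under the null and is the convention used for combining.
    """
    if alternative not in ("case_less", "case_greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = case.size, control.size
    pooled = np.concatenate([case, control])
    ranks2 = _doubled_midranks(pooled)
    w2 = int(ranks2[:n1].sum())

    if n1 + n2 <= exact_threshold:
        pmf = rank_sum_null(n1, tuple(sorted(ranks2)))
        half = pmf[w2] / 2.0 if mid_p else 0.0
        if alternative == "case_less":
            return float(pmf[: w2 + 1].sum() - half)
        return float(pmf[w2:].sum() - half)

    # normal approximation, tie-corrected variance, continuity correction
    n = n1 + n2
    w = w2 / 2.0
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    sd = np.sqrt(var)
    cc = 0.0 if mid_p else 0.5  # mid-p ≈ dropping the continuity correction
    if alternative == "case_less":
        return float(norm.cdf((w + cc - mean) / sd))
    return float(norm.sf((w - cc - mean) / sd))


def _rank_sum_p_many(
    case: np.ndarray, control: np.ndarray, alternative: str = "case_less",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD, mid_p: bool = False,
) -> np.ndarray:
    """Vectorized exact rank-sum p-values for a batch of small tests.

    ``case``: (..., n1), ``control``: (..., n2).  Used by the simulation
    harness; semantics identical to :func:`wilcoxon_one_tailed`.
    """
    n1 = case.shape[-1]
    pooled = np.concatenate([case, control], axis=-1)
    flat = pooled.reshape(-1, pooled.shape[-1])
    n = flat.shape[-1]
    if n > exact_threshold:
        raise ValidationError("vectorized path is exact-only")
    ranks2 = np.rint(2.0 * rankdata(flat, axis=-1)).astype(int)
    w2 = ranks2[:, :n1].sum(axis=-1)
    tied = (np.sort(flat, axis=-1)[:, 1:] == np.sort(flat, axis=-1)[:, :-1]).any(axis=-1)
    out = np.empty(flat.shape[0])
    untied_key = tuple(range(2, 2 * n + 1, 2))
    if (~tied).any():
        pmf = rank_sum_null(n1, untied_key)
        cdf = np.cumsum(pmf)
        sf = np.cumsum(pmf[::-1])[::-1]
        tail = cdf if alternative == "case_less" else sf
        out[~tied] = tail[w2[~tied]]
        if mid_p:
            out[~tied] -= pmf[w2[~tied]] / 2.0
    for i in np.nonzero(tied)[0]:
        pmf = rank_sum_null(n1, tuple(sorted(ranks2[i])))
        half = pmf[w2[i]] / 2.0 if mid_p else 0.0
        if alternative == "case_less":
            out[i] = pmf[: w2[i] + 1].sum() - half
        else:
            out[i] = pmf[w2[i]:].sum() - half
    return out.reshape(case.shape[:-1])


# ---------------------------------------------------------------------------
# unweighted Z-method (Stouffer)


def combine_z(per_gene_p: Sequence[float], clip_epsilon: float = CLIP_EPSILON) -> SetTestResult:
    """Combine k one-tailed p-values by the unweighted Z-method.

    Z_i = Φ⁻¹(1 − p_i); Z = ΣZ_i / √k; combined p = 1 − Φ(Z).  p-values
    are clipped into [clip_epsilon, 1 − clip_epsilon] so that degenerate
    inputs cannot produce infinite deviates; the clip is far below any
    printed-scale p-value.
    """
    p = np.asarray(per_gene_p, dtype=float)
    if p.size == 0:
        raise ValidationError("cannot combine an empty list of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    clipped = np.clip(p, clip_epsilon, 1.0 - clip_epsilon)
    z = norm.isf(clipped)          # Φ⁻¹(1 − p)
    z_combined = float(z.sum() / np.sqrt(p.size))
    p_combined = float(norm.sf(z_combined))
    return SetTestResult(
        set_name="",
        genes=[],
        per_gene_p=p.tolist(),
        per_gene_z=z.tolist(),
        z_combined=z_combined,
        p_combined=p_combined,
    )


def set_downregulation_test(
    m: ExpressionMatrix,
    d: GroupDesign,
    s: GeneSet,
    alternative: str = "case_less",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
    mid_p: bool = True,
) -> SetTestResult:
    """Coordinated-shift test for one gene set on a gene-level log2 matrix.

    Each member gene present in the matrix contributes a one-tailed
    rank-sum p-value (default direction: case below control); the set-level
    evidence is their unweighted Z-method combination.  Members absent from
    the matrix are dropped with a logged warning.

    The per-gene p-values entering the combination use the mid-p
    convention by default (see :func:`wilcoxon_one_tailed`): Stouffer's
    method assumes null p-values uniform on (0, 1), and feeding it the
    inclusive p of a discrete rank statistic makes the combined test
    conservative.  Set ``mid_p=False`` to combine the inclusive p-values.
    """
    if not m.is_log2:
        raise ValidationError("set tests run on the log2-scaled, gene-level matrix")
    d.validate_against(m)
    present = [g for g in s.members if g in m.data.index]
    absent = [g for g in s.members if g not in m.data.index]
    if absent:
        logger.warning("set %s: %d member(s) absent from matrix: %s",
                       s.name, len(absent), absent)
    if not present:
        raise ValidationError(f"no member of set {s.name!r} present in the matrix")
    case_cols, control_cols = d.case_samples, d.control_samples
    per_p = [
        wilcoxon_one_tailed(
            m.data.loc[g, case_cols].to_numpy(dtype=float),
            m.data.loc[g, control_cols].to_numpy(dtype=float),
            alternative=alternative,
            exact_threshold=exact_threshold,
            mid_p=mid_p,
        )
        for g in present
    ]
    combined = combine_z(per_p)
    combined.set_name = s.name
    combined.genes = present
    return combined


# ---------------------------------------------------------------------------
# set-membership enrichment


def binomial_set_enrichment(n_selected: int, n_in_set: int, p0: float) -> float:
    """One-sided exact binomial test of set over-representation.

    Probability of observing at least ``n_in_set`` set members among
    ``n_selected`` draws when the background proportion of set members
    is ``p0``.
    """
    if not (0.0 < p0 < 1.0):
        raise ValidationError("background proportion must lie strictly in (0, 1)")
    if not (0 <= n_in_set <= n_selected):
        raise ValidationError("need 0 <= n_in_set <= n_selected")
    return float(stats.binomtest(n_in_set, n_selected, p0, alternative="greater").pvalue)
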