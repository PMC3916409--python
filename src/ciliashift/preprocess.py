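"""Matrix preprocessing: intensity flooring, log2 scaling, optional
quantile normalization, and probe→gene aggregation.

The floor-and-log2 step mirrors array practice for low-intensity noise:
every linear intensity below a detection threshold (default 5) is raised
to the threshold before taking log2, so values below the detection floor
cannot manufacture spurious fold changes.  Probes mapping to the same gene
are averaged on the log2 scale, i.e. a geometric mean of intensities.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import ExpressionMatrix, ProbeGeneMap, ValidationError

__all__ = ["floor_and_log2", "quantile_normalize", "aggregate_probes_to_genes"]

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 5.0


def floor_and_log2(m: ExpressionMatrix, threshold: float = DEFAULT_FLOOR) -> ExpressionMatrix:
    """Raise linear intensities below ``threshold`` to it, then log2-scale.

    Monotone and idempotent in effect: flooring an already-floored linear
    matrix changes nothing.
    """
    if m.is_log2:
        raise ValidationError("matrix is already on the log2 scale")
    if threshold <= 0:
        raise ValidationError("floor threshold must be positive")
    values = np.log2(np.maximum(m.data.to_numpy(dtype=float), threshold))
    return ExpressionMatrix(
        pd.DataFrame(values, index=m.data.index, columns=m.data.columns),
        is_log2=True,
    )


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean of sorted values.

    After normalization all sample distributions are identical; ties within
    a sample receive the average of the reference values spanned by the
    tied ranks.  Within-sample rank order is preserved up to ties.
    """
    if m.n_samples < 2:
        warnings.warn("quantile normalization needs >=2 samples; returning input")
        return ExpressionMatrix(m.data.copy(), m.is_log2)
    x = m.data.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    grid = np.arange(1, x.shape[0] + 1, dtype=float)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        # fractional midranks interpolate between adjacent reference values
        out[:, j] = np.interp(ranks, grid, reference)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), m.is_log2
    )


def aggregate_probes_to_genes(m: ExpressionMatrix, probe_map: ProbeGeneMap) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene by per-sample mean of log2 values.

    Probes absent from the map are dropped (with a logged count): downstream
    statistics are gene-level, so unmapped probes carry no information.
    """
    if not m.is_log2:
        raise ValidationError("aggregate on the log2 scale (run floor_and_log2 first)")
    mapped = [p for p in m.data.index if p in probe_map.entries]
    if not mapped:
        raise ValidationError("no probe in the matrix is present in the probe map")
    n_dropped = m.n_rows - len(mapped)
    if n_dropped:
        logger.info("dropping %d unmapped probes of %d", n_dropped, m.n_rows)
    sub = m.data.loc[mapped]
    genes = pd.Index([probe_map.entries[p] for p in mapped], name="gene")
    agg = sub.groupby(genes, sort=False).mean()
    return ExpressionMatrix(agg, is_log2=True)
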