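"""Low-intensity filtering and quantile normalization.

The filter removes probes whose signal never clears a biotype-specific
raw-intensity threshold (5 for lncRNA probes, 6 for mRNA probes by
default): a probe is kept iff the larger of its two group means is at or
above its threshold, so probes expressed in only one condition survive.
Filtering operates on raw intensities and precedes normalization; the
kept set defines the matrix that is normalized.

Quantile normalization then forces every sample column to share one value
distribution: the value at rank r in each column becomes the mean over
columns of the r-th smallest values.  Ties within a column receive the
mean of the row-means over their tied ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import (
    BIOTYPE_LNCRNA,
    BIOTYPE_MRNA,
    ExpressionMatrix,
    FeatureAnnotation,
    GROUP_CASE,
    GROUP_CONTROL,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["quantile_normalize", "filter_low_intensity", "FilterReport"]


@dataclass
class FilterReport:
    """Partition of probes into kept and removed, with the thresholds used."""

    kept: set[str]
    removed: set[str]
    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        if self.kept & self.removed:
            raise ValidationError("kept and removed probe sets overlap")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return a matrix whose columns all share the rank-averaged distribution.

    After normalization every column holds the same multiset of values (the
    per-rank means of the sorted input columns), so sorted columns are
    identical and column sums equal.  The operation is idempotent.  A
    single-sample matrix is returned unchanged with a warning.
    """
    values = matrix.values
    n_probes, n_samples = values.shape
    if n_samples < 2:
        logger.warning("single-sample matrix: quantile normalization is a no-op")
        return ExpressionMatrix(
            probe_ids=list(matrix.probe_ids),
            sample_ids=list(matrix.sample_ids),
            groups=dict(matrix.groups),
            values=values.copy(),
        )
    order = np.argsort(values, axis=0, kind="stable")
    row_means = np.mean(np.take_along_axis(values, order, axis=0), axis=1)
    out = np.empty_like(values)
    ranks = np.empty(n_probes, dtype=np.intp)
    for j in range(n_samples):
        ranks[order[:, j]] = np.arange(n_probes)
        col = row_means[ranks].copy()
        # ties: average the row-means over each tied run of the sorted column
        sorted_col = values[order[:, j], j]
        tie_starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        tie_ends = np.r_[tie_starts[1:], n_probes]
        for s, e in zip(tie_starts, tie_ends):
            if e - s > 1:
                col[order[s:e, j]] = row_means[s:e].mean()
        out[:, j] = col
    return ExpressionMatrix(
        probe_ids=list(matrix.probe_ids),
        sample_ids=list(matrix.sample_ids),
        groups=dict(matrix.groups),
        values=out,
    )


def filter_low_intensity(
    matrix: ExpressionMatrix,
    annotation: FeatureAnnotation,
    lnc_threshold: float = 5.0,
    mrna_threshold: float = 6.0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop probes whose max group-mean raw intensity is below threshold.

    The threshold is biotype-specific (lncRNA vs mRNA); the boundary is
    inclusive (a group mean exactly at threshold keeps the probe).  Every
    probe must map to an annotated feature.
    """
    thresholds = {BIOTYPE_LNCRNA: lnc_threshold, BIOTYPE_MRNA: mrna_threshold}
    case = matrix.group_columns(GROUP_CASE).mean(axis=1)
    control = matrix.group_columns(GROUP_CONTROL).mean(axis=1)
    best = np.maximum(case, control)
    kept: set[str] = set()
    removed: set[str] = set()
    for i, probe in enumerate(matrix.probe_ids):
        if probe not in annotation:
            raise ValidationError(f"probe {probe!r} has no annotation entry")
        biotype = annotation[probe].biotype
        if biotype not in thresholds:
            raise ValidationError(f"probe {probe!r}: unknown biotype {biotype!r}")
        (kept if best[i] >= thresholds[biotype] else removed).add(probe)
    report = FilterReport(kept=kept, removed=removed, thresholds=thresholds)
    logger.info("low-intensity filter: kept %d, removed %d probes",
                len(kept), len(removed))
    return matrix.subset_probes(kept), report
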