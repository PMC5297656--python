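"""Fold-change and Student's t-test differential-expression calling.

A feature is called *up* when its case/control ratio of group means is at
or above the fold-change threshold (default 2) and its two-sided
equal-variance t-test p-value (computed on log2 intensities) is below
alpha (default 0.05); *down* symmetrically for ratios at or below the
reciprocal; *unchanged* otherwise.  Benjamini-Hochberg q-values are
reported alongside but do not enter the call.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    DEResult,
    ExpressionMatrix,
    GROUP_CASE,
    GROUP_CONTROL,
    ValidationError,
)

__all__ = ["fold_change", "t_test", "call_de", "de_to_frame"]

DIR_UP = "up"
DIR_DOWN = "down"
DIR_UNCHANGED = "unchanged"


def fold_change(case_values, control_values) -> tuple[float, float, float]:
    """Linear-scale (mean_case, mean_control, fold_change).

    The fold change is the ratio of arithmetic group means on the linear
    intensity scale (the convention in which array results are reported).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValidationError("both groups must be non-empty")
    if np.any(case <= 0) or np.any(control <= 0):
        raise ValidationError("intensities must be strictly positive")
    mean_case = float(case.mean())
    mean_control = float(control.mean())
    if mean_control <= 0:
        raise ValidationError("control mean must be positive")
    return mean_case, mean_control, mean_case / mean_control


def t_test(case_values, control_values) -> float:
    """Two-sided equal-variance (Student's) t-test on log2 intensities.

    Degenerate inputs follow fixed conventions: zero pooled variance with
    equal means gives p = 1.0; zero pooled variance with unequal means
    gives p = 0.0.
    """
    case = np.log2(np.asarray(case_values, dtype=float))
    control = np.log2(np.asarray(control_values, dtype=float))
    if case.size < 2 or control.size < 2:
        raise ValidationError("t-test requires at least 2 values per group")
    if np.ptp(case) == 0 and np.ptp(control) == 0:
        return 1.0 if case[0] == control[0] else 0.0
    with warnings.catch_warnings():
        # quantile normalization can leave near-identical replicate values;
        # scipy warns about precision loss in the moment calculation
        warnings.filterwarnings("ignore", message="Precision loss",
                                category=RuntimeWarning)
        _, p = stats.ttest_ind(case, control, equal_var=True)
    return float(p)


def call_de(
    matrix: ExpressionMatrix,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    inclusive: bool = True,
) -> list[DEResult]:
    """Per-feature DE calls on a normalized, filtered matrix.

    ``inclusive`` controls the fold-change boundary: by default a ratio of
    exactly ``fc_threshold`` (or its reciprocal) qualifies.
    """
    if fc_threshold < 1:
        raise ValidationError("fc_threshold must be >= 1")
    case = matrix.group_columns(GROUP_CASE)
    control = matrix.group_columns(GROUP_CONTROL)
    results = []
    p_values = np.empty(len(matrix.probe_ids))
    rows = []
    for i, probe in enumerate(matrix.probe_ids):
        mean_case, mean_control, fc = fold_change(case[i], control[i])
        p = t_test(case[i], control[i])
        p_values[i] = p
        rows.append((probe, mean_control, mean_case, fc, p))
    if len(rows):
        q_values = multipletests(p_values, method="fdr_bh")[1]
    else:
        q_values = np.empty(0)
    for (probe, mean_control, mean_case, fc, p), q in zip(rows, q_values):
        if inclusive:
            up_fc, down_fc = fc >= fc_threshold, fc <= 1.0 / fc_threshold
        else:
            up_fc, down_fc = fc > fc_threshold, fc < 1.0 / fc_threshold
        if p < alpha and up_fc:
            direction = DIR_UP
        elif p < alpha and down_fc:
            direction = DIR_DOWN
        else:
            direction = DIR_UNCHANGED
        results.append(
            DEResult(
                feature_id=probe,
                mean_control=mean_control,
                mean_case=mean_case,
                fold_change=fc,
                log2_fc=float(np.log2(fc)),
                p_value=p,
                q_value=float(q),
                direction=direction,
            )
        )
    return results


def de_to_frame(results: list[DEResult]):
    """DE results as a DataFrame in the canonical column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "mean_control": r.mean_control,
                "mean_case": r.mean_case,
                "fold_change": r.fold_change,
                "log2_fc": r.log2_fc,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
            }
            for r in results
        ]
    )
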