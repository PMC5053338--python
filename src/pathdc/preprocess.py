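"""Missing-data handling and degenerate-row guards for impact matrices.

Pathways with too many missing contrasts are dropped outright; sparser
gaps are filled with the mean of the pathway's own observed values (row
mean, not column mean — each pathway's impact scale is its own).
Constant rows are removed afterwards because Pearson correlation is
undefined for them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["filter_and_impute", "drop_degenerate"]

REASON_MISSING = "missing_count>=max_missing"
REASON_CONSTANT = "zero_variance"


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=["pathway_id", "reason"])


def filter_and_impute(
    matrix: pd.DataFrame, max_missing: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop heavily-missing pathways and mean-impute the rest.

    Rows whose missing-value count is >= ``max_missing`` are removed and
    logged; remaining missing cells are replaced by the mean of the
    row's observed values.  Observed cells are never modified.

    Returns ``(matrix, removal_log)`` where the log has columns
    ``pathway_id`` and ``reason``.
    """
    if matrix.shape[1] == 0:
        raise ValueError("impact matrix has no contrast columns")
    if max_missing < 1:
        raise ValueError(f"max_missing must be >= 1, got {max_missing}")
    missing = matrix.isna().sum(axis=1)
    removed = matrix.index[missing >= max_missing]
    kept = matrix.drop(index=removed)
    all_missing = kept.index[kept.isna().all(axis=1)]
    if len(all_missing) > 0:
        raise ValueError(
            f"pathway(s) {list(all_missing)} have no observed values but fall "
            f"below max_missing={max_missing}; cannot impute"
        )
    out = kept.apply(lambda row: row.fillna(row.mean()), axis=1)
    log = pd.DataFrame(
        {"pathway_id": list(removed), "reason": REASON_MISSING}
    ) if len(removed) else _empty_log()
    return out, log


def drop_degenerate(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove zero-variance (constant) pathway rows.

    Expects a complete matrix (run :func:`filter_and_impute` first).
    """
    if matrix.isna().any().any():
        raise ValueError("matrix still contains missing values")
    values = matrix.to_numpy(dtype=float)
    constant = matrix.index[np.ptp(values, axis=1) == 0] if matrix.shape[0] else matrix.index[:0]
    out = matrix.drop(index=constant)
    log = pd.DataFrame(
        {"pathway_id": list(constant), "reason": REASON_CONSTANT}
    ) if len(constant) else _empty_log()
    return out, log
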