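"""Decision-coefficient statistics: DC vector, subdivision table,
t-based cutoffs, significance selection, direction and percentages."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimator import (
    DIRECTION_ACTIVATED,
    DIRECTION_INHIBITED,
    DIRECTION_NEUTRAL,
    PathwayDecisionAnalysis,
)
from .path_model import PathModel

__all__ = [
    "decision_coefficients",
    "dc_cutoff",
    "select_impacted",
    "impact_direction",
    "decision_percentages",
]


def decision_coefficients(model: PathModel) -> tuple[pd.Series, pd.DataFrame]:
    """Decision coefficients and the q x q determination-factor table.

    The subdivision table S has (b*_j)^2 on the diagonal and
    2 b*_t r_tj b*_j elsewhere; its column sums are the DC vector.
    """
    est = model.to_estimator()
    ids = list(model.child_ids)
    dc = pd.Series(est.dc_, index=pd.Index(ids, name="child_id"), name="dc")
    subdivision = pd.DataFrame(est.subdivision_, index=ids, columns=ids)
    return dc, subdivision


def dc_cutoff(model: PathModel, alpha: float) -> pd.Series:
    """Per-child significance cutoff for |DC| at two-sided level alpha."""
    est = model.to_estimator()
    return pd.Series(
        est.cutoff(alpha), index=pd.Index(list(model.child_ids), name="child_id"),
        name=f"cutoff_{alpha:g}",
    )


def select_impacted(
    dc: pd.Series, cutoff: pd.Series | float
) -> tuple[pd.Series, list[str]]:
    """Flag children with |DC| >= cutoff and rank them.

    ``cutoff`` is either a per-child Series (aligned on index) or a
    single fixed threshold.  The ranking is by |DC| descending, ties
    broken lexicographically by child id.
    """
    if isinstance(cutoff, pd.Series):
        cutoff = cutoff.reindex(dc.index)
        if cutoff.isna().any():
            raise ValueError("cutoff series does not cover all children")
        flags = dc.abs() >= cutoff
    else:
        flags = dc.abs() >= float(cutoff)
    order = sorted(dc.index, key=lambda c: (-abs(dc[c]), str(c)))
    return flags, order


def impact_direction(dc: pd.Series | Sequence[float]) -> pd.Series:
    """Direction labels from the DC sign: positive -> activated (up),
    negative -> inhibited (down), zero -> neutral."""
    dc = pd.Series(dc) if not isinstance(dc, pd.Series) else dc
    labels = np.full(len(dc), DIRECTION_NEUTRAL, dtype=object)
    labels[dc.to_numpy() > 0] = DIRECTION_ACTIVATED
    labels[dc.to_numpy() < 0] = DIRECTION_INHIBITED
    return pd.Series(labels, index=dc.index, name="direction")


def decision_percentages(dc: pd.Series | Sequence[float]) -> pd.Series:
    """|DC_j| / sum_k |DC_k| * 100 over siblings; sums to 100."""
    dc = pd.Series(dc) if not isinstance(dc, pd.Series) else dc
    total = dc.abs().sum()
    if total == 0:
        raise ValueError("decision percentages undefined: all DC values are zero")
    return (dc.abs() / total * 100.0).rename("decision_percentage")
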