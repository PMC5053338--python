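"""Functional surface for the standardized path-analysis model.

These are thin wrappers over :class:`~pathdc.estimator.PathwayDecisionAnalysis`,
which owns the numerics.  The convention throughout: *variables* are
child pathways, *observations* are contrasts/time points, and all
statistics are computed on Pearson correlations (standardization is
implicit in r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import PathwayDecisionAnalysis

__all__ = [
    "PathModel",
    "EffectDecomposition",
    "CDBreakdown",
    "fit_path_model",
    "correlation_structure",
    "solve_path_coefficients",
    "effect_decomposition",
    "coefficient_of_determination",
]


@dataclass(frozen=True)
class PathModel:
    """Fitted correlation structure and path coefficients for one parent."""

    parent_id: str
    child_ids: tuple[str, ...]
    n: int
    r_x: np.ndarray
    r_xy: np.ndarray
    b_star: np.ndarray
    r2: float
    c_diag: np.ndarray
    condition_flag: bool

    @property
    def q(self) -> int:
        return len(self.child_ids)

    def to_estimator(self, **params) -> PathwayDecisionAnalysis:
        """Rebuild the fitted estimator behind this model."""
        return PathwayDecisionAnalysis.from_correlations(
            self.r_x, self.r_xy, self.n, child_ids=self.child_ids, **params
        )


@dataclass(frozen=True)
class EffectDecomposition:
    """Direct / indirect / total / retro effects per child.

    ``components`` holds r_jk b*_k in cell (j, k), NaN on the diagonal;
    ``table`` has one row per child with columns direct, indirect_sum,
    total and retro.
    """

    components: pd.DataFrame
    table: pd.DataFrame


@dataclass(frozen=True)
class CDBreakdown:
    """Decomposition of the coefficient of determination."""

    direct_cd: float
    indirect_cd: float
    total_cd: float
    direct_ratio: float
    indirect_ratio: float


def _estimator(model: PathModel, **params) -> PathwayDecisionAnalysis:
    return model.to_estimator(**params)


def fit_path_model(
    x_block, y_row, *, child_ids=None, parent_id: str = "", **params
) -> PathModel:
    """Fit the path model for one parent node.

    Parameters
    ----------
    x_block : array-like of shape (q, n)
        Child pathway rows (variables x observations, the impact-matrix
        row layout).
    y_row : array-like of shape (n,)
        The parent pathway's impact row.
    """
    x_block = np.asarray(x_block, dtype=float)
    est = PathwayDecisionAnalysis(**params).fit(x_block.T, np.asarray(y_row, float))
    if child_ids is not None:
        est.child_ids_ = [str(c) for c in child_ids]
    return PathModel(
        parent_id=parent_id,
        child_ids=tuple(est.child_ids_),
        n=est.n_,
        r_x=est.r_x_,
        r_xy=est.r_xy_,
        b_star=est.b_star_,
        r2=est.r2_,
        c_diag=est.c_diag_,
        condition_flag=est.condition_flag_,
    )


def correlation_structure(x_block, y_row) -> tuple[np.ndarray, np.ndarray, int]:
    """Pearson correlation structure (R_x, R_xy, n) for one parent."""
    model = fit_path_model(x_block, y_row)
    return model.r_x, model.r_xy, model.n


def solve_path_coefficients(
    r_x, r_xy, *, on_singular: str = "warn", cond_threshold: float = 1e12
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Solve R_x b* = R_xy.

    Returns ``(b_star, c_diag, condition_flag)``.  With
    ``on_singular="raise"`` a (near-)singular R_x raises
    :class:`~pathdc.estimator.SingularCorrelationError`; otherwise the
    pseudo-inverse is used and the flag set.
    """
    est = PathwayDecisionAnalysis.from_correlations(
        r_x, r_xy, n=len(np.asarray(r_xy).ravel()) + 2,
        on_singular=on_singular, cond_threshold=cond_threshold,
    )
    return est.b_star_, est.c_diag_, est.condition_flag_


def effect_decomposition(model: PathModel) -> EffectDecomposition:
    """Direct, indirect, total and retro-regulation effects per child."""
    est = _estimator(model)
    ids = list(model.child_ids)
    components = pd.DataFrame(est.effect_components_, index=ids, columns=ids)
    table = pd.DataFrame(
        {
            "direct": est.b_star_,
            "indirect_sum": est.indirect_sum_,
            "total": est.total_effect_,
            "retro": est.retro_,
        },
        index=pd.Index(ids, name="child_id"),
    )
    return EffectDecomposition(components=components, table=table)


def coefficient_of_determination(model: PathModel) -> CDBreakdown:
    """R^2 and its direct/indirect subdivision with ratios."""
    est = _estimator(model)
    return CDBreakdown(
        direct_cd=est.direct_cd_,
        indirect_cd=est.indirect_cd_,
        total_cd=est.r2_,
        direct_ratio=est.direct_cd_ratio_,
        indirect_ratio=est.indirect_cd_ratio_,
    )
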