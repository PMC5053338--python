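"""End-to-end pipeline: preprocess -> per-parent path model ->
decision statistics -> annotated decision tree.

Each parent node whose own impact row and all children's impact rows
survive preprocessing is modelled independently; execution order is
hierarchy order but the per-parent results do not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import PathwayDecisionAnalysis
from .hierarchy import PathwayHierarchy
from .preprocess import drop_degenerate, filter_and_impute
from .tree import DecisionTree, build_decision_tree

__all__ = ["AnalysisResult", "analyze_hierarchy"]

_STANDARD_ALPHAS = (0.01, 0.05, 0.10)


@dataclass
class AnalysisResult:
    """Everything one pipeline run produces."""

    report: pd.DataFrame
    subdivisions: dict[str, pd.DataFrame]
    removed: pd.DataFrame
    skipped: list[tuple[str, str]]
    tree: DecisionTree


def _report_rows(
    parent_id: str, est: PathwayDecisionAnalysis, alphas
) -> list[dict]:
    rows = []
    direct = np.diag(est.subdivision_)
    for j, child in enumerate(est.child_ids_):
        significant_at = ",".join(
            f"{alpha:g}" for alpha in alphas
            if alpha in est.significant_ and est.significant_[alpha][j]
        )
        row = {
            "parent_id": parent_id,
            "child_id": child,
            "b_star": est.b_star_[j],
            "direct_factor": direct[j],
            "indirect_factor": est.dc_[j] - direct[j],
            "dc": est.dc_[j],
            "significant_at": significant_at,
            "direction": est.direction_[j],
            "decision_percentage": est.decision_percentage_[j],
        }
        for alpha in _STANDARD_ALPHAS:
            key = f"cutoff_{alpha:.2f}"
            row[key] = est.cutoffs_[alpha][j] if alpha in est.cutoffs_ else np.nan
        rows.append(row)
    return rows


def analyze_hierarchy(
    hierarchy: PathwayHierarchy,
    impact: pd.DataFrame,
    *,
    alphas: tuple[float, ...] = _STANDARD_ALPHAS,
    dc_threshold: float = 0.4,
    max_missing: int = 3,
    on_singular: str = "warn",
    preprocess: bool = True,
) -> AnalysisResult:
    """Run the full decision analysis over every analyzable parent.

    A parent is analyzable when its own impact row and the rows of all
    its (at least two) children survive preprocessing; others are listed
    in ``skipped`` with a reason.  With ``on_singular="raise"`` a
    near-singular child correlation matrix aborts the run.
    """
    removed = pd.DataFrame(columns=["pathway_id", "reason"])
    if preprocess:
        impact, log1 = filter_and_impute(impact, max_missing=max_missing)
        impact, log2 = drop_degenerate(impact)
        removed = pd.concat([log1, log2], ignore_index=True)

    rows: list[dict] = []
    subdivisions: dict[str, pd.DataFrame] = {}
    skipped: list[tuple[str, str]] = []
    for parent_id in hierarchy.parents_with_children():
        children = hierarchy.children(parent_id)
        if parent_id not in impact.index:
            skipped.append((parent_id, "parent impact row missing"))
            continue
        absent = [c for c in children if c not in impact.index]
        if absent:
            skipped.append((parent_id, f"child impact rows missing: {absent}"))
            continue
        if len(children) < 2:
            skipped.append((parent_id, "fewer than two children: correlation structure degenerate"))
            continue
        x = impact.loc[children].to_numpy(dtype=float).T
        y = impact.loc[parent_id].to_numpy(dtype=float)
        est = PathwayDecisionAnalysis(
            alphas=alphas, dc_threshold=dc_threshold, on_singular=on_singular
        ).fit(x, y)
        est.child_ids_ = list(children)
        rows.extend(_report_rows(parent_id, est, alphas))
        subdivisions[parent_id] = pd.DataFrame(
            est.subdivision_, index=children, columns=children
        )

    columns = [
        "parent_id", "child_id", "b_star", "direct_factor", "indirect_factor",
        "dc", "cutoff_0.01", "cutoff_0.05", "cutoff_0.10", "significant_at",
        "direction", "decision_percentage",
    ]
    report = pd.DataFrame(rows, columns=columns)
    tree = build_decision_tree(hierarchy, report)
    return AnalysisResult(
        report=report,
        subdivisions=subdivisions,
        removed=removed,
        skipped=skipped,
        tree=tree,
    )
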