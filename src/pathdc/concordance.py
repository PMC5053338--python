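"""Method-comparison metrics: direction concordance and top-a overlap.

Both metrics are symmetric in their two inputs and, for the overlap,
invariant under monotone transforms of the scores (only the |score|
ranking matters).  Ties in the ranking are broken lexicographically by
id for determinism.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

__all__ = ["direction_concordance", "top_a_overlap"]


def direction_concordance(
    labels_a: Sequence, labels_b: Sequence
) -> tuple[float, int, int]:
    """Fraction of positions with identical direction labels.

    Returns ``(fraction, matches, total)``.
    """
    labels_a, labels_b = list(labels_a), list(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label vectors differ in length ({len(labels_a)} vs {len(labels_b)})"
        )
    if not labels_a:
        raise ValueError("direction concordance undefined for empty vectors")
    matches = sum(a == b for a, b in zip(labels_a, labels_b))
    return matches / len(labels_a), matches, len(labels_a)


def _top_a(scores: pd.Series, a: int) -> set:
    order = sorted(scores.index, key=lambda i: (-abs(scores[i]), str(i)))
    return set(order[:a])


def top_a_overlap(
    scores_a: pd.Series, scores_b: pd.Series, a: int
) -> tuple[float, set]:
    """Overlap of the top-``a`` pathways ranked by |score| in each method.

    ``scores_a`` and ``scores_b`` must share an index (pathway ids).
    Returns ``(fraction, overlap_set)`` with fraction = |A ∩ B| / a.
    """
    scores_a = pd.Series(scores_a) if not isinstance(scores_a, pd.Series) else scores_a
    scores_b = pd.Series(scores_b) if not isinstance(scores_b, pd.Series) else scores_b
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("score vectors must be indexed by the same pathway ids")
    if not 1 <= a <= len(scores_a):
        raise ValueError(f"a must lie in [1, {len(scores_a)}], got {a}")
    overlap = _top_a(scores_a, a) & _top_a(scores_b, a)
    return len(overlap) / a, overlap
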