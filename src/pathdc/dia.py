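"""Pathway impact values from gene-level differential-expression results.

The impact of a pathway in one contrast aggregates its differentially
expressed genes (DEG):

    impact = (#DEG / #annotated genes)
             * mean(|log2 fold change| over DEG)
             * mean(-log10 p-value over DEG)

and is zero when the pathway has no DEG.  The signed direction value is
the impact of the up-regulated DEG minus the impact of the down-regulated
DEG.  Log fold changes enter the magnitude as absolute values; their sign
only routes genes into the up/down split.  DEG status is an input flag —
this module does not define differential expression.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import DEGRecord

__all__ = ["pathway_impact", "impact_direction_value", "impact_table"]


def _deg_subset(degs: Iterable[DEGRecord], pathway: str) -> list[DEGRecord]:
    subset = []
    for record in degs:
        if pathway in record.pathway_ids:
            if record.pvalue <= 0:
                raise ValueError(
                    f"gene {record.gene_id!r}: p-value must be positive"
                )
            if record.is_deg:
                subset.append(record)
    return subset


def _impact_of(subset: list[DEGRecord], gene_universe: int) -> float:
    if not subset:
        return 0.0
    lfc = np.array([abs(r.log2fc) for r in subset])
    logp = np.array([-np.log10(r.pvalue) for r in subset])
    return len(subset) / gene_universe * lfc.mean() * logp.mean()


def pathway_impact(
    degs: Iterable[DEGRecord], pathway: str, gene_universe: int
) -> float:
    """Impact value of ``pathway`` for one contrast's DEG records.

    ``gene_universe`` is the number of genes annotated to the pathway.
    """
    if gene_universe < 1:
        raise ValueError(f"gene_universe must be >= 1, got {gene_universe}")
    return _impact_of(_deg_subset(degs, pathway), gene_universe)


def impact_direction_value(
    degs: Iterable[DEGRecord], pathway: str, gene_universe: int
) -> float:
    """impact(up-regulated DEG) - impact(down-regulated DEG).

    Genes with log2fc exactly zero contribute to neither side.
    """
    if gene_universe < 1:
        raise ValueError(f"gene_universe must be >= 1, got {gene_universe}")
    subset = _deg_subset(degs, pathway)
    up = [r for r in subset if r.log2fc > 0]
    down = [r for r in subset if r.log2fc < 0]
    return _impact_of(up, gene_universe) - _impact_of(down, gene_universe)


def impact_table(
    degs: Iterable[DEGRecord],
    gene_universe: Mapping[str, int],
    *,
    signed: bool = False,
) -> pd.DataFrame:
    """Pathway x contrast impact matrix from a pooled DEG collection.

    ``gene_universe`` maps each pathway id to its annotated gene count
    and fixes the row set of the output.  With ``signed=True`` the
    direction values are tabulated instead of the impact magnitudes.
    """
    degs = list(degs)
    contrasts = sorted({r.contrast for r in degs})
    score = impact_direction_value if signed else pathway_impact
    table = {
        contrast: [
            score([r for r in degs if r.contrast == contrast], pw, count)
            for pw, count in gene_universe.items()
        ]
        for contrast in contrasts
    }
    return pd.DataFrame(
        table, index=pd.Index(list(gene_universe), name="pathway_id")
    )
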