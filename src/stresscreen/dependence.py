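"""Msn2/4-dependence score of a knockout's effect.

For knockout X, compare reporter levels of the single mutant ΔX with the
triple mutant ΔXΔmsn2Δmsn4 and the double Δmsn2Δmsn4:

    D_X = (GFP_ΔX − GFP_ΔXΔmsn2Δmsn4) / (GFP_ΔX − GFP_Δmsn2Δmsn4)

D_X = 1 when the triple mutant collapses to the Δmsn2Δmsn4 level (the
knockout's effect is fully Msn2/4 dependent); 0 ≤ D_X < 1 when part of the
effect survives without Msn2/4 (only D_X·100 percent of the effect is
Msn2/4 dependent); D_X > 1 when the triple drops below Δmsn2Δmsn4 (the gene
cooperates with Msn2/4); and D_X < 0 when removing Msn2/4 on the ΔX
background *raises* reporter levels relative to ΔX.  The score is a ratio
of differences, so it is invariant to affine rescaling of the fluorescence
unit.  When ΔX and Δmsn2Δmsn4 levels are too close the score is undefined
(division by a vanishing effect) and is flagged rather than reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cytometry import ExpressionMatrix
from .synthetic import genotype_name

__all__ = ["DependenceScore", "dependence_score", "screen_dependence"]

#: |D - 1| tolerance for calling the fully-dependent regime.
DEPENDENT_RTOL = 0.05
#: Default denominator floor as a fraction of GFP_WT.
DENOMINATOR_FLOOR_FRAC = 0.02


@dataclass
class DependenceScore:
    gene: str
    condition: str
    value: float | None  # None when undefined
    regime: str  # dependent / partially_independent / cooperative / negative / undefined
    gfp_wt: float
    gfp_x: float
    gfp_msn24: float
    gfp_x_msn24: float

    @property
    def defined(self) -> bool:
        return self.value is not None


def _regime(d: float, rtol: float = DEPENDENT_RTOL) -> str:
    if abs(d - 1.0) <= rtol:
        return "dependent"
    if d < 0.0:
        return "negative"
    if d > 1.0:
        return "cooperative"
    return "partially_independent"


def dependence_score(
    gfp_wt: float,
    gfp_x: float,
    gfp_msn24: float,
    gfp_x_msn24: float,
    gene: str = "X",
    condition: str = "",
    denominator_floor_frac: float = DENOMINATOR_FLOOR_FRAC,
    dependent_rtol: float = DEPENDENT_RTOL,
) -> DependenceScore:
    """Compute D_X with its regime label.

    The denominator GFP_ΔX − GFP_Δmsn2Δmsn4 must exceed
    ``denominator_floor_frac * GFP_WT`` in magnitude; otherwise the score is
    flagged undefined and no number is emitted.
    """
    denom = gfp_x - gfp_msn24
    floor = denominator_floor_frac * abs(gfp_wt)
    if abs(denom) < floor or denom == 0.0:
        return DependenceScore(
            gene, condition, None, "undefined", gfp_wt, gfp_x, gfp_msn24, gfp_x_msn24
        )
    d = (gfp_x - gfp_x_msn24) / denom
    return DependenceScore(
        gene, condition, float(d), _regime(d, dependent_rtol),
        gfp_wt, gfp_x, gfp_msn24, gfp_x_msn24,
    )


def screen_dependence(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    conditions: Sequence[str] | None = None,
    msn24_strain: str | None = None,
    **kwargs,
) -> pd.DataFrame:
    """D_X for every gene x condition available in an expression matrix.

    Expects strains named by :func:`~stresscreen.synthetic.genotype_name`
    conventions: ``geneX``, ``msn2 msn4`` and ``geneX msn2 msn4``.  Genes
    with a missing single or triple strain are skipped.
    """
    conditions = list(conditions or matrix.conditions)
    msn24_strain = msn24_strain or genotype_name(["msn2", "msn4"])
    rows = []
    for gene in genes:
        single = genotype_name([gene])
        triple = genotype_name([gene, "msn2", "msn4"])
        if single not in matrix.values.index or triple not in matrix.values.index:
            continue
        for condition in conditions:
            vals = [
                matrix.value(s, condition)
                for s in ("WT", single, msn24_strain, triple)
            ]
            if not np.all(np.isfinite(vals)):
                continue
            s = dependence_score(*vals, gene=gene, condition=condition, **kwargs)
            rows.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "D": s.value if s.defined else np.nan,
                    "regime": s.regime,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "condition", "D", "regime"])
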