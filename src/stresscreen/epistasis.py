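"""Masking-epistasis calls and their cross-condition consensus.

A pair (X, Y) shows masking epistasis of Y over X when the double mutant's
reporter level resembles the ΔY single mutant (Y's phenotype masks X's; X
is then inferred upstream of Y).  A pair is eligible only when the two
single-knockout effects differ enough to make "resembles one of them"
meaningful: |e_X − e_Y| ≥ 20% of max(|e_X|, |e_Y|) with e_X = GFP_ΔX −
GFP_WT.  On eligible pairs, Y-over-X is called when the double sits within
a fraction δ (default 0.25) of the ΔX–ΔY span from ΔY; symmetrically for
X-over-Y; the closer side wins when both qualify, and an exact tie yields
no call (keeping the call invariant under relabeling of the pair).

The consensus over the three stress conditions colors a pair when epistasis
is called in at least two of them: the shared direction if all calls agree,
otherwise a direction-changed flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cytometry import ExpressionMatrix
from .synthetic import genotype_name

__all__ = [
    "EpistasisParams",
    "EpistasisCall",
    "ConsensusCell",
    "call_epistasis",
    "consensus_epistasis",
    "screen_epistasis",
]

STRESS_CONDITIONS = ("heat", "KCl", "diamide")


@dataclass(frozen=True)
class EpistasisParams:
    #: Minimum effect difference as a fraction of the larger effect.
    eligibility_fraction: float = 0.2
    #: Fraction of the ΔX-ΔY span within which the double "resembles" a single.
    delta: float = 0.25


@dataclass
class EpistasisCall:
    gene_x: str
    gene_y: str
    condition: str
    call: str  # Y_over_X / X_over_Y / none
    eligible: bool
    gfp_wt: float
    gfp_x: float
    gfp_y: float
    gfp_xy: float


@dataclass
class ConsensusCell:
    gene_x: str
    gene_y: str
    consensus: str  # Y_over_X / X_over_Y / direction_changed / none
    supporting_conditions: list[str]


def call_epistasis(
    gfp_wt: float,
    gfp_x: float,
    gfp_y: float,
    gfp_xy: float,
    params: EpistasisParams = EpistasisParams(),
    gene_x: str = "X",
    gene_y: str = "Y",
    condition: str = "",
) -> EpistasisCall:
    """Call masking epistasis for one pair in one condition."""
    e_x = gfp_x - gfp_wt
    e_y = gfp_y - gfp_wt
    max_eff = max(abs(e_x), abs(e_y))
    eligible = max_eff > 0 and abs(e_x - e_y) >= params.eligibility_fraction * max_eff

    call = "none"
    if eligible:
        span = abs(gfp_x - gfp_y)
        if span > 0:
            dist_to_y = abs(gfp_xy - gfp_y)  # small -> double resembles ΔY
            dist_to_x = abs(gfp_xy - gfp_x)
            y_over_x = dist_to_y <= params.delta * span
            x_over_y = dist_to_x <= params.delta * span
            if y_over_x and x_over_y:
                if dist_to_y < dist_to_x:
                    call = "Y_over_X"
                elif dist_to_x < dist_to_y:
                    call = "X_over_Y"
                # exact tie: no call (symmetry under pair relabeling)
            elif y_over_x:
                call = "Y_over_X"
            elif x_over_y:
                call = "X_over_Y"
    return EpistasisCall(gene_x, gene_y, condition, call, eligible, gfp_wt, gfp_x, gfp_y, gfp_xy)


def consensus_epistasis(
    calls_by_condition: Mapping[str, str],
    gene_x: str = "X",
    gene_y: str = "Y",
    min_conditions: int = 2,
) -> ConsensusCell:
    """Cross-condition consensus of a pair's per-condition calls.

    ``calls_by_condition`` maps condition -> call string.  With at least
    ``min_conditions`` real calls: the common direction if unanimous, else
    direction_changed.  Fewer calls -> none.
    """
    called = {c: v for c, v in calls_by_condition.items() if v in ("Y_over_X", "X_over_Y")}
    if len(called) < min_conditions:
        return ConsensusCell(gene_x, gene_y, "none", sorted(called))
    directions = set(called.values())
    consensus = directions.pop() if len(directions) == 1 else "direction_changed"
    return ConsensusCell(gene_x, gene_y, consensus, sorted(called))


def screen_epistasis(
    matrix: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    conditions: Sequence[str] = STRESS_CONDITIONS,
    params: EpistasisParams = EpistasisParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition calls and stress-condition consensus for a pair list.

    Strains are looked up by genotype naming conventions; pairs with a
    missing single or double strain in a condition are skipped there.
    Returns (per-condition call table, consensus table).
    """
    call_rows = []
    consensus_rows = []
    for gx, gy in pairs:
        sx, sy = genotype_name([gx]), genotype_name([gy])
        sxy = genotype_name([gx, gy])
        per_condition: dict[str, str] = {}
        for condition in conditions:
            try:
                vals = [matrix.value(s, condition) for s in ("WT", sx, sy, sxy)]
            except KeyError:
                continue
            if any(pd.isna(v) for v in vals):
                continue
            c = call_epistasis(*vals, params=params, gene_x=gx, gene_y=gy, condition=condition)
            per_condition[condition] = c.call
            call_rows.append(
                {
                    "gene_x": gx,
                    "gene_y": gy,
                    "condition": condition,
                    "call": c.call,
                    "eligible": c.eligible,
                }
            )
        cons = consensus_epistasis(per_condition, gene_x=gx, gene_y=gy)
        consensus_rows.append(
            {
                "gene_x": gx,
                "gene_y": gy,
                "consensus": cons.consensus,
                "supporting_conditions": ",".join(cons.supporting_conditions),
            }
        )
    calls = pd.DataFrame(call_rows, columns=["gene_x", "gene_y", "condition", "call", "eligible"])
    consensus = pd.DataFrame(
        consensus_rows, columns=["gene_x", "gene_y", "consensus", "supporting_conditions"]
    )
    return calls, consensus
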