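"""WT-relative effects and condition specificity.

A knockout's response magnitude in a condition is the ratio of its median
reporter level to the wild-type level in the same condition.  Ratios above
1.1 count as an increase, below 0.8 as a decrease (strict inequalities;
both thresholds configurable).  A knockout with effects in several
conditions is condition-specific when its effect magnitudes spread by more
than 0.3, in which case it is assigned to the above-average conditions (for
increases) or below-average ones (for decreases); otherwise the effect is
common to those conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cytometry import ExpressionMatrix

__all__ = [
    "EffectThresholds",
    "EffectProfile",
    "effect_ratio",
    "classify_effect",
    "assign_specificity",
    "summarize_specificity",
    "profile_strain",
]

STRESS_CONDITIONS = ("heat", "KCl", "diamide")
GROWTH_CONDITIONS = ("log", "post-diauxic")


@dataclass(frozen=True)
class EffectThresholds:
    increase: float = 1.1
    decrease: float = 0.8
    specificity_spread: float = 0.3


@dataclass
class EffectProfile:
    """Per-strain condition effects and their specificity."""

    strain: str
    ratios: dict[str, float]
    log2_ratios: dict[str, float]
    labels: dict[str, str]  # condition -> increase / decrease / none
    #: direction -> list of specific conditions, or the string "common"
    specificity: dict[str, object] = field(default_factory=dict)
    stress_general: bool = False
    stress_magnitude: float | None = None

    def effect_conditions(self, subset: Sequence[str] | None = None) -> list[str]:
        conds = self.labels if subset is None else [c for c in subset if c in self.labels]
        return [c for c in conds if self.labels[c] != "none"]


def effect_ratio(matrix: ExpressionMatrix, strain: str, condition: str) -> float:
    """Strain / WT median reporter ratio in one condition."""
    wt = matrix.wt(condition)
    if not np.isfinite(wt) or wt <= 0:
        raise ValueError(f"WT value missing or non-positive for condition {condition!r}")
    return matrix.value(strain, condition) / wt


def classify_effect(ratio: float, thresholds: EffectThresholds = EffectThresholds()) -> str:
    """Threshold a WT ratio into increase / decrease / none.

    Boundary values are 'none': the thresholds are strict inequalities.
    """
    if ratio <= 0 or not np.isfinite(ratio):
        raise ValueError("ratio must be positive and finite")
    if ratio > thresholds.increase:
        return "increase"
    if ratio < thresholds.decrease:
        return "decrease"
    return "none"


def _magnitude(ratio: float) -> float:
    """Effect magnitude on a common scale: the ratio itself.

    Within one direction magnitudes are compared directly as ratios;
    mixed-direction strains are handled per direction, so this never
    compares an increase against a decrease.
    """
    return ratio


def assign_specificity(
    ratios: Mapping[str, float],
    labels: Mapping[str, str],
    compared: Sequence[str],
    thresholds: EffectThresholds = EffectThresholds(),
) -> dict[str, object]:
    """Assign condition specificity over a compared condition set.

    Returns a mapping from effect direction to either the list of conditions
    the knockout is specific to, or ``"common"`` when its magnitudes across
    effect-bearing conditions spread by at most the specificity threshold.
    Mixed-direction strains are labeled per direction.
    """
    if len(compared) < 2:
        raise ValueError("need at least two conditions to compare")
    out: dict[str, object] = {}
    for direction in ("increase", "decrease"):
        conds = [c for c in compared if labels.get(c) == direction]
        if not conds:
            continue
        if len(conds) == 1:
            out[direction] = conds
            continue
        mags = np.array([_magnitude(ratios[c]) for c in conds])
        if mags.max() - mags.min() > thresholds.specificity_spread:
            mean = mags.mean()
            if direction == "increase":
                keep = [c for c, m in zip(conds, mags) if m > mean]
            else:
                keep = [c for c, m in zip(conds, mags) if m < mean]
            out[direction] = keep
        else:
            out[direction] = "common"
    return out


def profile_strain(
    matrix: ExpressionMatrix,
    strain: str,
    stress_conditions: Sequence[str] = STRESS_CONDITIONS,
    thresholds: EffectThresholds = EffectThresholds(),
) -> EffectProfile:
    """Build the full effect profile of one strain across all conditions."""
    ratios, labels = {}, {}
    for condition in matrix.conditions:
        r = effect_ratio(matrix, strain, condition)
        ratios[condition] = r
        labels[condition] = classify_effect(r, thresholds)
    log2_ratios = {c: float(np.log2(max(r, 1e-12))) for c, r in ratios.items()}

    stress_eff = [c for c in stress_conditions if labels.get(c, "none") != "none"]
    stress_general = len(stress_eff) > 0
    stress_magnitude = (
        max(_magnitude(ratios[c]) for c in stress_eff) if stress_general else None
    )
    compared = [c for c in stress_conditions if c in ratios]
    specificity = (
        assign_specificity(ratios, labels, compared, thresholds) if len(compared) >= 2 else {}
    )
    return EffectProfile(
        strain=strain,
        ratios=ratios,
        log2_ratios=log2_ratios,
        labels=labels,
        specificity=specificity,
        stress_general=stress_general,
        stress_magnitude=stress_magnitude,
    )


def summarize_specificity(
    profiles: Sequence[EffectProfile],
    stress_conditions: Sequence[str] = STRESS_CONDITIONS,
    growth_conditions: Sequence[str] = GROWTH_CONDITIONS,
) -> dict[str, dict[str, int]]:
    """Venn-region counts of effect specificity.

    Two diagrams: (1) among stress conditions, each effect-bearing strain is
    placed in exactly one region -- the subset of stress conditions it is
    specific to (common effects occupy the region of all their effect-bearing
    conditions); (2) stress vs growth, with regions stress-only, growth-only
    and both.  Region keys are '+'-joined sorted condition names.
    """
    stress_regions: dict[str, int] = {}
    cross: dict[str, int] = {"stress_only": 0, "growth_only": 0, "both": 0}
    for p in profiles:
        eff_stress = p.effect_conditions(stress_conditions)
        eff_growth = p.effect_conditions(growth_conditions)
        if eff_stress:
            region: set[str] = set()
            for direction, spec in p.specificity.items():
                conds = [c for c in stress_conditions if p.labels.get(c) == direction]
                if spec == "common":
                    region.update(conds)
                else:
                    region.update(spec)
            if not region:  # no specificity computed (e.g. single condition)
                region = set(eff_stress)
            key = "+".join(sorted(region))
            stress_regions[key] = stress_regions.get(key, 0) + 1
        if eff_stress and eff_growth:
            cross["both"] += 1
        elif eff_stress:
            cross["stress_only"] += 1
        elif eff_growth:
            cross["growth_only"] += 1
    return {"stress": stress_regions, "stress_vs_growth": cross}


def profiles_to_frame(profiles: Sequence[EffectProfile]) -> pd.DataFrame:
    """Flatten profiles into a tidy table (one row per strain x condition)."""
    rows = []
    for p in profiles:
        for c, r in p.ratios.items():
            rows.append(
                {
                    "strain": p.strain,
                    "condition": c,
                    "ratio": r,
                    "log2_ratio": p.log2_ratios[c],
                    "label": p.labels[c],
                    "stress_general": p.stress_general,
                }
            )
    return pd.DataFrame(rows)
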