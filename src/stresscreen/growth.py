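"""Dilution planning for strains of unknown growth rate.

Before a screen, every strain must reach a narrow mid-log OD window at
experiment onset.  Because mutant doubling times are unknown (typically
1.5-3.5 h), each well is split into an X:2X:4X:8X dilution series; after a
fixed growth period the replicate ("source") whose OD best fits the target
window is used.  The planner chooses the dilution constant X that maximizes
the expected number of strains with at least one in-window source, assuming
exponential growth OD(t) = OD0 * 2^(t/dt) with the doubling time dt uniform
over its stated range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DilutionPlan", "plan_dilution", "select_sources", "success_probability"]

#: Fold factors of the dilution series.
SERIES = (1, 2, 4, 8)


@dataclass
class DilutionPlan:
    dilution_constant: float  # X, dimensionless > 1
    series: tuple[float, ...]  # (X, 2X, 4X, 8X)
    success_probability: np.ndarray  # per strain, in [0, 1]

    @property
    def expected_successes(self) -> float:
        return float(self.success_probability.sum())


def _success_for_x(
    od: np.ndarray,
    x: float,
    dt_grid: np.ndarray,
    od_target_range: tuple[float, float],
    growth_hours: float,
) -> np.ndarray:
    """P(at least one source lands in the target window) per strain,
    averaging over the doubling-time grid."""
    lo, hi = od_target_range
    # growth factor per doubling time: shape (n_dt,)
    growth = 2.0 ** (growth_hours / dt_grid)
    # final OD per strain, dt, and series member: (n_strain, n_dt, 4)
    final = od[:, None, None] * growth[None, :, None] / (x * np.array(SERIES)[None, None, :])
    ok = ((final >= lo) & (final <= hi)).any(axis=2)  # (n_strain, n_dt)
    return ok.mean(axis=1)


def success_probability(
    od: np.ndarray | list[float],
    x: float,
    doubling_time_range: tuple[float, float] = (1.5, 3.5),
    od_target_range: tuple[float, float] = (0.2, 0.6),
    growth_hours: float = 10.0,
    dt_resolution: int = 513,
) -> np.ndarray:
    """Per-strain probability that the series X:2X:4X:8X yields an in-window
    source, for a given dilution constant ``x``."""
    od = np.asarray(od, dtype=float)
    lo, hi = doubling_time_range
    dt_grid = np.array([lo]) if lo == hi else np.linspace(lo, hi, dt_resolution)
    return _success_for_x(od, x, dt_grid, od_target_range, growth_hours)


def plan_dilution(
    od: np.ndarray | list[float],
    doubling_time_range: tuple[float, float] = (1.5, 3.5),
    od_target_range: tuple[float, float] = (0.2, 0.6),
    growth_hours: float = 10.0,
    x_grid: np.ndarray | None = None,
    dt_resolution: int = 513,
) -> DilutionPlan:
    """Choose the dilution constant X maximizing expected in-window strains.

    X is searched on a log grid (default 200 points over [2, 512]); ties go
    to the smallest X.  Deterministic.
    """
    od = np.asarray(od, dtype=float)
    if od.size == 0:
        raise ValueError("empty OD vector")
    if np.any(od <= 0):
        raise ValueError("ODs must be positive")
    lo_dt, hi_dt = doubling_time_range
    if not 0 < lo_dt <= hi_dt:
        raise ValueError("invalid doubling time range")
    if od_target_range[0] > od_target_range[1]:
        raise ValueError("inverted OD target range")
    if growth_hours <= 0:
        raise ValueError("growth_hours must be positive")

    if x_grid is None:
        x_grid = np.logspace(np.log10(2.0), np.log10(512.0), 200)
    dt_grid = (
        np.array([lo_dt]) if lo_dt == hi_dt else np.linspace(lo_dt, hi_dt, dt_resolution)
    )
    best_x, best_score, best_probs = None, -np.inf, None
    for x in x_grid:  # ascending grid; strict > keeps the smallest optimum
        probs = _success_for_x(od, float(x), dt_grid, od_target_range, growth_hours)
        score = probs.sum()
        if score > best_score + 1e-12:
            best_x, best_score, best_probs = float(x), score, probs
    return DilutionPlan(
        dilution_constant=best_x,
        series=tuple(best_x * k for k in SERIES),
        success_probability=best_probs,
    )


def select_sources(
    final_ods: np.ndarray | list[list[float]],
    od_target_range: tuple[float, float] = (0.2, 0.6),
) -> list[int | None]:
    """Pick, per well, the dilution source whose final OD best fits the
    target window.

    ``final_ods`` is (n_wells, 4).  "Best fits" is the in-range source
    closest to the window midpoint; wells with no in-range source get None
    (the well stays empty).
    """
    final_ods = np.asarray(final_ods, dtype=float)
    if final_ods.ndim != 2 or final_ods.shape[1] != len(SERIES):
        raise ValueError(f"expected an (n_wells, {len(SERIES)}) OD array")
    lo, hi = od_target_range
    mid = 0.5 * (lo + hi)
    chosen: list[int | None] = []
    for row in final_ods:
        in_range = np.where((row >= lo) & (row <= hi))[0]
        if len(in_range) == 0:
            chosen.append(None)
        else:
            chosen.append(int(in_range[np.argmin(np.abs(row[in_range] - mid))]))
    return chosen
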