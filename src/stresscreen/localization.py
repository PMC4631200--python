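"""Nuclear-localization quantification of a stress-responsive factor.

From per-cell nuclear and cytoplasmic intensity tables: the per-cell N/C
ratio, a per-timepoint population summary (mean by default, median by
config), the area under the summary time course (trapezoid rule, in
ratio·minutes) as a measure of time spent in the nucleus, and averaging
over biological repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocalizationTrace",
    "nc_ratio",
    "timepoint_summary",
    "trace_auc",
    "average_repeats",
    "trace_from_cell_table",
]


@dataclass
class LocalizationTrace:
    strain: str
    condition: str
    timepoints: np.ndarray  # minutes
    ratio: np.ndarray  # population N/C summary per timepoint
    n_cells: np.ndarray  # surviving cells per timepoint
    auc: float  # ratio·minutes
    repeat: int = 0


def nc_ratio(
    nuclear: np.ndarray, cytoplasmic: np.ndarray, background: float = 0.0
) -> tuple[np.ndarray, int]:
    """Per-cell nuclear/cytoplasmic ratio.

    Optional uniform background is subtracted from both channels first.
    Cells whose (background-corrected) cytoplasmic intensity is not positive
    are dropped; returns (ratios of surviving cells, number dropped).
    """
    nuc = np.asarray(nuclear, dtype=float) - background
    cyt = np.asarray(cytoplasmic, dtype=float) - background
    ok = cyt > 0
    return nuc[ok] / cyt[ok], int((~ok).sum())


def timepoint_summary(cell_ratios: np.ndarray, statistic: str = "mean") -> float:
    """Population summary of per-cell ratios at one timepoint."""
    cell_ratios = np.asarray(cell_ratios, dtype=float)
    if len(cell_ratios) == 0:
        raise ValueError("no surviving cells at this timepoint")
    if statistic == "mean":
        return float(np.mean(cell_ratios))
    if statistic == "median":
        return float(np.median(cell_ratios))
    raise ValueError(f"unknown statistic {statistic!r}")


def trace_auc(
    timepoints: Sequence[float],
    ratios: Sequence[float],
    baseline_subtract: bool = False,
) -> float:
    """Trapezoid integral of the summary ratio over time (ratio·minutes).

    With ``baseline_subtract`` the t=0 ratio is removed and the curve clipped
    at zero before integrating; default is the plain integral.
    """
    t = np.asarray(timepoints, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two timepoints")
    if np.any(np.diff(t) < 0):
        raise ValueError("timepoints must be sorted")
    if baseline_subtract:
        r = np.clip(r - r[0], 0.0, None)
    return float(np.trapezoid(r, t))


def trace_from_cell_table(
    cells: pd.DataFrame,
    strain: str = "",
    condition: str = "",
    repeat: int = 0,
    statistic: str = "mean",
    background: float = 0.0,
    baseline_subtract: bool = False,
) -> LocalizationTrace:
    """Summarize a long per-cell table (columns: time, nuclear, cytoplasmic)
    into a population trace with its AUC."""
    times, summaries, counts = [], [], []
    for t, sub in cells.groupby("time", sort=True):
        ratios, _dropped = nc_ratio(
            sub["nuclear"].to_numpy(), sub["cytoplasmic"].to_numpy(), background
        )
        if len(ratios) == 0:
            continue
        times.append(float(t))
        summaries.append(timepoint_summary(ratios, statistic))
        counts.append(len(ratios))
    times_arr = np.array(times)
    ratio_arr = np.array(summaries)
    return LocalizationTrace(
        strain=strain,
        condition=condition,
        timepoints=times_arr,
        ratio=ratio_arr,
        n_cells=np.array(counts, dtype=int),
        auc=trace_auc(times_arr, ratio_arr, baseline_subtract),
        repeat=repeat,
    )


def average_repeats(
    traces: Sequence[LocalizationTrace],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean AUC per strain x condition, plus a repeat-vs-repeat scatter table.

    Returns (final table with columns strain, condition, auc, n_repeats;
    scatter table with one row per repeat pair for reproducibility plots).
    """
    if not traces:
        raise ValueError("no traces given")
    df = pd.DataFrame(
        {
            "strain": [t.strain for t in traces],
            "condition": [t.condition for t in traces],
            "repeat": [t.repeat for t in traces],
            "auc": [t.auc for t in traces],
        }
    )
    final = (
        df.groupby(["strain", "condition"], as_index=False)
        .agg(auc=("auc", "mean"), n_repeats=("auc", "size"))
    )
    scatter_rows = []
    for (strain, condition), sub in df.groupby(["strain", "condition"]):
        reps = sub.sort_values("repeat")
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                scatter_rows.append(
                    {
                        "strain": strain,
                        "condition": condition,
                        "repeat_a": reps["repeat"].iloc[i],
                        "repeat_b": reps["repeat"].iloc[j],
                        "auc_a": reps["auc"].iloc[i],
                        "auc_b": reps["auc"].iloc[j],
                    }
                )
    scatter = pd.DataFrame(
        scatter_rows,
        columns=["strain", "condition", "repeat_a", "repeat_b", "auc_a", "auc_b"],
    )
    return final, scatter
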