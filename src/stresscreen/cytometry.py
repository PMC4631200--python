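"""Flow-cytometry processing: event streams to an expression matrix.

A plate arrives as one continuous, time-stamped event stream from a
sequential plate sampler.  Processing steps: split the stream back into
wells (the sampler leaves dead time between wells), remove debris and
atypical events with an automatic FSC/SSC density gate, take the median
reporter fluorescence per well, subtract the autofluorescence of a GFP-less
control, and average biological replicates into a strain x condition
expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WellMeasurement",
    "ExpressionMatrix",
    "partition_wells",
    "gate_events",
    "well_median_gfp",
    "correct_autofluorescence",
    "aggregate_replicates",
    "read_event_csv",
    "process_plate_stream",
]


@dataclass
class WellMeasurement:
    """Median reporter level of one gated well."""

    strain: str
    condition: str
    replicate: int
    median_gfp: float | None  # None flags a missing/empty well
    n_events_total: int
    n_events_gated: int

    @property
    def missing(self) -> bool:
        return self.median_gfp is None


@dataclass
class ExpressionMatrix:
    """Strain x condition matrix of corrected, replicate-averaged reporter
    levels, with per-condition WT values and replicate provenance."""

    values: pd.DataFrame  # strains x conditions, a.u.
    n_replicates: pd.DataFrame  # same shape, int counts

    def __post_init__(self) -> None:
        if "WT" not in self.values.index:
            raise ValueError("expression matrix must contain a WT row")

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def value(self, strain: str, condition: str) -> float:
        return float(self.values.loc[strain, condition])

    def wt(self, condition: str) -> float:
        return float(self.values.loc["WT", condition])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="strain")


def read_event_csv(path, fsc="fsc", ssc="ssc", gfp="gfp", time="time") -> pd.DataFrame:
    """Read a CSV event table, mapping channel columns to canonical names."""
    df = pd.read_csv(path)
    df = df.rename(columns={fsc: "fsc", ssc: "ssc", gfp: "gfp", time: "time"})
    missing = {"fsc", "ssc", "gfp", "time"} - set(df.columns)
    if missing:
        raise ValueError(f"event table lacks columns: {sorted(missing)}")
    return df


def partition_wells(events: pd.DataFrame, n_wells: int) -> np.ndarray:
    """Assign each event of a time-sorted stream to one of ``n_wells``
    contiguous-in-time segments.

    The segmentation maximizes the total dead time between consecutive
    segments.  Over contiguous ordered segmentations this objective separates
    across boundaries, so the optimum of the dynamic program is attained
    exactly by cutting at the ``n_wells - 1`` largest inter-event gaps (ties
    broken toward the earliest boundary); that closed form is what is
    computed.  Empty trailing segments are allowed when there are fewer
    events than wells.

    Returns an integer array of well indices (0-based, in time order).
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    t = events["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("event stream must be time-sorted")
    n = len(t)
    if n == 0:
        return np.zeros(0, dtype=int)
    if n_wells == 1:
        return np.zeros(n, dtype=int)

    gaps = np.diff(t)  # gap i sits between events i and i+1
    k = min(n_wells - 1, n - 1)
    # stable selection of the k largest gaps, earliest first on ties
    order = np.lexsort((np.arange(len(gaps)), -gaps))
    cut_after = np.sort(order[:k])
    assignment = np.zeros(n, dtype=int)
    assignment[cut_after + 1] = 1
    return np.cumsum(assignment)


def gate_events(
    events: pd.DataFrame, retain_fraction: float = 0.9, resolution: int = 64
) -> pd.DataFrame:
    """Automatic FSC/SSC density gate.

    Builds a ``resolution x resolution`` 2-D histogram over the event cloud
    and retains the events in the densest bins, adding bins in decreasing
    density order until the retained fraction first reaches
    ``retain_fraction``.  The realized fraction therefore overshoots the
    target by at most one bin's mass.

    Returns the gated subset (original row order preserved).
    """
    if not 0.0 < retain_fraction <= 1.0:
        raise ValueError("retain_fraction must be in (0, 1]")
    if resolution < 8:
        raise ValueError("resolution must be >= 8")
    if len(events) == 0:
        raise ValueError("cannot gate an empty event table")
    if retain_fraction == 1.0:
        return events

    x = events["fsc"].to_numpy(dtype=float)
    y = events["ssc"].to_numpy(dtype=float)
    counts, xe, ye = np.histogram2d(x, y, bins=resolution)
    ix = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, resolution - 1)
    iy = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, resolution - 1)
    flat_bin = ix * resolution + iy

    flat_counts = counts.ravel()
    order = np.argsort(-flat_counts, kind="stable")
    cum = np.cumsum(flat_counts[order])
    target = retain_fraction * len(events)
    n_bins = int(np.searchsorted(cum, target, side="left")) + 1
    keep_bins = set(order[:n_bins].tolist())
    mask = np.fromiter((b in keep_bins for b in flat_bin), count=len(flat_bin), dtype=bool)
    return events.loc[mask]


def well_median_gfp(gated: pd.DataFrame) -> float | None:
    """Exact median of the reporter channel; ``None`` flags an empty well."""
    if len(gated) == 0:
        return None
    return float(np.median(gated["gfp"].to_numpy(dtype=float)))


def correct_autofluorescence(median: float, control_median: float) -> float:
    """Subtract the GFP-less control median, clipping at zero.

    Negative corrected values would break downstream ratios and log
    transforms, hence the clip.
    """
    return max(float(median) - float(control_median), 0.0)


def aggregate_replicates(
    measurements: Iterable[WellMeasurement],
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Average corrected replicate medians into an expression matrix.

    Input measurements must already be autofluorescence-corrected.  Returns
    the matrix plus a reproducibility report: the Pearson correlation of
    log10 medians between every replicate pair, per condition, computed over
    the strains present in both replicates.  (Expression is compared on a
    log scale: reporter levels span orders of magnitude across strains.)
    """
    rows = [
        m for m in measurements if not m.missing
    ]
    if not rows:
        raise ValueError("no usable well measurements")
    df = pd.DataFrame(
        {
            "strain": [m.strain for m in rows],
            "condition": [m.condition for m in rows],
            "replicate": [m.replicate for m in rows],
            "median_gfp": [m.median_gfp for m in rows],
        }
    )
    mean = df.pivot_table(index="strain", columns="condition", values="median_gfp", aggfunc="mean")
    counts = df.pivot_table(
        index="strain", columns="condition", values="median_gfp", aggfunc="count"
    ).fillna(0).astype(int)

    report_rows = []
    for condition, sub in df.groupby("condition"):
        pivot = sub.pivot_table(index="strain", columns="replicate", values="median_gfp")
        reps = list(pivot.columns)
        for i, r1 in enumerate(reps):
            for r2 in reps[i + 1 :]:
                pair = pivot[[r1, r2]].dropna()
                if len(pair) < 3:
                    continue
                a = np.log10(np.maximum(pair[r1].to_numpy(), 1e-12))
                b = np.log10(np.maximum(pair[r2].to_numpy(), 1e-12))
                if np.ptp(a) == 0 and np.ptp(b) == 0:
                    r = 1.0  # identical constant vectors
                else:
                    r = float(stats.pearsonr(a, b)[0])
                report_rows.append(
                    {
                        "condition": condition,
                        "replicate_a": r1,
                        "replicate_b": r2,
                        "n_strains": len(pair),
                        "pearson_r_log": r,
                    }
                )
    report = pd.DataFrame(
        report_rows,
        columns=["condition", "replicate_a", "replicate_b", "n_strains", "pearson_r_log"],
    )
    return ExpressionMatrix(values=mean, n_replicates=counts), report


def process_plate_stream(
    stream: pd.DataFrame,
    layout_wells: Sequence[tuple[str, str, str, int]],
    retain_fraction: float = 0.9,
    resolution: int = 64,
    control_strain: str = "noGFP",
) -> list[WellMeasurement]:
    """Full per-plate chain: demultiplex wells, gate, median, correct.

    ``layout_wells`` gives (well id, strain, condition, replicate) in sampler
    order; the stream is split into ``len(layout_wells)`` segments matched to
    that order.  The autofluorescence control median is taken from the
    ``control_strain`` wells of the same plate (per condition; if a condition
    has no control well, the plate-wide control median is used, else 0).
    """
    assignment = partition_wells(stream, len(layout_wells))
    raw: list[tuple[str, str, int, float | None, int, int]] = []
    control_by_condition: dict[str, float] = {}
    control_all: list[float] = []
    for i, (_well_id, strain, condition, replicate) in enumerate(layout_wells):
        seg = stream.loc[assignment == i]
        if len(seg) == 0:
            raw.append((strain, condition, replicate, None, 0, 0))
            continue
        gated = gate_events(seg, retain_fraction, resolution)
        med = well_median_gfp(gated)
        raw.append((strain, condition, replicate, med, len(seg), len(gated)))
        if strain == control_strain and med is not None:
            control_by_condition[condition] = med
            control_all.append(med)

    fallback = float(np.mean(control_all)) if control_all else 0.0
    out = []
    for strain, condition, replicate, med, n_tot, n_gate in raw:
        if med is not None and strain != control_strain:
            med = correct_autofluorescence(med, control_by_condition.get(condition, fallback))
        out.append(
            WellMeasurement(
                strain=strain,
                condition=condition,
                replicate=replicate,
                median_gfp=med,
                n_events_total=n_tot,
                n_events_gated=n_gate,
            )
        )
    return out
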