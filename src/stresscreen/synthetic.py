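"""Synthetic screen generator.

Produces ground-truthed strains, cytometry event streams and localization
traces with the statistical structure the downstream analysis assumes:
log-normal per-cell reporter distributions around strain medians, dense
FSC/SSC clouds with a sparse outlier halo, time-structured per-well event
bursts, and pulsatile nuclear/cytoplasmic localization dynamics.

The generative model for expression mirrors the combined interaction model
used by the analysis: each knockout carries a multiplicative component ``m``
(fold change of the wild-type baseline) and an additive component ``a``
(a.u. offset), so a single knockout's expected reporter level is
``baseline * m + a`` and a double knockout's neutral expectation is
``baseline * m_x * m_y + a_x + a_y``.  A per-gene fraction ``d_frac``
controls how much of the knockout's effect requires the Msn2/4 activators:
in a Δmsn2Δmsn4 background each gene's wild-type-relative effect is scaled
by ``1 - d_frac`` and the baseline drops to a small residual fraction of
the wild-type induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TruthConfig",
    "TruthTable",
    "PlateLayout",
    "WT",
    "NO_GFP",
    "genotype_name",
    "make_truth",
    "expected_gfp",
    "simulate_event_table",
    "simulate_plate_stream",
    "simulate_localization_trace",
    "default_pulse",
    "matrix_from_truth",
]

#: Reserved strain names.
WT = "WT"
NO_GFP = "noGFP"
MSN2 = "msn2"
MSN4 = "msn4"


def genotype_name(genes: Iterable[str]) -> str:
    """Canonical strain name for a set of deleted genes ('' set -> 'WT')."""
    genes = sorted(set(genes))
    return " ".join(genes) if genes else WT


def parse_genotype(name: str) -> frozenset[str]:
    """Inverse of :func:`genotype_name`."""
    if name == WT:
        return frozenset()
    return frozenset(name.split())


@dataclass
class TruthConfig:
    """Sampling ranges and noise levels for :func:`make_truth`.

    Ranges are inclusive.  ``m`` is sampled log-uniformly (fold effects are
    naturally symmetric on a log scale); ``a`` is sampled uniformly as a
    fraction of the condition baseline; ``d_frac`` uniformly on its range.
    """

    m_range: tuple[float, float] = (0.3, 3.0)
    a_frac_range: tuple[float, float] = (-0.3, 0.5)
    d_frac_range: tuple[float, float] = (0.0, 1.2)
    baseline_range: tuple[float, float] = (200.0, 2000.0)
    autofluorescence: float = 20.0
    #: Residual Δmsn2Δmsn4 baseline as a fraction of the WT baseline.
    msn24_baseline_frac: float = 0.2
    #: Per-condition overrides of the residual fraction (e.g. KCl-like 0.3).
    msn24_baseline_frac_by_condition: Mapping[str, float] = field(default_factory=dict)
    replicate_cv: float = 0.05
    cell_log_sd: float = 0.30
    outlier_fraction: float = 0.10
    #: Couple d_frac to the m/a split instead of sampling it independently:
    #: the multiplicative component acts entirely through Msn2/4 and the
    #: additive component entirely bypasses it, so the triple-mutant probe
    #: reports a dependent effect of wt*(m-1) and an independent effect of a.
    #: Emulates screens where multiplicative effects run through the
    #: activators; d_frac is clamped to [-2, 2] for near-neutral knockouts.
    couple_dfrac_to_components: bool = False


@dataclass
class TruthTable:
    """Ground-truth parameters of a synthetic screen."""

    genes: list[str]
    conditions: list[str]
    m: pd.DataFrame  # gene x condition, multiplicative component
    a: pd.DataFrame  # gene x condition, additive component (a.u.)
    d_frac: pd.DataFrame  # gene x condition, Msn2/4-dependent fraction
    wt_baseline: pd.Series  # per condition, a.u. (> 0)
    autofluorescence: pd.Series  # per condition, a.u. (>= 0)
    msn24_baseline_frac: pd.Series  # per condition, dimensionless
    replicate_cv: float
    cell_log_sd: float
    outlier_fraction: float
    #: Optional injected pairwise interaction terms keyed by
    #: (gene_x, gene_y, condition) with gene_x < gene_y; added to the neutral
    #: double-knockout expectation, for testing interaction detection.
    interactions: dict[tuple[str, str, str], float] = field(default_factory=dict)
    seed: int | None = None

    def single_ko_expectation(self, gene: str, condition: str) -> float:
        return float(
            self.wt_baseline[condition] * self.m.loc[gene, condition]
            + self.a.loc[gene, condition]
        )

    def total_effect(self, gene: str, condition: str) -> float:
        """WT-relative effect F of a single knockout."""
        return self.single_ko_expectation(gene, condition) - float(self.wt_baseline[condition])

    def msn24_baseline(self, condition: str) -> float:
        return float(self.wt_baseline[condition] * self.msn24_baseline_frac[condition])

    def to_yaml(self) -> str:
        payload = {
            "genes": list(self.genes),
            "conditions": list(self.conditions),
            "m": {g: self.m.loc[g].to_dict() for g in self.genes},
            "a": {g: self.a.loc[g].to_dict() for g in self.genes},
            "d_frac": {g: self.d_frac.loc[g].to_dict() for g in self.genes},
            "wt_baseline": self.wt_baseline.to_dict(),
            "autofluorescence": self.autofluorescence.to_dict(),
            "msn24_baseline_frac": self.msn24_baseline_frac.to_dict(),
            "replicate_cv": self.replicate_cv,
            "cell_log_sd": self.cell_log_sd,
            "outlier_fraction": self.outlier_fraction,
            "seed": self.seed,
        }
        return yaml.safe_dump(payload, sort_keys=True)


@dataclass
class PlateLayout:
    """Ordered well list of a measurement plate."""

    wells: list[tuple[str, str, str, int]]  # (well id, strain name, condition, replicate)
    plate_format: int = 96

    def __post_init__(self) -> None:
        ids = [w[0] for w in self.wells]
        if len(ids) != len(set(ids)):
            raise ValueError("well ids must be unique")
        if self.plate_format not in (96, 384):
            raise ValueError("plate format must be 96 or 384")

    def __len__(self) -> int:
        return len(self.wells)


def make_truth(
    genes: Sequence[str],
    conditions: Sequence[str],
    config: TruthConfig | None = None,
    seed: int = 0,
) -> TruthTable:
    """Sample a ground-truth parameter table for a synthetic screen.

    Deterministic: the same (genes, conditions, config, seed) always yields
    an identical table.
    """
    if len(genes) == 0:
        raise ValueError("at least one gene is required")
    if len(conditions) == 0:
        raise ValueError("at least one condition is required")
    config = config or TruthConfig()
    if config.baseline_range[0] <= 0:
        raise ValueError("baseline range must be positive")

    rng = np.random.default_rng(seed)
    genes = list(genes)
    conditions = list(conditions)
    n_g, n_c = len(genes), len(conditions)

    lo, hi = config.m_range
    m = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_g, n_c)))
    baseline = rng.uniform(*config.baseline_range, size=n_c)
    a = rng.uniform(*config.a_frac_range, size=(n_g, n_c)) * baseline[None, :]
    frac = pd.Series(
        [config.msn24_baseline_frac_by_condition.get(c, config.msn24_baseline_frac) for c in conditions],
        index=conditions,
        dtype=float,
    )
    if config.couple_dfrac_to_components:
        # choose d so the triple-mutant probe D = (x - triple)/(x - msn24b)
        # satisfies D*F = wt*(m-1) exactly, i.e. the dependent effect is the
        # multiplicatively routed share and the independent effect is a
        F = baseline[None, :] * (m - 1.0) + a
        span = F + baseline[None, :] * (1.0 - frac.to_numpy()[None, :])  # x - msn24b
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(np.abs(F) > 1e-9, 1.0 - span * a / F**2, 1.0)
        d = np.clip(d, -2.0, 2.0)
    else:
        d = rng.uniform(*config.d_frac_range, size=(n_g, n_c))
    return TruthTable(
        genes=genes,
        conditions=conditions,
        m=pd.DataFrame(m, index=genes, columns=conditions),
        a=pd.DataFrame(a, index=genes, columns=conditions),
        d_frac=pd.DataFrame(d, index=genes, columns=conditions),
        wt_baseline=pd.Series(baseline, index=conditions),
        autofluorescence=pd.Series(config.autofluorescence, index=conditions, dtype=float),
        msn24_baseline_frac=frac,
        replicate_cv=config.replicate_cv,
        cell_log_sd=config.cell_log_sd,
        outlier_fraction=config.outlier_fraction,
        seed=seed,
    )


def expected_gfp(genotype: Iterable[str], condition: str, truth: TruthTable) -> float:
    """Noise-free expected reporter level of a genotype (a.u., without
    autofluorescence).

    Non-msn genotypes compose as ``baseline * prod(m_i) + sum(a_i)`` plus any
    injected interaction terms.  When both msn2 and msn4 are deleted the
    baseline drops to its configured residual fraction and every other gene's
    WT-relative effect is scaled by ``1 - d_frac`` (its Msn2/4-independent
    share); a gene whose deletion is fully Msn2/4 dependent (d_frac = 1) then
    contributes nothing beyond the Δmsn2Δmsn4 level.
    """
    genes = frozenset(genotype)
    wt = float(truth.wt_baseline[condition])
    if {MSN2, MSN4} <= genes:
        rest = sorted(genes - {MSN2, MSN4})
        unknown = [g for g in rest if g not in truth.m.index]
        if unknown:
            raise KeyError(f"unknown genes: {unknown}")
        value = truth.msn24_baseline(condition)
        for g in rest:
            effect = truth.total_effect(g, condition)
            value += (1.0 - float(truth.d_frac.loc[g, condition])) * effect
        return value

    unknown = [g for g in genes if g not in truth.m.index]
    if unknown:
        raise KeyError(f"unknown genes: {unknown}")
    value = wt
    for g in genes:
        value *= float(truth.m.loc[g, condition])
    for g in genes:
        value += float(truth.a.loc[g, condition])
    for gx, gy in {(x, y) for x in genes for y in genes if x < y}:
        value += truth.interactions.get((gx, gy, condition), 0.0)
    return value


# FSC/SSC dense-cloud parameters (a.u.): a tight correlated cell cluster on
# an 18-bit digital scatter scale.  Outliers (debris, dead cells, doublets)
# are uniform over the instrument's full measurement range.
_FSC_MEAN, _FSC_SD = 50_000.0, 8_000.0
_SSC_MEAN, _SSC_SD = 30_000.0, 6_000.0
_SCATTER_CORR = 0.6
_SCATTER_RANGE = (0.0, 262_144.0)


def _scatter_cloud(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    cov = np.array(
        [
            [_FSC_SD**2, _SCATTER_CORR * _FSC_SD * _SSC_SD],
            [_SCATTER_CORR * _FSC_SD * _SSC_SD, _SSC_SD**2],
        ]
    )
    xy = rng.multivariate_normal([_FSC_MEAN, _SSC_MEAN], cov, size=n, method="cholesky")
    return xy[:, 0], xy[:, 1]


def simulate_event_table(
    genotype: Iterable[str] | str,
    condition: str,
    truth: TruthTable,
    n_events: int,
    seed: int = 0,
    outlier_fraction: float | None = None,
    mean_event_spacing: float = 0.01,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Simulate the raw event table of one cytometer well.

    Returns a DataFrame with columns ``fsc, ssc, gfp, time`` plus a hidden
    boolean ``is_outlier`` column recording which events came from the sparse
    halo rather than the dense cell cloud (ground truth for gate testing).

    Per-event GFP is the autofluorescence offset plus a log-normal draw whose
    median equals ``scale`` times the genotype's expected reporter level
    (``scale`` carries well-level biological replicate noise); the no-GFP
    control strain shows only (log-normally jittered) autofluorescence.
    """
    if n_events <= 0:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    offset = float(truth.autofluorescence[condition])
    outlier_fraction = (
        truth.outlier_fraction if outlier_fraction is None else float(outlier_fraction)
    )

    log_noise = np.exp(rng.normal(0.0, truth.cell_log_sd, size=n_events))
    if isinstance(genotype, str) and genotype == NO_GFP:
        gfp = offset * log_noise
    else:
        genes = parse_genotype(genotype) if isinstance(genotype, str) else frozenset(genotype)
        expected = expected_gfp(genes, condition, truth)
        gfp = offset + scale * expected * log_noise

    n_out = int(round(outlier_fraction * n_events))
    fsc, ssc = _scatter_cloud(rng, n_events)
    is_outlier = np.zeros(n_events, dtype=bool)
    if n_out > 0:
        idx = rng.choice(n_events, size=n_out, replace=False)
        is_outlier[idx] = True
        fsc[idx] = rng.uniform(*_SCATTER_RANGE, size=n_out)
        ssc[idx] = rng.uniform(*_SCATTER_RANGE, size=n_out)
    time = np.cumsum(rng.exponential(mean_event_spacing, size=n_events))
    return pd.DataFrame(
        {"fsc": fsc, "ssc": ssc, "gfp": gfp, "time": time, "is_outlier": is_outlier}
    )


def simulate_plate_stream(
    layout: PlateLayout,
    truth: TruthTable,
    events_per_well: int = 5000,
    gap_seconds: float = 5.0,
    seed: int = 0,
    mean_event_spacing: float = 0.01,
    replicate_noise: bool = True,
) -> pd.DataFrame:
    """Simulate the continuous event stream of a sequentially sampled plate.

    Wells are emitted in layout order as bursts separated by ``gap_seconds``
    of dead time (the sampler moving between wells).  Each well's expected
    level is jittered by a log-normal biological replicate factor of CV
    ``truth.replicate_cv`` unless ``replicate_noise`` is off.  The returned
    table carries hidden ``true_well`` labels for testing well
    demultiplexing.
    """
    if len(layout) == 0:
        raise ValueError("layout must contain at least one well")
    rng = np.random.default_rng(seed)
    frames = []
    t0 = 0.0
    cv = truth.replicate_cv if replicate_noise else 0.0
    for i, (well_id, strain, condition, _rep) in enumerate(layout.wells):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        scale = float(np.exp(rng.normal(0.0, cv))) if cv > 0 else 1.0
        tbl = simulate_event_table(
            strain, condition, truth, events_per_well, seed=sub_seed,
            mean_event_spacing=mean_event_spacing, scale=scale,
        )
        tbl["time"] = tbl["time"].to_numpy() + t0
        tbl["true_well"] = i
        tbl["well_id"] = well_id
        t0 = float(tbl["time"].iloc[-1]) + gap_seconds
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)


@dataclass
class PulseShape:
    """Population N/C-ratio time course of a localization experiment.

    ``kind='pulse'`` is a log-normal-in-time bump (sharp import, slower
    export, full adaptation), the osmotic-stress prototype; ``kind='sustained'``
    is a saturating rise with no return, the redox-stress prototype.
    Times in minutes, ratios dimensionless.
    """

    baseline: float = 1.0
    amplitude: float = 2.0
    peak_minutes: float = 15.0
    width: float = 0.45  # log-time sd of the pulse / rise time constant scale
    kind: str = "pulse"

    def ratio(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "pulse":
            shape = np.zeros_like(t)
            pos = t > 0
            shape[pos] = np.exp(
                -((np.log(t[pos] / self.peak_minutes)) ** 2) / (2.0 * self.width**2)
            )
        elif self.kind == "sustained":
            shape = 1.0 - np.exp(-np.maximum(t, 0.0) / self.peak_minutes)
        else:
            raise ValueError(f"unknown pulse kind {self.kind!r}")
        return self.baseline + self.amplitude * shape


def default_pulse(condition: str) -> PulseShape:
    """Condition-prototypical localization dynamics.

    KCl-like: strong pulse peaking near 15 min, back to baseline by ~45-50
    min.  Diamide-like: lower amplitude, sustained for >100 min.  Any other
    condition gets a flat trace (no nuclear accumulation).
    """
    c = condition.lower()
    if "kcl" in c or "osmotic" in c:
        return PulseShape(baseline=1.0, amplitude=2.0, peak_minutes=15.0, width=0.45, kind="pulse")
    if "diamide" in c or "redox" in c:
        return PulseShape(baseline=1.0, amplitude=0.8, peak_minutes=10.0, kind="sustained")
    return PulseShape(baseline=1.0, amplitude=0.0)


def simulate_localization_trace(
    strain: str,
    condition: str,
    truth: TruthTable | None,
    timepoints: Sequence[float],
    n_cells: int = 100,
    seed: int = 0,
    pulse: PulseShape | None = None,
    cell_noise_sd: float = 0.10,
    cytoplasm_mean: float = 100.0,
) -> pd.DataFrame:
    """Simulate a per-cell nuclear/cytoplasmic intensity table.

    Returns a long DataFrame with columns ``cell, time, nuclear, cytoplasmic``
    such that the per-timepoint population median N/C ratio follows the pulse
    (the per-cell log-normal jitter has median 1).  ``truth`` is accepted for
    interface symmetry with the other simulators and may be None.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.ndim != 1 or len(timepoints) < 2:
        raise ValueError("need at least two timepoints")
    if np.any(np.diff(timepoints) < 0):
        raise ValueError("timepoints must be sorted")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    pulse = pulse or default_pulse(condition)
    rng = np.random.default_rng(seed)

    target = pulse.ratio(timepoints)  # population ratio per timepoint
    n_t = len(timepoints)
    cyto = cytoplasm_mean * np.exp(rng.normal(0.0, 0.2, size=(n_cells, 1)))
    cyto = np.broadcast_to(cyto, (n_cells, n_t)).copy()
    jitter = np.exp(rng.normal(0.0, cell_noise_sd, size=(n_cells, n_t))) if cell_noise_sd > 0 else 1.0
    nuc = cyto * target[None, :] * jitter
    cells, times = np.meshgrid(np.arange(n_cells), timepoints, indexing="ij")
    return pd.DataFrame(
        {
            "cell": cells.ravel(),
            "time": times.ravel(),
            "nuclear": nuc.ravel(),
            "cytoplasmic": cyto.ravel(),
        }
    )


def matrix_from_truth(
    truth: TruthTable,
    pairs: Sequence[tuple[str, str]] = (),
    include_triples: bool = False,
    replicate_cv: float | None = None,
    n_replicates: int = 1,
    seed: int = 0,
):
    """Build an expression matrix of noise-free expectations (plus optional
    log-normal replicate noise) directly from a truth table.

    Skips the cytometry simulation entirely: strains are WT, every single
    knockout, the requested doubles, and optionally the Δmsn2Δmsn4 double
    and all ΔXΔmsn2Δmsn4 triples needed for dependence scoring.  With
    ``replicate_cv`` > 0, each strain value is the mean of ``n_replicates``
    independently jittered replicates (CV per replicate).
    """
    from .cytometry import ExpressionMatrix  # deferred: avoid import cycle

    rng = np.random.default_rng(seed)
    cv = truth.replicate_cv if replicate_cv is None else replicate_cv
    genotypes: list[frozenset[str]] = [frozenset()]
    genotypes += [frozenset([g]) for g in truth.genes]
    genotypes += [frozenset(p) for p in pairs]
    if include_triples:
        genotypes.append(frozenset([MSN2, MSN4]))
        genotypes += [
            frozenset([g, MSN2, MSN4]) for g in truth.genes if g not in (MSN2, MSN4)
        ]
    # dedupe, stable order
    seen: list[frozenset[str]] = []
    for g in genotypes:
        if g not in seen:
            seen.append(g)

    values = {}
    for geno in seen:
        row = {}
        for condition in truth.conditions:
            exp = expected_gfp(geno, condition, truth)
            if cv > 0:
                reps = exp * np.exp(rng.normal(0.0, cv, size=n_replicates))
                row[condition] = float(np.mean(reps))
            else:
                row[condition] = exp
        values[genotype_name(geno)] = row
    df = pd.DataFrame.from_dict(values, orient="index")[list(truth.conditions)]
    counts = pd.DataFrame(n_replicates, index=df.index, columns=df.columns)
    return ExpressionMatrix(values=df, n_replicates=counts)
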