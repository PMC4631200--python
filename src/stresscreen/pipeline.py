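"""End-to-end screen pipeline: simulate -> process -> analyze -> report.

Orchestrates the full chain on a synthetic screen: ground-truth sampling,
per-plate event-stream simulation, well demultiplexing, gating, medians,
autofluorescence correction, replicate averaging, WT-relative effect
profiles, Msn2/4-dependence scores, epistasis calls and consensus,
interaction-model fits, and localization AUC quantification.  Every stage
writes a plain-text table; a JSON manifest records config and seeds so that
an identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cytometry import aggregate_replicates, process_plate_stream
from .dependence import screen_dependence
from .effects import (
    EffectThresholds,
    profile_strain,
    profiles_to_frame,
    summarize_specificity,
)
from .epistasis import EpistasisParams, screen_epistasis
from .interactions import (
    component_dependence_correlation,
    fit_additive,
    fit_combined,
    fit_multiplicative,
)
from .localization import average_repeats, trace_from_cell_table
from .synthetic import (
    NO_GFP,
    WT,
    PlateLayout,
    TruthConfig,
    genotype_name,
    make_truth,
    simulate_localization_trace,
    simulate_plate_stream,
)

__all__ = ["RunConfig", "run_screen", "build_screen_layout"]

DEFAULT_CONDITIONS = ["log", "heat", "KCl", "diamide", "post-diauxic"]


@dataclass
class RunConfig:
    """Pipeline configuration with screen-protocol defaults.

    The default synthetic screen is a scaled-down epistasis map (6 query x
    10 target genes, all query-target doubles, 2 replicates, 1,000 events
    per well) over the five standard conditions; thresholds carry the
    screen's published defaults (effect ratios 1.1/0.8, specificity spread
    0.3, 20% epistasis eligibility, 90% gate retention at 64x64 bins).
    """

    outdir: str = "screen_output"
    conditions: list[str] = field(default_factory=lambda: list(DEFAULT_CONDITIONS))
    query_genes: list[str] = field(default_factory=lambda: [f"q{i:02d}" for i in range(6)])
    target_genes: list[str] = field(default_factory=lambda: [f"t{i:02d}" for i in range(10)])
    replicates: int = 2
    events_per_well: int = 1000
    gap_seconds: float = 5.0
    retain_fraction: float = 0.9
    resolution: int = 64
    increase_threshold: float = 1.1
    decrease_threshold: float = 0.8
    specificity_spread: float = 0.3
    epistasis_eligibility: float = 0.2
    epistasis_delta: float = 0.25
    localization_strains: list[str] = field(default_factory=lambda: [WT, "q00", "q01"])
    localization_conditions: list[str] = field(default_factory=lambda: ["KCl", "diamide"])
    localization_repeats: int = 2
    localization_cells: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.retain_fraction <= 1:
            raise ValueError("retain_fraction must be in (0, 1]")
        if self.resolution < 8:
            raise ValueError("resolution must be >= 8")
        if self.decrease_threshold >= self.increase_threshold:
            raise ValueError("decrease threshold must lie below increase threshold")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.query_genes + self.target_genes))

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """Double-knockout design: every query x target cross plus the
        query x query doubles.

        The within-query doubles make the combined-model decomposition
        identifiable: on a purely bipartite query x target design the
        bilinear term of the model admits a one-parameter rescaling of the
        two sides that leaves every expectation unchanged.
        """
        crosses = [
            tuple(sorted((q, t)))
            for q in self.query_genes
            for t in self.target_genes
            if q != t
        ]
        within = [
            tuple(sorted((a, b)))
            for i, a in enumerate(self.query_genes)
            for b in self.query_genes[i + 1 :]
        ]
        return sorted(set(crosses + within))

    def effect_thresholds(self) -> EffectThresholds:
        return EffectThresholds(
            increase=self.increase_threshold,
            decrease=self.decrease_threshold,
            specificity_spread=self.specificity_spread,
        )

    def epistasis_params(self) -> EpistasisParams:
        return EpistasisParams(
            eligibility_fraction=self.epistasis_eligibility, delta=self.epistasis_delta
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def build_screen_layout(
    config: RunConfig, condition: str, replicate: int
) -> list[PlateLayout]:
    """Well lists (chunked into 96-well plates) for one condition/replicate.

    Strains: controls (WT, no-GFP, Δmsn2Δmsn4), every single knockout, every
    query x target double, and the ΔXΔmsn2Δmsn4 triples needed for
    dependence scoring.
    """
    strains = [WT, NO_GFP, genotype_name(["msn2", "msn4"])]
    strains += [genotype_name([g]) for g in config.genes]
    strains += [genotype_name(p) for p in config.pairs]
    strains += [genotype_name([g, "msn2", "msn4"]) for g in config.genes]
    strains = list(dict.fromkeys(strains))

    plates = []
    for start in range(0, len(strains), 96):
        chunk = strains[start : start + 96]
        wells = [
            (f"{condition}-r{replicate}-p{start // 96}-w{i:03d}", s, condition, replicate)
            for i, s in enumerate(chunk)
        ]
        plates.append(PlateLayout(wells=wells, plate_format=96))
    return plates


def run_screen(config: RunConfig) -> dict:
    """Run the full pipeline and write all outputs under ``config.outdir``.

    Returns a results bundle (in-memory objects plus output paths).
    Deterministic: identical config + seed give identical tables.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)

    # --- simulate ground truth -------------------------------------------
    truth = make_truth(
        config.genes,
        config.conditions,
        TruthConfig(msn24_baseline_frac_by_condition={"KCl": 0.3}),
        seed=int(master.integers(0, 2**31 - 1)),
    )
    (outdir / "truth.yaml").write_text(truth.to_yaml())

    # --- cytometry chain --------------------------------------------------
    measurements = []
    for condition in config.conditions:
        for replicate in range(config.replicates):
            for layout in build_screen_layout(config, condition, replicate):
                stream = simulate_plate_stream(
                    layout,
                    truth,
                    events_per_well=config.events_per_well,
                    gap_seconds=config.gap_seconds,
                    seed=int(master.integers(0, 2**31 - 1)),
                )
                measurements += process_plate_stream(
                    stream,
                    layout.wells,
                    retain_fraction=config.retain_fraction,
                    resolution=config.resolution,
                    control_strain=NO_GFP,
                )
    matrix, repro = aggregate_replicates(
        [m for m in measurements if m.strain != NO_GFP]
    )
    matrix.to_tsv(outdir / "expression_matrix.tsv")
    repro.to_csv(outdir / "replicate_reproducibility.tsv", sep="\t", index=False)

    # --- effects ----------------------------------------------------------
    thresholds = config.effect_thresholds()
    profiles = [
        profile_strain(matrix, genotype_name([g]), thresholds=thresholds)
        for g in config.genes
        if genotype_name([g]) in matrix.values.index
    ]
    profiles_to_frame(profiles).to_csv(outdir / "effect_profiles.tsv", sep="\t", index=False)
    venn = summarize_specificity(profiles)
    (outdir / "specificity_venn.json").write_text(json.dumps(venn, indent=2))

    # --- Msn2/4 dependence ------------------------------------------------
    dep = screen_dependence(matrix, config.genes)
    dep.to_csv(outdir / "dependence_scores.tsv", sep="\t", index=False)

    # --- epistasis --------------------------------------------------------
    stress = [c for c in ("heat", "KCl", "diamide") if c in config.conditions]
    calls, consensus = screen_epistasis(
        matrix, config.pairs, conditions=stress or config.conditions,
        params=config.epistasis_params(),
    )
    calls.to_csv(outdir / "epistasis_calls.tsv", sep="\t", index=False)
    consensus.to_csv(outdir / "epistasis_consensus.tsv", sep="\t", index=False)

    # --- interaction models ----------------------------------------------
    fits = {}
    fit_report = {}
    for condition in config.conditions:
        per_model = {
            "additive": fit_additive(matrix, condition, config.genes),
            "multiplicative": fit_multiplicative(matrix, condition, config.genes),
            "combined": fit_combined(matrix, condition, config.genes),
        }
        fits[condition] = per_model
        fit_report[condition] = {name: f.r2 for name, f in per_model.items()}
        per_model["combined"].pairs.to_csv(
            outdir / f"interactions_{condition}.tsv", sep="\t", index=False
        )
        comp_rows = [
            {"gene": c.gene, "F": c.F, "M": c.M, "a": c.a, "m": c.m}
            for c in per_model["combined"].components.values()
        ]
        pd.DataFrame(comp_rows).to_csv(
            outdir / f"components_{condition}.tsv", sep="\t", index=False
        )

    correlations = {}
    for condition in config.conditions:
        dep_c = dep[dep["condition"] == condition]
        comps = list(fits[condition]["combined"].components.values())
        try:
            correlations[condition] = component_dependence_correlation(comps, dep_c)
        except (ValueError, KeyError):
            correlations[condition] = None
    (outdir / "fit_report.json").write_text(
        json.dumps({"r2": fit_report, "component_dependence_correlation": correlations}, indent=2)
    )

    # --- localization -----------------------------------------------------
    timepoints = np.arange(0.0, 120.1, 7.0)  # 7-min sampling over ~2 h
    traces = []
    for condition in config.localization_conditions:
        for strain in config.localization_strains:
            for repeat in range(config.localization_repeats):
                cells = simulate_localization_trace(
                    strain,
                    condition,
                    truth,
                    timepoints,
                    n_cells=config.localization_cells,
                    seed=int(master.integers(0, 2**31 - 1)),
                )
                traces.append(
                    trace_from_cell_table(cells, strain=strain, condition=condition, repeat=repeat)
                )
    auc_table, auc_scatter = average_repeats(traces)
    auc_table.to_csv(outdir / "localization_auc.tsv", sep="\t", index=False)
    auc_scatter.to_csv(outdir / "localization_repeats.tsv", sep="\t", index=False)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_strains": len(matrix.strains),
        "n_wells": len(measurements),
        "outputs": sorted({p.name for p in outdir.iterdir()} | {"manifest.json"}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "truth": truth,
        "matrix": matrix,
        "reproducibility": repro,
        "profiles": profiles,
        "venn": venn,
        "dependence": dep,
        "epistasis_calls": calls,
        "epistasis_consensus": consensus,
        "fits": fits,
        "correlations": correlations,
        "localization": auc_table,
        "outdir": outdir,
    }
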