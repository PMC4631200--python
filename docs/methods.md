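# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `stresscreen`, in the order the pipeline runs them.

## Cytometry processing

**Well demultiplexing** (`cytometry.partition_wells`). A sequentially
sampled plate arrives as one time-stamped event stream; the sampler leaves
dead time between wells. The stream is split into `n_wells` contiguous
segments chosen to maximize the total inter-segment dead time. Over ordered
contiguous segmentations this objective separates across boundaries, so the
dynamic-programming optimum is attained exactly by cutting at the
`n_wells − 1` largest inter-event gaps; ties break toward the earliest
boundary, and trailing segments may be empty when events are scarce. The
assignment is invariant to shifting or positively rescaling the clock.
Recovery is exact in practice once the inter-well gap exceeds ~50× the
intra-well event spacing; with no gap structure at all (uniform spacing) a
valid but arbitrary segmentation at the earliest maximal gaps is returned.

**Density gating** (`cytometry.gate_events`). Debris, dead cells and other
atypical events are removed with an automatic FSC/SSC gate: a
`resolution × resolution` (default 64) square-bin 2-D histogram is built
over the event cloud, and bins are retained in decreasing density order
until the retained fraction first reaches the target (default 0.90). The
realized fraction therefore overshoots by at most one bin's mass, and the
realized value is reported rather than forced. No connectivity is imposed
on the retained bins; for unimodal cell clouds the densest bins form one
region in practice. Trade-off: the bin count trades gate fidelity against
running time; 64 bins per axis resolves the cell cloud's tail from sparse
debris at typical well sizes (≥ ~1,000 events). At very sparse wells,
singleton-bin ties between cloud-tail and debris bins are broken
arbitrarily, costing a few percent of outlier recall.

**Medians, correction, replicates.** The per-well statistic is the exact
median of the gated reporter channel (empty wells are flagged missing, not
zeroed). Autofluorescence is removed by subtracting the median of a
GFP-less control from the same plate and condition, clipping at zero —
negative corrected levels would poison downstream ratios and logs.
Biological replicates are averaged per strain × condition; reproducibility
is summarized as the Pearson correlation of log10 medians between each
replicate pair, per condition (expression spans orders of magnitude, so a
linear-scale correlation would be dominated by the brightest strains).

## Growth planning

Strains of unknown doubling time (assumed uniform on 1.5–3.5 h) grow
exponentially, `OD(t) = OD₀·2^(t/dt)`, for a fixed period (default 10 h)
after being split into an X:2X:4X:8X dilution series. The planner scans X
over 200 log-spaced candidates in [2, 512] and, integrating over the
doubling-time prior on a 513-point grid, picks the X maximizing the
expected number of strains with at least one series member landing in the
target OD window (default [0.2, 0.6]); ties go to the smallest X. After
growth, the source best fitting the window is the in-window replicate
closest to the window midpoint ("best fits" is otherwise underdetermined);
wells with no in-window source stay empty. No lag phase or saturation is
modeled; both would bias the prior optimistic for very sick strains.

## Effects and condition specificity

A knockout's response magnitude in a condition is its median reporter level
divided by the wild-type level in that condition. Ratios above 1.1 are
increases, below 0.8 decreases; boundary values are no-calls (strict
inequalities). With effects in several compared conditions, magnitudes
(the ratios, compared within one effect direction) that spread by more
than 0.3 mark the knockout condition-specific, assigned to the
above-average conditions for increases and below-average for decreases;
spreads ≤ 0.3 are common effects. Mixed-direction knockouts are labeled
per direction, since comparing an increase ratio against a decrease ratio
on one axis is not meaningful. With more than two effect-bearing
conditions, "spread" is max − min. All labels are invariant to rescaling
the fluorescence unit.

## Msn2/4-dependence score

    D_X = (GFP_ΔX − GFP_ΔXΔmsn2Δmsn4) / (GFP_ΔX − GFP_Δmsn2Δmsn4)

This single ratio reproduces all four qualitative regimes: D = 1 when the
triple mutant collapses to the Δmsn2Δmsn4 level (fully dependent);
0 ≤ D < 1 when part of the effect survives (only D·100% of the effect is
Msn2/4 dependent); D > 1 when the triple undershoots the double
(cooperative); D < 0 when deleting Msn2/4 on the ΔX background raises
expression relative to ΔX. It is a ratio of differences, hence invariant
to affine rescaling of the fluorescence unit. The score is computed on
linear fluorescence. When |GFP_ΔX − GFP_Δmsn2Δmsn4| falls below a floor
(default 2% of GFP_WT) the score is flagged undefined instead of emitting
an unstable number. The "dependent" regime label uses |D − 1| ≤ 0.05.

## Epistasis calls

Pair (X, Y) is eligible when its single-knockout effects
(e = GFP_Δ − GFP_WT) differ by at least 20% of the larger magnitude —
masking is undefined for near-identical effects. On eligible pairs,
Y-over-X is called when the double sits within δ (default 0.25) of the
ΔX–ΔY span from the ΔY level, symmetrically for X-over-Y; if both
qualify, the nearer side wins; an exact tie yields no call, which keeps
calls invariant under relabeling the pair. A single normalized-distance
rule is used for opposite-sign and same-sign pairs alike; δ is exposed in
configuration. The cross-condition consensus colors a pair when at least
two of the three stress conditions carry a call: the shared direction if
unanimous, otherwise a direction-changed flag.

## Interaction models

With `F_X = GFP_ΔX − GFP_WT` and `M_X = GFP_ΔX / GFP_WT`, the neutral
double-knockout expectations are additive `GFP_WT + F_X + F_Y`,
multiplicative `GFP_WT·M_X·M_Y`, and combined
`GFP_WT·m_X·m_Y + a_X + a_Y` subject to the per-gene sum constraint
`a_X + GFP_WT·(m_X − 1) = F_X` — the unique reading under which both pure
models satisfy the constraint (m ≡ 1 gives the additive model, a ≡ 0 the
multiplicative one). All fitting is on linear fluorescence. Substituting
the constraint gives the identity

    expected_combined(X,Y) = expected_additive(X,Y) + GFP_WT·(m_X−1)(m_Y−1),

leaving an unconstrained bounded least-squares problem in m alone
(bounds m ∈ [0, 10], analytic Jacobian), solved from three starts —
additive (m = 1), multiplicative (m = M), and their midpoint — keeping the
lowest-cost solution; since the optimizer never increases its objective,
the combined fit is never worse than either pure model started from. An
explicitly constrained SLSQP solver over (m, a) is kept as an independent
cross-check and agrees with the substituted solver to optimizer tolerance.
Genes with no measured doubles are pinned to the additive solution
(a = F, m = 1) and flagged. Missing doubles simply drop from the
objective. Interaction scores are `I = observed − expected`, optionally
normalized by GFP_WT; fit quality is `R² = 1 − SSE/SStot` over the fitted
doubles.

**Identifiability.** The bilinear term makes the decomposition
unidentifiable on a purely bipartite query × target design: scaling
`u = m − 1` by c on one side and 1/c on the other preserves every
expectation. The synthetic screen's default design therefore includes the
query × query doubles, which makes the solution unique up to a global sign
flip of u that the m ≥ 0 bound excludes whenever any true m exceeds 2
(essentially always under the default effect ranges). Analyses of real
designs without such off-bipartite pairs should expect a one-parameter
ridge in the fit.

**Component–dependence correlations.** Per gene, the Msn2/4-dependent
effect is `D_X·F_X` and the independent effect `(1 − D_X)·F_X`; these are
correlated (Pearson, two-sided p) against the fitted multiplicative part m
and additive part a respectively. Correlating against D itself instead of
D·F is available by configuration.

## Localization quantification

Per cell, the nuclear/cytoplasmic intensity ratio is taken after optional
uniform background subtraction; cells with non-positive cytoplasmic signal
are dropped and counted. Per timepoint, the population summary is the mean
over cells by default, with the median selectable — both conventions
appear in practice and they agree on symmetric populations; skewed
populations make the mean sit above the median. The trace's AUC is the
trapezoid integral of the summary ratio over time (ratio·minutes), over
the full movie, with no baseline subtraction by default (an optional mode
subtracts the t = 0 ratio and clips at zero). Repeats are averaged, and a
repeat-vs-repeat scatter table supports reproducibility reporting. The
default sampling grid is 7-minute intervals over ~2 h.

## Synthetic-data generator

The generator produces every input the analysis consumes, with ground
truth retained for testing.

- **Expression.** Each knockout carries a multiplicative component m
  (log-uniform on [0.3, 3] by default) and an additive component a
  (uniform on [−0.3, 0.5] of the condition baseline), so a single
  knockout's expectation is `baseline·m + a` and the neutral double
  expectation is `baseline·m_X·m_Y + a_X + a_Y` (the combined form);
  explicit interaction terms can be injected per pair for detection
  tests. Condition baselines are uniform on [200, 2000] a.u.;
  autofluorescence offset 20 a.u.
- **Msn2/4 dependence.** Each gene carries a dependent fraction d_frac
  (uniform on [0, 1.2] by default). In a Δmsn2Δmsn4 background the
  baseline drops to a residual fraction of wild type (default 0.2, 0.3
  for the KCl-like condition) and every other gene's WT-relative effect is
  scaled by 1 − d_frac. An optional coupled mode instead derives d_frac so
  that the triple-mutant probe reports a dependent effect of exactly
  `wt·(m − 1)` — the multiplicative component routed through the
  activators, the additive component bypassing them (clamped to [−2, 2]
  for near-neutral knockouts) — emulating screens in which mode of action
  and Msn2/4 dependence are linked.
- **Events.** Per-cell reporter fluorescence is the autofluorescence
  offset plus a log-normal draw whose median is the strain expectation
  (log-sd 0.30); the no-GFP control shows jittered offset only. FSC/SSC
  are a correlated Gaussian cloud (means 50,000/30,000 a.u., sds
  8,000/6,000, r = 0.6) on an 18-bit scale; outliers (default 10% of
  events) are uniform over the full instrument range [0, 262144]², the
  realistic model for debris and dead cells and one that keeps the 64×64
  histogram's dense-cloud bins well separated from outlier bins.
  Timestamps accumulate exponential spacings (mean 10 ms); plate streams
  concatenate per-well bursts separated by a configurable dead time and
  carry hidden well labels. Well-level biological replicate noise is a
  log-normal factor of CV 5% — the within-replicate CV is not established
  experimentally and 5% is this package's assumption, consistent with the
  replicate correlations such screens report.
- **Localization.** The population N/C ratio follows a configured pulse:
  KCl-like, a log-normal-in-time bump peaking at 15 min and back near
  baseline by ~45–50 min; diamide-like, a saturating rise of lower
  amplitude with no return within 100 min. Per-cell traces multiply the
  population curve by log-normal cell jitter (median 1), so the
  per-timepoint median recovers the pulse exactly at zero noise.

All generators are pure functions of their arguments and a seed; the
recorded seed plus configuration reproduces any table byte for byte.

**What the generator does not emulate** — and hence what passing tests do
not establish about measured data: instrument drift and day effects,
spillover/compensation, doublets, cell-cycle and size structure in the
scatter channels, non-log-normal expression tails, growth-rate coupling
between genotype and reporter level, and segmentation errors upstream of
the per-cell localization tables. Analyses of real screens must assess
those separately.

## Numerical choices and degenerate inputs

- Gate: first-crossing retention semantics; realized fraction reported.
  A single-point degenerate cloud retains everything at any target.
- Partitioning: unsorted streams are an error; uniform spacing yields the
  earliest-maximal-gap segmentation.
- Combined fit: xtol 10⁻¹⁴, constraint residual ≤ 10⁻⁸·GFP_WT enforced by
  construction in the substituted solver; non-convergence raises with
  diagnostics rather than returning silently.
- Dependence: denominator floor 0.02·GFP_WT; undefined scores carry no
  number.
- Zero-variance inputs to R² or correlations raise instead of returning
  NaN.

## Default problem sizes

The shipped pipeline configuration runs a scaled-down screen (6 query ×
10 target genes, two replicates, 1,000 events per well, five conditions)
sized for quick, deterministic end-to-end runs; parameter-recovery
validation uses the full 30 × 56 design at the expression-matrix level,
where event-level simulation adds nothing to the question being tested.

## Known limitations

- The epistasis rule set uses one normalized-distance criterion (δ = 0.25)
  for all pair geometries; dataset-level call counts are sensitive to δ
  and to the eligibility threshold.
- The combined model fits point estimates without uncertainties; a
  bootstrap over doubles is straightforward but not built in.
- FCS binary files are not read; event tables are consumed as CSV with
  mapped channel columns.
- The growth planner's exponential model ignores lag and saturation.
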