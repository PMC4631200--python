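"""Genetic-interaction models: additive, multiplicative and combined.

Genetic interactions are deviations of a double mutant's phenotype from a
neutral expectation built from the single mutants.  Three neutral models
are provided, all on linear (raw) fluorescence:

additive        expected(X,Y) = GFP_WT + F_X + F_Y,   F_X = GFP_ΔX − GFP_WT
multiplicative  expected(X,Y) = GFP_WT · M_X · M_Y,   M_X = GFP_ΔX / GFP_WT
combined        expected(X,Y) = GFP_WT · m_X · m_Y + a_X + a_Y

In the combined model every knockout carries both an additive part ``a``
(a.u.) and a multiplicative part ``m`` (fold), constrained so the two sum
to the knockout's total measured effect:

    a_X + GFP_WT · (m_X − 1) = F_X          for every gene X.

The (m, a) split is found by least squares over all measured double
knockouts.  Substituting the constraint leaves an unconstrained problem in
m alone, with the identity

    expected_combined(X,Y) = expected_additive(X,Y) + GFP_WT·(m_X−1)·(m_Y−1),

so both pure models are nested in the combined one (m ≡ 1 gives additive,
a ≡ 0 gives multiplicative).  The interaction score of a pair is
I = observed − expected, optionally normalized by GFP_WT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cytometry import ExpressionMatrix
from .synthetic import genotype_name, parse_genotype

__all__ = [
    "KnockoutComponents",
    "InteractionFit",
    "available_pairs",
    "fit_additive",
    "fit_multiplicative",
    "fit_combined",
    "variance_explained",
    "component_dependence_correlation",
]

M_BOUNDS = (0.0, 10.0)


@dataclass
class KnockoutComponents:
    """Single-knockout effect decomposition in one condition."""

    gene: str
    condition: str
    F: float  # total additive effect, GFP_ΔX − GFP_WT
    M: float  # total multiplicative ratio, GFP_ΔX / GFP_WT
    a: float | None = None  # combined-model additive part
    m: float | None = None  # combined-model multiplicative part
    no_doubles: bool = False  # components fixed to the additive solution


@dataclass
class InteractionFit:
    model: str  # additive / multiplicative / combined
    condition: str
    pairs: pd.DataFrame  # gene_x, gene_y, observed, expected, score, normalized_score
    r2: float
    sse: float
    components: dict[str, KnockoutComponents] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def available_pairs(matrix: ExpressionMatrix, genes: Sequence[str]) -> list[tuple[str, str]]:
    """Unordered gene pairs whose double-knockout strain is in the matrix."""
    genes = set(genes)
    pairs = []
    for strain in matrix.strains:
        g = parse_genotype(strain)
        if len(g) == 2 and g <= genes:
            pairs.append(tuple(sorted(g)))
    return sorted(set(pairs))


def _collect(
    matrix: ExpressionMatrix, condition: str, genes: Sequence[str]
) -> tuple[float, dict[str, KnockoutComponents], list[tuple[str, str, float]]]:
    """WT level, per-gene single effects, and observed doubles for one
    condition; pairs missing a single or a double measurement are skipped."""
    wt = matrix.wt(condition)
    if not np.isfinite(wt) or wt <= 0:
        raise ValueError(f"WT value must be positive in condition {condition!r}")
    comps: dict[str, KnockoutComponents] = {}
    for g in genes:
        name = genotype_name([g])
        if name not in matrix.values.index:
            continue
        v = matrix.value(name, condition)
        if not np.isfinite(v):
            continue
        comps[g] = KnockoutComponents(g, condition, F=v - wt, M=v / wt)
    doubles = []
    for gx, gy in available_pairs(matrix, list(comps)):
        v = matrix.value(genotype_name([gx, gy]), condition)
        if np.isfinite(v):
            doubles.append((gx, gy, float(v)))
    return wt, comps, doubles


def variance_explained(observed: np.ndarray, expected: np.ndarray) -> float:
    """R² = 1 − SSE/SStot of expected vs observed double-knockout levels."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if len(observed) < 2:
        raise ValueError("need at least two pairs")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed doubles have zero variance")
    sse = float(np.sum((observed - expected) ** 2))
    return 1.0 - sse / ss_tot


def _build_fit(
    model: str,
    condition: str,
    wt: float,
    doubles: list[tuple[str, str, float]],
    expected: np.ndarray,
    comps: dict[str, KnockoutComponents],
    diagnostics: dict | None = None,
) -> InteractionFit:
    obs = np.array([d[2] for d in doubles])
    score = obs - expected
    pairs = pd.DataFrame(
        {
            "gene_x": [d[0] for d in doubles],
            "gene_y": [d[1] for d in doubles],
            "observed": obs,
            "expected": expected,
            "score": score,
            "normalized_score": score / wt,
        }
    )
    r2 = variance_explained(obs, expected) if len(obs) >= 2 else np.nan
    return InteractionFit(
        model=model,
        condition=condition,
        pairs=pairs,
        r2=r2,
        sse=float(np.sum(score**2)),
        components=comps,
        diagnostics=diagnostics or {},
    )


def fit_additive(
    matrix: ExpressionMatrix, condition: str, genes: Sequence[str]
) -> InteractionFit:
    """Neutral model GFP_WT + F_X + F_Y over all measured doubles."""
    wt, comps, doubles = _collect(matrix, condition, genes)
    expected = np.array([wt + comps[x].F + comps[y].F for x, y, _ in doubles])
    return _build_fit("additive", condition, wt, doubles, expected, comps)


def fit_multiplicative(
    matrix: ExpressionMatrix, condition: str, genes: Sequence[str]
) -> InteractionFit:
    """Neutral model GFP_WT · M_X · M_Y over all measured doubles."""
    wt, comps, doubles = _collect(matrix, condition, genes)
    expected = np.array([wt * comps[x].M * comps[y].M for x, y, _ in doubles])
    return _build_fit("multiplicative", condition, wt, doubles, expected, comps)


def _combined_expected(
    wt: float, m: np.ndarray, F: np.ndarray, ix: np.ndarray, iy: np.ndarray
) -> np.ndarray:
    # via the sum constraint a = F − wt·(m−1):
    # wt·m_x·m_y + a_x + a_y = wt·(m_x−1)(m_y−1) + wt + F_x + F_y
    return wt * (m[ix] - 1.0) * (m[iy] - 1.0) + wt + F[ix] + F[iy]


def fit_combined(
    matrix: ExpressionMatrix,
    condition: str,
    genes: Sequence[str],
    method: str = "substituted",
    xtol: float = 1e-14,
) -> InteractionFit:
    """Fit the combined additive+multiplicative decomposition.

    ``method='substituted'`` (default) eliminates the sum constraint
    analytically and solves an unconstrained bounded least-squares problem in
    the multiplicative parts m alone, from three starts (additive m=1,
    multiplicative m=M, and their midpoint) to guard against local minima.
    ``method='constrained'`` solves the equivalent explicitly constrained
    problem in (m, a) with SLSQP; it exists as an independent cross-check.

    Genes without any measured double keep the additive solution
    (a = F, m = 1) and are flagged.
    """
    wt, comps, doubles = _collect(matrix, condition, genes)
    fitted_genes = sorted({g for x, y, _ in doubles for g in (x, y)})
    gene_idx = {g: i for i, g in enumerate(fitted_genes)}
    ix = np.array([gene_idx[x] for x, y, _ in doubles], dtype=int)
    iy = np.array([gene_idx[y] for x, y, _ in doubles], dtype=int)
    obs = np.array([v for _, _, v in doubles])
    F = np.array([comps[g].F for g in fitted_genes])
    M = np.array([comps[g].M for g in fitted_genes])

    if not fitted_genes:
        raise ValueError("no double knockouts available to fit")

    lo, hi = M_BOUNDS
    m_mult = np.clip(M, lo, hi)
    starts = [np.ones_like(M), m_mult, 0.5 * (np.ones_like(M) + m_mult)]

    if method == "substituted":
        def residuals(m: np.ndarray) -> np.ndarray:
            return _combined_expected(wt, m, F, ix, iy) - obs

        def jac(m: np.ndarray) -> np.ndarray:
            J = np.zeros((len(obs), len(m)))
            rows = np.arange(len(obs))
            J[rows, ix] += wt * (m[iy] - 1.0)
            J[rows, iy] += wt * (m[ix] - 1.0)
            return J

        best = None
        for x0 in starts:
            res = optimize.least_squares(
                residuals, x0, jac=jac, bounds=(lo, hi), xtol=xtol, ftol=1e-15, gtol=1e-15
            )
            if best is None or res.cost < best.cost:
                best = res
        m_fit = best.x
        diagnostics = {"method": "substituted", "cost": float(best.cost), "status": int(best.status)}
        if best.status <= 0:
            raise RuntimeError(f"combined-model fit did not converge: {best}")
    elif method == "constrained":
        # variables z = [m, a]; linear equality a_i + wt·(m_i − 1) = F_i
        n = len(fitted_genes)

        def objective(z: np.ndarray) -> float:
            m, a = z[:n], z[n:]
            expected = wt * m[ix] * m[iy] + a[ix] + a[iy]
            return float(np.sum((expected - obs) ** 2))

        constraints = {"type": "eq", "fun": lambda z: z[n:] + wt * (z[:n] - 1.0) - F}
        bounds = [(lo, hi)] * n + [(None, None)] * n
        best = None
        for m0 in starts:
            z0 = np.concatenate([m0, F - wt * (m0 - 1.0)])
            res = optimize.minimize(
                objective, z0, method="SLSQP", bounds=bounds, constraints=constraints,
                options={"maxiter": 5000, "ftol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
        m_fit = best.x[: len(fitted_genes)]
        diagnostics = {"method": "constrained", "cost": float(best.fun), "status": int(best.status)}
        if not best.success:
            raise RuntimeError(f"constrained combined-model fit failed: {best.message}")
    else:
        raise ValueError(f"unknown method {method!r}")

    a_fit = F - wt * (m_fit - 1.0)
    for g in comps.values():
        if g.gene in gene_idx:
            i = gene_idx[g.gene]
            g.m, g.a = float(m_fit[i]), float(a_fit[i])
        else:
            g.m, g.a, g.no_doubles = 1.0, g.F, True

    expected = _combined_expected(wt, m_fit, F, ix, iy)
    diagnostics["max_constraint_residual"] = float(
        np.max(np.abs(a_fit + wt * (m_fit - 1.0) - F))
    )
    return _build_fit("combined", condition, wt, doubles, expected, comps, diagnostics)


def component_dependence_correlation(
    components: Sequence[KnockoutComponents],
    dependence: pd.DataFrame,
    use_effect_scale: bool = True,
) -> dict[str, tuple[float, float]]:
    """Correlate the combined-model split with Msn2/4 dependence.

    Per gene, the Msn2/4-dependent share of its effect is D_X·F_X and the
    independent share (1 − D_X)·F_X (``use_effect_scale=False`` correlates
    against D_X and 1 − D_X themselves).  Returns Pearson (R, p) for
    (multiplicative part m vs dependent effect) and (additive part a vs
    independent effect).

    ``dependence`` needs columns gene, D (one condition's scores).
    """
    dep = dependence.dropna(subset=["D"]).set_index("gene")["D"]
    rows = [
        (c.m, c.a, dep[c.gene], c.F)
        for c in components
        if c.m is not None and c.gene in dep.index
    ]
    if len(rows) < 3:
        raise ValueError("need at least three genes with both quantities defined")
    m, a, d, F = (np.array(v, dtype=float) for v in zip(*rows))
    dep_eff = d * F if use_effect_scale else d
    indep_eff = (1.0 - d) * F if use_effect_scale else 1.0 - d
    if np.ptp(m) == 0 or np.ptp(a) == 0 or np.ptp(dep_eff) == 0 or np.ptp(indep_eff) == 0:
        raise ValueError("degenerate variance in correlation inputs")
    r1 = stats.pearsonr(m, dep_eff)
    r2 = stats.pearsonr(a, indep_eff)
    return {
        "multiplicative_vs_dependent": (float(r1[0]), float(r1[1])),
        "additive_vs_independent": (float(r2[0]), float(r2[1])),
    }
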