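"""Recovery benchmarks: the package's estimators run against known truth.

Each routine generates data under stated study conditions, runs the
corresponding estimator, and measures recovery (bias, interval coverage,
model-selection support, oracle agreement, test calibration).  They are
used by the test suite and the acceptance script; the brute-force simplex
oracle here is independent of the polytope solver it checks.
"""

from __future__ import annotations

import numpy as np

from . import abundance as ab
from . import competition as comp
from . import mixing as mx
from . import niche as nk
from .simulate import SimConfig, child_rng, simulate_dynamics, truth_regression_table

__all__ = [
    "m0_recovery",
    "alpha_recovery",
    "simplex_grid_oracle",
    "knn_type1_rate",
    "kud_gaussian_area",
]


def m0_recovery(
    n_true: int = 100,
    p: float = 0.3,
    t_occasions: int = 5,
    n_reps: int = 500,
    seed: int = 1,
) -> dict:
    """Closed-population M0 recovery: mean estimate, percent bias, CI coverage."""
    rng = child_rng(seed, "m0-recovery")
    n_hats = []
    covered = 0
    for _ in range(n_reps):
        det = (rng.random((n_true, t_occasions)) < p).astype(int)
        det = det[det.sum(axis=1) > 0]
        cm = ab.CaptureMatrix(det, t_occasions)
        res = ab.ClosedPopulationM0(cm).fit()
        n_hats.append(res.n_hat)
        lo, hi = res.interval
        covered += lo <= n_true <= hi
    mean_nhat = float(np.mean(n_hats))
    return {
        "mean_nhat": mean_nhat,
        "bias_pct": 100.0 * (mean_nhat - n_true) / n_true,
        "coverage_pct": 100.0 * covered / n_reps,
        "n_reps": n_reps,
    }


GENERATING_TERMS = (comp.LAG, comp.MOUSE_TERM)


def alpha_recovery(
    alpha: float = -0.9,
    noise_sd: float = 0.3,
    n_grids: int = 21,
    n_reps: int = 200,
    seed: int = 1,
) -> dict:
    """Competition-coefficient recovery on the standardized truth.

    Per replicate: one simulated year of 21 grids (2 session transitions),
    OLS of shrew z on (lag, mouse) for the CI check, and the full 16-model
    auto-regressive candidate set for the selection check (does the
    generating configuration sit within delta AICc <= 2?).
    """
    covered = supported = 0
    alphas = []
    for rep in range(n_reps):
        cfg = SimConfig(
            n_grids=n_grids, n_years=1, alpha_true=alpha, noise_sd=noise_sd,
            seed=int(child_rng(seed, "alpha-recovery", rep).integers(2**31)),
        )
        state = simulate_dynamics(cfg)
        tbl = truth_regression_table(state, 0)
        fit = comp.fit_ols(tbl["shrew_density"], tbl, GENERATING_TERMS)
        lo, hi = fit.conf_int(comp.MOUSE_TERM)
        covered += lo <= alpha <= hi
        alphas.append(fit.alpha)
        res = comp.CompetitionModel(tbl, autoregressive=True).fit()
        supported += any(
            f.terms == GENERATING_TERMS and f.delta_aicc <= 2.0 for f in res.fits
        )
    return {
        "mean_alpha": float(np.mean(alphas)),
        "ci_coverage_pct": 100.0 * covered / n_reps,
        "selection_support_pct": 100.0 * supported / n_reps,
        "n_reps": n_reps,
    }


def simplex_grid_oracle(
    mixture: tuple,
    sources: list,
    resolution: float = 0.002,
    tol: float = 0.01,
) -> np.ndarray:
    """Brute-force 4-source mixing oracle: mean of all simplex grid points
    (step ``resolution``) whose implied mixture matches within ``tol`` permil.

    Enumerates p1..p3 on the grid with p4 = 1 - p1 - p2 - p3 >= 0 and keeps
    mass-balance solutions; independent of the vertex-enumeration solver.
    """
    if len(sources) != 4:
        raise ValueError("grid oracle is for 4 sources")
    mc, mn = mixture
    d13 = np.array([s.d13c for s in sources])
    d15 = np.array([s.d15n for s in sources])
    cc = np.array([s.conc_c for s in sources])
    cn = np.array([s.conc_n for s in sources])
    steps = int(round(1.0 / resolution))
    grid = np.arange(steps + 1) / steps
    p2g, p3g = np.meshgrid(grid, grid, indexing="ij")
    p2f, p3f = p2g.ravel(), p3g.ravel()
    total = np.zeros(4)
    count = 0
    for p1 in grid:
        p4 = 1.0 - p1 - p2f - p3f
        ok = p4 >= -1e-12
        if not ok.any():
            continue
        p2, p3, p4v = p2f[ok], p3f[ok], np.clip(p4[ok], 0.0, None)
        wc = p1 * cc[0] + p2 * cc[1] + p3 * cc[2] + p4v * cc[3]
        wn = p1 * cn[0] + p2 * cn[1] + p3 * cn[2] + p4v * cn[3]
        rc = (
            p1 * cc[0] * d13[0] + p2 * cc[1] * d13[1] + p3 * cc[2] * d13[2] + p4v * cc[3] * d13[3]
        ) / wc - mc
        rn = (
            p1 * cn[0] * d15[0] + p2 * cn[1] * d15[1] + p3 * cn[2] * d15[2] + p4v * cn[3] * d15[3]
        ) / wn - mn
        keep = (np.abs(rc) <= tol) & (np.abs(rn) <= tol)
        if keep.any():
            total[0] += p1 * keep.sum()
            total[1] += p2[keep].sum()
            total[2] += p3[keep].sum()
            total[3] += p4v[keep].sum()
            count += int(keep.sum())
    if count == 0:
        raise ValueError("oracle found no feasible grid point")
    return total / count


def knn_type1_rate(
    n_per_group: int = 12,
    n_reps: int = 200,
    n_perm: int = 999,
    k: int = 3,
    level: float = 0.05,
    seed: int = 1,
) -> dict:
    """Type-I error of the KNN randomization test on a homogeneous cloud."""
    rng = child_rng(seed, "knn-type1")
    rejections = 0
    for rep in range(n_reps):
        a = rng.normal(0.0, 1.0, (n_per_group, 2))
        b = rng.normal(0.0, 1.0, (n_per_group, 2))
        _, p = mx.knn_randomization_test(
            a, b, k=k, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rejections += p <= level
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def kud_gaussian_area(
    n_points: int = 2000, mass: float = 0.95, seed: int = 1
) -> dict:
    """95% KUD region area of standard-bivariate-normal draws vs the closed form."""
    rng = child_rng(seed, "kud-gaussian")
    pts = rng.normal(0.0, 1.0, (n_points, 2))
    surface = nk.fit_kud(pts)
    region = nk.contour_region(surface, mass)
    analytic = -2.0 * np.pi * np.log(1.0 - mass)
    return {
        "area": region.area,
        "analytic": float(analytic),
        "relative_error_pct": 100.0 * abs(region.area - analytic) / analytic,
        "n_points": n_points,
    }
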