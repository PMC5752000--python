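"""Concentration-dependent dual-isotope linear mixing and group comparison.

A consumer's (d13C, d15N) signature is modelled as a mass-balance mixture of
diet sources, each weighted by its proportion and its elemental (C or N)
concentration, after adding consumer-specific diet-tissue discrimination
offsets to the source values.  With three sources the proportion vector is
the unique solution of a 3x3 linear system (when the corrected source
triangle contains the mixture); with four or more the feasible set is a
polytope whose vertices are enumerated and summarised by the mean +/- SD of
points sampled uniformly from it — the "all feasible solutions" semantics
of dual-isotope mixing solvers.

Also provides the >20% dietary-overlap criterion and a K-nearest-neighbor
randomization test for differences between isotope groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

__all__ = [
    "SourceProfile",
    "DietSolution",
    "DISCRIMINATION",
    "correct_sources",
    "solve_mixing",
    "dietary_overlap",
    "knn_randomization_test",
]

# diet-tissue discrimination offsets (d13C, d15N) in permil
DISCRIMINATION = {"mouse": (1.0, 3.0), "shrew": (1.3, 2.5)}


@dataclass(frozen=True)
class SourceProfile:
    """One diet source: raw isotope values and elemental concentrations."""

    name: str
    d13c: float
    d15n: float
    conc_c: float
    conc_n: float

    def __post_init__(self) -> None:
        if self.conc_c <= 0 or self.conc_n <= 0:
            raise ValueError(f"source {self.name}: concentrations must be positive")


@dataclass
class DietSolution:
    """Assimilated-diet proportions for one consumer (mean +/- SD over the feasible set)."""

    source_names: tuple
    mean: np.ndarray
    sd: np.ndarray
    solution_type: str  # unique | polytope | infeasible
    n_samples: int = 0
    vertices: np.ndarray | None = None

    @property
    def feasible(self) -> bool:
        return self.solution_type != "infeasible"

    def proportion(self, name: str) -> float:
        return float(self.mean[self.source_names.index(name)])


def correct_sources(
    sources: list, species: str, offsets: dict | None = None
) -> list:
    """Shift source isotope values by the species' discrimination offsets."""
    table = offsets or DISCRIMINATION
    if species not in table:
        raise ValueError(f"no discrimination offsets configured for species {species!r}")
    dc, dn = table[species]
    return [replace(s, d13c=s.d13c + dc, d15n=s.d15n + dn) for s in sources]


def _mass_balance_system(mixture, sources):
    """Rows: C balance, N balance, unit sum.  A p = (0, 0, 1)."""
    mc, mn = mixture
    d13 = np.array([s.d13c for s in sources])
    d15 = np.array([s.d15n for s in sources])
    cc = np.array([s.conc_c for s in sources])
    cn = np.array([s.conc_n for s in sources])
    a = np.vstack([cc * (d13 - mc), cn * (d15 - mn), np.ones(len(sources))])
    b = np.array([0.0, 0.0, 1.0])
    return a, b


def mass_balance_residual(props, mixture, sources) -> float:
    """Max permil deviation of the implied mixture from the observed one."""
    p = np.asarray(props, dtype=float)
    d13 = np.array([s.d13c for s in sources])
    d15 = np.array([s.d15n for s in sources])
    cc = np.array([s.conc_c for s in sources])
    cn = np.array([s.conc_n for s in sources])
    rc = np.sum(p * cc * d13) / np.sum(p * cc) - mixture[0]
    rn = np.sum(p * cn * d15) / np.sum(p * cn) - mixture[1]
    return float(max(abs(rc), abs(rn)))


def solve_mixing(
    mixture: tuple,
    sources: list,
    n_samples: int = 10_000,
    seed: int = 0,
    tol: float = 1e-9,
) -> DietSolution:
    """Solve the concentration-dependent mixing system for one consumer.

    ``mixture`` is the consumer's (d13C, d15N); ``sources`` must already be
    discrimination-corrected.  3 sources: unique solution or infeasible.
    >= 4 sources: vertex enumeration of the feasible polytope and uniform
    sampling of ``n_samples`` points (seeded) for the mean +/- SD.
    """
    names = tuple(s.name for s in sources)
    s = len(sources)
    if s < 2:
        raise ValueError("need >= 2 sources")
    if not np.isfinite(mixture).all():
        raise ValueError("mixture must be finite")
    a, b = _mass_balance_system(mixture, sources)

    if s == 3:
        scale = max(np.abs(a).max(), 1.0)
        if abs(np.linalg.det(a)) < 1e-10 * scale**3:
            raise ValueError("collinear corrected sources: mixing system is ill-conditioned")
        p = np.linalg.solve(a, b)
        if (p < -tol).any():
            return DietSolution(names, np.full(s, np.nan), np.full(s, np.nan), "infeasible")
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        return DietSolution(names, p, np.zeros(s), "unique", n_samples=1)

    if s == 2:
        # over-determined: least squares, feasible only if residual vanishes
        p, *_ = np.linalg.lstsq(a, b, rcond=None)
        if (p < -tol).any() or mass_balance_residual(np.clip(p, 0, None), mixture, sources) > 1e-6:
            return DietSolution(names, np.full(s, np.nan), np.full(s, np.nan), "infeasible")
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        return DietSolution(names, p, np.zeros(s), "unique", n_samples=1)

    # s >= 4: basic feasible solutions = vertices of the polytope
    vertices = []
    for support in combinations(range(s), 3):
        sub = a[:, support]
        if abs(np.linalg.det(sub)) < 1e-12:
            continue
        p_sub = np.linalg.solve(sub, b)
        if (p_sub < -tol).any():
            continue
        p = np.zeros(s)
        p[list(support)] = np.clip(p_sub, 0.0, None)
        p /= p.sum()
        vertices.append(p)
    if not vertices:
        return DietSolution(names, np.full(s, np.nan), np.full(s, np.nan), "infeasible")
    v = np.unique(np.round(np.array(vertices), 9), axis=0)
    if len(v) == 1:
        return DietSolution(names, v[0], np.zeros(s), "unique", n_samples=1, vertices=v)
    pts = _sample_polytope(v, n_samples, seed)
    return DietSolution(
        names, pts.mean(axis=0), pts.std(axis=0, ddof=1), "polytope",
        n_samples=n_samples, vertices=v,
    )


def _sample_polytope(vertices: np.ndarray, n_samples: int, seed: int) -> np.ndarray:
    """Uniform points from the convex hull of the vertices.

    The polytope is affine of dimension d = rank(V - v0): a segment (d=1) is
    sampled by a uniform parameter; faces and solids (d>=2) are triangulated
    (Delaunay in affine coordinates) and simplices sampled proportionally to
    volume, uniformly within each simplex via exponential spacings.
    """
    rng = np.random.default_rng(seed)
    v0 = vertices[0]
    diff = vertices - v0
    u, sv, vt = np.linalg.svd(diff, full_matrices=False)
    dim = int((sv > 1e-9 * max(sv.max(), 1.0)).sum())
    if dim == 0:
        return np.tile(v0, (n_samples, 1))
    if dim == 1:
        axis = vt[0]
        t = diff @ axis
        lo, hi = t.min(), t.max()
        ts = rng.uniform(lo, hi, n_samples)
        return v0 + np.outer(ts, axis)
    from scipy.spatial import Delaunay

    coords = diff @ vt[:dim].T  # (n_vert, dim)
    tri = Delaunay(coords)
    simplices = tri.simplices
    vols = np.abs(
        np.linalg.det(coords[simplices[:, 1:]] - coords[simplices[:, :1]])
    )
    vols = vols / vols.sum()
    which = rng.choice(len(simplices), size=n_samples, p=vols)
    out = np.empty((n_samples, vertices.shape[1]))
    for i, si in enumerate(which):
        w = rng.dirichlet(np.ones(dim + 1))
        out[i] = w @ vertices[simplices[si]]
    return out


def dietary_overlap(
    shrew_solution: DietSolution,
    mouse_solutions: list,
    threshold: float = 0.2,
) -> list:
    """Per-source dietary-overlap report under the > threshold criterion.

    A source overlaps when the shrew population-mean proportion exceeds the
    threshold AND at least one criterion holds on the mouse side: the report
    carries the percent of individual mice whose proportion exceeds the
    threshold, and the joint flag requires that percent to be positive.
    """
    names = shrew_solution.source_names
    for msol in mouse_solutions:
        if msol.source_names != names:
            raise ValueError("mismatched source lists between species")
    feasible_mice = [m for m in mouse_solutions if m.feasible]
    if not feasible_mice:
        import warnings

        warnings.warn("no feasible mouse solutions: overlap undefined on the mouse side")
    report = []
    for i, name in enumerate(names):
        shrew_included = bool(
            shrew_solution.feasible and shrew_solution.mean[i] > threshold
        )
        if feasible_mice:
            pct = 100.0 * np.mean([m.mean[i] > threshold for m in feasible_mice])
            overlap = shrew_included and pct > 0.0
        else:
            pct = float("nan")
            overlap = False
        report.append(
            {
                "source": name,
                "shrew_proportion": float(shrew_solution.mean[i])
                if shrew_solution.feasible
                else float("nan"),
                "shrew_included": shrew_included,
                "mouse_percent": pct,
                "n_mice": len(feasible_mice),
                "overlap": overlap,
            }
        )
    return report


def _knn_neighbors(points: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors per point (self excluded, ties by smallest index)."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def knn_randomization_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    k: int = 3,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple:
    """K-nearest-neighbor randomization test for a difference between two
    isotope point clouds.

    The statistic is the mean, over all points, of the fraction of a point's
    k nearest neighbors (Euclidean in delta-space) sharing its group label;
    the null distribution comes from shuffling labels.  ``exhaustive``
    enumerates every label assignment instead of sampling (small n only).
    Returns (statistic, p_value).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if len(a) < k + 1 or len(b) < k + 1:
        raise ValueError(f"each group needs >= k+1 = {k + 1} points")
    pts = np.vstack([a, b])
    labels = np.concatenate([np.zeros(len(a), int), np.ones(len(b), int)])
    nbrs = _knn_neighbors(pts, k)

    def stat(lab: np.ndarray) -> float:
        return float((lab[nbrs] == lab[:, None]).mean())

    observed = stat(labels)
    eps = 1e-12
    if exhaustive:
        n = len(pts)
        hits = total = 0
        for comb in combinations(range(n), len(a)):
            lab = np.ones(n, int)
            lab[list(comb)] = 0
            total += 1
            if stat(lab) >= observed - eps:
                hits += 1
        return observed, hits / total
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    hits = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if stat(lab) >= observed - eps:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return observed, p
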