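"""Abundance, growth rate and density estimation from trapping records.

Marked mice are estimated per grid x primary session with a closed-population
M0 model (constant detection probability) via profile likelihood; unmarked
shrews with a dead-and-alive Horvitz-Thompson procedure that inflates the
live-capture count by an externally supplied detection probability and adds
trap mortalities back.  Densities divide abundance by the effective trapping
area (trap rectangle plus a boundary-strip buffer, by default 50 m or half
the mean maximum distance moved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammaln

from .simulate import TrapGrid

__all__ = [
    "CaptureMatrix",
    "AbundanceEstimate",
    "DensityEstimate",
    "mnka",
    "ht_abundance",
    "ClosedPopulationM0",
    "M0Results",
    "m0_mle",
    "mt_mle",
    "growth_rates",
    "mmdm",
    "effective_area",
    "density",
    "capture_matrix",
]

CHI2_95_1DF = 3.841458820694124  # chi^2_1 0.95 quantile, profile-CI cutoff


@dataclass
class CaptureMatrix:
    """Binary individual x occasion detections for one grid x primary session.

    A dead fate censors the row: occasions after death contribute neither
    detections nor exposure.
    """

    detections: np.ndarray  # (n, T) in {0, 1}
    t_occasions: int
    death_occasion: np.ndarray = field(default=None)  # occasion index (1-based) or 0

    def __post_init__(self) -> None:
        x = np.asarray(self.detections)
        if x.ndim != 2:
            raise ValueError("detections must be 2-D (individuals x occasions)")
        if not np.isin(x, (0, 1)).all():
            raise ValueError("detections must be binary")
        if x.shape[1] != self.t_occasions:
            raise ValueError("occasion count mismatch")
        if x.size and (x.sum(axis=1) == 0).any():
            raise ValueError("every individual must have >= 1 detection")
        if self.death_occasion is None:
            self.death_occasion = np.zeros(x.shape[0], dtype=int)
        self.detections = x.astype(int)

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]

    @property
    def total_detections(self) -> int:
        return int(self.detections.sum())

    @property
    def exposures(self) -> np.ndarray:
        """Occasions at risk per observed individual (death censors the tail)."""
        exp = np.full(self.n_individuals, self.t_occasions, dtype=float)
        dead = self.death_occasion > 0
        exp[dead] = self.death_occasion[dead]
        return exp


@dataclass
class AbundanceEstimate:
    """Point abundance with a 95% interval for one grid x session."""

    n_hat: float
    interval: tuple
    method: str
    live_estimate: float = 0.0
    deaths_added: int = 0
    p_hat: float | None = None
    boundary: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (lo <= self.n_hat + 1e-9 and self.n_hat <= hi + 1e-9):
            raise ValueError(f"interval {self.interval} does not bracket {self.n_hat}")


@dataclass
class DensityEstimate:
    """Animals per hectare, with the interval scaled by the same area."""

    density: float
    interval: tuple
    effective_area: float
    abundance: AbundanceEstimate


def capture_matrix(records: pd.DataFrame, t_occasions: int) -> CaptureMatrix:
    """Pivot capture records of one grid x primary session into a CaptureMatrix.

    Expects columns ``animal_id``, ``night`` (1-based), ``fate``.
    """
    ids = sorted(records.animal_id.unique())
    det = np.zeros((len(ids), t_occasions), dtype=int)
    death = np.zeros(len(ids), dtype=int)
    idx = {a: i for i, a in enumerate(ids)}
    for _, r in records.iterrows():
        i = idx[r.animal_id]
        det[i, int(r.night) - 1] = 1
        if r.fate == "dead":
            death[i] = int(r.night)
    return CaptureMatrix(detections=det, t_occasions=t_occasions, death_occasion=death)


def mnka(records: pd.DataFrame, *, marked: bool) -> int:
    """Minimum number known alive for one grid x primary session.

    Marked species: distinct individual ids.  Unmarked species: the count of
    live-capture events (identity is unknowable without marks; this is the
    literal 'number of live captures as MNKA' rule, biased high when the
    same animal is re-caught).
    """
    if records.empty:
        return 0
    if marked:
        return int(records.animal_id.nunique())
    return int((records.fate == "live").sum())


def ht_abundance(
    n_live: int, n_dead: int, p_star: float, p_ci: tuple
) -> AbundanceEstimate:
    """Dead-and-alive Horvitz-Thompson abundance for an unmarked species.

    ``p_star`` is the probability an animal present is caught at least once
    in the primary session (the 5-night aggregate).  The live count is
    inflated by 1/p_star and trap mortalities are added back; the interval
    carries the detection-probability CI through the same arithmetic.
    """
    lo, hi = p_ci
    if not 0.0 < p_star <= 1.0:
        raise ValueError(f"p_star must be in (0, 1], got {p_star}")
    if lo <= 0.0:
        raise ValueError("lower detection bound of 0 gives an unbounded interval")
    if not (lo <= p_star <= hi <= 1.0):
        raise ValueError(f"need 0 < lo <= p_star <= hi <= 1, got {p_ci}")
    if n_live == 0 and n_dead == 0:
        # zero-capture session: rule-of-three upper bound on the latent count
        return AbundanceEstimate(
            n_hat=0.0, interval=(0.0, 3.0 / p_star), method="horvitz_thompson",
            live_estimate=0.0, deaths_added=0,
        )
    n_hat = n_live / p_star + n_dead
    interval = (n_live / hi + n_dead, n_live / lo + n_dead)
    return AbundanceEstimate(
        n_hat=n_hat,
        interval=interval,
        method="horvitz_thompson",
        live_estimate=n_live / p_star,
        deaths_added=int(n_dead),
    )


def per_session_detection(p_night: float, n_nights: int = 5) -> float:
    """Convert a per-night capture probability to the per-session aggregate."""
    return 1.0 - (1.0 - p_night) ** n_nights


class ClosedPopulationM0:
    """Closed-population abundance model with constant detection (M0).

    Within one primary session the population is assumed closed except for
    trap deaths, which censor exposure.  The likelihood over (N, p) is
    L(N, p) = [N!/(N-n)!] p^d (1-p)^(E(N)-d) with n observed individuals,
    d total detections and E(N) = sum of observed exposures + (N-n) T.
    ``fit`` profiles p out analytically and maximizes over continuous N.
    """

    def __init__(self, cm: CaptureMatrix):
        if cm.t_occasions < 2:
            raise ValueError("need >= 2 occasions")
        if cm.n_individuals < 1:
            raise ValueError("need >= 1 observed individual")
        self.cm = cm

    def profile_loglik(self, n_pop: float) -> float:
        cm = self.cm
        n, d, t = cm.n_individuals, cm.total_detections, cm.t_occasions
        if n_pop < n:
            return -np.inf
        exposure = float(cm.exposures.sum()) + (n_pop - n) * t
        p = d / exposure
        ll = gammaln(n_pop + 1.0) - gammaln(n_pop - n + 1.0) + d * math.log(p)
        if p < 1.0:
            ll += (exposure - d) * math.log1p(-p)
        return float(ll)

    def fit(self) -> "M0Results":
        cm = self.cm
        n, d, t = cm.n_individuals, cm.total_detections, cm.t_occasions
        obs_exposure = float(cm.exposures.sum())
        # saturated detection: every exposure a detection -> boundary at N = n
        if d >= obs_exposure:
            return M0Results(
                model=self,
                n_hat=float(n),
                p_hat=1.0,
                interval=(float(n), float(n)),
                loglik=self.profile_loglik(n),
                boundary=True,
            )
        if d <= n:
            # every individual caught exactly once: the profile likelihood is
            # asymptotically flat in N (no recaptures to pin it down)
            return M0Results(
                model=self,
                n_hat=float(n),
                p_hat=d / obs_exposure,
                interval=(float(n), float("inf")),
                loglik=self.profile_loglik(n),
                boundary=True,
                identified=False,
            )
        # bracket the maximizer over N >= n
        hi = max(4.0 * n, n + 10.0)
        while self.profile_loglik(hi) > self.profile_loglik(hi - 1e-3) and hi < 1e9:
            hi *= 2.0
        res = minimize_scalar(
            lambda v: -self.profile_loglik(v), bounds=(float(n), hi), method="bounded",
            options={"xatol": 1e-6},
        )
        n_hat = float(res.x)
        ll_max = self.profile_loglik(n_hat)
        boundary = n_hat <= n + 1e-4
        if boundary:
            n_hat = float(n)
            ll_max = self.profile_loglik(n_hat)
        exposure = obs_exposure + (n_hat - n) * t
        p_hat = d / exposure
        cutoff = ll_max - CHI2_95_1DF / 2.0
        g = lambda v: self.profile_loglik(v) - cutoff
        lo_ci = float(n) if g(n) >= 0 else brentq(g, float(n), n_hat, xtol=1e-6)
        ub = max(n_hat * 2.0, n_hat + 5.0)
        while g(ub) > 0 and ub < 1e8:
            ub *= 2.0
        hi_ci = float(ub) if ub >= 1e8 else brentq(g, max(n_hat, float(n) + 1e-9), ub, xtol=1e-6)
        return M0Results(
            model=self,
            n_hat=n_hat,
            p_hat=float(p_hat),
            interval=(float(lo_ci), float(hi_ci)),
            loglik=float(ll_max),
            boundary=boundary,
        )


@dataclass
class M0Results:
    """Fitted M0 abundance: MLE, profile-likelihood 95% interval, diagnostics."""

    model: ClosedPopulationM0
    n_hat: float
    p_hat: float
    interval: tuple
    loglik: float
    boundary: bool
    identified: bool = True

    def as_estimate(self) -> AbundanceEstimate:
        return AbundanceEstimate(
            n_hat=self.n_hat,
            interval=self.interval,
            method="m0_mle",
            live_estimate=self.n_hat,
            deaths_added=0,
            p_hat=self.p_hat,
            boundary=self.boundary,
        )

    def summary(self) -> str:
        cm = self.model.cm
        lines = [
            "Closed-population M0 abundance",
            f"  individuals observed : {cm.n_individuals}",
            f"  occasions (T)        : {cm.t_occasions}",
            f"  total detections     : {cm.total_detections}",
            f"  N-hat                : {self.n_hat:.2f}",
            f"  p-hat (per occasion) : {self.p_hat:.4f}",
            f"  95% profile interval : ({self.interval[0]:.2f}, {self.interval[1]:.2f})",
            f"  log-likelihood       : {self.loglik:.3f}",
        ]
        if self.boundary:
            lines.append("  note: MLE at boundary N = n (saturated detection)")
        return "\n".join(lines)


def m0_mle(cm: CaptureMatrix) -> AbundanceEstimate:
    """Convenience wrapper: fit M0 and return the AbundanceEstimate."""
    return ClosedPopulationM0(cm).fit().as_estimate()


def mt_mle(occasion_counts: np.ndarray, n_distinct: int) -> float:
    """Time-varying detection (Mt) abundance MLE.

    Solves 1 - n/N = prod_j (1 - n_j/N) for N.  For T = 2 this is the
    Lincoln-Petersen estimator n1 n2 / m2.  Returns inf when there are no
    recaptures (no finite MLE).
    """
    nj = np.asarray(occasion_counts, dtype=float)
    n = float(n_distinct)
    if n >= nj.sum():
        return float("inf")

    def f(big_n: float) -> float:
        return (1.0 - n / big_n) - np.prod(1.0 - nj / big_n)

    lo = max(n, float(nj.max())) + 1e-9
    hi = max(10.0 * n, lo * 10.0)
    while f(hi) < 0 and hi < 1e12:
        hi *= 10.0
    return float(brentq(f, lo, hi, xtol=1e-9))


def growth_rates(abundances: tuple) -> tuple:
    """Per-session growth rates (lambda_12, lambda_23) = (N2/N1, N3/N2).

    A zero denominator yields nan for that transition (excluded downstream).
    """
    n1, n2, n3 = abundances
    lam12 = n2 / n1 if n1 > 0 else float("nan")
    lam23 = n3 / n2 if n2 > 0 else float("nan")
    return (lam12, lam23)


def mmdm(records: pd.DataFrame) -> float:
    """Mean maximum distance moved (meters) between subsequent captures.

    Per individual with >= 2 captures (ordered by year, primary, night), the
    maximum Euclidean distance between consecutive capture locations; MMDM
    averages these maxima.  Returns nan when no individual moved twice
    (caller should fall back to the configured buffer).
    """
    maxima = []
    for _, grp in records.groupby("animal_id", sort=True):
        grp = grp.sort_values(["year", "primary", "night"], kind="stable")
        if len(grp) < 2:
            continue
        xy = grp[["trap_x", "trap_y"]].to_numpy(dtype=float)
        steps = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
        maxima.append(float(steps.max()))
    if not maxima:
        return float("nan")
    return float(np.mean(maxima))


def effective_area(grid: TrapGrid, buffer: float) -> float:
    """Effective trapping area (hectares): trap rectangle + Euclidean buffer.

    With rectangle area A, perimeter P and buffer r the buffered area is
    A + P r + pi r^2 (rounded corners).
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    w, h = grid.width, grid.height
    if w <= 0 or h <= 0:
        raise ValueError("trap array must span a positive-area rectangle")
    area_m2 = w * h + 2.0 * (w + h) * buffer + math.pi * buffer**2
    return area_m2 / 1e4


def density(est: AbundanceEstimate, area: float) -> DensityEstimate:
    """Animals per hectare: abundance (and its interval) divided by the ETA."""
    if area <= 0:
        raise ValueError("effective area must be positive")
    lo, hi = est.interval
    return DensityEstimate(
        density=est.n_hat / area,
        interval=(lo / area, hi / area),
        effective_area=area,
        abundance=est,
    )
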