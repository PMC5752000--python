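"""Competition-coefficient estimation by standardized regression with AICc selection.

Shrew density is regressed on mouse density plus habitat covariates (two
ordination axes and elevation), all standardized to mean 0 / sd 1, so the
slope on mouse density is the dimensionless competition coefficient alpha.
Two candidate sets are enumerated: 15 regressive models (all non-empty
subsets of the four predictors) and 16 auto-regressive models (previous-
session shrew density always included, plus every subset of the four).
Models are ranked by small-sample AICc; among those with considerable
support (delta AICc <= 2) the most parsimonious is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PREDICTORS",
    "LAG",
    "CompetitionFit",
    "CompetitionModel",
    "standardize",
    "build_model_set",
    "fit_ols",
    "aicc",
    "rank_models",
    "session_table",
    "fit_candidates",
]

MOUSE_TERM = "mouse_density"
LAG = "shrew_lag"
PREDICTORS = (MOUSE_TERM, "nmds1", "nmds2", "elevation")


def standardize(values) -> np.ndarray:
    """z-scores with sample sd (n-1 denominator); errors on zero variance."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardize needs >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance vector")
    return (x - x.mean()) / sd


def build_model_set(autoregressive: bool) -> list:
    """Enumerate candidate term configurations.

    Regressive: every non-empty subset of the four predictors (15 models).
    Auto-regressive: the lag term always present, plus every subset of the
    four predictors including the empty one (16 models).  Ordering is
    deterministic: by subset size, then by predictor order.
    """
    subsets = []
    for r in range(0, len(PREDICTORS) + 1):
        subsets.extend(combinations(PREDICTORS, r))
    if autoregressive:
        return [(LAG,) + s for s in subsets]
    return [s for s in subsets if s]


@dataclass
class CompetitionFit:
    """One fitted candidate model with its selection statistics."""

    terms: tuple
    params: pd.Series  # includes "const"
    bse: pd.Series
    loglik: float
    k: int  # parameters incl. intercept and residual variance
    n: int
    aicc: float
    r2: float
    delta_aicc: float = float("nan")

    @property
    def alpha(self) -> float | None:
        """Competition coefficient: the slope on mouse density, if present."""
        return float(self.params[MOUSE_TERM]) if MOUSE_TERM in self.terms else None

    @property
    def label(self) -> str:
        return "shrew ~ " + (" + ".join(self.terms) if self.terms else "1")

    def conf_int(self, term: str, level: float = 0.95):
        """Normal-approximation CI for one coefficient."""
        from scipy.stats import t as t_dist

        q = t_dist.ppf(0.5 + level / 2.0, self.n - (self.k - 1))
        est, se = float(self.params[term]), float(self.bse[term])
        return (est - q * se, est + q * se)


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); undefined when n <= k+1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def fit_ols(y, x: pd.DataFrame, terms: tuple | None = None) -> CompetitionFit:
    """Least-squares fit with Gaussian log-likelihood (sigma^2 = RSS/n).

    ``x`` carries the predictor columns (no intercept); an intercept is
    added.  k counts the intercept, the slopes, and the residual variance.
    """
    y = np.asarray(y, dtype=float)
    terms = tuple(terms if terms is not None else x.columns)
    design = sm.add_constant(x[list(terms)] if terms else pd.DataFrame(index=x.index))
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(f"singular design for terms {terms}")
    res = sm.OLS(y, design).fit()
    n = len(y)
    k = len(res.params) + 1  # + residual variance
    r2 = 0.0 if not terms else float(res.rsquared)
    return CompetitionFit(
        terms=terms,
        params=res.params,
        bse=res.bse,
        loglik=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n) if n > k + 1 else float("nan"),
        r2=r2,
    )


class CompetitionModel:
    """Candidate-set competition regression for one year of standardized data.

    Parameters
    ----------
    data : DataFrame with a ``shrew_density`` response column and the
        predictor columns (``mouse_density``, ``nmds1``, ``nmds2``,
        ``elevation`` and, for the auto-regressive set, ``shrew_lag``),
        all already standardized.
    autoregressive : include the previous-session shrew term in every model.
    """

    def __init__(self, data: pd.DataFrame, autoregressive: bool = True):
        self.data = data.reset_index(drop=True)
        self.autoregressive = autoregressive
        self.model_set = build_model_set(autoregressive)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "CompetitionModel":
        return cls(data, **kw)

    def fit(self) -> "CompetitionResults":
        y = self.data["shrew_density"]
        fits = [fit_ols(y, self.data, terms) for terms in self.model_set]
        ranked, selected = rank_models(fits)
        return CompetitionResults(model=self, fits=ranked, selected=selected)


@dataclass
class CompetitionResults:
    """Ranked candidate fits plus the parsimony-selected model."""

    model: CompetitionModel
    fits: list
    selected: CompetitionFit

    @property
    def alpha(self) -> float | None:
        return self.selected.alpha

    def table(self) -> pd.DataFrame:
        """Candidate table shaped like a model-selection report (AICc, dAICc, R2, alpha)."""
        return pd.DataFrame(
            {
                "model": [f.label for f in self.fits],
                "k": [f.k for f in self.fits],
                "AICc": [f.aicc for f in self.fits],
                "dAICc": [f.delta_aicc for f in self.fits],
                "R2": [f.r2 for f in self.fits],
                "alpha": [f.alpha for f in self.fits],
                "selected": [f is self.selected for f in self.fits],
            }
        )

    def summary(self, max_rows: int = 10) -> str:
        t = self.table().head(max_rows)
        lines = [
            f"Competition model selection ({'auto-regressive' if self.model.autoregressive else 'regressive'} set, "
            f"{len(self.fits)} models, n = {self.selected.n})",
            t.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            f"selected: {self.selected.label}",
        ]
        a = self.alpha
        lines.append(f"alpha (effect of mice on shrews): {'-' if a is None else f'{a:.3f}'}")
        return "\n".join(lines)


def rank_models(fits: list) -> tuple:
    """Sort by AICc, attach delta AICc, and select by parsimony.

    Among models with delta AICc <= 2 the one with fewest parameters wins;
    remaining ties break by higher R2, then by lower AICc.
    """
    if not fits:
        raise ValueError("rank_models needs at least one fit")
    ranked = sorted(fits, key=lambda f: f.aicc)
    best = ranked[0].aicc
    for f in ranked:
        f.delta_aicc = f.aicc - best
    supported = [f for f in ranked if f.delta_aicc <= 2.0]
    selected = min(supported, key=lambda f: (f.k, -f.r2, f.aicc))
    return ranked, selected


def session_table(
    density_df: pd.DataFrame,
    habitat_df: pd.DataFrame,
    *,
    year: int,
    density_col: str = "density",
    autoregressive: bool = True,
) -> pd.DataFrame:
    """Assemble the standardized regression table for one year.

    ``density_df`` has one row per grid x session x species with a density
    column; within-year standardization pools all grids and sessions of the
    year per species.  For the auto-regressive set, response rows are
    sessions 2..P with the lag equal to the same grid's previous session
    (no cross-winter lag); the regressive set uses all sessions.
    Rows with missing density are dropped pairwise (count in
    ``attrs['n_dropped']``).
    """
    d = density_df[density_df.year == year]
    wide = d.pivot_table(
        index=["grid_id", "session"], columns="species", values=density_col
    ).reset_index()
    for sp in ("mouse", "shrew"):
        if sp not in wide:
            raise ValueError(f"no {sp} densities for year {year}")
        wide[f"{sp}_z"] = standardize(wide[sp])
    wide = wide.merge(habitat_df, on="grid_id")
    for col, out in (("nmds1", "nmds1"), ("nmds2", "nmds2"), ("elevation_m", "elevation")):
        wide[out] = standardize(wide[col]) if wide[col].std(ddof=1) > 0 else 0.0
    n0 = len(wide)
    if autoregressive:
        lag = wide[["grid_id", "session", "shrew_z"]].copy()
        lag["session"] += 1
        lag = lag.rename(columns={"shrew_z": LAG})
        tbl = wide[wide.session >= 2].merge(lag, on=["grid_id", "session"], how="inner")
    else:
        tbl = wide.copy()
    tbl = tbl.rename(columns={"shrew_z": "shrew_density", "mouse_z": MOUSE_TERM})
    cols = ["grid_id", "session", "shrew_density", MOUSE_TERM, "nmds1", "nmds2", "elevation"]
    if autoregressive:
        cols.append(LAG)
    out = tbl[cols].dropna().reset_index(drop=True)
    out.attrs["n_dropped"] = n0 - len(out) if not autoregressive else len(tbl) - len(out)
    out.attrs["year"] = year
    return out


def fit_candidates(
    density_df: pd.DataFrame,
    habitat_df: pd.DataFrame,
    *,
    year: int,
    autoregressive: bool = True,
    density_col: str = "density",
) -> CompetitionResults:
    """session_table -> CompetitionModel.fit for one year and one model set."""
    tbl = session_table(
        density_df, habitat_df, year=year, density_col=density_col,
        autoregressive=autoregressive,
    )
    return CompetitionModel(tbl, autoregressive=autoregressive).fit()
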