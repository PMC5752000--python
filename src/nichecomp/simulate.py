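"""Synthetic data generator for a two-species robust-design trapping study.

Emulates a field study of Keen's mice (*Peromyscus keeni*, marked with PIT
tags) and dusky shrews (*Sorex monticolus*, released unmarked) trapped on
rectangular live-trap grids: three primary sessions of five consecutive
nights per year, traps at 25-m spacing.  The generator plants a known
negative density coupling (competition coefficient ``alpha_true`` on the
standardized scale) between the two species, species-specific trap
mortality, and isotope mixtures built from known source proportions, so
that every downstream estimator can be tested against ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TrapGrid",
    "TrueState",
    "make_grid",
    "child_rng",
    "simulate_dynamics",
    "simulate_captures",
    "simulate_isotope_data",
    "write_simulation",
]

MOUSE = "mouse"
SHREW = "shrew"
SPECIES = (MOUSE, SHREW)


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Derive an independent, reproducible stream from (seed, op-name, ...).

    Every stochastic operation in the package pulls its own stream this
    way, so stages can be rerun in any order without perturbing each other.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        entropy.append(zlib.crc32(str(key).encode("utf-8")))
    return np.random.default_rng(entropy)


@dataclass(frozen=True)
class TrapGrid:
    """A rectangular live-trap lattice; coordinates in grid-local meters."""

    rows: int
    cols: int
    spacing: float
    coords: np.ndarray  # (rows*cols, 2), row-major, x = col * spacing

    @property
    def width(self) -> float:
        """Extent along x (meters)."""
        return (self.cols - 1) * self.spacing

    @property
    def height(self) -> float:
        """Extent along y (meters)."""
        return (self.rows - 1) * self.spacing

    @property
    def n_traps(self) -> int:
        return self.rows * self.cols


def make_grid(rows: int, cols: int, spacing: float) -> TrapGrid:
    """Build a rows x cols trap lattice with the given spacing (meters)."""
    if rows < 2 or cols < 2:
        raise ValueError(f"trap grid needs rows, cols >= 2, got {rows}x{cols}")
    if spacing <= 0:
        raise ValueError(f"trap spacing must be positive, got {spacing}")
    xs = np.arange(cols) * float(spacing)
    ys = np.arange(rows) * float(spacing)
    gx, gy = np.meshgrid(xs, ys)  # row-major: y (row) outer, x inner
    coords = np.column_stack([gx.ravel(), gy.ravel()])
    return TrapGrid(rows=rows, cols=cols, spacing=float(spacing), coords=coords)


@dataclass
class SimConfig:
    """Study-design and ground-truth parameters of the synthetic study.

    Densities are animals/ha; distances meters; probabilities per night or
    per capture.  ``alpha_true`` is the competition coefficient on the
    standardized (z-score) scale, typically negative.
    """

    n_grids: int = 21
    grid_rows: int = 7
    grid_cols: int = 6
    trap_spacing: float = 25.0
    n_years: int = 3
    n_primary: int = 3
    n_secondary: int = 5
    buffer_m: float = 50.0
    # ground-truth density model
    true_mouse_density: float = 8.0
    mouse_density_sd: float = 2.4
    mouse_year_trend: tuple = (1.0, 1.3, 0.35)  # peak then crash
    shrew_mean_density: float = 6.0
    shrew_density_sd: float = 1.5
    shrew_year_trend: tuple = (1.0, 0.9, 1.4)  # release after the crash
    alpha_true: float = -0.9
    noise_sd: float = 0.3
    beta_habitat: tuple = (0.0, 0.0, 0.0)  # nmds1, nmds2, elevation
    lag_coef: float | None = None  # derived from the unit-variance budget
    # detection / mortality
    p_night: dict = field(default_factory=lambda: {MOUSE: 0.25, SHREW: 0.10})
    mortality_prob: dict = field(default_factory=lambda: {MOUSE: 0.11, SHREW: 0.35})
    movement_sigma: float = 25.0
    # body mass (g)
    mass_mean: dict = field(default_factory=lambda: {MOUSE: 20.8, SHREW: 7.0})
    mass_sd: dict = field(default_factory=lambda: {MOUSE: 2.5, SHREW: 0.8})
    seed: int = 0

    def __post_init__(self) -> None:
        for sp in SPECIES:
            if not 0.0 <= self.p_night[sp] <= 1.0:
                raise ValueError(f"p_night[{sp}] outside [0, 1]")
            if not 0.0 <= self.mortality_prob[sp] <= 1.0:
                raise ValueError(f"mortality_prob[{sp}] outside [0, 1]")
        if self.trap_spacing <= 0:
            raise ValueError("trap_spacing must be positive")
        if self.n_secondary < 2:
            raise ValueError("n_secondary must be >= 2")
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError("grid dimensions must be >= 2")

    @property
    def derived_lag_coef(self) -> float:
        """Lag coefficient completing the unit-variance budget of the shrew latent."""
        if self.lag_coef is not None:
            return self.lag_coef
        budget = 1.0 - self.alpha_true**2 - self.noise_sd**2 - sum(
            b * b for b in self.beta_habitat
        )
        return float(np.sqrt(max(budget, 0.0)))

    @property
    def grid(self) -> TrapGrid:
        return make_grid(self.grid_rows, self.grid_cols, self.trap_spacing)

    @property
    def eta_ha(self) -> float:
        """Effective trapping area (ha) used to convert densities to counts."""
        from .abundance import effective_area

        return effective_area(self.grid, self.buffer_m)


@dataclass
class TrueState:
    """Ground truth of one simulated study, kept beside the data it produced.

    ``density`` has one row per grid x year x session x species with the true
    density, the integer abundance, and the standardized latent ``z`` that the
    competition regression targets.  ``individuals`` carries activity centers
    and body masses; ``habitat`` the two ordination axes and elevation.
    """

    config: SimConfig
    habitat: pd.DataFrame
    density: pd.DataFrame
    individuals: pd.DataFrame

    def abundance(self, grid_id: int, year: int, session: int, species: str) -> int:
        d = self.density
        row = d[
            (d.grid_id == grid_id)
            & (d.year == year)
            & (d.session == session)
            & (d.species == species)
        ]
        return int(row.true_abundance.iloc[0])


def simulate_dynamics(config: SimConfig) -> TrueState:
    """Draw ground-truth densities, abundances, habitat, and individuals.

    The shrew latent follows the auto-regressive competition structure
    z_t = b_lag z_(t-1) + alpha m_t + beta.h + sigma eps with a variance
    budget summing to one, so alpha_true is exactly the coefficient a
    standardized regression estimates.  Raw densities are affine in the
    latents and truncated at zero (truncations are counted in
    ``density.attrs['n_truncated']``).
    """
    rng = child_rng(config.seed, "dynamics")
    G, Y, P = config.n_grids, config.n_years, config.n_primary

    habitat = pd.DataFrame(
        {
            "grid_id": np.arange(G),
            "nmds1": rng.normal(0.0, 1.0, G),
            "nmds2": rng.normal(0.0, 1.0, G),
            "elevation_m": rng.uniform(0.0, 305.0, G),
        }
    )
    # habitat effects enter on the standardized scale
    elev_sd = habitat.elevation_m.std(ddof=1)
    elev_z = (
        (habitat.elevation_m - habitat.elevation_m.mean()) / elev_sd
        if np.isfinite(elev_sd) and elev_sd > 0
        else np.zeros(G)
    )
    hz = np.column_stack([habitat.nmds1, habitat.nmds2, elev_z])
    beta = np.asarray(config.beta_habitat, dtype=float)
    hab_term = hz @ beta  # (G,)

    b_lag = config.derived_lag_coef
    alpha = config.alpha_true
    sigma = config.noise_sd
    init_sd = float(np.sqrt(max(1.0 - beta @ beta, 0.0)))

    eta = config.eta_ha
    n_trunc = 0
    rows = []
    for y in range(Y):
        m = rng.normal(0.0, 1.0, (G, P))  # mouse standardized latent
        z = np.empty((G, P))
        z[:, 0] = hab_term + init_sd * rng.normal(0.0, 1.0, G)
        for t in range(1, P):
            z[:, t] = (
                b_lag * z[:, t - 1]
                + alpha * m[:, t]
                + hab_term
                + sigma * rng.normal(0.0, 1.0, G)
            )
        d_mouse = (
            config.true_mouse_density * config.mouse_year_trend[y % len(config.mouse_year_trend)]
            + config.mouse_density_sd * m
        )
        d_shrew = (
            config.shrew_mean_density * config.shrew_year_trend[y % len(config.shrew_year_trend)]
            + config.shrew_density_sd * z
        )
        n_trunc += int((d_mouse < 0).sum() + (d_shrew < 0).sum())
        d_mouse = np.clip(d_mouse, 0.0, None)
        d_shrew = np.clip(d_shrew, 0.0, None)
        for g in range(G):
            for t in range(P):
                for sp, dens, lat in (
                    (MOUSE, d_mouse[g, t], m[g, t]),
                    (SHREW, d_shrew[g, t], z[g, t]),
                ):
                    rows.append(
                        {
                            "grid_id": g,
                            "year": y,
                            "session": t + 1,
                            "species": sp,
                            "true_density": dens,
                            "true_abundance": int(round(dens * eta)),
                            "z": lat,
                        }
                    )
    density = pd.DataFrame(rows)
    density.attrs["n_truncated"] = n_trunc

    # individual pools per grid x year: activity centers uniform over the
    # trap rectangle plus the boundary-strip margin, masses Gaussian
    grid = config.grid
    margin = config.buffer_m
    ind_rows = []
    for y in range(Y):
        for g in range(G):
            for sp in SPECIES:
                n_sessions = density[
                    (density.grid_id == g)
                    & (density.year == y)
                    & (density.species == sp)
                ].sort_values("session").true_abundance.to_numpy()
                pool = int(n_sessions.max()) if len(n_sessions) else 0
                if pool == 0:
                    continue
                r = child_rng(config.seed, "individuals", y, g, sp)
                x = r.uniform(-margin, grid.width + margin, pool)
                yy = r.uniform(-margin, grid.height + margin, pool)
                mass = np.clip(
                    r.normal(config.mass_mean[sp], config.mass_sd[sp], pool),
                    0.4 * config.mass_mean[sp],
                    None,
                )
                tag = "M" if sp == MOUSE else "S"
                for i in range(pool):
                    ind_rows.append(
                        {
                            "grid_id": g,
                            "year": y,
                            "species": sp,
                            "animal_id": f"{tag}-g{g:02d}-y{y}-{i:04d}",
                            "x": x[i],
                            "y": yy[i],
                            "mass_g": mass[i],
                            "pool_index": i,
                        }
                    )
    individuals = pd.DataFrame(ind_rows)
    return TrueState(config=config, habitat=habitat, density=density, individuals=individuals)


def truth_regression_table(state: TrueState, year: int) -> pd.DataFrame:
    """Standardized-truth regression table for one year.

    Response rows are sessions 2..P; columns carry the generator's own
    standardized latents (shrew z, its lag, the mouse latent) plus
    standardized habitat covariates, so a regression on this table targets
    ``alpha_true`` exactly.
    """
    d = state.density[state.density.year == year]
    wide = d.pivot_table(index=["grid_id", "session"], columns="species", values="z").reset_index()
    wide = wide.rename(columns={"mouse": "mouse_density", "shrew": "shrew_density"})
    lag = wide[["grid_id", "session", "shrew_density"]].copy()
    lag["session"] += 1
    lag = lag.rename(columns={"shrew_density": "shrew_lag"})
    tbl = wide[wide.session >= 2].merge(lag, on=["grid_id", "session"])
    hab = state.habitat.copy()
    for col, out in (("nmds1", "nmds1"), ("nmds2", "nmds2"), ("elevation_m", "elevation")):
        sd = hab[col].std(ddof=1)
        hab[out] = (hab[col] - hab[col].mean()) / sd if sd > 0 else 0.0
    tbl = tbl.merge(hab[["grid_id", "nmds1", "nmds2", "elevation"]], on="grid_id")
    return tbl.reset_index(drop=True)


def simulate_captures(state: TrueState, config: SimConfig | None = None) -> pd.DataFrame:
    """Run the nightly trapping process over a TrueState.

    Each individual present in a session is caught on any night with
    probability ``p_night`` for its species; the record is assigned to the
    trap nearest its perturbed position (activity center + isotropic
    Gaussian of scale ``movement_sigma``).  Every capture independently
    becomes a trap mortality with ``mortality_prob``, after which the
    individual produces no further records.  Mice keep their id across
    sessions; shrew ids are carried in the table but downstream estimators
    treat the species as unmarked.
    """
    config = config or state.config
    grid = config.grid
    spacing = config.trap_spacing
    records: list[dict] = []
    if state.individuals.empty:
        return _captures_frame(records)

    for (y, g, sp), pool in state.individuals.groupby(["year", "grid_id", "species"], sort=True):
        pool = pool.sort_values("pool_index").reset_index(drop=True)
        n_pool = len(pool)
        alive = np.ones(n_pool, dtype=bool)
        p = config.p_night[sp]
        mort = config.mortality_prob[sp]
        rng = child_rng(config.seed, "captures", y, g, sp)
        for t in range(1, config.n_primary + 1):
            n_true = state.abundance(g, y, t, sp)
            present = np.flatnonzero(alive[:n_true]) if n_true > 0 else np.array([], int)
            for night in range(1, config.n_secondary + 1):
                if len(present) == 0:
                    # keep stream alignment cheaply
                    continue
                caught = present[rng.random(len(present)) < p]
                if len(caught) == 0:
                    continue
                dx = rng.normal(0.0, config.movement_sigma, len(caught))
                dy = rng.normal(0.0, config.movement_sigma, len(caught))
                px = pool.x.to_numpy()[caught] + dx
                py = pool.y.to_numpy()[caught] + dy
                tx = np.clip(np.round(px / spacing), 0, grid.cols - 1) * spacing
                ty = np.clip(np.round(py / spacing), 0, grid.rows - 1) * spacing
                dies = rng.random(len(caught)) < mort
                for j, idx in enumerate(caught):
                    records.append(
                        {
                            "grid_id": g,
                            "year": y,
                            "primary": t,
                            "night": night,
                            "trap_x": tx[j],
                            "trap_y": ty[j],
                            "species": sp,
                            "animal_id": pool.animal_id.iloc[idx],
                            "fate": "dead" if dies[j] else "live",
                            "mass_g": round(float(pool.mass_g.iloc[idx]), 2),
                        }
                    )
                if dies.any():
                    alive[caught[dies]] = False
                    present = np.flatnonzero(alive[:n_true])
    return _captures_frame(records)


def _captures_frame(records: list[dict]) -> pd.DataFrame:
    cols = [
        "grid_id",
        "year",
        "primary",
        "night",
        "trap_x",
        "trap_y",
        "species",
        "animal_id",
        "fate",
        "mass_g",
    ]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(records, columns=cols)


def mixture_signature(
    props: np.ndarray, sources: list, offsets: tuple[float, float]
) -> tuple[float, float]:
    """Concentration-weighted mixture (d13C, d15N) of discrimination-corrected sources.

    For each element e, delta_mix,e = sum_i p_i c_ei delta'_ei / sum_i p_i c_ei,
    where delta' adds the consumer's discrimination offset to the raw source value.
    """
    props = np.asarray(props, dtype=float)
    d13 = np.array([s.d13c + offsets[0] for s in sources])
    d15 = np.array([s.d15n + offsets[1] for s in sources])
    cc = np.array([s.conc_c for s in sources])
    cn = np.array([s.conc_n for s in sources])
    mix_c = float(np.sum(props * cc * d13) / np.sum(props * cc))
    mix_n = float(np.sum(props * cn * d15) / np.sum(props * cn))
    return mix_c, mix_n


def simulate_isotope_data(
    sources: list,
    true_props: np.ndarray,
    *,
    species: str = SHREW,
    offsets: tuple[float, float] | None = None,
    noise_sd: float = 0.2,
    n: int = 50,
    seed: int = 0,
    group: str = "all",
) -> pd.DataFrame:
    """Draw consumer isotope samples from known assimilated-diet proportions.

    Consumer values are the concentration-weighted mixing identity applied to
    discrimination-corrected sources, plus isotropic Gaussian noise of
    ``noise_sd`` permil.  The true proportions are stored in
    ``df.attrs['true_props']``.
    """
    from .mixing import DISCRIMINATION

    props = np.asarray(true_props, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"true_props must sum to 1, got {props.sum()!r}")
    if (props < 0).any():
        raise ValueError("true_props must be non-negative")
    if offsets is None:
        offsets = DISCRIMINATION[species]
    mix_c, mix_n = mixture_signature(props, sources, offsets)
    rng = child_rng(seed, "isotopes", species, group)
    df = pd.DataFrame(
        {
            "sample_id": [f"{species}-{group}-{i:04d}" for i in range(n)],
            "species": species,
            "group": group,
            "d13c": mix_c + rng.normal(0.0, noise_sd, n),
            "d15n": mix_n + rng.normal(0.0, noise_sd, n),
        }
    )
    df.attrs["true_props"] = props
    return df


def write_simulation(state: TrueState, captures: pd.DataFrame, out_dir: str | Path) -> None:
    """Write captures.csv, habitat.csv and truth.json for one simulation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    captures.to_csv(out / "captures.csv", index=False)
    state.habitat.to_csv(out / "habitat.csv", index=False)
    state.density.to_csv(out / "truth_density.csv", index=False)
    cfg = asdict(state.config)
    cfg["derived_lag_coef"] = state.config.derived_lag_coef
    cfg["eta_ha"] = state.config.eta_ha
    with open(out / "truth.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=list)
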