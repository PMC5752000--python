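"""End-to-end orchestration: simulate -> estimate -> compete -> mix -> niche -> energize.

Runs the whole synthetic study under one configuration and seed and writes
report tables shaped like the field study's outputs: per-grid densities, a
model-selection table with competition coefficients per year, a diet table
(assimilated proportions for shrews, percent of individual mice above the
overlap threshold), a niche-size/overlap table with the subsampling
control, an energy table with compensation ratios, a run log, and a
machine-readable summary.json.  Every number in the reports is computed by
the stage operations; the pipeline only wires them together.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import competition as comp
from . import energetics as en
from . import mixing as mx
from . import niche as nk
from .simulate import (
    MOUSE,
    SHREW,
    SimConfig,
    TrueState,
    child_rng,
    mixture_signature,
    simulate_captures,
    simulate_dynamics,
    write_simulation,
)

__all__ = ["RunConfig", "run_all", "read_captures", "read_habitat", "write_report"]

log = logging.getLogger("nichecomp")

HABITATS = ("clearcut", "young_growth", "thinned", "old_growth")

# raw (uncorrected) diet sources; concentrations are elemental mass fractions
DEFAULT_SOURCES = (
    mx.SourceProfile("invertebrates", -25.0, 3.5, 0.50, 0.10),
    mx.SourceProfile("mushrooms", -23.0, 0.5, 0.43, 0.04),
    mx.SourceProfile("earthworms", -27.5, 7.5, 0.40, 0.09),
)

# assimilated-diet ground truth per habitat (invertebrates, mushrooms, earthworms)
SHREW_DIET = {
    "clearcut": (0.296, 0.031, 0.673),
    "young_growth": (0.592, 0.347, 0.061),
    "thinned": (0.082, 0.194, 0.724),
    "old_growth": (0.309, 0.053, 0.638),
}
MOUSE_DIET = {
    "clearcut": (0.35, 0.35, 0.30),
    "young_growth": (0.25, 0.55, 0.20),
    "thinned": (0.30, 0.45, 0.25),
    "old_growth": (0.45, 0.30, 0.25),
}


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (round-trips to YAML)."""

    sim: SimConfig = field(default_factory=SimConfig)
    # shrew detection: per-primary-session aggregate probability and its 95% CI
    p_star_shrew: float = 0.41
    p_star_shrew_ci: tuple = (0.27, 0.55)
    buffer_m: float = 50.0
    use_mmdm_buffer: bool = False
    discrimination: dict = field(default_factory=lambda: dict(mx.DISCRIMINATION))
    overlap_threshold: float = 0.2
    kud_levels: tuple = (0.50, 0.75, 0.95)
    bandwidth_scale: float = 1.0
    grid_resolution: int = 256
    # isotope study conditions
    isotope_noise_sd: dict = field(default_factory=lambda: {MOUSE: 0.35, SHREW: 0.15})
    mouse_dirichlet_conc: float = 10.0
    n_period_a: dict = field(default_factory=lambda: {MOUSE: 280, SHREW: 231})
    n_period_b: dict = field(default_factory=lambda: {MOUSE: 21, SHREW: 64})
    n_habitat_diet: dict = field(
        default_factory=lambda: {
            MOUSE: {"clearcut": 27, "young_growth": 65, "thinned": 71, "old_growth": 39},
            SHREW: {"clearcut": 42, "young_growth": 61, "thinned": 85, "old_growth": 43},
        }
    )
    knn_k: int = 3
    knn_n_perm: int = 999
    n_subsample_reps: int = 5
    # energetics reference constants (kJ/day)
    shrew_fmr_ref: float = 90.0
    shrew_mass_ref: float = 8.2
    mouse_fmr: float = 30.0
    scale_mouse_fmr: bool = False
    mouse_mass_ref: float = 20.8
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def habitat_of(self, grid_id: int) -> str:
        return HABITATS[grid_id % len(HABITATS)]


# ---------------------------------------------------------------- I/O

CAPTURE_COLUMNS = {
    "grid_id": int,
    "year": int,
    "primary": int,
    "night": int,
    "trap_x": float,
    "trap_y": float,
    "species": str,
    "animal_id": str,
    "fate": str,
    "mass_g": float,
}


def read_captures(path: str | Path) -> pd.DataFrame:
    """Read and validate a captures.csv; malformed rows are rejected with line numbers."""
    df = pd.read_csv(path)
    missing = set(CAPTURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"captures file missing columns: {sorted(missing)}")
    if df.empty:
        return df
    bad = df.index[~df.species.isin([MOUSE, SHREW])].tolist()
    if bad:
        raise ValueError(f"unknown species tag at data rows {bad[:5]}")
    bad = df.index[~df.fate.isin(["live", "dead"])].tolist()
    if bad:
        raise ValueError(f"non-binary fate at data rows {bad[:5]}")
    bad = df.index[(df.trap_x < 0) | (df.trap_y < 0)].tolist()
    if bad:
        raise ValueError(f"negative trap coordinates at data rows {bad[:5]}")
    return df.astype({k: v for k, v in CAPTURE_COLUMNS.items() if k in df.columns})


def read_habitat(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"grid_id", "nmds1", "nmds2", "elevation_m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"habitat file missing columns: {sorted(missing)}")
    return df


def write_report(tables: dict, out_dir: str | Path) -> list:
    """Write each named DataFrame as <name>.csv in the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written


# ---------------------------------------------------------------- stages


def stage_abundance(cfg: RunConfig, captures: pd.DataFrame, state: TrueState | None = None) -> pd.DataFrame:
    """Per grid x year x session abundance and density for both species."""
    sim = cfg.sim
    grid = sim.grid
    rows = []
    mouse_caps = captures[captures.species == MOUSE]
    pooled_mmdm = ab.mmdm(mouse_caps) if len(mouse_caps) else float("nan")
    if cfg.use_mmdm_buffer and np.isfinite(pooled_mmdm):
        buffer = pooled_mmdm / 2.0
    else:
        buffer = cfg.buffer_m
    eta = ab.effective_area(grid, buffer)
    for g in range(sim.n_grids):
        for y in range(sim.n_years):
            for t in range(1, sim.n_primary + 1):
                sel = captures[
                    (captures.grid_id == g) & (captures.year == y) & (captures.primary == t)
                ]
                for sp in (MOUSE, SHREW):
                    recs = sel[sel.species == sp]
                    if sp == MOUSE:
                        if recs.empty:
                            p_star = ab.per_session_detection(sim.p_night[MOUSE], sim.n_secondary)
                            est = ab.AbundanceEstimate(
                                0.0, (0.0, 3.0 / p_star), method="m0_mle"
                            )
                            log.info("zero-capture mouse session grid=%d year=%d session=%d", g, y, t)
                        else:
                            cm = ab.capture_matrix(recs, sim.n_secondary)
                            res = ab.ClosedPopulationM0(cm).fit()
                            low_information = res.n_hat > 50.0 * cm.n_individuals
                            if not res.identified or low_information:
                                # no recaptures: M0 MLE unbounded; fall back to
                                # inflating the distinct-id count by the
                                # configured per-session detection probability
                                p_star = ab.per_session_detection(
                                    sim.p_night[MOUSE], sim.n_secondary
                                )
                                n_live = cm.n_individuals
                                est = ab.ht_abundance(
                                    n_live, 0, p_star, (0.6 * p_star, min(1.0, 1.4 * p_star))
                                )
                                est.method = "m0_unidentified_ht_fallback"
                                log.info(
                                    "unidentified M0 (no recaptures) grid=%d year=%d session=%d; HT fallback",
                                    g, y, t,
                                )
                            else:
                                if res.boundary:
                                    log.info(
                                        "boundary M0 MLE grid=%d year=%d session=%d", g, y, t
                                    )
                                est = res.as_estimate()
                    else:
                        n_live = ab.mnka(recs, marked=False)
                        n_dead = int((recs.fate == "dead").sum())
                        est = ab.ht_abundance(
                            n_live, n_dead, cfg.p_star_shrew, cfg.p_star_shrew_ci
                        )
                    dens = ab.density(est, eta)
                    rows.append(
                        {
                            "grid_id": g,
                            "habitat": cfg.habitat_of(g),
                            "year": y,
                            "session": t,
                            "species": sp,
                            "n_hat": est.n_hat,
                            "n_lo": est.interval[0],
                            "n_hi": est.interval[1],
                            "eta_ha": eta,
                            "density": dens.density,
                            "density_lo": dens.interval[0],
                            "density_hi": dens.interval[1],
                            "method": est.method,
                        }
                    )
    df = pd.DataFrame(rows)
    df.attrs["mmdm_m"] = pooled_mmdm
    df.attrs["buffer_m"] = buffer
    return df


def stage_competition(cfg: RunConfig, density_df: pd.DataFrame, habitat_df: pd.DataFrame) -> tuple:
    """Per-year candidate sets (regressive and auto-regressive), ranked."""
    tables = []
    selected = {}
    for year in sorted(density_df.year.unique()):
        for autoreg in (False, True):
            res = comp.fit_candidates(
                density_df, habitat_df, year=int(year), autoregressive=autoreg
            )
            t = res.table()
            t.insert(0, "set", "auto-regressive" if autoreg else "regressive")
            t.insert(0, "year", int(year))
            tables.append(t)
            if autoreg:
                selected[int(year)] = res
    return pd.concat(tables, ignore_index=True), selected


def _draw_consumers(cfg: RunConfig, species: str, habitat: str, props, n: int, seed_keys) -> pd.DataFrame:
    """Individual consumer signatures from (possibly individual-level) diet proportions."""
    sources = list(DEFAULT_SOURCES)
    offsets = cfg.discrimination[species]
    noise = cfg.isotope_noise_sd[species]
    rng = child_rng(cfg.seed, "consumers", *seed_keys)
    rows = []
    props = np.asarray(props, float)
    for i in range(n):
        if species == MOUSE:
            p_i = rng.dirichlet(props * cfg.mouse_dirichlet_conc)
        else:
            p_i = props
        mc, mn = mixture_signature(p_i, sources, offsets)
        rows.append(
            {
                "sample_id": f"{species}-{habitat}-{seed_keys[-1]}-{i:04d}",
                "species": species,
                "group": habitat,
                "d13c": mc + rng.normal(0.0, noise),
                "d15n": mn + rng.normal(0.0, noise),
            }
        )
    return pd.DataFrame(rows)


def stage_diet(cfg: RunConfig) -> tuple:
    """Per-habitat mixing solutions and the dietary-overlap report.

    Shrews are solved on the habitat-population mean signature; mice per
    individual.  Infeasible individual mixtures are logged and dropped.
    """
    rows = []
    knn_rows = []
    samples = {}
    for hab in HABITATS:
        shrew_df = _draw_consumers(
            cfg, SHREW, hab, SHREW_DIET[hab], cfg.n_habitat_diet[SHREW][hab], ("diet", hab, SHREW)
        )
        mouse_df = _draw_consumers(
            cfg, MOUSE, hab, MOUSE_DIET[hab], cfg.n_habitat_diet[MOUSE][hab], ("diet", hab, MOUSE)
        )
        samples[hab] = {SHREW: shrew_df, MOUSE: mouse_df}
        shrew_sources = mx.correct_sources(list(DEFAULT_SOURCES), SHREW, cfg.discrimination)
        mouse_sources = mx.correct_sources(list(DEFAULT_SOURCES), MOUSE, cfg.discrimination)
        shrew_mean = (shrew_df.d13c.mean(), shrew_df.d15n.mean())
        shrew_sol = mx.solve_mixing(shrew_mean, shrew_sources, seed=cfg.seed)
        mouse_sols = []
        n_infeasible = 0
        for _, r in mouse_df.iterrows():
            sol = mx.solve_mixing((r.d13c, r.d15n), mouse_sources, seed=cfg.seed)
            if sol.feasible:
                mouse_sols.append(sol)
            else:
                n_infeasible += 1
        if n_infeasible:
            log.info("%d infeasible mouse mixtures in %s", n_infeasible, hab)
        report = mx.dietary_overlap(shrew_sol, mouse_sols, cfg.overlap_threshold)
        for item in report:
            item.update(
                habitat=hab,
                true_shrew_proportion=SHREW_DIET[hab][
                    [s.name for s in DEFAULT_SOURCES].index(item["source"])
                ],
                n_mice_infeasible=n_infeasible,
            )
            rows.append(item)
        stat, p = mx.knn_randomization_test(
            shrew_df[["d13c", "d15n"]].to_numpy(),
            mouse_df[["d13c", "d15n"]].to_numpy(),
            k=cfg.knn_k,
            n_perm=cfg.knn_n_perm,
            seed=int(child_rng(cfg.seed, "knn", hab).integers(2**31)),
        )
        knn_rows.append({"habitat": hab, "knn_statistic": stat, "knn_p": p})
    diet_df = pd.DataFrame(rows)[
        [
            "habitat",
            "source",
            "shrew_proportion",
            "true_shrew_proportion",
            "shrew_included",
            "mouse_percent",
            "n_mice",
            "n_mice_infeasible",
            "overlap",
        ]
    ]
    return diet_df, pd.DataFrame(knn_rows), samples


def _period_points(cfg: RunConfig, period: str) -> dict:
    """Pooled isotope clouds per species for one study period.

    Period A ("2010-2011") uses the base diet truths; period B ("2012")
    contracts the mouse niche (tighter Dirichlet) and shifts shrew diets
    halfway toward the mouse means (the post-crash resource shift).
    """
    counts = cfg.n_period_a if period == "2010-2011" else cfg.n_period_b
    pts = {}
    for sp in (MOUSE, SHREW):
        per_hab = int(np.ceil(counts[sp] / len(HABITATS)))
        frames = []
        for hab in HABITATS:
            if sp == SHREW:
                base = np.asarray(SHREW_DIET[hab])
                props = base if period == "2010-2011" else 0.5 * base + 0.5 * np.asarray(MOUSE_DIET[hab])
            else:
                props = np.asarray(MOUSE_DIET[hab])
            sub_cfg = cfg
            if sp == MOUSE and period == "2012":
                # niche contraction: tighter individual diets
                sub_cfg = _with_conc(cfg, cfg.mouse_dirichlet_conc * 4.0)
            frames.append(
                _draw_consumers(sub_cfg, sp, hab, props, per_hab, ("niche", period, hab, sp))
            )
        df = pd.concat(frames, ignore_index=True).iloc[: counts[sp]]
        pts[sp] = df[["d13c", "d15n"]].to_numpy()
    return pts


def _with_conc(cfg: RunConfig, conc: float) -> RunConfig:
    import copy

    c2 = copy.copy(cfg)
    c2.mouse_dirichlet_conc = conc
    return c2


def stage_niche(cfg: RunConfig) -> pd.DataFrame:
    """Niche sizes and directed overlaps per period, plus the subsampling control."""
    kud_kw = dict(bandwidth_scale=cfg.bandwidth_scale, grid_resolution=cfg.grid_resolution)
    points = {p: _period_points(cfg, p) for p in ("2010-2011", "2012")}
    rows = []
    for period, pts in points.items():
        sm = nk.fit_kud(pts[MOUSE], **kud_kw)
        ss = nk.fit_kud(pts[SHREW], **kud_kw)
        for lev in cfg.kud_levels:
            rm = nk.contour_region(sm, lev, species=MOUSE, period=period)
            rs = nk.contour_region(ss, lev, species=SHREW, period=period)
            om, osh = nk.niche_overlap(rm, rs)
            rows.append(
                {
                    "period": period,
                    "contour": int(lev * 100),
                    "mouse_area": rm.area,
                    "shrew_area": rs.area,
                    "mouse_overlap_pct": om,
                    "shrew_overlap_pct": osh,
                }
            )
    # within-shrew self-overlap between periods (the diet-shift measure)
    for lev in cfg.kud_levels:
        s_a = nk.contour_region(nk.fit_kud(points["2010-2011"][SHREW], **kud_kw), lev)
        s_b = nk.contour_region(nk.fit_kud(points["2012"][SHREW], **kud_kw), lev)
        o_b, o_a = nk.niche_overlap(s_b, s_a)
        rows.append(
            {
                "period": "shrew 2012 vs 2010-2011",
                "contour": int(lev * 100),
                "mouse_area": float("nan"),
                "shrew_area": s_b.area,
                "mouse_overlap_pct": float("nan"),
                "shrew_overlap_pct": o_b,
            }
        )
    # subsampling control: period A at period-B sample sizes
    sub = nk.subsample_niche(
        points["2010-2011"][MOUSE],
        points["2010-2011"][SHREW],
        cfg.n_period_b[MOUSE],
        cfg.n_period_b[SHREW],
        n_reps=cfg.n_subsample_reps,
        seed=int(child_rng(cfg.seed, "subsample").integers(2**31)),
        levels=tuple(cfg.kud_levels),
        **kud_kw,
    )
    for lev in cfg.kud_levels:
        s = sub[lev]
        rows.append(
            {
                "period": "2010-2011 sub-sampled",
                "contour": int(lev * 100),
                "mouse_area": s["area_a"]["mean"],
                "shrew_area": s["area_b"]["mean"],
                "mouse_overlap_pct": s["overlap_a"]["mean"],
                "shrew_overlap_pct": s["overlap_b"]["mean"],
                "mouse_area_ci_half": s["area_a"]["mean"] - s["area_a"]["ci"][0],
                "shrew_area_ci_half": s["area_b"]["mean"] - s["area_b"]["ci"][0],
            }
        )
    return pd.DataFrame(rows)


def stage_energy(cfg: RunConfig, density_df: pd.DataFrame, captures: pd.DataFrame) -> pd.DataFrame:
    """Session-3 community energy per habitat x year and compensation ratios."""
    last = density_df[density_df.session == density_df.session.max()]
    rows = []
    for year in sorted(last.year.unique()):
        caps_y = captures[captures.year == year]
        masses = {
            sp: float(caps_y[caps_y.species == sp].mass_g.mean())
            if (caps_y.species == sp).any()
            else cfg.mouse_mass_ref
            for sp in (MOUSE, SHREW)
        }
        fmr_shrew = en.mass_specific_fmr(cfg.shrew_fmr_ref, cfg.shrew_mass_ref, masses[SHREW])
        fmr_mouse = (
            en.mass_specific_fmr(cfg.mouse_fmr, cfg.mouse_mass_ref, masses[MOUSE])
            if cfg.scale_mouse_fmr
            else cfg.mouse_fmr
        )
        for hab in HABITATS:
            sel = last[(last.year == year) & (last.habitat == hab)]
            n_by_sp = {
                sp: float(sel[sel.species == sp].n_hat.sum()) for sp in (MOUSE, SHREW)
            }
            budget = en.community_energy(
                n_by_sp, {MOUSE: fmr_mouse, SHREW: fmr_shrew}, habitat=hab, year=int(year)
            )
            rows.append(
                {
                    "habitat": hab,
                    "year": int(year),
                    "mouse_abundance": n_by_sp[MOUSE],
                    "shrew_abundance": n_by_sp[SHREW],
                    "mouse_mass_g": masses[MOUSE],
                    "shrew_mass_g": masses[SHREW],
                    "mouse_fmr": fmr_mouse,
                    "shrew_fmr": fmr_shrew,
                    "mouse_energy": budget.species_energy[MOUSE],
                    "shrew_energy": budget.species_energy[SHREW],
                    "total_energy": budget.total,
                }
            )
    df = pd.DataFrame(rows)
    final = df.year.max()
    comp_rows = []
    for hab in HABITATS:
        e_final = float(df[(df.habitat == hab) & (df.year == final)].total_energy.iloc[0])
        for ref_year in sorted(df.year.unique()):
            if ref_year == final:
                continue
            e_ref = float(df[(df.habitat == hab) & (df.year == ref_year)].total_energy.iloc[0])
            comp_rows.append(
                {
                    "habitat": hab,
                    "reference_year": int(ref_year),
                    "compensation_pct": en.compensation(e_final, e_ref),
                }
            )
    df.attrs["compensation"] = pd.DataFrame(comp_rows)
    return df


def run_all(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage, write the report bundle, return the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"seed": cfg.seed}
    stage = "simulate"
    try:
        log.info("stage: simulate")
        state = simulate_dynamics(cfg.sim)
        captures = simulate_captures(state)
        write_simulation(state, captures, out)
        summary["simulate"] = {
            "n_grids": cfg.sim.n_grids,
            "n_captures": int(len(captures)),
            "n_mice_individuals": int(captures[captures.species == MOUSE].animal_id.nunique())
            if len(captures)
            else 0,
            "n_truncated_densities": int(state.density.attrs.get("n_truncated", 0)),
        }

        stage = "abundance"
        log.info("stage: abundance")
        density_df = stage_abundance(cfg, captures, state)
        summary["abundance"] = {
            "mmdm_m": float(density_df.attrs["mmdm_m"]),
            "buffer_m": float(density_df.attrs["buffer_m"]),
            "eta_ha": float(density_df.eta_ha.iloc[0]),
            "mean_density": {
                sp: float(density_df[density_df.species == sp].density.mean())
                for sp in (MOUSE, SHREW)
            },
        }

        stage = "competition"
        log.info("stage: competition")
        comp_df, selected = stage_competition(cfg, density_df, state.habitat)
        summary["competition"] = {
            str(year): {
                "selected_model": res.selected.label,
                "alpha": res.alpha,
                "r2": res.selected.r2,
                "aicc": res.selected.aicc,
            }
            for year, res in selected.items()
        }

        stage = "diet"
        log.info("stage: diet mixing")
        diet_df, knn_df, _ = stage_diet(cfg)
        summary["diet"] = {
            "n_overlapping_items": int(diet_df.overlap.sum()),
            "knn_p_by_habitat": {
                r.habitat: float(r.knn_p) for r in knn_df.itertuples()
            },
        }

        stage = "niche"
        log.info("stage: isotopic niche")
        niche_df = stage_niche(cfg)
        full = niche_df[niche_df.period == "2010-2011"]
        summary["niche"] = {
            f"{int(r.contour)}pct": {
                "mouse_area": float(r.mouse_area),
                "shrew_area": float(r.shrew_area),
                "shrew_overlap_pct": float(r.shrew_overlap_pct),
            }
            for r in full.itertuples()
        }

        stage = "energy"
        log.info("stage: energetics")
        energy_df = stage_energy(cfg, density_df, captures)
        comp_tbl = energy_df.attrs["compensation"]
        summary["energy"] = {
            "compensation_pct": {
                f"{r.habitat}_vs_{int(r.reference_year)}": float(r.compensation_pct)
                for r in comp_tbl.itertuples()
            }
        }

        write_report(
            {
                "density": density_df,
                "competition_table": comp_df,
                "diet_table": diet_df,
                "knn_table": knn_df,
                "niche_table": niche_df,
                "energy_table": energy_df,
                "compensation_table": comp_tbl,
            },
            out,
        )
        summary["status"] = "ok"
    except Exception as exc:  # persist partial results and the failing stage
        log.error("stage %s failed: %s", stage, exc)
        summary["status"] = f"failed at {stage}: {exc}"
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        log.removeHandler(handler)
        handler.close()
        raise
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    log.removeHandler(handler)
    handler.close()
    return summary
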