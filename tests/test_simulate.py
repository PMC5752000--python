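"""Tests of the synthetic-study generator: lattice geometry, determinism,
detection arithmetic, and the isotope mixing identity."""

import numpy as np
import pandas as pd
import pytest

from nichecomp.simulate import (
    MOUSE,
    SHREW,
    SimConfig,
    make_grid,
    mixture_signature,
    simulate_captures,
    simulate_dynamics,
    simulate_isotope_data,
    truth_regression_table,
)


class TestMakeGrid:
    def test_2x2_lattice(self):
        g = make_grid(2, 2, 25)
        assert g.n_traps == 4
        np.testing.assert_allclose(
            g.coords, [[0, 0], [25, 0], [0, 25], [25, 25]]
        )

    def test_field_scale_grid_spans_150_by_125(self):
        g = make_grid(7, 6, 25)
        assert g.n_traps == 42
        assert (g.height, g.width) == (150.0, 125.0)
        assert 40 <= g.n_traps <= 52  # per-grid trap counts of the study design

    @pytest.mark.parametrize("rows,cols,spacing", [(1, 6, 25), (2, 1, 25), (2, 2, 0)])
    def test_degenerate_dimensions_rejected(self, rows, cols, spacing):
        with pytest.raises(ValueError):
            make_grid(rows, cols, spacing)


class TestDynamics:
    def test_same_seed_identical_truth(self):
        cfg = SimConfig(n_grids=4, seed=11)
        a = simulate_dynamics(cfg)
        b = simulate_dynamics(SimConfig(n_grids=4, seed=11))
        pd.testing.assert_frame_equal(a.density, b.density)
        pd.testing.assert_frame_equal(a.individuals, b.individuals)

    def test_null_coupling_makes_shrews_independent_of_mice(self):
        """With alpha = 0, zero noise and no habitat effects the shrew latent
        depends only on its own lag, not on mouse density."""
        cfg = SimConfig(n_grids=10, n_years=1, alpha_true=0.0, noise_sd=0.0, seed=3)
        state = simulate_dynamics(cfg)
        tbl = truth_regression_table(state, 0)
        # residual after regressing out the lag alone is exactly zero
        b_lag = cfg.derived_lag_coef
        resid = tbl.shrew_density - b_lag * tbl.shrew_lag
        assert np.abs(resid).max() < 1e-12

    def test_variance_budget_sums_to_one(self):
        cfg = SimConfig(alpha_true=-0.9, noise_sd=0.3)
        assert cfg.derived_lag_coef == pytest.approx(np.sqrt(0.1))


class TestCaptures:
    def test_certain_detection_shows_every_individual_every_night(self):
        cfg = SimConfig(
            n_grids=2, n_years=1, seed=5,
            p_night={MOUSE: 1.0, SHREW: 1.0},
            mortality_prob={MOUSE: 0.0, SHREW: 0.0},
        )
        state = simulate_dynamics(cfg)
        caps = simulate_captures(state)
        for g in range(2):
            for t in (1, 2, 3):
                n_true = state.abundance(g, 0, t, MOUSE)
                sel = caps[
                    (caps.grid_id == g) & (caps.primary == t) & (caps.species == MOUSE)
                ]
                assert sel.animal_id.nunique() == n_true
                # every alive individual appears all 5 nights
                assert (sel.groupby("animal_id").night.count() == 5).all()

    def test_zero_detection_gives_empty_table(self):
        cfg = SimConfig(
            n_grids=2, n_years=1, seed=5, p_night={MOUSE: 0.0, SHREW: 0.0}
        )
        caps = simulate_captures(simulate_dynamics(cfg))
        assert caps.empty

    def test_no_mortality_keeps_mouse_ids_constant_across_sessions(self):
        cfg = SimConfig(
            n_grids=1, n_years=1, seed=9,
            p_night={MOUSE: 1.0, SHREW: 0.0},
            mortality_prob={MOUSE: 0.0, SHREW: 0.0},
        )
        state = simulate_dynamics(cfg)
        caps = simulate_captures(state)
        per_session = [
            set(caps[caps.primary == t].animal_id)
            for t in (1, 2, 3)
        ]
        n_by_session = [state.abundance(0, 0, t, MOUSE) for t in (1, 2, 3)]
        # the session with the smallest truth is a subset of the others
        smallest = per_session[int(np.argmin(n_by_session))]
        for s in per_session:
            assert smallest <= s

    def test_detection_complement_matches_closed_form(self):
        """P(caught at least once in 5 nights) = 1 - (1-p)^5."""
        p = 0.3
        expected = 1.0 - (1.0 - p) ** 5
        fractions = []
        for rep in range(40):
            cfg = SimConfig(
                n_grids=1, n_years=1, n_primary=1, seed=100 + rep,
                p_night={MOUSE: p, SHREW: 0.0},
                mortality_prob={MOUSE: 0.0, SHREW: 0.0},
            )
            state = simulate_dynamics(cfg)
            caps = simulate_captures(state)
            n_true = state.abundance(0, 0, 1, MOUSE)
            if n_true == 0:
                continue
            fractions.append(caps.animal_id.nunique() / n_true)
        # binomial tolerance over ~40 x 40 individuals
        assert np.mean(fractions) == pytest.approx(expected, abs=0.03)

    def test_dead_individuals_produce_no_further_records(self):
        cfg = SimConfig(
            n_grids=3, n_years=1, seed=21,
            p_night={MOUSE: 0.5, SHREW: 0.3},
            mortality_prob={MOUSE: 0.5, SHREW: 0.5},
        )
        caps = simulate_captures(simulate_dynamics(cfg))
        for _, grp in caps.groupby("animal_id"):
            grp = grp.sort_values(["primary", "night"])
            fates = grp.fate.to_numpy()
            if "dead" in fates:
                assert fates[-1] == "dead"
                assert (fates[:-1] == "live").all()


class TestIsotopeGenerator:
    def test_pure_diet_reproduces_corrected_source(self, three_sources):
        df = simulate_isotope_data(
            three_sources, [0, 1, 0], species="shrew", noise_sd=0.0, n=3, seed=1
        )
        assert df.d13c.unique() == pytest.approx(three_sources[1].d13c + 1.3)
        assert df.d15n.unique() == pytest.approx(three_sources[1].d15n + 2.5)

    def test_equal_concentrations_put_even_mixture_at_centroid(self):
        from nichecomp.mixing import SourceProfile

        srcs = [
            SourceProfile("a", -26.0, 2.0, 0.5, 0.1),
            SourceProfile("b", -22.0, 8.0, 0.5, 0.1),
            SourceProfile("c", -24.0, 5.0, 0.5, 0.1),
        ]
        mc, mn = mixture_signature(np.ones(3) / 3, srcs, (0.0, 0.0))
        assert mc == pytest.approx(np.mean([s.d13c for s in srcs]))
        assert mn == pytest.approx(np.mean([s.d15n for s in srcs]))

    def test_bad_proportions_rejected(self, three_sources):
        with pytest.raises(ValueError):
            simulate_isotope_data(three_sources, [0.5, 0.5, 0.5], n=2, seed=0)

    def test_recovery_of_true_proportions_from_group_mean(self, three_sources):
        from nichecomp.mixing import correct_sources, solve_mixing

        truth = np.array([0.3, 0.2, 0.5])
        df = simulate_isotope_data(
            three_sources, truth, species="shrew", noise_sd=0.2, n=200, seed=4
        )
        sol = solve_mixing(
            (df.d13c.mean(), df.d15n.mean()),
            correct_sources(three_sources, "shrew"),
        )
        assert sol.feasible
        np.testing.assert_allclose(sol.mean, truth, atol=0.05)
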