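"""Tests of abundance, growth-rate, movement and density estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nichecomp import abundance as ab
from nichecomp.simulate import make_grid


class TestMnka:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["animal_id", "night", "fate", "trap_x", "trap_y"]
        )

    def test_unmarked_counts_live_capture_events(self):
        rows = [("x", 1, "live", 0, 0)] * 12 + [("x", 2, "dead", 0, 0)] * 3
        assert ab.mnka(self._records(rows), marked=False) == 12

    def test_marked_counts_distinct_ids(self):
        rows = [(f"id{i}", n, "live", 0, 0) for i in range(5) for n in (1, 2)]
        assert ab.mnka(self._records(rows), marked=True) == 5

    def test_empty_table(self):
        assert ab.mnka(self._records([]), marked=False) == 0


class TestHorvitzThompson:
    @pytest.mark.parametrize(
        "args,expected_nhat,expected_interval",
        [
            ((20, 5, 0.5, (0.4, 0.6)), 45.0, (20 / 0.6 + 5, 55.0)),
            ((20, 5, 1.0, (1.0, 1.0)), 25.0, (25.0, 25.0)),
            ((0, 7, 0.3, (0.2, 0.4)), 7.0, (7.0, 7.0)),
        ],
    )
    def test_closed_form(self, args, expected_nhat, expected_interval):
        est = ab.ht_abundance(*args)
        assert est.n_hat == pytest.approx(expected_nhat)
        assert est.interval == pytest.approx(expected_interval)

    def test_invalid_detection_probabilities(self):
        with pytest.raises(ValueError):
            ab.ht_abundance(10, 0, 0.0, (0.1, 0.2))
        with pytest.raises(ValueError):
            ab.ht_abundance(10, 0, 0.5, (0.0, 0.6))

    def test_zero_capture_session_uses_rule_of_three(self):
        est = ab.ht_abundance(0, 0, 0.3, (0.2, 0.4))
        assert est.n_hat == 0.0
        assert est.interval[1] == pytest.approx(10.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n_live=st.integers(1, 500),
        n_dead=st.integers(0, 100),
        p1=st.floats(0.05, 0.95),
        p2=st.floats(0.05, 0.95),
    )
    def test_monotone_in_detection_and_additive_in_deaths(self, n_live, n_dead, p1, p2):
        lo_p, hi_p = sorted([p1, p2])
        e_lo = ab.ht_abundance(n_live, n_dead, lo_p, (lo_p, hi_p))
        e_hi = ab.ht_abundance(n_live, n_dead, hi_p, (lo_p, hi_p))
        assert e_lo.n_hat >= e_hi.n_hat  # decreasing in p_star
        e0 = ab.ht_abundance(n_live, 0, lo_p, (lo_p, hi_p))
        assert e_lo.n_hat == pytest.approx(e0.n_hat + n_dead)


class TestClosedPopulationM0:
    def test_saturated_detection_returns_observed_count(self):
        cm = ab.CaptureMatrix(np.ones((30, 5), int), 5)
        res = ab.ClosedPopulationM0(cm).fit()
        assert res.n_hat == 30.0
        assert res.p_hat == 1.0
        assert res.boundary
        assert "boundary" in res.summary()

    def test_lincoln_petersen_equivalence_for_two_occasions(self):
        # n1 = 50, n2 = 40, m2 = 20 recaptures -> N = n1 n2 / m2 = 100
        assert ab.mt_mle([50, 40], 50 + 40 - 20) == pytest.approx(100.0, rel=1e-6)

    def test_no_recaptures_is_unidentified(self):
        det = np.eye(4, 5, dtype=int)
        res = ab.ClosedPopulationM0(ab.CaptureMatrix(det, 5)).fit()
        assert not res.identified
        assert np.isinf(res.interval[1])

    def test_death_censors_exposure(self):
        det = np.array([[1, 1, 0, 0, 0], [1, 0, 1, 0, 1]])
        cm = ab.CaptureMatrix(det, 5, death_occasion=np.array([2, 0]))
        assert cm.exposures.tolist() == [2.0, 5.0]

    def test_interval_brackets_estimate_and_contains_truth_mostly(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(60):
            det = (rng.random((100, 5)) < 0.3).astype(int)
            det = det[det.sum(axis=1) > 0]
            res = ab.ClosedPopulationM0(ab.CaptureMatrix(det, 5)).fit()
            lo, hi = res.interval
            assert lo <= res.n_hat <= hi
            hits += lo <= 100 <= hi
        assert hits / 60 >= 0.85

    def test_capture_matrix_validation(self):
        with pytest.raises(ValueError):
            ab.CaptureMatrix(np.zeros((2, 5), int), 5)  # row without detection
        with pytest.raises(ValueError):
            ab.CaptureMatrix(np.array([[2, 0, 0, 0, 0]]), 5)  # non-binary


class TestGrowthRates:
    @pytest.mark.parametrize(
        "abunds,expected",
        [((10, 20, 30), (2.0, 1.5)), ((10, 10, 10), (1.0, 1.0))],
    )
    def test_ratios(self, abunds, expected):
        assert ab.growth_rates(abunds) == pytest.approx(expected)

    def test_zero_denominator_marks_undefined(self):
        lam12, lam23 = ab.growth_rates((0, 5, 10))
        assert np.isnan(lam12)
        assert lam23 == pytest.approx(2.0)


class TestMovementAndDensity:
    def _caps(self, rows):
        return pd.DataFrame(
            rows, columns=["animal_id", "year", "primary", "night", "trap_x", "trap_y"]
        )

    def test_single_step_distance(self):
        caps = self._caps([("a", 0, 1, 1, 0, 0), ("a", 0, 1, 2, 0, 52)])
        assert ab.mmdm(caps) == pytest.approx(52.0)

    def test_max_of_consecutive_steps(self):
        caps = self._caps(
            [("a", 0, 1, 1, 0, 0), ("a", 0, 1, 2, 0, 30), ("a", 0, 1, 3, 40, 30)]
        )
        assert ab.mmdm(caps) == pytest.approx(40.0)

    def test_mean_over_individuals_and_singletons_excluded(self):
        caps = self._caps(
            [
                ("a", 0, 1, 1, 0, 0), ("a", 0, 1, 2, 0, 30),
                ("b", 0, 1, 1, 0, 0), ("b", 0, 2, 1, 0, 50),
                ("c", 0, 1, 1, 10, 10),
            ]
        )
        assert ab.mmdm(caps) == pytest.approx(40.0)

    def test_no_movers_is_undefined(self):
        caps = self._caps([("a", 0, 1, 1, 0, 0)])
        assert np.isnan(ab.mmdm(caps))

    @pytest.mark.parametrize(
        "rows,cols,buffer,expected_ha",
        [
            (7, 6, 50.0, (18750 + 550 * 50 + np.pi * 2500) / 1e4),
            (7, 6, 0.0, 1.875),
            (5, 5, 50.0, (10000 + 20000 + np.pi * 2500) / 1e4),
        ],
    )
    def test_effective_area_closed_form(self, rows, cols, buffer, expected_ha):
        g = make_grid(rows, cols, 25)
        assert ab.effective_area(g, buffer) == pytest.approx(expected_ha, abs=1e-4)

    def test_density_scales_estimate_and_interval(self):
        est = ab.ht_abundance(20, 5, 0.5, (0.4, 0.6))
        d = ab.density(est, 5.41)
        assert d.density == pytest.approx(45 / 5.41)
        assert d.interval[0] == pytest.approx(est.interval[0] / 5.41)
        # density x area reconstructs n_hat to machine precision
        assert d.density * d.effective_area == pytest.approx(est.n_hat, rel=1e-12)

    def test_nonpositive_area_rejected(self):
        est = ab.ht_abundance(1, 0, 0.5, (0.4, 0.6))
        with pytest.raises(ValueError):
            ab.density(est, 0.0)
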