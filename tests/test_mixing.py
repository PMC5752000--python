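"""Tests of discrimination correction, the concentration-dependent mixing
solver (unique and polytope cases), dietary overlap, and the KNN test."""

import numpy as np
import pytest

from nichecomp import mixing as mx
from nichecomp.benchmarks import simplex_grid_oracle
from nichecomp.simulate import mixture_signature


class TestCorrectSources:
    def test_shrew_offsets(self, three_sources):
        src = mx.SourceProfile("x", -26.0, 2.0, 0.5, 0.1)
        out = mx.correct_sources([src], "shrew")[0]
        assert (out.d13c, out.d15n) == pytest.approx((-24.7, 4.5))
        assert (out.conc_c, out.conc_n) == (0.5, 0.1)

    def test_mouse_offsets(self):
        src = mx.SourceProfile("x", -26.0, 2.0, 0.5, 0.1)
        out = mx.correct_sources([src], "mouse")[0]
        assert (out.d13c, out.d15n) == pytest.approx((-25.0, 5.0))

    def test_zero_offsets_identity(self, three_sources):
        out = mx.correct_sources(three_sources, "none", {"none": (0.0, 0.0)})
        assert out[0] == three_sources[0]

    def test_unknown_species_rejected(self, three_sources):
        with pytest.raises(ValueError):
            mx.correct_sources(three_sources, "vole")


class TestSolveMixingUnique:
    def test_vertex_identity(self, three_sources):
        s2 = three_sources[1]
        sol = mx.solve_mixing((s2.d13c, s2.d15n), three_sources)
        assert sol.solution_type == "unique"
        np.testing.assert_allclose(sol.mean, [0, 1, 0], atol=1e-9)
        assert sol.sd.max() == 0.0

    def test_centroid_symmetry_with_equal_concentrations(self):
        srcs = [
            mx.SourceProfile("a", -26.0, 2.0, 0.5, 0.1),
            mx.SourceProfile("b", -22.0, 2.0, 0.5, 0.1),
            mx.SourceProfile("c", -24.0, 5.0, 0.5, 0.1),
        ]
        centroid = (np.mean([s.d13c for s in srcs]), np.mean([s.d15n for s in srcs]))
        sol = mx.solve_mixing(centroid, srcs)
        np.testing.assert_allclose(sol.mean, np.ones(3) / 3, atol=1e-9)

    def test_known_proportions_recovered_exactly(self, three_sources):
        truth = np.array([0.3, 0.2, 0.5])
        mix = mixture_signature(truth, three_sources, (0.0, 0.0))
        sol = mx.solve_mixing(mix, three_sources)
        np.testing.assert_allclose(sol.mean, truth, atol=1e-9)

    def test_outside_triangle_is_infeasible(self, three_sources):
        sol = mx.solve_mixing((-10.0, 50.0), three_sources)
        assert sol.solution_type == "infeasible"
        assert not sol.feasible

    def test_collinear_sources_rejected(self):
        srcs = [
            mx.SourceProfile("a", -26.0, 2.0, 0.5, 0.1),
            mx.SourceProfile("b", -24.0, 4.0, 0.5, 0.1),
            mx.SourceProfile("c", -22.0, 6.0, 0.5, 0.1),
        ]
        with pytest.raises(ValueError, match="ill-conditioned"):
            mx.solve_mixing((-24.0, 4.0), srcs)


class TestSolveMixingPolytope:
    def test_polytope_mean_matches_grid_oracle(self, four_sources):
        mix = mixture_signature(np.full(4, 0.25), four_sources, (0.0, 0.0))
        sol = mx.solve_mixing(mix, four_sources, seed=3)
        assert sol.solution_type == "polytope"
        oracle = simplex_grid_oracle(mix, four_sources, resolution=0.004)
        np.testing.assert_allclose(sol.mean, oracle, atol=0.02)

    def test_mass_balance_of_reported_solution(self, four_sources):
        mix = mixture_signature(np.array([0.4, 0.1, 0.3, 0.2]), four_sources, (0.0, 0.0))
        sol = mx.solve_mixing(mix, four_sources, seed=5)
        assert sol.feasible
        assert mx.mass_balance_residual(sol.mean, mix, four_sources) < 1e-6
        assert sol.mean.sum() == pytest.approx(1.0, abs=1e-9)
        assert (sol.mean >= 0).all()

    def test_equal_concentration_limit_matches_plain_linear_mixing(self):
        """With equal concentrations the solver reduces to the standard
        (non-concentration-dependent) dual-isotope linear solution."""
        srcs = [
            mx.SourceProfile("a", -26.0, 2.0, 0.5, 0.1),
            mx.SourceProfile("b", -22.0, 8.0, 0.5, 0.1),
            mx.SourceProfile("c", -24.0, 1.0, 0.5, 0.1),
        ]
        mix = (-24.2, 4.0)
        a = np.array(
            [[s.d13c for s in srcs], [s.d15n for s in srcs], [1.0, 1.0, 1.0]]
        )
        plain = np.linalg.solve(a, [mix[0], mix[1], 1.0])
        sol = mx.solve_mixing(mix, srcs)
        np.testing.assert_allclose(sol.mean, plain, atol=1e-9)

    def test_permutation_equivariance(self, four_sources):
        mix = mixture_signature(np.full(4, 0.25), four_sources, (0.0, 0.0))
        sol = mx.solve_mixing(mix, four_sources, seed=7)
        perm = [2, 0, 3, 1]
        sol_p = mx.solve_mixing(mix, [four_sources[i] for i in perm], seed=7)
        # same feasible segment: means agree up to sampling error
        np.testing.assert_allclose(sol_p.mean, sol.mean[perm], atol=0.01)


class TestDietaryOverlap:
    def _sol(self, means, names=("inv", "mush", "worm")):
        m = np.asarray(means, float)
        return mx.DietSolution(tuple(names), m, np.zeros(len(m)), "unique")

    def test_joint_criterion(self):
        shrew = self._sol([0.29, 0.05, 0.66])
        mice = [self._sol([0.5, 0.3, 0.2]), self._sol([0.1, 0.6, 0.3]),
                self._sol([0.3, 0.1, 0.6]), self._sol([0.25, 0.4, 0.35])]
        rep = mx.dietary_overlap(shrew, mice)
        inv = next(r for r in rep if r["source"] == "inv")
        assert inv["shrew_included"]
        assert inv["mouse_percent"] == pytest.approx(75.0)
        assert inv["overlap"]
        mush = next(r for r in rep if r["source"] == "mush")
        assert not mush["shrew_included"]  # 0.05 < 0.2
        assert not mush["overlap"]

    def test_threshold_is_strict(self):
        shrew = self._sol([0.19, 0.41, 0.40])
        rep = mx.dietary_overlap(shrew, [self._sol([1.0, 0.0, 0.0])])
        assert not rep[0]["overlap"]

    def test_no_mice_is_undefined_not_error(self):
        shrew = self._sol([0.5, 0.3, 0.2])
        rep = mx.dietary_overlap(shrew, [])
        assert np.isnan(rep[0]["mouse_percent"])
        assert not rep[0]["overlap"]

    def test_mismatched_sources_rejected(self):
        shrew = self._sol([0.5, 0.3, 0.2])
        other = self._sol([0.5, 0.3, 0.2], names=("x", "y", "z"))
        with pytest.raises(ValueError):
            mx.dietary_overlap(shrew, [other])


class TestKnnRandomization:
    def test_separated_clusters(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.3, (15, 2))
        b = rng.normal(10.0, 0.3, (15, 2))
        stat, p = mx.knn_randomization_test(a, b, k=3, n_perm=999, seed=2)
        assert stat == 1.0
        assert p <= 0.01

    def test_reproducible_and_label_symmetric(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, (10, 2))
        b = rng.normal(0.5, 1.0, (10, 2))
        r1 = mx.knn_randomization_test(a, b, seed=5)
        r2 = mx.knn_randomization_test(a, b, seed=5)
        assert r1 == r2
        r3 = mx.knn_randomization_test(b, a, seed=5)
        assert r3[0] == pytest.approx(r1[0])

    def test_exhaustive_agrees_with_sampled_on_tiny_input(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, (4, 2))
        b = rng.normal(0.0, 1.0, (4, 2))
        stat_e, p_e = mx.knn_randomization_test(a, b, k=3, exhaustive=True)
        stat_s, p_s = mx.knn_randomization_test(a, b, k=3, n_perm=4999, seed=6)
        assert stat_e == stat_s
        assert p_s == pytest.approx(p_e, abs=0.05)

    def test_interleaved_lattices_are_indistinguishable(self):
        # identical interleaved 1-D lattices: statistic near chance, p large
        xs = np.arange(8, dtype=float)
        a = np.column_stack([xs * 2, np.zeros(8)])
        b = np.column_stack([xs * 2 + 1, np.zeros(8)])
        stat, p = mx.knn_randomization_test(a, b, k=3, exhaustive=True)
        assert p > 0.1

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            mx.knn_randomization_test(np.zeros((3, 2)), np.ones((10, 2)), k=3)
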