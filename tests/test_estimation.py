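"""Gaussian-Lorentzian kernel, spectrum synthesis, objective, and the fit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import approx_fprime

from nmrsearch.estimation import (
    EstimationError,
    LineshapeParams,
    OptimizeConfig,
    cosine_similarity,
    kernel,
    objective,
    objective_gradient,
    optimize,
    synthesize_spectrum,
)
from nmrsearch.spectra import Spectrum


class TestKernel:
    def test_unit_height_at_center(self):
        for lam in np.linspace(0, 1, 11):
            assert kernel(0.0, lam) == pytest.approx(1.0, abs=1e-15)

    def test_unit_fwhm(self):
        # both components equal 1/2 at z = +-1/2, so sigma is exactly the FWHM
        for lam in np.linspace(0, 1, 21):
            assert kernel(0.5, lam) == pytest.approx(0.5, abs=1e-15)
            assert kernel(-0.5, lam) == pytest.approx(0.5, abs=1e-15)

    def test_component_values_at_unit_z(self):
        assert kernel(1.0, 1.0) == pytest.approx(0.2)
        assert kernel(1.0, 0.0) == pytest.approx(0.0625)

    def test_tail_behavior(self):
        # Gaussian component is negligible by 10 widths; Lorentzian tail is not
        assert kernel(10.0, 0.0) < 1e-3
        assert kernel(10.0, 1.0) == pytest.approx(1.0 / 401.0)

    def test_rejects_lambda_outside_unit_interval(self):
        with pytest.raises(EstimationError):
            kernel(0.0, 1.5)

    @given(z=st.floats(-50, 50), lam=st.floats(0, 1))
    def test_symmetric_bounded_positive(self, z, lam):
        v = kernel(z, lam)
        assert kernel(-z, lam) == v
        assert 0.0 <= v <= 1.0
        # strictly positive wherever float64 can represent the Gaussian tail
        if lam > 0 or abs(z) <= 10:
            assert v > 0.0


class TestSynthesize:
    def test_single_peak_values(self, carbon_grid):
        p = LineshapeParams(mu=[50.0], sigma=[1.0], lam=[0.0])
        est = synthesize_spectrum(carbon_grid, p)
        at = {x: y for x, y in zip(carbon_grid.round(4), est.intensities)}
        assert at[50.0] == pytest.approx(1.0)
        assert at[50.5] == pytest.approx(0.5)

    def test_coincident_peaks_stack_additively(self, carbon_grid):
        one = synthesize_spectrum(
            carbon_grid, LineshapeParams([50.0], [0.3], [0.5])
        ).intensities
        two = synthesize_spectrum(
            carbon_grid, LineshapeParams([50.0, 50.0], [0.3, 0.3], [0.5, 0.5])
        ).intensities
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)

    def test_translation_equivariance(self, carbon_grid):
        a = synthesize_spectrum(carbon_grid, LineshapeParams([48.0], [0.2], [0.4]))
        b = synthesize_spectrum(carbon_grid, LineshapeParams([53.0], [0.2], [0.4]))
        shift = int(round(5.0 / 0.05))
        np.testing.assert_allclose(
            a.intensities[:-shift], b.intensities[shift:], atol=1e-12
        )

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(EstimationError):
            LineshapeParams([50.0], [0.0], [0.5])


class TestCosineSimilarity:
    def test_self_similarity_and_scale_invariance(self):
        y = np.array([1.0, 2.0, 0.5])
        assert cosine_similarity(y, y) == pytest.approx(1.0)
        assert cosine_similarity(y, 2 * y) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_zero_vector_is_explicit_failure(self):
        with pytest.raises(EstimationError):
            cosine_similarity([1.0, 0.0], [0.0, 0.0])


def _self_query(grid, params):
    """Query whose intensities are exactly the model's own synthesis."""
    return Spectrum(grid, synthesize_spectrum(grid, params).intensities)


class TestObjective:
    def test_perfect_match_leaves_only_width_penalty(self, carbon_grid):
        p = LineshapeParams([50.0], [1.0], [0.5])
        q = _self_query(carbon_grid, p)
        assert objective(p, q, np.array([50.0])) == pytest.approx(0.0, abs=1e-12)
        p2 = LineshapeParams([50.0], [0.5], [0.5])
        q2 = _self_query(carbon_grid, p2)
        assert objective(p2, q2, np.array([50.0])) == pytest.approx(0.75, abs=1e-12)

    def test_coincident_pair_pays_ordering_margin(self, carbon_grid):
        p = LineshapeParams([50.0, 50.0], [1.0, 1.0], [0.5, 0.5])
        q = _self_query(carbon_grid, p)
        j = objective(p, q, np.array([50.0, 50.0]), OptimizeConfig(epsilon=0.01))
        assert j == pytest.approx(1.0 - 2.0 - 1e-4, abs=1e-12)

    def test_anchor_term_is_squared_distance(self, carbon_grid):
        p = LineshapeParams([50.0], [1.0], [0.5])
        q = _self_query(carbon_grid, p)
        j = objective(p, q, np.array([49.0]))
        assert j == pytest.approx(0.0 - 1.0, abs=1e-12)

    def test_all_zero_query_is_explicit_failure(self, carbon_grid):
        p = LineshapeParams([50.0], [1.0], [0.5])
        q = Spectrum(carbon_grid, np.zeros_like(carbon_grid))
        with pytest.raises(EstimationError):
            objective(p, q, np.array([50.0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_analytic_gradient_matches_finite_differences(self, carbon_grid, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 4))
        truth = LineshapeParams(
            mu=np.sort(rng.uniform(44, 56, m)),
            sigma=rng.uniform(0.05, 0.5, m),
            lam=rng.uniform(0.1, 0.9, m),
        )
        q = _self_query(carbon_grid, truth)
        anchors = truth.mu + rng.uniform(-0.3, 0.3, m)
        at = LineshapeParams(
            mu=truth.mu + rng.uniform(-0.2, 0.2, m),
            sigma=rng.uniform(0.1, 0.8, m),
            lam=rng.uniform(0.2, 0.8, m),
        )
        x0 = np.concatenate([at.mu, at.sigma, at.lam])

        def j_of(x):
            p = LineshapeParams(x[:m], x[m : 2 * m], x[2 * m :])
            return objective(p, q, anchors)

        g_fd = approx_fprime(x0, j_of, 1e-7)
        g_an = objective_gradient(at, q, anchors)
        np.testing.assert_allclose(g_an, g_fd, rtol=1e-4, atol=1e-6)


class TestOptimize:
    def test_single_peak_center_recovered(self, carbon_grid):
        truth = LineshapeParams([50.0], [0.3], [0.5])
        q = _self_query(carbon_grid, truth)
        q = Spectrum(carbon_grid, q.intensities / q.intensities.max())
        res = optimize(np.array([49.5]), q)
        assert abs(res.delta_star[0] - 50.0) <= 0.05

    def test_never_decreases_objective(self, carbon_grid):
        truth = LineshapeParams([48.0, 52.0], [0.2, 0.3], [0.3, 0.7])
        q = _self_query(carbon_grid, truth)
        res = optimize(truth.mu.copy(), q)
        assert res.j_final >= res.j_init - 1e-8

    def test_well_separated_peaks_decouple(self):
        grid = np.arange(30.0, 170.0 + 1e-9, 0.05)
        truth = LineshapeParams([50.0, 150.0], [0.1, 0.1], [0.5, 0.5])
        y = synthesize_spectrum(grid, truth).intensities
        q = Spectrum(grid, y / y.max())
        res = optimize(np.array([50.3, 149.7]), q)
        assert np.max(np.abs(res.delta_star - truth.mu)) <= 0.1

    def test_iteration_cap_returns_best_iterate_without_raising(self, carbon_grid):
        truth = LineshapeParams([50.0], [0.3], [0.5])
        q = _self_query(carbon_grid, truth)
        res = optimize(np.array([49.5]), q, OptimizeConfig(max_iter=1))
        assert res.j_final >= res.j_init
        assert res.converged is False

    def test_empty_anchors_rejected(self, carbon_grid):
        q = Spectrum(carbon_grid, np.ones_like(carbon_grid))
        with pytest.raises(EstimationError):
            optimize(np.array([]), q)

    def test_bounds_respected(self, carbon_grid):
        truth = LineshapeParams([50.0], [0.05], [1.0])
        q = _self_query(carbon_grid, truth)
        res = optimize(np.array([50.0]), q)
        assert np.all(res.params.sigma >= 1e-3)
        assert np.all((res.params.lam >= 0) & (res.params.lam <= 1))
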