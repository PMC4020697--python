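import itertools

import numpy as np
import pytest
from scipy import optimize

from smoltherit.greml import (GREML, MixedModelSpec, NumericalRankError, fit_greml,
                              heritabilities, liability_boundary, liability_transform,
                              reml_gradient, reml_loglik, sex_design)
from smoltherit.simulate import SimulationConfig, simulate_cohort
from smoltherit import apply_marker_qc, build_grms

from conftest import random_toy_spec


def grid_polish_oracle(spec, two_component=False):
    """Independent numeric maximization of the restricted likelihood: coarse
    3-D grid over components, refined by Nelder-Mead on the log scale."""
    vy = np.var(spec.y, ddof=1)
    grid = vy * np.array([1e-6, 0.01, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0, 1.5])
    axes = (grid, [0.0], grid[1:]) if two_component else (grid, grid, grid[1:])
    best, bestll = None, -np.inf
    for c in itertools.product(*axes):
        ll = reml_loglik(c, spec)
        if ll > bestll:
            bestll, best = ll, np.array(c)
    active = [0, 2] if two_component else [0, 1, 2]

    def neg(t):
        theta = np.zeros(3)
        theta[active] = np.maximum(np.exp(t), 1e-14)
        return -reml_loglik(theta, spec)

    res = optimize.minimize(neg, np.log(np.maximum(best[active], 1e-12)),
                            method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    theta = np.zeros(3)
    theta[active] = np.maximum(np.exp(res.x), 1e-14)
    return theta, -res.fun


class TestRemlLoglik:
    def test_iid_limit_matches_scalar_formula(self):
        """With no genetic variance and an intercept-only design the REML
        objective collapses to -[n log s2 + log(n/s2) + RSS/s2]/2."""
        rng = np.random.default_rng(0)
        n = 12
        y = rng.standard_normal(n)
        spec = MixedModelSpec(y=y, X=np.ones((n, 1)), A=np.zeros((n, n)),
                              D=np.zeros((n, n)))
        s2 = 0.7
        rss = np.sum((y - y.mean()) ** 2)
        expected = -0.5 * (n * np.log(s2) + np.log(n / s2) + rss / s2)
        assert reml_loglik((0.0, 0.0, s2), spec) == pytest.approx(expected, rel=1e-12)

    def test_matches_dense_algebra_oracle(self):
        """Direct evaluation with explicit inverses and determinants."""
        rng = np.random.default_rng(1)
        spec = random_toy_spec(rng, n=6)
        theta = (0.4, 0.3, 0.6)
        V = theta[0] * spec.A + theta[1] * spec.D + theta[2] * np.eye(6)
        Vinv = np.linalg.inv(V)
        XtVX = spec.X.T @ Vinv @ spec.X
        P = Vinv - Vinv @ spec.X @ np.linalg.inv(XtVX) @ spec.X.T @ Vinv
        expected = -0.5 * (np.log(np.linalg.det(V)) + np.log(np.linalg.det(XtVX))
                           + spec.y @ P @ spec.y)
        assert reml_loglik(theta, spec) == pytest.approx(expected, rel=1e-10)

    def test_scaling_y_shifts_by_jacobian_term(self):
        """l(4 theta; 2y) = l(theta; y) - (n - f)/2 * log 4."""
        rng = np.random.default_rng(2)
        spec = random_toy_spec(rng, n=8)
        spec2 = MixedModelSpec(y=2 * spec.y, X=spec.X, A=spec.A, D=spec.D)
        theta = np.array([0.5, 0.2, 0.8])
        n, f = spec.n, spec.X.shape[1]
        assert reml_loglik(4 * theta, spec2) == pytest.approx(
            reml_loglik(theta, spec) - 0.5 * (n - f) * np.log(4), rel=1e-10)

    def test_reference_level_invariance(self):
        """Same sex-factor column space, different reference level."""
        rng = np.random.default_rng(3)
        spec = random_toy_spec(rng, n=10)
        sex = np.array(["F", "M", "NA", "F", "M", "NA", "F", "M", "F", "M"])
        X1 = sex_design(sex, 10)
        X2 = np.column_stack([np.ones(10), (sex == "F").astype(float),
                              (sex == "NA").astype(float)])  # M as reference
        s1 = MixedModelSpec(y=spec.y, X=X1, A=spec.A, D=spec.D)
        s2 = MixedModelSpec(y=spec.y, X=X2, A=spec.A, D=spec.D)
        theta = (0.3, 0.3, 0.5)
        assert reml_loglik(theta, s1) == pytest.approx(reml_loglik(theta, s2), rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        spec = random_toy_spec(rng, n=9)
        theta = np.array([0.5, 0.3, 0.7])
        g = reml_gradient(theta, spec)
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1e-6
            fd = (reml_loglik(theta + e, spec) - reml_loglik(theta - e, spec)) / 2e-6
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_singular_v_raises(self):
        spec = MixedModelSpec(y=np.arange(4.0), X=np.ones((4, 1)),
                              A=np.eye(4), D=np.eye(4))
        with pytest.raises(NumericalRankError):
            reml_loglik((0.0, 0.0, 0.0), spec)


class TestFitGreml:
    def test_agrees_with_grid_oracle_on_toy(self):
        rng = np.random.default_rng(8)
        spec = random_toy_spec(rng, n=8)
        est = fit_greml(spec, optimizer="em", max_iter=200_000, cross_check=False,
                        restarts=5)
        oracle, _ = grid_polish_oracle(spec)
        np.testing.assert_allclose(heritabilities(est.components()),
                                   heritabilities(oracle), atol=2e-3)

    def test_additive_only_matches_two_component_oracle(self):
        """Dropping the dominance term reproduces the additive-only run and
        agrees with a 2-D grid oracle."""
        rng = np.random.default_rng(12)
        spec = random_toy_spec(rng, n=10, include_dominance=False)
        est = fit_greml(spec, optimizer="bounded", cross_check=False, restarts=5)
        assert est.sigma2_d == 0.0
        oracle, oll = grid_polish_oracle(spec, two_component=True)
        assert est.loglik == pytest.approx(oll, abs=1e-6)
        np.testing.assert_allclose(heritabilities(est.components()),
                                   heritabilities(oracle), atol=1e-3)

    def test_em_iterates_stay_positive_and_likelihood_monotone(self):
        rng = np.random.default_rng(5)
        spec = random_toy_spec(rng, n=10)
        est = fit_greml(spec, optimizer="em", max_iter=400, cross_check=False)
        trace = est.trace
        assert np.all(trace[:, :3] > 0)  # never clamped to 0 or negative
        assert np.all(np.diff(trace[:, 3]) >= -1e-10)

    def test_em_and_bounded_agree(self, small_fit_inputs):
        """EM and quasi-Newton land on the same optimum; near a variance
        boundary EM approaches it sub-linearly, so agreement is asserted at
        the precision its finite iteration budget supports."""
        spec = small_fit_inputs[3]
        em = fit_greml(spec, optimizer="em", cross_check=False)
        qn = fit_greml(spec, optimizer="bounded", cross_check=False)
        assert abs(em.h2_a - qn.h2_a) < 2e-2
        assert abs(em.h2_d - qn.h2_d) < 2e-2
        assert em.loglik <= qn.loglik + 1e-6

    def test_null_data_recovers_near_zero_heritability(self):
        """Phenotypes simulated with no genetic signal give small average
        heritability estimates (n=200, 20 seeds)."""
        h2a, h2d = [], []
        for seed in range(20):
            cfg = SimulationConfig(n1=120, n2=80, m=300, h2_a_target=0.0,
                                   h2_d_target=0.0, n_causal_add=10,
                                   n_causal_dom=10, missing_geno_rate=0.0,
                                   seed=1000 + seed)
            g, cohort, truth = simulate_cohort(cfg)
            g_qc, _ = apply_marker_qc(g)
            pair = build_grms(g_qc)
            spec = MixedModelSpec.from_cohort(pair, cohort, y=truth.liability)
            est = fit_greml(spec, optimizer="bounded", cross_check=False)
            h2a.append(est.h2_a)
            h2d.append(est.h2_d)
        assert np.mean(h2a) < 0.15 and np.mean(h2d) < 0.15

    def test_nonconvergence_warns_not_silent(self):
        rng = np.random.default_rng(6)
        spec = random_toy_spec(rng, n=10)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            est = fit_greml(spec, optimizer="em", max_iter=3, cross_check=False)
        assert est.converged is False

    def test_cross_check_warns_on_disagreement(self):
        """A surface with distinct local optima triggers the EM-vs-quasi-Newton
        disagreement warning when the two optimizers split."""
        rng = np.random.default_rng(6)
        spec = random_toy_spec(rng, n=10)
        # starved EM vs converged bounded must disagree
        with pytest.warns(RuntimeWarning):
            fit_greml(spec, optimizer="em", max_iter=2, cross_check=True)


class TestHeritabilities:
    @pytest.mark.parametrize("components, expected", [
        ((0.094, 0.0044, 2.6e-28), (0.955, 0.045, 1.000)),
        ((8.3e-59, 0.097, 0.15), (0.000, 0.393, 0.393)),
        ((0.0, 0.0, 1.0), (0.0, 0.0, 0.0)),
    ])
    def test_ratio_identities(self, components, expected):
        h = heritabilities(components)
        np.testing.assert_allclose(np.round(h, 3), expected, atol=5e-4)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            heritabilities((0.0, 0.0, 0.0))


class TestLiabilityTransform:
    def test_uyr_value(self):
        assert liability_transform(1.00, 29 / 127) == pytest.approx(1.93, abs=0.01)

    def test_zero_heritability_maps_to_zero(self):
        assert liability_transform(0.0, 0.3) == 0.0

    def test_boundary_is_two_over_pi(self):
        assert liability_boundary() == pytest.approx(2 / np.pi, abs=1e-8)

    def test_unclamped_above_one(self):
        assert liability_transform(0.9, 0.5) > 1.0

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_prevalence_domain(self, bad):
        with pytest.raises(ValueError):
            liability_transform(0.5, bad)


class TestGREMLEstimator:
    def test_sklearn_interface_and_fit(self, small_sim):
        from sklearn.base import clone

        g, cohort, truth = small_sim
        gq, _ = apply_marker_qc(g)
        model = GREML(optimizer="bounded")
        assert clone(model).get_params()["optimizer"] == "bounded"
        model.fit(gq.codes, truth.liability, sex=cohort.aligned_to(gq).table["sex"].to_numpy())
        assert 0 <= model.h2_a_ <= 1 and 0 <= model.H2_ <= 1
        np.testing.assert_allclose(model.gblup_g_, model.gblup_a_ + model.gblup_d_,
                                   atol=1e-12)
        np.testing.assert_array_equal(model.predict(), model.gblup_g_)

    def test_precomputed_kernels(self, small_fit_inputs):
        _, cohort, pair, spec, truth = small_fit_inputs
        model = GREML(optimizer="bounded", precomputed=True)
        model.fit((pair.A, pair.D), truth.liability)
        direct = fit_greml(MixedModelSpec(y=truth.liability, X=np.ones((spec.n, 1)),
                                          A=pair.A, D=pair.D),
                           optimizer="bounded", cross_check=False)
        assert model.h2_a_ == pytest.approx(direct.h2_a, abs=1e-8)
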