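"""REML likelihood, variance-component estimation, LRT and AIC machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from culturekin import (
    AnimalModel,
    DesignSpec,
    RelationshipMatrix,
    VarianceComponents,
    additive_matrix,
    apply_cross_fostering,
    compare_models,
    cultural_relatedness_matrix,
    fit_animal_model,
    gxc_interaction_matrix,
    heritabilities,
    identity_matrix,
    lrt_component,
    make_design,
    restricted_loglik,
    simulate_phenotypes,
)
from culturekin.model import FitResult


def dense_projection_reml(y, X, K_list, variances):
    """Brute-force REML log-likelihood forming P = V^-1 - V^-1 X (...) explicitly."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    V = variances[-1] * np.eye(n)
    for s2, K in zip(variances[:-1], K_list):
        V += s2 * K
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, logdet_V = np.linalg.slogdet(V)
    _, logdet_X = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_V + logdet_X
                   + y @ P @ y)


def random_psd(rng, n, rank=None):
    W = rng.standard_normal((n, rank or n))
    K = W @ W.T / (rank or n)
    d = np.sqrt(np.diag(K))
    return K / np.outer(d, d)  # unit diagonal


def small_dataset(seed=0, n=120, s2A=0.5, s2C=0.0, s2R=0.5,
                  swap=0.5, envs=1):
    fams = max(2, n // (2 * envs * 4))
    spec = DesignSpec(n_cultures=2, n_environments=envs,
                      n_families_per_cell=fams, brood_size=4,
                      swap_fraction=swap, seed=seed)
    pop = apply_cross_fostering(make_design(spec), spec)
    vc = VarianceComponents(sigma2_A=s2A, sigma2_C=s2C, sigma2_R=s2R)
    ph = simulate_phenotypes(pop, vc, seed=seed + 1)
    ids = list(ph["id"])
    A = additive_matrix(pop.ped).subset(ids)
    C = cultural_relatedness_matrix(pop.cped).subset(ids)
    return ph, A, C


class TestRestrictedLoglik:
    def test_iid_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(25) * 1.7 + 3.0
        X = np.ones((25, 1))
        s2 = 0.9
        n, p = 25, 1
        # closed-form REML loglik of iid N(mu, s2) with an intercept
        rss = np.sum((y - y.mean()) ** 2)
        expected = -0.5 * ((n - p) * np.log(2 * np.pi) + n * np.log(s2)
                           + np.log(n / s2) + rss / s2)
        assert restricted_loglik(y, X, [], [s2]) == pytest.approx(
            expected, abs=1e-10)

    def test_translation_invariance_with_intercept(self):
        rng = np.random.default_rng(1)
        n = 30
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        K = random_psd(rng, n, rank=8)
        base = restricted_loglik(y, X, [K], [0.4, 0.6])
        shifted = restricted_loglik(y + 100.0, X, [K], [0.4, 0.6])
        assert shifted == pytest.approx(base, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 31))
        m = int(rng.integers(1, 4))
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n),
                             rng.standard_normal((n, int(rng.integers(0, 3))))])
        K_list = [random_psd(rng, n, rank=max(3, n // 2)) for _ in range(m)]
        variances = list(rng.uniform(0.1, 1.5, size=m + 1))
        assert restricted_loglik(y, X, K_list, variances) == pytest.approx(
            dense_projection_reml(y, X, K_list, variances), abs=1e-8)

    def test_singular_design_rejected(self):
        y = np.zeros(10)
        X = np.ones((10, 2))  # duplicated column
        with pytest.raises(np.linalg.LinAlgError):
            restricted_loglik(y, X, [], [1.0])

    def test_non_pd_covariance_rejected(self):
        y = np.zeros(5)
        X = np.ones((5, 1))
        with pytest.raises(np.linalg.LinAlgError):
            restricted_loglik(y, X, [], [-1.0])


class TestAnimalModelFit:
    def test_iid_intercept_only_matches_sample_variance(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(80) * 2.0 + 1.0
        df = pd.DataFrame({"id": [f"i{k}" for k in range(80)], "y": y})
        res = fit_animal_model(df)
        assert res.estimates["residual"] == pytest.approx(
            np.var(y, ddof=1), rel=1e-10)
        assert res.fixed_estimates["intercept"] == pytest.approx(y.mean())

    def test_null_genetic_component_stays_near_boundary(self):
        """With no genetic variance the A estimate averages near zero."""
        est_A, est_R = [], []
        for seed in range(6):
            ph, A, _ = small_dataset(seed=seed, n=160, s2A=0.0, s2R=1.0)
            res = fit_animal_model(ph, random_effects={"A": A},
                                   compute_se=False)
            est_A.append(res.estimates["A"])
            est_R.append(res.estimates["residual"])
        assert np.mean(est_A) < 0.15
        assert np.mean(est_R) == pytest.approx(1.0, abs=0.15)

    def test_estimator_sklearn_contract(self):
        ph, A, _ = small_dataset(seed=6, n=80)
        est = AnimalModel(random_effects={"A": A}, compute_se=False)
        params = est.get_params()
        assert "random_effects" in params and "n_restarts" in params
        est.set_params(n_restarts=2)
        est.fit(ph, ph["y"].to_numpy())
        assert hasattr(est, "variance_components_")
        assert est.n_used_ == len(ph)
        assert est.aic_ == pytest.approx(
            -2 * est.loglik_ + 2 * len(est.variance_components_))
        # population-mean prediction uses the fixed part only
        assert np.allclose(est.predict(ph),
                           est.fixed_effects_["intercept"])

    def test_estimates_invariant_under_relabeling(self):
        ph, A, C = small_dataset(seed=7, n=120, s2C=0.3)
        res = fit_animal_model(ph, random_effects={"A": A, "C": C},
                               compute_se=False, random_state=2)
        perm = np.random.default_rng(0).permutation(len(ph))
        ph2 = ph.iloc[perm].reset_index(drop=True)
        ids2 = list(ph2["id"])
        res2 = fit_animal_model(ph2, random_effects={"A": A.subset(ids2),
                                                     "C": C.subset(ids2)},
                                compute_se=False, random_state=2)
        for k in res.estimates:
            assert res2.estimates[k] == pytest.approx(res.estimates[k],
                                                      abs=1e-4)

    def test_group_effect_absorbs_brood_variance(self):
        spec = DesignSpec(n_cultures=1, n_families_per_cell=40, brood_size=4)
        pop = make_design(spec)
        vc = VarianceComponents(sigma2_CB=0.6, sigma2_R=0.4)
        ph = simulate_phenotypes(pop, vc, seed=9)
        res = fit_animal_model(ph, group_effects=("brood",),
                               compute_se=False)
        assert res.estimates["brood"] == pytest.approx(0.6, abs=0.2)
        assert res.estimates["residual"] == pytest.approx(0.4, abs=0.1)


class TestHeritabilities:
    def test_ratio_arithmetic(self):
        fit = FitResult(
            estimates={"A": 0.4, "C": 0.3, "residual": 0.3},
            fixed_estimates={}, loglik_restricted=0.0, aic=0.0, se=None,
            converged=True, n_used=10, term_names=("A", "C", "residual"),
            fixed_names=("intercept",), data_hash="x",
        )
        h = heritabilities(fit)
        assert h["A"] == pytest.approx(0.4)
        assert h["C"] == pytest.approx(0.3)
        assert sum(h[k] for k in ("A", "C", "residual")) == pytest.approx(1)

    def test_all_residual(self):
        fit = FitResult(
            estimates={"A": 0.0, "residual": 1.0}, fixed_estimates={},
            loglik_restricted=0.0, aic=0.0, se=None, converged=True,
            n_used=10, term_names=("A", "residual"),
            fixed_names=("intercept",), data_hash="x",
        )
        assert heritabilities(fit)["A"] == 0.0

    def test_zero_total_variance_rejected(self):
        fit = FitResult(
            estimates={"residual": 0.0}, fixed_estimates={},
            loglik_restricted=0.0, aic=0.0, se=None, converged=True,
            n_used=10, term_names=("residual",),
            fixed_names=("intercept",), data_hash="x",
        )
        with pytest.raises(ValueError):
            heritabilities(fit)

    def test_scale_equivariance(self):
        """Rescaling y by c scales variances by c^2 but not the ratios."""
        ph, A, _ = small_dataset(seed=11, n=120, s2A=0.6, s2R=0.4)
        res1 = fit_animal_model(ph, random_effects={"A": A},
                                compute_se=False, random_state=3)
        ph2 = ph.copy()
        ph2["y"] = ph2["y"] * 3.0
        res2 = fit_animal_model(ph2, random_effects={"A": A},
                                compute_se=False, random_state=3)
        h1, h2 = heritabilities(res1), heritabilities(res2)
        assert h2["A"] == pytest.approx(h1["A"], abs=1e-3)
        assert res2.estimates["A"] == pytest.approx(
            9.0 * res1.estimates["A"], rel=0.01)


def _mk_fit(loglik, terms, aic=None, data_hash="h", fixed=("intercept",)):
    estimates = {t: 0.1 for t in terms}
    return FitResult(
        estimates=estimates, fixed_estimates={},
        loglik_restricted=loglik,
        aic=aic if aic is not None else -2 * loglik + 2 * len(terms),
        se=None, converged=True, n_used=50, term_names=tuple(terms),
        fixed_names=fixed, data_hash=data_hash,
    )


class TestLRT:
    def test_zero_statistic_gives_half(self):
        full = _mk_fit(-10.0, ("A", "C", "residual"))
        red = _mk_fit(-10.0, ("A", "residual"))
        rep = lrt_component(full, red)
        assert rep.statistic == 0.0
        assert rep.p_corrected == 0.5
        assert rep.dropped_term == "C"

    def test_mixture_tail_at_2706(self):
        # half the chi-square(1) upper tail at 2.706 is 0.05
        full = _mk_fit(-10.0 + 2.706 / 2, ("A", "C", "residual"))
        red = _mk_fit(-10.0, ("A", "residual"))
        rep = lrt_component(full, red)
        assert rep.p_corrected == pytest.approx(0.05, abs=5e-4)
        assert rep.p_naive == pytest.approx(
            stats.chi2.sf(2.706, 1), abs=1e-12)

    def test_negative_statistic_floored(self):
        full = _mk_fit(-11.0, ("A", "C", "residual"))
        red = _mk_fit(-10.0, ("A", "residual"))
        assert lrt_component(full, red).statistic == 0.0

    def test_non_nested_rejected(self):
        full = _mk_fit(-10.0, ("A", "C", "residual"))
        other = _mk_fit(-10.0, ("B", "residual"))
        with pytest.raises(ValueError):
            lrt_component(full, other)
        with pytest.raises(ValueError):
            lrt_component(full, _mk_fit(-10.0, ("A", "C", "residual")))

    def test_different_data_rejected(self):
        full = _mk_fit(-10.0, ("A", "C", "residual"), data_hash="a")
        red = _mk_fit(-10.0, ("A", "residual"), data_hash="b")
        with pytest.raises(ValueError, match="data"):
            lrt_component(full, red)


class TestCompareModels:
    def test_single_fit(self):
        t = compare_models({"m": _mk_fit(-5.0, ("residual",))})
        assert t["delta_aic"].iloc[0] == 0.0

    def test_extra_parameter_penalty(self):
        t = compare_models({
            "small": _mk_fit(-5.0, ("residual",)),
            "big": _mk_fit(-5.0, ("A", "residual")),
        })
        assert t.set_index("model")["delta_aic"]["big"] == pytest.approx(2.0)
        assert t["model"].iloc[0] == "small"

    def test_mismatched_data_refused(self):
        with pytest.raises(ValueError):
            compare_models({
                "a": _mk_fit(-5.0, ("residual",), data_hash="1"),
                "b": _mk_fit(-5.0, ("residual",), data_hash="2"),
            })

    def test_mismatched_fixed_effects_refused(self):
        with pytest.raises(ValueError, match="fixed"):
            compare_models({
                "a": _mk_fit(-5.0, ("residual",)),
                "b": _mk_fit(-5.0, ("residual",),
                             fixed=("intercept", "environment")),
            })


class TestGxCInteraction:
    def test_identity_culture_extracts_diagonal(self, trio):
        A = additive_matrix(trio)
        I = identity_matrix(A.ids)
        M = gxc_interaction_matrix(A, I)
        assert np.array_equal(M.values, np.diag(np.diag(A.values)))

    def test_all_ones_culture_returns_A(self, trio):
        A = additive_matrix(trio)
        ones = RelationshipMatrix(A.ids, np.ones((3, 3)))
        assert np.array_equal(gxc_interaction_matrix(A, ones).values,
                              A.values)

    def test_product_of_psd_is_psd(self):
        rng = np.random.default_rng(2)
        ids = tuple(f"i{k}" for k in range(12))
        P = RelationshipMatrix(ids, random_psd(rng, 12))
        Q = RelationshipMatrix(ids, random_psd(rng, 12))
        assert gxc_interaction_matrix(P, Q).is_psd()

    def test_dimension_mismatch(self, trio):
        A = additive_matrix(trio)
        with pytest.raises(ValueError):
            gxc_interaction_matrix(A, identity_matrix(("a", "b")))
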