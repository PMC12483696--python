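import dataclasses

import numpy as np
import pytest
from numpy.testing import assert_allclose

from polycdm.attribute_space import AttributeSpec, QMatrix
from polycdm.estimation import (
    ExpectedCounts,
    FitOptions,
    FitResult,
    ModelConfig,
    classify,
    e_step,
    eap_marginals,
    fit_em,
    fit_statistics,
    m_step_reduced,
    m_step_saturated,
    marginal_loglik,
    standard_errors,
    update_structural,
)
from polycdm.model_irf import build_item_model
from polycdm.simulation import (
    SimulationDesign,
    generate_attributes,
    generate_responses,
)


def assert_em_ascent(fit, rtol=1e-8):
    trace = np.asarray(fit.trace)
    drops = np.diff(trace) < -rtol * np.abs(trace[:-1])
    assert not drops.any(), f"log-likelihood decreased at iterations {np.where(drops)[0]}"


def _spec2_models(p_vectors):
    spec = AttributeSpec((2,))
    return spec, [
        build_item_model("saturated", "identity", [1], spec, delta=[p[0], p[1] - p[0]])
        for p in p_vectors
    ]


class TestMarginalLoglik:
    def test_coin_flip_items(self):
        spec, models = _spec2_models([(0.5, 0.5)])
        X = np.array([[0], [1], [1]])
        ll = marginal_loglik(X, models, np.array([0.5, 0.5]))
        assert_allclose(ll, 3 * np.log(0.5))

    def test_deterministic_item_halves_the_mass(self):
        spec, models = _spec2_models([(1.0, 0.0)])
        ll = marginal_loglik(np.array([[1]]), models, np.array([0.5, 0.5]))
        assert_allclose(ll, np.log(0.5), atol=1e-9)

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(5)
        spec, models = _spec2_models([(0.2, 0.7), (0.4, 0.9), (0.1, 0.6)])
        pi = np.array([0.3, 0.7])
        X = rng.integers(0, 2, size=(20, 3))
        P = np.array([m.group_probabilities() for m in models]).T  # class x item
        direct = 0.0
        for x in X:
            lik = sum(
                pi[c] * np.prod(P[c] ** x * (1 - P[c]) ** (1 - x)) for c in range(2)
            )
            direct += np.log(lik)
        assert_allclose(marginal_loglik(X, models, pi), direct, atol=1e-12)


class TestESten:
    def test_uniform_inputs_give_uniform_posterior(self):
        spec, models = _spec2_models([(0.5, 0.5)])
        X = np.array([[1], [0]])
        post, counts, _ = e_step(X, models, np.array([0.5, 0.5]))
        assert_allclose(post, 0.5)

    def test_group_counts_conserve_sample_size(self):
        rng = np.random.default_rng(0)
        spec, models = _spec2_models([(0.2, 0.8), (0.3, 0.9)])
        X = rng.integers(0, 2, size=(50, 2))
        _, counts, _ = e_step(X, models, np.array([0.4, 0.6]))
        for c in counts:
            assert_allclose(c.N.sum(), 50)
            assert (c.R <= c.N + 1e-12).all()

    def test_deterministic_item_concentrates_posterior(self):
        spec, models = _spec2_models([(1.0, 0.0)])
        post, _, _ = e_step(np.array([[1], [0]]), models, np.array([0.5, 0.5]))
        assert post[0, 0] > 0.999  # responded 1 -> class 0 (P=1)
        assert post[1, 1] > 0.999


class TestMSteps:
    def test_saturated_update_is_count_ratio(self):
        counts = ExpectedCounts(N=np.array([10.0, 20.0]), R=np.array([1.0, 18.0]))
        p = m_step_saturated(counts, np.array([0.5, 0.5]))
        assert_allclose(p, [0.1, 0.9])

    def test_empty_group_keeps_previous_value(self):
        counts = ExpectedCounts(N=np.array([10.0, 0.0]), R=np.array([4.0, 0.0]))
        p = m_step_saturated(counts, np.array([0.5, 0.77]))
        assert_allclose(p, [0.4, 0.77])

    def test_boundary_ratio_allowed(self):
        counts = ExpectedCounts(N=np.array([5.0, 5.0]), R=np.array([0.0, 5.0]))
        assert_allclose(m_step_saturated(counts, np.array([0.5, 0.5])), [0.0, 1.0])

    def test_monotone_projection_pools_violating_groups(self):
        spec = AttributeSpec((3,))
        model = build_item_model("saturated", "identity", [1], spec)
        counts = ExpectedCounts(
            N=np.array([100.0, 100.0, 100.0]), R=np.array([20.0, 60.0, 40.0])
        )
        p = m_step_saturated(counts, np.full(3, 0.5), model.partition, monotone=True)
        # weighted PAVA pools the inverted pair (0.6, 0.4) to its mean
        assert_allclose(p, [0.2, 0.5, 0.5])

    def test_reduced_conjunctive_matches_two_group_mle(self):
        spec = AttributeSpec((2, 2))
        model = build_item_model("conjunctive", "identity", [1, 1], spec)
        counts = ExpectedCounts(
            N=np.array([10.0, 20.0, 30.0, 40.0]),
            R=np.array([2.0, 5.0, 6.0, 35.0]),
        )
        delta = m_step_reduced(counts, model, np.array([0.2, 0.5]))
        g = (2 + 5 + 6) / (10 + 20 + 30)
        assert_allclose(delta, [g, 35 / 40 - g], atol=1e-5)

    def test_reduced_saturated_design_reproduces_ratio(self):
        spec = AttributeSpec((2,))
        model = build_item_model("saturated", "identity", [1], spec)
        counts = ExpectedCounts(N=np.array([50.0, 50.0]), R=np.array([10.0, 45.0]))
        delta = m_step_reduced(counts, model, np.array([0.3, 0.3]))
        p = model.design @ delta
        assert_allclose(p, [0.2, 0.9], atol=1e-5)

    def test_update_structural_is_posterior_mean(self):
        post = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        assert_allclose(update_structural(post), [0.75, 0.25])


class TestFitEM:
    def test_uninformative_items_recover_item_means(self):
        # constant success probability: the saturated group estimates should
        # collapse to the observed item means
        spec = AttributeSpec((2,))
        Q = QMatrix(np.array([[1], [1], [1]]), spec)
        models = [
            build_item_model("conjunctive", "identity", [1], spec, delta=[0.55, 0.0])
            for _ in range(3)
        ]
        patterns = generate_attributes(2000, spec, seed=0)
        X = generate_responses(patterns, models, spec, seed=1)
        fit = fit_em(X, Q, ModelConfig(), FitOptions(seed=2))
        assert_em_ascent(fit)
        for j in range(3):
            assert np.all(np.abs(fit.group_probs[j] - X[:, j].mean()) < 0.08)

    def test_em_attains_grid_search_optimum(self):
        # two items, one dichotomous attribute, uniform structure: brute
        # force the 4-parameter likelihood on a 0.05 grid and require EM to
        # do at least as well, landing within grid resolution
        spec = AttributeSpec((2,))
        Q = QMatrix(np.array([[1], [1]]), spec)
        truth = [(0.25, 0.8), (0.3, 0.75)]
        models = [
            build_item_model("saturated", "identity", [1], spec, delta=[a, b - a])
            for a, b in truth
        ]
        patterns = generate_attributes(200, spec, seed=10)
        X = generate_responses(patterns, models, spec, seed=11)

        counts = np.zeros((2, 2))
        for x1, x2 in X:
            counts[x1, x2] += 1
        grid = np.arange(0.05, 0.951, 0.05)
        p10, p11, p20, p21 = np.meshgrid(grid, grid, grid, grid, indexing="ij")
        feasible = (p10 <= p11) & (p20 <= p21)  # monotone, as in estimation
        ll = np.zeros_like(p10)
        for x1 in (0, 1):
            for x2 in (0, 1):
                lik = 0.5 * (
                    p10**x1 * (1 - p10) ** (1 - x1) * p20**x2 * (1 - p20) ** (1 - x2)
                ) + 0.5 * (
                    p11**x1 * (1 - p11) ** (1 - x1) * p21**x2 * (1 - p21) ** (1 - x2)
                )
                ll += counts[x1, x2] * np.log(lik)
        ll[~feasible] = -np.inf
        best = np.unravel_index(np.argmax(ll), ll.shape)
        best_params = np.array([grid[i] for i in best])

        fit = fit_em(
            X, Q, ModelConfig(), FitOptions(seed=3, fix_pi_uniform=True, tol=1e-6)
        )
        assert_em_ascent(fit)
        assert fit.loglik >= ll[best] - 1e-6
        fitted = np.concatenate(fit.group_probs)
        assert np.all(np.abs(fitted - best_params) <= 0.05 + 1e-9)

    def test_refit_from_solution_is_fixed_point(self, small_dataset, small_fit):
        _, Q, _, _, X = small_dataset
        refit = fit_em(
            X, Q, ModelConfig(), FitOptions(seed=9),
            init_probs=small_fit.group_probs, init_pi=small_fit.pi,
        )
        assert refit.n_iter <= 3
        assert_allclose(refit.loglik, small_fit.loglik, rtol=1e-6)

    def test_em_ascent_across_model_kinds_and_links(self, small_dataset):
        _, Q, _, _, X = small_dataset
        for cfg in [
            ModelConfig("saturated", "identity"),
            ModelConfig("fam", "identity"),
            ModelConfig("pgdina", "identity"),
            ModelConfig("conjunctive", "identity"),
            ModelConfig("fam", "logit"),
        ]:
            fit = fit_em(X, Q, cfg, FitOptions(seed=4, max_iter=300))
            assert_em_ascent(fit)
            assert np.all(np.isfinite(fit.pi))
            assert_allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_saturated_deviance_never_exceeds_reduced(self, small_dataset):
        _, Q, _, _, X = small_dataset
        devs = {}
        for kind in ["saturated", "fam", "pgdina", "conjunctive", "disjunctive"]:
            fit = fit_em(X, Q, ModelConfig(kind=kind), FitOptions(seed=5))
            devs[kind] = fit_statistics(fit).deviance
        for kind in ["fam", "pgdina", "conjunctive", "disjunctive"]:
            assert devs["saturated"] <= devs[kind] + 1e-6

    def test_recovery_improves_with_sample_size(self):
        from polycdm.evaluation import bias_rmse

        rmses = {}
        for N in (500, 2000):
            design = SimulationDesign(
                K=2, levels=(3, 3), J=8, N=N, quality="high",
                replications=3, seed=21,
            )
            Q = QMatrix(
                np.array([[1, 0], [2, 0], [0, 1], [0, 2],
                          [1, 1], [2, 2], [1, 2], [2, 1]]),
                design.spec,
            )
            true_models = design.true_item_models(Q)
            truth = [m.group_probabilities() for m in true_models]
            ests = []
            for r in range(3):
                patterns, X = design.replicate(r, Q, true_models)
                fit = fit_em(X, Q, ModelConfig(), FitOptions(seed=r))
                ests.append(fit.group_probs)
            rmses[N] = bias_rmse(ests, truth).mean_rmse
        assert rmses[2000] < rmses[500]

    def test_rejects_nonbinary_responses(self, small_dataset):
        _, Q, _, _, X = small_dataset
        bad = X.copy()
        bad[0, 0] = 2
        with pytest.raises(ValueError):
            fit_em(bad, Q)


def _degenerate_fit(probs, post, spec, q_rows):
    """FitResult with a known posterior, for closed-form SE checks."""
    Q = QMatrix(np.array(q_rows), spec)
    models = []
    for j, q in enumerate(q_rows):
        m = build_item_model("saturated", "identity", q, spec)
        models.append(m)
    return FitResult(
        spec=spec, qmatrix=Q, item_models=models,
        group_probs=[np.asarray(p, dtype=float) for p in probs],
        pi=np.full(spec.n_classes, 1 / spec.n_classes),
        posterior=post, loglik=0.0, trace=[0.0], converged=True, n_iter=1,
        options=FitOptions(),
    )


class TestStandardErrors:
    def test_known_class_intercept_matches_binomial(self):
        rng = np.random.default_rng(8)
        spec = AttributeSpec((2,))
        N = 2000
        classes = rng.integers(0, 2, N)
        p = np.array([0.3, 0.7])
        X = (rng.random(N) < p[classes]).astype(int)[:, None]
        post = np.eye(2)[classes]
        fit = _degenerate_fit([p], post, spec, [[1]])
        se, avail = standard_errors(fit, X)
        n0 = (classes == 0).sum()
        assert avail[0].all()
        assert_allclose(se[0][0], np.sqrt(0.3 * 0.7 / n0), rtol=0.1)

    def test_duplicated_data_shrinks_se_by_sqrt2(self, small_dataset, small_fit):
        _, Q, _, _, X = small_dataset
        se1, _ = standard_errors(small_fit, X)
        doubled = dataclasses.replace(
            small_fit, posterior=np.vstack([small_fit.posterior] * 2)
        )
        se2, _ = standard_errors(doubled, np.vstack([X] * 2))
        for a, b in zip(se1, se2):
            ratio = b[np.isfinite(a)] / a[np.isfinite(a)]
            assert_allclose(ratio, 1 / np.sqrt(2), rtol=1e-6)

    def test_empty_group_parameter_flagged_unavailable(self):
        rng = np.random.default_rng(3)
        spec = AttributeSpec((3,))
        N = 300
        classes = rng.integers(0, 2, N)  # level 2 never observed
        p = np.array([0.3, 0.7, 0.8])
        X = (rng.random(N) < p[classes]).astype(int)[:, None]
        post = np.zeros((N, 3))
        post[np.arange(N), classes] = 1.0
        fit = _degenerate_fit([p], post, spec, [[1]])
        se, avail = standard_errors(fit, X)
        assert avail[0][:2].all()
        assert not avail[0][2]
        assert np.isnan(se[0][2])


class TestClassification:
    def _posterior_only_fit(self, spec, posterior):
        Q = QMatrix(np.array([[1] + [0] * (spec.n_attributes - 1)]), spec)
        m = build_item_model("saturated", "identity", Q.entries[0], spec)
        return FitResult(
            spec=spec, qmatrix=Q, item_models=[m],
            group_probs=[np.linspace(0.2, 0.8, m.partition.n_groups)],
            pi=np.full(spec.n_classes, 1 / spec.n_classes),
            posterior=np.asarray(posterior, dtype=float),
            loglik=0.0, trace=[0.0], converged=True, n_iter=1,
            options=FitOptions(),
        )

    def test_map_takes_argmax_class(self):
        spec = AttributeSpec((3,))
        fit = self._posterior_only_fit(spec, [[0.1, 0.3, 0.6]])
        assert classify(fit, "MAP").tolist() == [[2]]

    def test_map_tie_goes_to_lowest_pattern_index(self):
        spec = AttributeSpec((2,))
        fit = self._posterior_only_fit(spec, [[0.5, 0.5]])
        assert classify(fit, "MAP").tolist() == [[0]]

    def test_eap_marginals_normalize_and_argmax(self):
        spec = AttributeSpec((2, 2))
        post = [[0.05, 0.15, 0.35, 0.45]]
        fit = self._posterior_only_fit(spec, post)
        margs = eap_marginals(fit)
        for m in margs:
            assert_allclose(m.sum(axis=1), 1.0)
        assert_allclose(margs[0], [[0.2, 0.8]])
        assert classify(fit, "EAP").tolist() == [[1, 1]]


class TestFitStatistics:
    def test_information_criteria_identities(self, small_fit):
        stats = fit_statistics(small_fit)
        assert_allclose(stats.deviance, -2 * small_fit.loglik)
        assert_allclose(stats.aic - stats.deviance, 2 * stats.n_parameters)
        assert_allclose(
            stats.bic - stats.deviance,
            stats.n_parameters * np.log(small_fit.n_examinees),
        )
        # two 3-level attributes: 9 classes, 8 free structural proportions
        assert stats.n_structural_parameters == 8
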