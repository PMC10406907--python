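import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cwboost.base_learners import RidgeBaseLearner, fit_base_learner
from cwboost.data_model import build_design
from cwboost.engine import (
    BoostConfig,
    KStep,
    KStepConfig,
    boost,
    cv_mstop,
    init_offset,
    kstep_boost,
    negative_gradient,
    predict,
    risk,
)
from cwboost.models import make_mb

from .conftest import random_binary_design


def mb_learners(design):
    return make_mb(design).learners


def brute_force_path(design, y, learners, eta, M, family="binomial"):
    """Independent re-implementation: refit every learner at every step.

    Uses the same documented tie rule as the engine: the first learner
    whose SSE lies within 1e-9 (relative to ||u||^2) of the minimum wins.
    """
    X = design.values
    f = np.full(len(y), init_offset(y, family))
    path = []
    for _ in range(M):
        u = negative_gradient(y, f, family)
        fits = [
            (l, fit_base_learner(l, X[:, list(l.cols)], u))
            for l in learners
            if not l.excluded
        ]
        tol = 1e-9 * float(u @ u)
        best_sse = min(fit.sse for _, fit in fits)
        l, fit = next((l, fit) for l, fit in fits if fit.sse <= best_sse + tol)
        f = f + eta * fit.fitted
        path.append(l.term_id)
    return path, f


class TestNegativeGradient:
    def test_known_values(self):
        assert negative_gradient(np.array([1.0]), np.array([0.0]))[0] == pytest.approx(0.5)
        assert negative_gradient(np.array([0.0]), np.array([40.0]))[0] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_numerical_differentiation(self, rng):
        y = rng.integers(0, 2, size=50).astype(float)
        f = rng.normal(scale=1.5, size=50)
        grad = negative_gradient(y, f)
        eps = 1e-6
        for i in range(50):
            fp, fm = f.copy(), f.copy()
            fp[i] += eps
            fm[i] -= eps
            numeric = -(risk(y, fp) - risk(y, fm)) / (2 * eps)
            assert grad[i] == pytest.approx(numeric, abs=1e-6)


class TestInitOffset:
    def test_balanced_outcome_gives_zero(self):
        y = np.array([0, 1, 0, 1], dtype=float)
        assert init_offset(y) == pytest.approx(0.0)

    def test_survey_prevalence(self):
        y = np.concatenate([np.ones(358), np.zeros(443)])
        assert init_offset(y) == pytest.approx(np.log(358 / 443))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            init_offset(np.ones(10))

    def test_minimizes_risk_over_constant_grid(self, rng):
        y = rng.integers(0, 2, size=80).astype(float)
        off = init_offset(y)
        best = min(
            risk(y, np.full(80, c)) for c in np.linspace(-4, 4, 1000)
        )
        assert risk(y, np.full(80, off)) <= best + 1e-9


class TestBoost:
    def test_zero_iterations_is_offset_only(self, small_design, rng):
        y = rng.integers(0, 2, size=small_design.n).astype(float)
        cfg = BoostConfig(learners=mb_learners(small_design), m_stop=0)
        fit = boost(small_design, y, cfg)
        assert fit.selection_path == []
        np.testing.assert_allclose(fit.fitted, init_offset(y))
        probs = predict(fit, small_design.values)
        np.testing.assert_allclose(probs, y.mean(), atol=1e-12)

    def test_gaussian_single_learner_one_step_is_ols(self, rng):
        # lam=0, eta=1, one step: the update IS the least-squares fit
        x = rng.standard_normal(40)
        x -= x.mean()
        y = 1.5 * x + rng.standard_normal(40)

        class D:
            values = x.reshape(-1, 1)

        gram = np.array([[x @ x]])
        learner = RidgeBaseLearner(
            term_id="x", cols=(0,), target_df=1.0, lam=0.0,
            spectrum=np.array([x @ x]), basis=np.array([[1.0]]),
        )
        cfg = BoostConfig(learners=[learner], eta=0.999999999, m_stop=1,
                          family="gaussian")
        fit = boost(D(), y, cfg)
        slope = float(x @ (y - y.mean()) / (x @ x))
        assert fit.aggregated[0] == pytest.approx(slope, rel=1e-8)
        np.testing.assert_allclose(
            fit.fitted, y.mean() + x * slope, atol=1e-6
        )

    def test_selection_path_matches_brute_force(self, rng):
        tab, specs = random_binary_design(rng, n=60, p=8, n_cat=2)
        design = build_design(tab, specs)
        y = rng.integers(0, 2, size=60).astype(float)
        cfg = BoostConfig(learners=mb_learners(design), eta=0.1, m_stop=25)
        fit = boost(design, y, cfg)
        expected_path, expected_f = brute_force_path(
            design, y, cfg.learners, 0.1, 25
        )
        assert fit.selection_path == expected_path
        np.testing.assert_allclose(fit.fitted, expected_f, atol=1e-10)

    def test_reconstruction_identity(self, small_design, rng):
        y = rng.integers(0, 2, size=small_design.n).astype(float)
        cfg = BoostConfig(learners=mb_learners(small_design), m_stop=30)
        fit = boost(small_design, y, cfg)
        np.testing.assert_allclose(
            fit.fitted,
            fit.offset + small_design.values @ fit.aggregated,
            atol=1e-10,
        )

    def test_all_learners_excluded_warns(self, small_design, rng):
        y = rng.integers(0, 2, size=small_design.n).astype(float)
        learners = [
            RidgeBaseLearner.from_block(small_design, b, target_df=0.0)
            for b in small_design.blocks
        ]
        cfg = BoostConfig(learners=learners, m_stop=5)
        with pytest.warns(UserWarning, match="excluded"):
            fit = boost(small_design, y, cfg)
        assert fit.selection_path == []

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_risk_path_non_increasing(self, seed):
        """In-sample risk never increases along the path at eta = 0.1."""
        rng = np.random.default_rng(seed)
        tab, specs = random_binary_design(rng, n=50, p=6)
        design = build_design(tab, specs)
        y = rng.integers(0, 2, size=50).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        cfg = BoostConfig(learners=mb_learners(design), eta=0.1, m_stop=40)
        fit = boost(design, y, cfg)
        assert np.all(np.diff(fit.risk_path) <= 1e-10)


class TestCvMstop:
    def test_chosen_mstop_is_argmin_of_curve(self, rng):
        tab, specs = random_binary_design(rng, n=80, p=6)
        design = build_design(tab, specs)
        y = rng.integers(0, 2, size=80).astype(float)
        cfg = BoostConfig(learners=mb_learners(design), cv_max=40, seed=11)
        cv = cv_mstop(design, y, cfg, folds=5)
        assert cv.mstop == int(np.argmin(cv.risk))

    def test_noise_outcome_stops_early(self):
        """Pure-noise outcomes: CV picks a small mstop (median over seeds)."""
        chosen = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            tab, specs = random_binary_design(rng, n=200, p=10)
            design = build_design(tab, specs)
            y = rng.integers(0, 2, size=200).astype(float)
            cfg = BoostConfig(learners=mb_learners(design), cv_max=100, seed=seed)
            chosen.append(cv_mstop(design, y, cfg).mstop)
        assert np.median(chosen) <= 5  # 5% of cv_max

    def test_strong_signal_beats_offset(self, rng):
        tab, specs = random_binary_design(rng, n=150, p=5)
        design = build_design(tab, specs)
        logits = 2.5 * design.values[:, 0]
        y = (rng.random(150) < 1 / (1 + np.exp(-logits))).astype(float)
        cfg = BoostConfig(learners=mb_learners(design), cv_max=80, seed=3)
        cv = cv_mstop(design, y, cfg)
        assert cv.risk[cv.mstop] <= cv.risk[0]
        assert cv.mstop > 0


class TestKStep:
    def _setup(self, rng, n=60):
        tab, specs = random_binary_design(rng, n=n, p=6)
        design = build_design(tab, specs)
        y = rng.integers(0, 2, size=n).astype(float)
        return design, y

    def test_single_step_identical_to_boost(self, rng):
        design, y = self._setup(rng)
        learners = mb_learners(design)
        plain = boost(design, y, BoostConfig(learners=learners, m_stop=20))
        kfit = kstep_boost(
            design, y, KStepConfig(steps=[KStep(tuple(learners), 20)])
        )
        assert len(kfit) == 1
        assert kfit[0].selection_path == plain.selection_path
        assert np.array_equal(kfit[0].fitted, plain.fitted)
        assert np.array_equal(kfit[0].aggregated, plain.aggregated)

    def test_second_step_zero_iterations_changes_nothing(self, rng):
        design, y = self._setup(rng)
        learners = mb_learners(design)
        plain = boost(design, y, BoostConfig(learners=learners, m_stop=15))
        fits = kstep_boost(
            design, y,
            KStepConfig(steps=[KStep(tuple(learners), 15), KStep(tuple(learners), 0)]),
        )
        np.testing.assert_array_equal(
            predict(fits, design.values), predict(plain, design.values)
        )
        assert fits[1].selection_path == []

    def test_path_continuation_equals_single_run(self, rng):
        """Gaussian mode: K=2 with the same learners and M1+M2=M equals one run of M."""
        design, y0 = self._setup(rng)
        y = design.values @ rng.normal(size=design.p) + rng.normal(size=design.n)
        learners = mb_learners(design)
        single = boost(
            design, y, BoostConfig(learners=learners, m_stop=24, family="gaussian")
        )
        fits = kstep_boost(
            design, y,
            KStepConfig(
                steps=[KStep(tuple(learners), 10), KStep(tuple(learners), 14)],
                family="gaussian",
            ),
        )
        combined_path = fits[0].selection_path + fits[1].selection_path
        assert combined_path == single.selection_path
        np.testing.assert_allclose(fits[1].fitted, single.fitted, atol=1e-10)


class TestPredict:
    def test_response_bounded(self, small_design, rng):
        y = rng.integers(0, 2, size=small_design.n).astype(float)
        cfg = BoostConfig(learners=mb_learners(small_design), m_stop=50)
        fit = boost(small_design, y, cfg)
        probs = predict(fit, small_design.values)
        assert np.all((probs > 0) & (probs < 1))

    def test_link_scale_on_training_rows_equals_fitted(self, small_design, rng):
        y = rng.integers(0, 2, size=small_design.n).astype(float)
        cfg = BoostConfig(learners=mb_learners(small_design), m_stop=30)
        fit = boost(small_design, y, cfg)
        np.testing.assert_allclose(
            predict(fit, small_design.values, scale="link"), fit.fitted, atol=1e-10
        )

    def test_column_mismatch_rejected(self, small_design, rng):
        y = rng.integers(0, 2, size=small_design.n).astype(float)
        fit = boost(small_design, y, BoostConfig(learners=mb_learners(small_design), m_stop=5))
        with pytest.raises(ValueError, match="design columns"):
            predict(fit, np.zeros((3, small_design.p + 1)))
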