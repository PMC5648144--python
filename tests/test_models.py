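import warnings

import numpy as np
import pytest

from enmfactorial.models import (
    GAMClassifier,
    MaxentLQ,
    SVMClassifier,
    TunedRandomForest,
    predict_raster,
    select_threshold,
)
from enmfactorial.evaluation import auc
from enmfactorial.raster import GridStack, extract_values
from conftest import make_layer


def informative_data(n=80, p=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n, p))
    logit = 2.5 * X[:, 0]
    pr = 1 / (1 + np.exp(-logit))
    y = (rng.random(2 * n) < pr).astype(int)
    # guarantee both classes
    y[0], y[1] = 0, 1
    return X, y


def fit_quiet(model, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(X, y)


class TestGAM:
    def test_null_training_auc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((300, 2))
            y = np.r_[np.ones(150, int), np.zeros(150, int)]
            rng.shuffle(y)
            m = fit_quiet(GAMClassifier(), X, y)
            aucs.append(auc(y, m.predict_proba(X)[:, 1]))
        # permuted labels: mean training AUC stays near chance (smoothing
        # penalties keep the fit from memorizing noise)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_separable_case_perfect_training_auc(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.standard_normal(60))
        X = np.column_stack([x, rng.standard_normal(60)])
        y = (x > np.median(x)).astype(int)
        m = fit_quiet(GAMClassifier(), X, y)
        assert auc(y, m.predict_proba(X)[:, 1]) == 1.0

    def test_probabilities_in_unit_interval(self):
        X, y = informative_data(seed=2)
        m = fit_quiet(GAMClassifier(), X, y)
        grid = np.random.default_rng(0).standard_normal((500, 3)) * 3
        p = m.predict_proba(grid)[:, 1]
        assert (p >= 0).all() and (p <= 1).all()

    def test_learns_monotone_signal(self):
        X, y = informative_data(seed=3)
        m = fit_quiet(GAMClassifier(), X, y)
        assert auc(y, m.predict_proba(X)[:, 1]) > 0.8


class TestMaxentLQ:
    def test_zero_iterations_uniform_model(self):
        X, y = informative_data(seed=4)
        m = MaxentLQ(max_iter=0).fit(X, y)
        n_bg = m.n_background_
        assert m.entropy_ == pytest.approx(np.log(n_bg))
        q = m.raw_density(X)
        np.testing.assert_allclose(q, 1.0 / n_bg, rtol=1e-12)
        np.testing.assert_allclose(m.predict_proba(X)[:, 1], 0.5, atol=1e-12)

    def test_moment_constraint_matches_bisection(self):
        # one binary feature; presences mean 0.8, raw background mean 0.5.
        # With beta = 0 the fitted Gibbs density must satisfy E_q[f] = 0.8
        # over the model background (raw background plus presences).
        bg = np.r_[np.zeros(50), np.ones(50)][:, None]
        pres = np.r_[np.zeros(4), np.ones(16)][:, None]
        X = np.vstack([pres, bg])
        y = np.r_[np.ones(20, int), np.zeros(100, int)]
        m = fit_quiet(MaxentLQ(beta_multiplier=0.0), X, y)
        # linear and quadratic features coincide on {0,1}; the moment
        # constraint depends on their sum
        lam_tot = m.lambda_.sum()
        n1 = 50 + 16  # background cells with feature 1
        n0 = 50 + 4

        def eq_moment(l):
            w1 = n1 * np.exp(l)
            return w1 / (w1 + n0)

        # independent 1-D bisection for E_q[f] = 0.8
        lo, hi = -10.0, 10.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if eq_moment(mid) < 0.8:
                lo = mid
            else:
                hi = mid
        assert lam_tot == pytest.approx((lo + hi) / 2, abs=1e-3)
        assert eq_moment(lam_tot) == pytest.approx(0.8, abs=1e-4)

    def test_objective_nonincreasing(self):
        X, y = informative_data(seed=5)
        m = fit_quiet(MaxentLQ(), X, y)
        trace = np.array(m.objective_trace_)
        # L-BFGS line search may probe uphill points, but accepted iterates
        # never end above the start and the final value is the minimum seen
        assert trace[-1] <= trace[0]
        assert m.objective_ == pytest.approx(trace.min(), abs=1e-9)

    def test_density_normalized_over_background(self):
        X, y = informative_data(seed=6)
        m = fit_quiet(MaxentLQ(), X, y)
        bg = np.vstack([X[y == 0], X[y == 1]])  # background incl presences
        assert m.raw_density(bg).sum() == pytest.approx(1.0)

    def test_heavy_regularization_shrinks_to_uniform(self):
        X, y = informative_data(seed=7)
        m = fit_quiet(MaxentLQ(beta_multiplier=1e6), X, y)
        np.testing.assert_allclose(m.lambda_, 0.0, atol=1e-8)
        np.testing.assert_allclose(m.predict_proba(X)[:, 1], 0.5, atol=1e-6)


class TestTunedRandomForest:
    def test_mtry_within_bounds_and_beats_default(self):
        X, y = informative_data(n=60, p=6, seed=8)
        m = fit_quiet(TunedRandomForest(seed=1), X, y)
        assert 1 <= m.mtry_ <= 6
        default = max(1, int(np.floor(np.sqrt(6))))
        assert m.oob_error_ <= m.oob_errors_[default] + 1e-12

    def test_seeded_determinism(self):
        X, y = informative_data(n=40, seed=9)
        a = fit_quiet(TunedRandomForest(seed=7), X, y).predict_proba(X)
        b = fit_quiet(TunedRandomForest(seed=7), X, y).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((20, 2))
        with pytest.raises(ValueError):
            TunedRandomForest().fit(X, np.ones(20, int))


class TestSVM:
    def test_radially_separable_accuracy(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(-2, 2, (200, 2))
        y = (np.hypot(X[:, 0], X[:, 1]) < 1.2).astype(int)
        m = fit_quiet(SVMClassifier(seed=0), X, y)
        assert (m.predict(X) == y).mean() > 0.95

    def test_null_probabilities_near_half(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((60, 3))
            y = np.r_[np.ones(30, int), np.zeros(30, int)]
            rng.shuffle(y)
            m = fit_quiet(SVMClassifier(seed=seed), X, y)
            means.append(m.predict_proba(X)[:, 1].mean())
        assert abs(np.mean(means) - 0.5) < 0.1

    def test_duplicated_training_set_same_decision_function(self):
        # in the separable regime the margin solution is unchanged when every
        # training point is duplicated (kernel width held fixed: the median
        # pairwise-distance heuristic itself shifts under duplicates)
        rng = np.random.default_rng(11)
        X = np.vstack(
            [rng.normal(3.0, 0.3, (30, 2)), rng.normal(-3.0, 0.3, (30, 2))]
        )
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        m1 = fit_quiet(SVMClassifier(seed=0, gamma=0.5), X, y)
        m2 = fit_quiet(
            SVMClassifier(seed=0, gamma=0.5), np.vstack([X, X]), np.r_[y, y]
        )
        np.testing.assert_allclose(
            m1.decision_function(X), m2.decision_function(X), atol=1e-6
        )

    def test_zero_variance_predictor_dropped(self):
        X, y = informative_data(n=40, seed=12)
        X = np.column_stack([X, np.full(len(X), 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            m = SVMClassifier(seed=0).fit(X, y)
        assert m.predict_proba(X).shape == (len(X), 2)


class TestPredictRaster:
    def _scores(self):
        rng = np.random.default_rng(13)
        vals = rng.standard_normal((12, 12))
        vals[0, 0] = np.nan
        return GridStack(
            [
                make_layer(vals, cell_size=1.0, name="pc1"),
                make_layer(rng.standard_normal((12, 12)), cell_size=1.0,
                           name="pc2"),
            ]
        )

    def test_masked_cells_stay_masked(self):
        scores = self._scores()
        X, y = informative_data(n=40, p=2, seed=14)
        m = fit_quiet(SVMClassifier(seed=0), X, y)
        out = predict_raster(m, scores)
        assert not out.valid[0, 0]
        assert np.isnan(out.values[0, 0])
        vals = out.values[out.valid]
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_raster_equals_point_prediction_at_cell_center(self):
        scores = self._scores()
        X, y = informative_data(n=40, p=2, seed=15)
        m = fit_quiet(SVMClassifier(seed=0), X, y)
        out = predict_raster(m, scores)
        geom = scores.geometry
        lon = geom.origin_x + 5.5 * geom.cell_size
        lat = geom.origin_y - 3.5 * geom.cell_size
        Xc, ok = extract_values(scores, [lon], [lat])
        assert ok[0]
        assert out.values[3, 5] == pytest.approx(m.predict_proba(Xc)[0, 1])


class TestSelectThreshold:
    def test_perfectly_separated(self):
        obs = [0, 0, 1, 1]
        pred = [0.1, 0.2, 0.8, 0.9]
        assert select_threshold(obs, pred) == 0.8

    def test_all_equal_predictions(self):
        obs = [0, 1, 0, 1]
        pred = [0.5, 0.5, 0.5, 0.5]
        t = select_threshold(obs, pred)
        assert t == 0.5  # single candidate; sens + spec = 1 there

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(16)
        for trial in range(10):
            obs = rng.integers(0, 2, 20)
            if obs.min() == obs.max():
                obs[0] = 1 - obs[0]
            pred = np.round(rng.random(20), 2)  # induce ties
            got = select_threshold(obs, pred)
            # brute-force oracle
            best = None
            for t in np.unique(pred):
                sens = ((pred >= t) & (obs == 1)).sum() / (obs == 1).sum()
                spec = ((pred < t) & (obs == 0)).sum() / (obs == 0).sum()
                key = (-(sens + spec), t)
                if best is None or key < best:
                    best = key
            assert got == best[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([1, 1, 1], [0.1, 0.2, 0.3])
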