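"""The four niche-modeling algorithm adapters.

All adapters are scikit-learn style estimators: ``fit(X, y)`` with ``y`` in
{0, 1}, ``predict_proba`` returning class probabilities, ``get_params`` /
``set_params`` for composition with sklearn tooling, and fitted attributes
carrying a trailing underscore.  The factorial runner is therefore
algorithm-agnostic.

* :class:`GAMClassifier` — binomial additive model with one penalized
  B-spline smooth per predictor (statsmodels GLMGam); the shared penalty
  weight is optimized by minimizing the generalized cross-validation score.
* :class:`MaxentLQ` — a native maximum-entropy model with linear and
  quadratic features, L1-regularized with the published default beta
  schedules, logistic output via the entropy transform.  The "absence"
  class passed to ``fit`` is the background sample.
* :class:`TunedRandomForest` — 500-tree classification forest whose
  ``mtry`` (max_features) is tuned by walking step-factor multiples and
  keeping the minimum out-of-bag error.
* :class:`SVMClassifier` — RBF support vector machine, C = 1, kernel width
  from the median pairwise squared-distance heuristic, Platt-scaled
  probabilities.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from statsmodels.gam.api import BSplines, GLMGam
import statsmodels.api as sm

from .raster import GridLayer, GridStack

__all__ = [
    "GAMClassifier",
    "MaxentLQ",
    "TunedRandomForest",
    "SVMClassifier",
    "predict_raster",
    "select_threshold",
    "make_model",
]


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("y must contain both classes 0 and 1")
    return X, y.astype(int)


# ---------------------------------------------------------------------------
# GAM
# ---------------------------------------------------------------------------

class GAMClassifier(BaseEstimator, ClassifierMixin):
    """Binomial GAM: one univariate penalized B-spline smooth per predictor.

    No interactions and no term selection; the single shared penalty weight
    ``alpha`` is chosen by bounded scalar minimization of the GCV criterion
    over ``log10(alpha)`` unless ``alpha`` is given explicitly.

    Parameters
    ----------
    df : int
        Basis dimension per smooth (default 9, ~10-knot splines).
    degree : int
        Spline degree (cubic by default).
    alpha : float or None
        Fixed penalty weight; ``None`` triggers GCV optimization.
    """

    def __init__(self, df: int = 9, degree: int = 3, alpha: float | None = None,
                 alpha_bounds: tuple[float, float] = (-4.0, 7.0)):
        self.df = df
        self.degree = degree
        self.alpha = alpha
        self.alpha_bounds = alpha_bounds

    def _fit_alpha(self, y, smoother, alpha: float):
        gam = GLMGam(y, exog=np.ones((len(y), 1)), smoother=smoother,
                     alpha=[alpha] * smoother.k_variables,
                     family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return gam.fit(maxiter=100)

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        n, p = X.shape
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            raise ValueError("need at least 2 points per class")
        # clip df so the penalized design stays identifiable at small n
        df = int(min(self.df, max(self.degree + 1, n // 2)))
        self._bounds_ = np.column_stack([X.min(axis=0), X.max(axis=0)])
        degenerate = self._bounds_[:, 0] == self._bounds_[:, 1]
        if degenerate.any():
            warnings.warn("dropping zero-variance predictors from GAM")
        self._keep_ = ~degenerate
        Xf = X[:, self._keep_]
        if Xf.shape[1] == 0:
            raise ValueError("all predictors are constant")
        smoother = BSplines(Xf, df=[df] * Xf.shape[1],
                            degree=[self.degree] * Xf.shape[1],
                            include_intercept=False)
        self._smoother_ = smoother

        def gcv(log_alpha: float) -> float:
            try:
                res = self._fit_alpha(y, smoother, 10.0 ** log_alpha)
            except Exception:
                return np.inf
            # GCV = n * deviance / (n - edf)^2
            edf = getattr(res, "edf", None)
            edf_tot = float(np.sum(edf)) if edf is not None else res.df_model + 1
            denom = max(n - edf_tot, 1.0)
            return n * res.deviance / denom**2

        if self.alpha is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                opt = minimize_scalar(
                    gcv, bounds=self.alpha_bounds, method="bounded",
                    options={"xatol": 0.2},
                )
            self.alpha_ = float(10.0 ** opt.x)
        else:
            self.alpha_ = float(self.alpha)
        try:
            self.result_ = self._fit_alpha(y, smoother, self.alpha_)
        except Exception:
            # perfect separation or ill-conditioning: fall back to a heavy
            # penalty rather than crashing
            warnings.warn("GAM fit unstable; refitting with a large penalty")
            self.alpha_ = 1e6
            self.result_ = self._fit_alpha(y, smoother, self.alpha_)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        Xf = X[:, self._keep_]
        # constant extrapolation beyond the training range: B-spline bases
        # are undefined outside their knots
        lo, hi = self._bounds_[self._keep_, 0], self._bounds_[self._keep_, 1]
        Xf = np.clip(Xf, lo, hi)
        exog_smooth = self._smoother_.transform(Xf)
        exog = np.column_stack([np.ones(len(Xf)), exog_smooth])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = self.result_.model.predict(self.result_.params, exog=exog)
        p = np.clip(p, 0.0, 1.0)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# MaxEnt (linear + quadratic features)
# ---------------------------------------------------------------------------

#: Default regularization schedules (sample size -> beta) for the two
#: feature classes, linearly interpolated in presence count and clamped at
#: the schedule ends.
LINEAR_BETA_SCHEDULE = ((10, 1.0), (30, 0.2), (100, 0.05))
QUADRATIC_BETA_SCHEDULE = ((10, 1.3), (17, 0.8), (30, 0.5), (100, 0.05))


def _interp_schedule(schedule, m: int) -> float:
    xs = np.array([s[0] for s in schedule], float)
    ys = np.array([s[1] for s in schedule], float)
    return float(np.interp(m, xs, ys))


class MaxentLQ(BaseEstimator, ClassifierMixin):
    """Maximum-entropy niche model with linear and quadratic features.

    ``fit(X, y)`` treats rows with ``y == 1`` as presences and rows with
    ``y == 0`` as the background sample.  Features are each predictor and
    its square, affinely scaled to [0, 1] over the background.  The Gibbs
    density ``q(x) ∝ exp(λ·f(x))`` over background cells is fitted by
    minimizing the L1-regularized negative mean presence log-likelihood
    (convex; solved by L-BFGS-B on the positive/negative split of λ).

    Logistic output: ``p(x) = e^H q(x) / (1 + e^H q(x))`` with ``H`` the
    entropy of the fitted background distribution, so a featureless model
    (λ = 0) outputs 0.5 everywhere.

    Parameters
    ----------
    beta_multiplier : float
        Scales the default regularization schedule (1 = defaults).
    max_iter : int
        Optimizer iteration cap (default 1000).
    max_background : int
        Background rows beyond this are subsampled (default 10000).
    """

    def __init__(self, beta_multiplier: float = 1.0, max_iter: int = 1000,
                 max_background: int = 10000, seed: int = 0):
        self.beta_multiplier = beta_multiplier
        self.max_iter = max_iter
        self.max_background = max_background
        self.seed = seed

    # -- feature construction ----------------------------------------------
    def _raw_features(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([X, X**2])

    def _scale_features(self, F: np.ndarray) -> np.ndarray:
        span = np.where(self.f_max_ > self.f_min_, self.f_max_ - self.f_min_, 1.0)
        return np.clip((F - self.f_min_) / span, 0.0, 1.0)

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        pres = X[y == 1]
        bg = X[y == 0]
        if len(bg) > self.max_background:
            rng = np.random.default_rng(self.seed)
            bg = bg[rng.choice(len(bg), self.max_background, replace=False)]
        # presences join the background (keeps the likelihood bounded: the
        # presence feature mean then always lies in the background hull)
        bg = np.vstack([bg, pres])
        Fb_raw = self._raw_features(bg)
        self.f_min_ = Fb_raw.min(axis=0)
        self.f_max_ = Fb_raw.max(axis=0)
        Fb = self._scale_features(Fb_raw)
        Fp = self._scale_features(self._raw_features(pres))
        m, d = Fp.shape
        n_pred = X.shape[1]

        beta_lin = _interp_schedule(LINEAR_BETA_SCHEDULE, m)
        beta_quad = _interp_schedule(QUADRATIC_BETA_SCHEDULE, m)
        class_beta = np.concatenate(
            [np.full(n_pred, beta_lin), np.full(n_pred, beta_quad)]
        )
        # per-feature penalty: beta * sqrt(var over presences / m), floored
        s2 = Fp.var(axis=0)
        self.beta_ = (
            self.beta_multiplier * class_beta * np.sqrt(np.maximum(s2, 1e-4) / m)
        )

        mean_fp = Fp.mean(axis=0)
        self._trace_ = []

        def objective(w):
            lam = w[:d] - w[d:]
            eta = Fb @ lam
            logz = logsumexp(eta)
            nll = logz - mean_fp @ lam
            reg = self.beta_ @ (w[:d] + w[d:])
            # gradient: E_q[f] - mean_fp (wrt lam), plus beta on both halves
            q = np.exp(eta - logz)
            eq_f = q @ Fb
            g_lam = eq_f - mean_fp
            grad = np.concatenate([g_lam + self.beta_, -g_lam + self.beta_])
            self._trace_.append(nll + reg)
            return nll + reg, grad

        w0 = np.zeros(2 * d)
        if self.max_iter <= 0:
            self.lambda_ = np.zeros(d)
            self.objective_trace_ = []
        else:
            res = minimize(
                objective, w0, jac=True, method="L-BFGS-B",
                bounds=[(0, None)] * (2 * d),
                options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": 1e-8},
            )
            if not res.success and res.status == 1:  # iteration cap
                warnings.warn(
                    f"MaxEnt optimizer hit the iteration cap "
                    f"(objective {res.fun:.6g})"
                )
            self.lambda_ = res.x[:d] - res.x[d:]
            self.objective_trace_ = list(self._trace_)
        eta_b = Fb @ self.lambda_
        self.logz_ = float(logsumexp(eta_b))
        q = np.exp(eta_b - self.logz_)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.entropy_ = float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
        self.objective_ = float(
            self.logz_ - mean_fp @ self.lambda_ + self.beta_ @ np.abs(self.lambda_)
        )
        self.n_background_ = len(bg)
        self.classes_ = np.array([0, 1])
        return self

    def raw_density(self, X) -> np.ndarray:
        """q(x) = exp(λ·f(x)) / Z — normalized over the background sample."""
        F = self._scale_features(self._raw_features(np.asarray(X, float)))
        return np.exp(F @ self.lambda_ - self.logz_)

    def predict_proba(self, X):
        q = self.raw_density(X)
        eh_q = np.exp(self.entropy_) * q
        p = eh_q / (1.0 + eh_q)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Random forest with OOB-tuned mtry
# ---------------------------------------------------------------------------

class TunedRandomForest(BaseEstimator, ClassifierMixin):
    """Classification forest; mtry tuned by out-of-bag error.

    Starting from the default ``mtry = floor(sqrt(p))``, candidates are
    walked by multiplying/dividing by ``step_factor`` while the relative OOB
    improvement exceeds ``improve``; the candidate with minimum OOB error is
    kept and the final 500-tree forest is refit at that mtry.
    """

    def __init__(self, n_estimators: int = 500, step_factor: float = 2.0,
                 improve: float = 0.05, seed: int = 0):
        self.n_estimators = n_estimators
        self.step_factor = step_factor
        self.improve = improve
        self.seed = seed

    def _fit_forest(self, X, y, mtry: int) -> RandomForestClassifier:
        rf = RandomForestClassifier(
            n_estimators=self.n_estimators, max_features=mtry,
            oob_score=True, random_state=self.seed, bootstrap=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(X, y)
        return rf

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        p = X.shape[1]
        mtry0 = max(1, int(np.floor(np.sqrt(p))))
        # each candidate is a full n_estimators-tree forest; the best one IS
        # the final model (same seed), so no refit is needed
        forests = {mtry0: self._fit_forest(X, y, mtry0)}
        tried = {mtry0: 1.0 - forests[mtry0].oob_score_}
        for direction in (1.0 / self.step_factor, self.step_factor):
            prev_err = tried[mtry0]
            mtry = mtry0
            while True:
                nxt = int(max(1, min(p, round(mtry * direction))))
                if nxt == mtry or nxt in tried:
                    break
                forests[nxt] = self._fit_forest(X, y, nxt)
                err = tried[nxt] = 1.0 - forests[nxt].oob_score_
                if err > prev_err * (1.0 - self.improve):
                    break  # no sufficient improvement; stop walking
                prev_err, mtry = err, nxt
        self.oob_errors_ = dict(sorted(tried.items()))
        self.mtry_ = min(tried, key=lambda k: (tried[k], k))
        self.forest_ = forests[self.mtry_]
        self.oob_error_ = tried[self.mtry_]
        self.classes_ = self.forest_.classes_
        return self

    def predict_proba(self, X):
        return self.forest_.predict_proba(np.asarray(X, float))

    def predict(self, X):
        return self.forest_.predict(np.asarray(X, float))


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

class SVMClassifier(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM, C = 1, Platt-scaled probabilities.

    Kernel width: ``gamma = 1 / median(||x_i - x_j||²)`` over (a capped
    sample of) training pairs — the data-driven analogue of kernlab's
    ``sigest``.  Zero-variance predictors are dropped with a warning.
    """

    def __init__(self, C: float = 1.0, seed: int = 0, max_pairs_sample: int = 500,
                 gamma: float | None = None):
        self.C = C
        self.seed = seed
        self.max_pairs_sample = max_pairs_sample
        self.gamma = gamma

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        keep = X.std(axis=0) > 0
        if not keep.all():
            warnings.warn("dropping zero-variance predictors from SVM")
        if not keep.any():
            raise ValueError("all predictors are constant")
        self._keep_ = keep
        Xf = X[:, keep]
        if self.gamma is not None:
            self.gamma_ = float(self.gamma)
        else:
            rng = np.random.default_rng(self.seed)
            sub = Xf
            if len(Xf) > self.max_pairs_sample:
                sub = Xf[rng.choice(len(Xf), self.max_pairs_sample, replace=False)]
            d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
            med = np.median(d2[np.triu_indices(len(sub), k=1)])
            self.gamma_ = 1.0 / med if med > 0 else 1.0
        self.svc_ = SVC(
            C=self.C, kernel="rbf", gamma=self.gamma_, probability=True,
            random_state=self.seed,
        )
        self.svc_.fit(Xf, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict_proba(self, X):
        X = np.asarray(X, float)
        return self.svc_.predict_proba(X[:, self._keep_])

    def decision_function(self, X):
        X = np.asarray(X, float)
        return self.svc_.decision_function(X[:, self._keep_])

    def predict(self, X):
        X = np.asarray(X, float)
        return self.svc_.predict(X[:, self._keep_])


# ---------------------------------------------------------------------------
# shared utilities
# ---------------------------------------------------------------------------

ALGORITHMS = ("GAM", "MElq", "RF", "SVM")


def make_model(algorithm: str, seed: int = 0):
    """Instantiate one of the four adapters by its label."""
    if algorithm == "GAM":
        return GAMClassifier()
    if algorithm == "MElq":
        return MaxentLQ(seed=seed)
    if algorithm == "RF":
        return TunedRandomForest(seed=seed)
    if algorithm == "SVM":
        return SVMClassifier(seed=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def predict_raster(model, scores: GridStack) -> GridLayer:
    """Project a fitted model onto the whole grid of PC-score layers."""
    mat, idx = scores.to_matrix(where_valid=True)
    p = model.predict_proba(mat)[:, 1]
    geom = scores.geometry
    nr, nc = geom.shape
    values = np.full(nr * nc, np.nan)
    values[idx] = p
    return GridLayer(
        name="suitability",
        values=values.reshape(nr, nc),
        valid=scores.joint_valid,
        origin_x=geom.origin_x,
        origin_y=geom.origin_y,
        cell_size=geom.cell_size,
        crs_label=geom.crs_label,
    )


def select_threshold(obs, pred) -> float:
    """Threshold maximizing sensitivity + specificity (rule: pred >= t).

    Candidates are the unique predicted values; ties resolve to the smallest
    candidate.
    """
    obs = np.asarray(obs).astype(int)
    pred = np.asarray(pred, float)
    if np.unique(obs).size < 2:
        raise ValueError("threshold selection needs both classes observed")
    cands = np.unique(pred)  # sorted ascending
    npos = (obs == 1).sum()
    nneg = (obs == 0).sum()
    # vectorized: for each candidate t, sens = P(pred >= t | obs=1)
    sens = (pred[obs == 1][:, None] >= cands[None, :]).sum(axis=0) / npos
    spec = (pred[obs == 0][:, None] < cands[None, :]).sum(axis=0) / nneg
    score = sens + spec
    best = np.flatnonzero(score == score.max())[0]  # smallest candidate wins ties
    return float(cands[best])
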