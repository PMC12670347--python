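"""Learner library for the stacking ensemble.

Mirrors the classic five-algorithm nuisance library used in applied TMLE
work: a constant-mean predictor, an unpenalized generalized linear model, an
elastic-net-penalized GLM with internal cross-validation for the penalty, a
random forest, and multivariate adaptive regression splines (MARS). The MARS
learner is implemented here (forward hinge-basis selection followed by GCV
backward pruning, additive/degree-1 form).

Each learner exposes ``fit(X, y)`` and ``predict(X)``; for the binomial loss
``predict`` returns event probabilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import ElasticNetCV, LinearRegression, LogisticRegression, \
    LogisticRegressionCV
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = ["make_learner", "LEARNER_NAMES", "MARS"]

LEARNER_NAMES = ("mean", "glm", "glmnet", "rf", "mars")

_CLIP = 1e-6


class MeanLearner:
    """Constant prediction at the training mean (the SL.mean analogue)."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


class GLMLearner:
    def __init__(self, binomial: bool):
        self.binomial = binomial

    def fit(self, X, y):
        if self.binomial:
            # standardization keeps lbfgs fast on raw clinical scales
            self.model_ = make_pipeline(
                StandardScaler(),
                LogisticRegression(C=np.inf, max_iter=1000)).fit(X, y)
        else:
            self.model_ = LinearRegression().fit(X, y)
        return self

    def predict(self, X):
        if self.binomial:
            return self.model_.predict_proba(X)[:, 1]
        return self.model_.predict(X)


class ElasticNetLearner:
    """Penalized GLM with internal CV over the penalty strength (mixing = 1)."""

    def __init__(self, binomial: bool, seed: int = 0):
        self.binomial = binomial
        self.seed = seed

    def fit(self, X, y):
        if self.binomial:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                self.model_ = make_pipeline(
                    StandardScaler(),
                    LogisticRegressionCV(Cs=5, cv=3, penalty="l1", solver="liblinear",
                                         random_state=self.seed, max_iter=500)).fit(X, y)
        else:
            self.model_ = make_pipeline(
                StandardScaler(),
                ElasticNetCV(l1_ratio=1.0, n_alphas=20, cv=3,
                             random_state=self.seed)).fit(X, y)
        return self

    def predict(self, X):
        if self.binomial:
            return self.model_.predict_proba(X)[:, 1]
        return self.model_.predict(X)


class ForestLearner:
    def __init__(self, binomial: bool, seed: int = 0, n_estimators: int = 500):
        self.binomial = binomial
        self.seed = seed
        self.n_estimators = n_estimators

    def fit(self, X, y):
        cls = RandomForestClassifier if self.binomial else RandomForestRegressor
        self.model_ = cls(n_estimators=self.n_estimators, min_samples_leaf=5,
                          random_state=self.seed, n_jobs=1).fit(X, y)
        return self

    def predict(self, X):
        if self.binomial:
            return self.model_.predict_proba(X)[:, 1]
        return self.model_.predict(X)


class MARS:
    """Additive multivariate adaptive regression splines.

    Forward pass: greedily add mirrored hinge pairs max(x_j - t, 0) /
    max(t - x_j, 0) at candidate knots (training quantiles) while the
    residual sum of squares improves, up to ``max_terms`` basis columns.
    Backward pass: prune terms one at a time, keeping the model with the
    best generalized cross-validation (GCV) score, with the conventional
    per-term complexity charge of 2.

    For binary outcomes the spline is fit on the 0/1 labels and predictions
    are clipped into (0, 1), which is adequate for its role as one member of
    a probability-calibrated convex ensemble.
    """

    def __init__(self, binomial: bool = False, max_terms: int = 15, n_knots: int = 7,
                 penalty: float = 2.0):
        self.binomial = binomial
        self.max_terms = max_terms
        self.n_knots = n_knots
        self.penalty = penalty

    @staticmethod
    def _hinges(x: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        return np.maximum(x - t, 0.0), np.maximum(t - x, 0.0)

    def _gcv(self, rss: float, n: int, m: int) -> float:
        c = m + self.penalty * (m - 1) / 2.0
        denom = (1.0 - c / n) ** 2
        return np.inf if denom <= 0 else rss / n / denom

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        knots = [np.unique(np.quantile(X[:, j], np.linspace(0.1, 0.9, self.n_knots)))
                 for j in range(p)]
        basis_cols = [np.ones(n)]
        terms: list[tuple[int, float, int]] = [(-1, 0.0, 0)]  # (feature, knot, sign)
        B = np.ones((n, 1))
        coef, rss_prev = self._lstsq(B, y)
        while B.shape[1] + 2 <= self.max_terms:
            best = None
            for j in range(p):
                for t in knots[j]:
                    h1, h2 = self._hinges(X[:, j], t)
                    cand = np.column_stack([B, h1, h2])
                    c, rss = self._lstsq(cand, y)
                    if best is None or rss < best[0]:
                        best = (rss, j, t)
            if best is None or best[0] > rss_prev - 1e-10 * max(rss_prev, 1.0):
                break
            rss_prev, j, t = best
            h1, h2 = self._hinges(X[:, j], t)
            basis_cols += [h1, h2]
            terms += [(j, t, +1), (j, t, -1)]
            B = np.column_stack(basis_cols)
        # backward pruning on GCV
        keep = list(range(len(terms)))
        coef, rss = self._lstsq(B[:, keep], y)
        best_model = (self._gcv(rss, n, len(keep)), list(keep), coef)
        while len(keep) > 1:
            trial_best = None
            for i in keep[1:]:  # never drop the intercept
                sub = [k for k in keep if k != i]
                c, rss = self._lstsq(B[:, sub], y)
                g = self._gcv(rss, n, len(sub))
                if trial_best is None or g < trial_best[0]:
                    trial_best = (g, sub, c)
            keep = trial_best[1]
            if trial_best[0] < best_model[0]:
                best_model = trial_best
        _, self.keep_, self.coef_ = best_model
        self.terms_ = [terms[k] for k in self.keep_]
        return self

    @staticmethod
    def _lstsq(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        resid = y - B @ coef
        return coef, float(resid @ resid)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        out = np.zeros(X.shape[0])
        for (j, t, sign), c in zip(self.terms_, self.coef_):
            if j < 0:
                out += c
            elif sign > 0:
                out += c * np.maximum(X[:, j] - t, 0.0)
            else:
                out += c * np.maximum(t - X[:, j], 0.0)
        if self.binomial:
            out = np.clip(out, _CLIP, 1 - _CLIP)
        return out


def make_learner(name: str, binomial: bool, seed: int = 0, **hyper):
    """Instantiate a library learner by its registry name."""
    if name == "mean":
        return MeanLearner()
    if name == "glm":
        return GLMLearner(binomial)
    if name == "glmnet":
        return ElasticNetLearner(binomial, seed)
    if name == "rf":
        return ForestLearner(binomial, seed, hyper.get("n_estimators", 500))
    if name == "mars":
        return MARS(binomial, hyper.get("max_terms", 15), hyper.get("n_knots", 7))
    raise ValueError(f"unknown learner {name!r}; known: {LEARNER_NAMES}")
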