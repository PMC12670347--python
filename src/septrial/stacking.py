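"""Cross-validated stacking ("super learner") for nuisance estimation.

Fits a library of prediction algorithms with k-fold cross-validation, builds
the out-of-fold prediction matrix, and finds the convex (simplex) weight
vector minimizing cross-validated risk — squared error or binomial negative
log-likelihood. The weighted ensemble's cross-validated risk is therefore
never worse than the best single learner's (up to optimizer tolerance),
which is the finite-sample face of the super-learner oracle property.

Every nuisance regression in the TMLE engine goes through this interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import KFold, StratifiedKFold

from .learners import make_learner

__all__ = ["StackFit", "fit_stack", "predict_stack", "DEFAULT_LIBRARY", "FAST_LIBRARY"]

logger = logging.getLogger(__name__)

DEFAULT_LIBRARY = ("mean", "glm", "glmnet", "rf", "mars")
# well-suited to logistic-structured simulation studies where thousands of
# fits are needed; see docs for the library-choice discussion
FAST_LIBRARY = ("mean", "glm")

_CLIP = 1e-6


@dataclass
class StackFit:
    learner_names: list
    fold_map: np.ndarray
    cv_risks: dict
    weights: np.ndarray
    fitted_learners: list  # None for learners that failed to fit
    loss_family: str
    n_features: int
    feature_names: list | None

    @property
    def ensemble_cv_risk(self) -> float:
        return self.cv_risks["_ensemble"]


def _as_matrix(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def _risk(pred: np.ndarray, y: np.ndarray, loss_family: str) -> float:
    if loss_family == "binomial":
        p = np.clip(pred, _CLIP, 1 - _CLIP)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return float(np.mean((y - pred) ** 2))


def _simplex_weights(Z: np.ndarray, y: np.ndarray, loss_family: str) -> np.ndarray:
    """Convex-combination weights minimizing empirical risk of Z @ w.

    A simplex-constrained minimization (SLSQP from a uniform start) followed
    by a vertex sweep: the returned weights are guaranteed to do at least as
    well as every single learner on the out-of-fold matrix.
    """
    L = Z.shape[1]
    if L == 1:
        return np.ones(1)

    def objective(w):
        return _risk(Z @ w, y, loss_family)

    w0 = np.full(L, 1.0 / L)
    res = minimize(objective, w0, method="SLSQP",
                   bounds=[(0.0, 1.0)] * L,
                   constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
                   options={"maxiter": 200, "ftol": 1e-12})
    candidates = [np.clip(res.x, 0, 1)] if res.success else []
    candidates.append(w0)
    candidates += [np.eye(L)[j] for j in range(L)]
    best = min(candidates, key=lambda w: objective(w / w.sum()))
    best = best / best.sum()
    return best


def fit_stack(X, y, loss_family: str = "binomial", k: int = 5, seed: int = 0,
              learners=DEFAULT_LIBRARY, fold_map=None, **hyper) -> StackFit:
    """Fit the cross-validated stacking ensemble.

    Parameters
    ----------
    X, y : training features (array or DataFrame) and outcome.
    loss_family : "binomial" (y must be 0/1) or "squared_error".
    k : number of cross-validation folds, stratified by y for binomial loss.
    learners : registry names of library members; a learner that fails to
        fit on any fold is dropped with weight 0 and a logged warning.
    fold_map : optional explicit row -> fold assignment overriding the
        seeded splitter (the ensemble weights are then a pure function of
        (X, y, fold_map), invariant to row order).
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if loss_family not in ("binomial", "squared_error"):
        raise ValueError(f"unknown loss family {loss_family!r}")
    if loss_family == "binomial" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial loss requires a binary outcome")
    binomial = loss_family == "binomial"

    if fold_map is not None:
        fold_map = np.asarray(fold_map, dtype=int)
        folds = sorted(np.unique(fold_map))
        splits = [(np.flatnonzero(fold_map != f), np.flatnonzero(fold_map == f))
                  for f in folds]
    else:
        if binomial and 1 < len(np.unique(y)):
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            splits = list(splitter.split(Xm, y))
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
            splits = list(splitter.split(Xm))
        fold_map = np.empty(n, dtype=int)
        for f, (_, test_idx) in enumerate(splits):
            fold_map[test_idx] = f

    L = len(learners)
    Z = np.full((n, L), np.nan)
    failed = [False] * L
    for j, name in enumerate(learners):
        for f, (train_idx, test_idx) in enumerate(splits):
            try:
                lrn = make_learner(name, binomial, seed=seed + 31 * f, **hyper)
                lrn.fit(Xm[train_idx], y[train_idx])
                Z[test_idx, j] = lrn.predict(Xm[test_idx])
            except Exception as exc:  # noqa: BLE001 — library member failure is survivable
                logger.warning("learner %s failed on fold %d (%s); dropped", name, f, exc)
                failed[j] = True
                break
    ok = [j for j in range(L) if not failed[j] and np.isfinite(Z[:, j]).all()]
    if not ok:
        raise RuntimeError("every learner in the stacking library failed to fit")
    if binomial:
        Z[:, ok] = np.clip(Z[:, ok], _CLIP, 1 - _CLIP)

    w_ok = _simplex_weights(Z[:, ok], y, loss_family)
    weights = np.zeros(L)
    weights[ok] = w_ok

    cv_risks = {name: _risk(Z[:, j], y, loss_family) if j in ok else np.inf
                for j, name in enumerate(learners)}
    cv_risks["_ensemble"] = _risk(Z[:, ok] @ w_ok, y, loss_family)

    fitted = []
    for j, name in enumerate(learners):
        if j in ok and weights[j] > 0:
            fitted.append(make_learner(name, binomial, seed=seed, **hyper).fit(Xm, y))
        elif j in ok:
            fitted.append(make_learner(name, binomial, seed=seed, **hyper).fit(Xm, y))
        else:
            fitted.append(None)
    return StackFit(list(learners), fold_map, cv_risks, weights, fitted,
                    loss_family, Xm.shape[1], names)


def predict_stack(fit: StackFit, X_new) -> np.ndarray:
    """Convex-combination prediction of a fitted stack on new rows."""
    Xm, names = _as_matrix(X_new)
    if Xm.shape[1] != fit.n_features:
        raise ValueError(f"X_new has {Xm.shape[1]} features, expected {fit.n_features}")
    if names is not None and fit.feature_names is not None and names != fit.feature_names:
        bad = [c for c in names if c not in fit.feature_names]
        raise ValueError(f"feature-name mismatch; offending columns: {bad or names}")
    out = np.zeros(Xm.shape[0])
    for w, lrn in zip(fit.weights, fit.fitted_learners):
        if w > 0 and lrn is not None:
            out += w * lrn.predict(Xm)
    if fit.loss_family == "binomial":
        out = np.clip(out, _CLIP, 1 - _CLIP)
    return out
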