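"""Targeted maximum likelihood estimation of point-exposure treatment effects.

Implements the canonical TMLE for the average treatment effect (ATE) of a
binary treatment on a binary or bounded-continuous outcome, and for the
counterfactual mean under a fixed arm:

1. initial outcome regressions Q̄⁰(a, X), a ∈ {0, 1}, via the stacking
   ensemble on a design that includes treatment-by-covariate products so
   linear library members can express effect modification;
2. propensity ĝ(X) = P(A = 1 | X) via the stacking ensemble, truncated to
   configurable bounds against practical positivity violations;
3. a one-step logistic fluctuation along the "clever covariate"
   H(A, X) = A/ĝ(X) − (1 − A)/(1 − ĝ(X)), fit by Newton's method on the
   offset-logit likelihood (one scalar ε, no intercept);
4. the targeted substitution estimate ψ̂ = mean[Q̄*(1, X) − Q̄*(0, X)] with a
   Wald CI from the sample variance of the efficient influence curve.

Bounded-continuous outcomes (28 hospital-free days) are mapped into [0, 1]
and fluctuated on the logit scale — the standard bounded-outcome device —
then back-transformed for reporting in days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .stacking import DEFAULT_LIBRARY, fit_stack, predict_stack

__all__ = [
    "TMLEResult",
    "EstimationError",
    "estimate_ate",
    "counterfactual_mean",
    "tmle_from_nuisances",
    "scale_bounded",
    "unscale_bounded",
    "stratified_ates",
]

_QBOUNDS = (1e-4, 1 - 1e-4)


class EstimationError(RuntimeError):
    """Raised when an effect cannot be estimated (e.g. positivity failure)."""


@dataclass
class TMLEResult:
    estimand: str  # "ate" or "counterfactual_mean"
    estimate: float
    se: float
    ci95: tuple
    stratum: tuple  # (treatment, cancer_category, severity_stratum)
    n: int
    g_range: tuple
    epsilon: float
    score_residual: float
    outcome: str = ""

    def scaled(self, factor: float) -> "TMLEResult":
        """Back-transform a [0,1]-scale fit to the outcome's natural units."""
        return TMLEResult(self.estimand, self.estimate * factor, self.se * factor,
                          (self.ci95[0] * factor, self.ci95[1] * factor), self.stratum,
                          self.n, self.g_range, self.epsilon, self.score_residual,
                          self.outcome)


def scale_bounded(y_raw, lo: float = 0.0, hi: float = 28.0) -> np.ndarray:
    """Map a bounded outcome into [0, 1] for logit-scale targeting."""
    if not lo < hi:
        raise ValueError("scale_bounded requires lo < hi")
    y = np.asarray(y_raw, dtype=float)
    bad = np.flatnonzero((y < lo) | (y > hi))
    if bad.size:
        raise ValueError(f"values outside [{lo}, {hi}] at rows {bad[:20].tolist()}")
    return (y - lo) / (hi - lo)


def unscale_bounded(value, lo: float = 0.0, hi: float = 28.0):
    return np.asarray(value, dtype=float) * (hi - lo) + lo


def _fluctuate(offset_logit: np.ndarray, H: np.ndarray, y: np.ndarray,
               tol: float = 1e-12, max_iter: int = 100) -> float:
    """Scalar MLE of the logistic fluctuation model expit(offset + eps*H).

    Newton iterations on the (quasi-)binomial likelihood; at convergence the
    score sum(H * (y - mu)) is numerically zero, which is exactly the
    efficient-influence-curve equation the targeting step must solve.
    """
    eps = 0.0
    n = len(y)
    for _ in range(max_iter):
        mu = expit(offset_logit + eps * H)
        score = float(np.sum(H * (y - mu)))
        info = float(np.sum(H * H * mu * (1 - mu)))
        if abs(score) / n < tol:
            break
        if info <= 0:
            break
        step = score / info
        eps += np.clip(step, -10.0, 10.0)
    return eps


def tmle_from_nuisances(Q0: np.ndarray, Q1: np.ndarray, g: np.ndarray,
                        A: np.ndarray, Y: np.ndarray, estimand: str = "ate",
                        a_target: int = 0, stratum=("", "", ""), outcome: str = "",
                        ) -> TMLEResult:
    """Targeting step given initial outcome regressions and propensities.

    ``Q0``/``Q1`` are the initial predictions Q̄⁰(a=0, X) and Q̄⁰(a=1, X);
    ``g`` is the (already truncated) propensity P(A=1|X). Exposed separately
    so nuisances may be supplied externally (e.g. known randomization
    probabilities, or a saturated model on a discrete confounder).
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Q0 = np.clip(np.asarray(Q0, dtype=float), *_QBOUNDS)
    Q1 = np.clip(np.asarray(Q1, dtype=float), *_QBOUNDS)
    n = len(Y)
    Q_A = np.where(A == 1, Q1, Q0)

    if estimand == "ate":
        H_A = A / g - (1 - A) / (1 - g)
        eps = _fluctuate(logit(Q_A), H_A, Y)
        Q1s = expit(logit(Q1) + eps / g)
        Q0s = expit(logit(Q0) - eps / (1 - g))
        Qs_A = np.where(A == 1, Q1s, Q0s)
        est = float(np.mean(Q1s - Q0s))
        ic = H_A * (Y - Qs_A) + (Q1s - Q0s) - est
    elif estimand == "counterfactual_mean":
        g_a = g if a_target == 1 else 1 - g
        ind = (A == a_target).astype(float)
        H_A = ind / g_a
        Q_a = Q1 if a_target == 1 else Q0
        eps = _fluctuate(logit(Q_A), H_A, Y)
        Q_as = expit(logit(Q_a) + eps / g_a)
        Qs_A = expit(logit(Q_A) + eps * H_A)
        est = float(np.mean(Q_as))
        ic = H_A * (Y - Qs_A) + Q_as - est
    else:
        raise ValueError(f"unknown estimand {estimand!r}")

    score_residual = float(np.mean(H_A * (Y - Qs_A)))
    se = float(np.std(ic, ddof=1) / np.sqrt(n))
    return TMLEResult(estimand, est, se, (est - 1.96 * se, est + 1.96 * se),
                      tuple(stratum), n, (float(g.min()), float(g.max())), eps,
                      score_residual, outcome)


def _check_inputs(A: np.ndarray, Y: np.ndarray, stratum) -> None:
    if not set(np.unique(A)) <= {0.0, 1.0}:
        raise EstimationError("treatment indicator must be binary 0/1")
    if Y.min() < 0 or Y.max() > 1:
        raise EstimationError("outcome must be binary or pre-scaled to [0, 1]")
    if A.sum() == 0 or A.sum() == len(A):
        raise EstimationError(f"positivity violation (single-arm data) in stratum {stratum}")


def _fit_nuisances(X, A, Y, loss_family, g_bounds, k, seed, learners):
    Xm = np.asarray(X, dtype=float)
    A = np.asarray(A, dtype=float)
    # outcome design [X, A, A*X]: lets GLM-type learners capture effect
    # modification without relying on tree/spline members
    XA = np.column_stack([Xm, A, A[:, None] * Xm])
    q_fit = fit_stack(XA, Y, loss_family, k=k, seed=seed, learners=learners)
    ones, zeros = np.ones_like(A), np.zeros_like(A)
    Q1 = predict_stack(q_fit, np.column_stack([Xm, ones, Xm]))
    Q0 = predict_stack(q_fit, np.column_stack([Xm, zeros, 0.0 * Xm]))
    g_fit = fit_stack(Xm, A, "binomial", k=k, seed=seed + 1, learners=learners)
    g = np.clip(predict_stack(g_fit, Xm), g_bounds[0], g_bounds[1])
    if loss_family == "squared_error":
        Q1, Q0 = np.clip(Q1, *_QBOUNDS), np.clip(Q0, *_QBOUNDS)
    return Q0, Q1, g


def estimate_ate(X, A, Y, loss_family: str = "binomial", g_bounds=(0.025, 0.975),
                 k: int = 5, seed: int = 0, learners=DEFAULT_LIBRARY,
                 stratum=("", "", ""), outcome: str = "",
                 g_override=None, q_override=None) -> TMLEResult:
    """ATE of a binary treatment, E[Y(1)] − E[Y(0)], with Wald inference.

    ``g_override`` (array of propensities) and ``q_override`` (a (Q0, Q1)
    pair) replace the corresponding stacked nuisance fits when supplied —
    e.g. the known randomization probability of a designed experiment.
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(A) < 50:
        raise EstimationError(f"n = {len(A)} too small for TMLE in stratum {stratum}")
    _check_inputs(A, Y, stratum)
    if g_override is not None and q_override is not None:
        Q0, Q1 = q_override
        g = np.clip(np.broadcast_to(np.asarray(g_override, dtype=float), A.shape),
                    g_bounds[0], g_bounds[1])
    else:
        Q0, Q1, g = _fit_nuisances(X, A, Y, loss_family, g_bounds, k, seed, learners)
        if g_override is not None:
            g = np.clip(np.broadcast_to(np.asarray(g_override, dtype=float), A.shape),
                        g_bounds[0], g_bounds[1])
        if q_override is not None:
            Q0, Q1 = q_override
    return tmle_from_nuisances(Q0, Q1, g, A, Y, "ate", stratum=stratum, outcome=outcome)


def counterfactual_mean(X, A, Y, a_target: int = 0, loss_family: str = "binomial",
                        g_bounds=(0.025, 0.975), k: int = 5, seed: int = 0,
                        learners=DEFAULT_LIBRARY, stratum=("", "", ""),
                        outcome: str = "", g_override=None, q_override=None) -> TMLEResult:
    """Counterfactual mean E[Y(a_target)] — e.g. baseline mortality with no
    treatment (a_target = 0)."""
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(A) < 50:
        raise EstimationError(f"n = {len(A)} too small for TMLE in stratum {stratum}")
    _check_inputs(A, Y, stratum)
    if g_override is not None and q_override is not None:
        Q0, Q1 = q_override
        g = np.clip(np.broadcast_to(np.asarray(g_override, dtype=float), A.shape),
                    g_bounds[0], g_bounds[1])
    else:
        Q0, Q1, g = _fit_nuisances(X, A, Y, loss_family, g_bounds, k, seed, learners)
        if g_override is not None:
            g = np.clip(np.broadcast_to(np.asarray(g_override, dtype=float), A.shape),
                        g_bounds[0], g_bounds[1])
        if q_override is not None:
            Q0, Q1 = q_override
    return tmle_from_nuisances(Q0, Q1, g, A, Y, "counterfactual_mean", a_target=a_target,
                               stratum=stratum, outcome=outcome)


_RESERVED = {"stay_id", "cancer_category", "severity_stratum", "pmp", "los_days"}


def covariate_columns(cohort: pd.DataFrame) -> list:
    """Confounder columns of an analysis table (everything that is neither an
    identifier, an arm indicator, an outcome, nor a stratification label)."""
    return [c for c in cohort.columns
            if c not in _RESERVED and not c.startswith(("A_", "Y_"))]


def stratified_ates(cohort: pd.DataFrame, treatments=("imv", "vasopressors"),
                    outcome: str = "Y_mortality", categories=None, strata=None,
                    loss_family=None, g_bounds=(0.025, 0.975), k: int = 5,
                    seed: int = 0, learners=DEFAULT_LIBRARY, hfd_cap: int = 28,
                    ) -> pd.DataFrame:
    """One TMLE ATE per treatment × cancer category × severity stratum.

    Categories default to {all, any, each observed category}; strata default
    to {0%-100% (full range), each observed stratum label}. Strata failing
    the positivity tabulation (an empty arm) are reported as skip rows with
    the reason, never silently dropped. Hospital-free-day effects are
    reported in days.
    """
    from .diagnostics import positivity_table  # local import avoids a cycle

    if categories is None:
        cats = ["all", "any"] + sorted(cohort["cancer_category"].unique())
    else:
        cats = list(categories)
    if strata is None:
        strat_labels = ["0%-100%"] + sorted(cohort["severity_stratum"].unique())
    else:
        strat_labels = list(strata)
    xcols = covariate_columns(cohort)

    continuous = outcome == "Y_hfd"
    if loss_family is None:
        loss_family = "squared_error" if continuous else "binomial"

    rows = []
    for t in treatments:
        ptab = positivity_table(cohort, [t])
        empty = {(r.cancer_category, r.severity_stratum)
                 for r in ptab.itertuples() if r.n_treated == 0 or r.n_control == 0}
        for cat in cats:
            if cat == "all":
                cmask = np.ones(len(cohort), dtype=bool)
            elif cat == "any":
                cmask = (cohort["cancer_category"] != "none").to_numpy()
            else:
                cmask = (cohort["cancer_category"] == cat).to_numpy()
            for lab in strat_labels:
                smask = (np.ones(len(cohort), dtype=bool) if lab == "0%-100%"
                         else (cohort["severity_stratum"] == lab).to_numpy())
                mask = cmask & smask
                sub = cohort[mask]
                stratum = (t, cat, lab)
                base = {"treatment": t, "cancer_category": cat, "stratum": lab,
                        "n": int(mask.sum()), "estimand": "ate", "outcome": outcome}
                if cat not in ("all", "any") and lab != "0%-100%" and (cat, lab) in empty:
                    rows.append({**base, "estimate": np.nan, "se": np.nan,
                                 "ci_lo": np.nan, "ci_hi": np.nan,
                                 "skipped_reason": "positivity: empty arm"})
                    continue
                try:
                    y = sub[outcome].to_numpy(dtype=float)
                    if continuous:
                        y = scale_bounded(y, 0, hfd_cap)
                    res = estimate_ate(sub[xcols], sub[f"A_{t}"].to_numpy(), y,
                                       loss_family, g_bounds, k, seed, learners,
                                       stratum=stratum, outcome=outcome)
                    if continuous:
                        res = res.scaled(float(hfd_cap))
                    rows.append({**base, "estimate": res.estimate, "se": res.se,
                                 "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                                 "skipped_reason": ""})
                except EstimationError as exc:
                    rows.append({**base, "estimate": np.nan, "se": np.nan,
                                 "ci_lo": np.nan, "ci_hi": np.nan,
                                 "skipped_reason": str(exc)})
    return pd.DataFrame(rows)
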