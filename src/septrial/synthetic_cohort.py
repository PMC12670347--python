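"""Synthetic septic-ICU cohort generator with a Monte-Carlo ground-truth oracle.

This module emulates the statistical structure of a stay-level sepsis cohort
(one row per ICU stay) so that every downstream stage — cohort filtering,
treatment-eligibility assignment, nuisance estimation, TMLE — can be tested
against known causal truth without access to any credentialed database.

The structural model, in generative order:

1. cancer category ~ Categorical(none / solid / hematological / metastasized),
   with diagnosis-code lists drawn consistently with the category so the
   code-based categorizer can be validated against the latent label;
2. baseline covariates (severity score, labs, vitals, age) from simple
   parametric families declared in :class:`DGPConfig`;
3. per-treatment latent "ever treated" ~ Bernoulli(expit(g·x)), a logistic
   propensity on centred covariates and cancer indicators;
4. an initiation hour given ever-treated, with mass inside and outside the
   24 h eligibility window; the *effective* exposure (ever treated AND start
   within 24 h) is what enters the outcome model, so the generator's causal
   effect is exactly the 24 h target-trial estimand;
5. composite in-hospital mortality (death or hospice discharge)
   ~ Bernoulli(expit(q·x + treatment terms + treatment x severity terms));
6. length of stay ~ 1 + LogNormal, shifted by survival status and severity;
7. an event hour-of-day drawn uniformly on {0..23}, independent of everything
   (the negative-control outcome), unless the adversarial switch forces its
   parity to equal the first treatment;
8. contamination rows (minors, repeat stays, missing discharge location,
   sub-day stays, non-sepsis) to exercise the exclusion filters.

All randomness flows through a single :class:`numpy.random.Generator` derived
from the config seed; identical configs produce byte-identical tables.

The covariate joint distribution is a frank invention: the source cohorts'
49-covariate joint law is unobservable at desk scale, so defaults were chosen
once to give clinically plausible marginals (median age 67, ~10% cancer
prevalence, ~16-20% mortality, median LOS ~5 days) and a designed amount of
severity-driven confounding.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CovariateSpec",
    "DGPConfig",
    "TruthOracle",
    "generate_cohort",
    "compute_truth",
    "write_cohort",
    "read_cohort",
    "CANCER_CATEGORIES",
]

CANCER_CATEGORIES = ("none", "solid", "hematological", "metastasized")

# Toy diagnosis codes per category; mirrors the packaged code-mapping table.
_SOLID_CODES = ("C18", "C34", "C50", "C61")
_HEME_CODES = ("C82", "C83", "C90", "C91")
_META_CODES = ("C77", "C78", "C79", "C80")
_NOISE_CODES = ("I10", "E11", "J44", "N17", "A41")


class ConfigurationError(ValueError):
    """Raised when a DGP or pipeline configuration is invalid."""


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate: distribution family plus linear-predictor scaling.

    ``family`` is one of ``normal``, ``lognormal``, ``discretized_gamma``
    (rounded, clipped to [0, clip_hi] — used for integer severity points).
    ``center``/``scale`` standardize the covariate wherever it enters a
    linear predictor, so coefficients read in SD-like units.
    ``agg`` records the first-24h aggregation tag the variable would carry
    in a real extraction (max, min, mean or static).
    """

    name: str
    family: str
    params: tuple
    agg: str = "static"
    center: float = 0.0
    scale: float = 1.0


def _default_covariates() -> list[CovariateSpec]:
    return [
        # integer acute-severity points (OASIS/APACHE stand-in)
        CovariateSpec("severity_score", "discretized_gamma", (4.0, 6.0, 80), "static", 24.0, 12.0),
        CovariateSpec("age", "normal", (66.0, 14.0, 18.0, 95.0), "static", 66.0, 14.0),
        CovariateSpec("lactate_max", "lognormal", (0.7, 0.5), "max", 2.3, 1.2),
        CovariateSpec("creatinine_max", "lognormal", (0.2, 0.45), "max", 1.35, 0.65),
        CovariateSpec("map_min", "normal", (65.0, 10.0, 30.0, 110.0), "min", 65.0, 10.0),
        CovariateSpec("heart_rate_mean", "normal", (95.0, 12.0, 40.0, 180.0), "mean", 95.0, 12.0),
    ]


def _default_propensity() -> dict:
    return {
        "imv": {
            "intercept": -0.55,
            "severity_score": 0.90,
            "lactate_max": 0.15,
            "cancer_solid": -0.10,
            "cancer_hematological": -0.35,
            "cancer_metastasized": -0.15,
        },
        "vasopressors": {
            "intercept": -0.40,
            "severity_score": 0.80,
            "lactate_max": 0.25,
            "map_min": -0.30,
            "cancer_hematological": -0.30,
        },
    }


def _default_outcome() -> dict:
    return {
        "intercept": -2.10,
        "severity_score": 1.10,
        "lactate_max": 0.25,
        "cancer_solid": 0.30,
        "cancer_hematological": 0.60,
        "cancer_metastasized": 0.90,
        "treat:imv": 0.25,
        "treat:vasopressors": 0.20,
        "treat:imv:severity_score": 0.25,
        "treat:vasopressors:severity_score": 0.15,
    }


def _default_start() -> dict:
    # p_within: probability initiation falls inside the 24 h window given
    # ever treated; within-window hours ~ 24*Beta(a, b) (early-skewed);
    # late starts ~ 24 + Exp(scale) capped at 240 h.
    return {
        "imv": {"p_within": 0.88, "within_beta": (1.2, 2.5), "late_scale": 30.0},
        "vasopressors": {"p_within": 0.90, "within_beta": (1.1, 2.8), "late_scale": 24.0},
    }


@dataclass
class DGPConfig:
    """Structural parameters of the synthetic septic cohort."""

    n_stays: int = 10_000
    seed: int = 0
    cancer_prevalences: dict = field(
        default_factory=lambda: {"solid": 0.040, "hematological": 0.025, "metastasized": 0.040}
    )
    covariate_spec: list = field(default_factory=_default_covariates)
    treatments: tuple = ("imv", "vasopressors")
    propensity_coefficients: dict = field(default_factory=_default_propensity)
    treatment_start_distribution: dict = field(default_factory=_default_start)
    outcome_coefficients: dict = field(default_factory=_default_outcome)
    los_model: dict = field(
        default_factory=lambda: {
            "base_meanlog": math.log(4.0),
            "sdlog": 0.80,
            "died_shift": -0.10,
            "severity_coef": 0.15,
        }
    )
    hospice_frac: float = 0.12
    # logistic link from raw severity points to predicted mortality probability
    pmp_calibration: tuple = (-4.3, 0.0917)
    missing_discharge_rate: float = 0.0
    under18_rate: float = 0.0
    repeat_stay_rate: float = 0.0
    short_stay_rate: float = 0.0
    non_sepsis_rate: float = 0.0
    parity_adversarial: bool = False

    def validate(self) -> None:
        if self.n_stays < 1:
            raise ConfigurationError("n_stays must be >= 1")
        prev = self.cancer_prevalences
        if any(not (0.0 <= p <= 1.0) for p in prev.values()):
            raise ConfigurationError("cancer prevalences must lie in [0, 1]")
        if sum(prev.values()) > 1.0:
            raise ConfigurationError("cancer prevalences must sum to <= 1")
        for rate_name in (
            "missing_discharge_rate",
            "under18_rate",
            "repeat_stay_rate",
            "short_stay_rate",
            "non_sepsis_rate",
            "hospice_frac",
        ):
            r = getattr(self, rate_name)
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError(f"{rate_name} must lie in [0, 1]")
        for tname, coefs in self.propensity_coefficients.items():
            if tname not in self.treatments:
                raise ConfigurationError(f"propensity coefficients for unknown treatment {tname!r}")
            if any(not np.isfinite(v) for v in coefs.values()):
                raise ConfigurationError(f"non-finite propensity coefficient for {tname!r}")
        if any(not np.isfinite(v) for v in self.outcome_coefficients.values()):
            raise ConfigurationError("non-finite outcome coefficient")
        known = {s.name for s in self.covariate_spec}
        for t in self.treatments:
            if t not in self.treatment_start_distribution:
                raise ConfigurationError(f"no start-hour distribution for treatment {t!r}")
        for term in self.outcome_coefficients:
            if term.startswith("treat:"):
                parts = term.split(":")
                if parts[1] not in self.treatments:
                    raise ConfigurationError(f"outcome term {term!r} names unknown treatment")
                if len(parts) == 3 and parts[2] not in known:
                    raise ConfigurationError(f"outcome term {term!r} names unknown covariate")

    def replace(self, **kwargs) -> "DGPConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TruthOracle:
    """Monte-Carlo ground truth for the generator's causal effects.

    Keys of the per-stratum dicts are ``(treatment, stratum)`` where stratum
    is one of ``overall``, ``cancer:<category>``, ``cancer:any`` or
    ``pmp:low|moderate|high`` (tertiles of the predicted mortality
    probability implied by the config calibration).
    """

    true_ate_mortality: dict
    true_ate_hfd: dict
    true_baseline_mean: dict
    mc_se: dict
    n_mc: int


# ---------------------------------------------------------------------------
# structural-equation internals (shared by the generator and the oracle)
# ---------------------------------------------------------------------------


def _draw_covariates(cfg: DGPConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    cols = {}
    for spec in cfg.covariate_spec:
        if spec.family == "normal":
            mu, sd, lo, hi = spec.params
            cols[spec.name] = np.clip(rng.normal(mu, sd, n), lo, hi)
        elif spec.family == "lognormal":
            mu, sd = spec.params
            cols[spec.name] = rng.lognormal(mu, sd, n)
        elif spec.family == "discretized_gamma":
            shape, scale, hi = spec.params
            cols[spec.name] = np.clip(np.round(rng.gamma(shape, scale, n)), 0, hi).astype(int)
        elif spec.family == "bernoulli":
            (p,) = spec.params
            cols[spec.name] = (rng.random(n) < p).astype(float)
        else:
            raise ConfigurationError(f"unknown covariate family {spec.family!r}")
    return pd.DataFrame(cols)


def _draw_cancer(cfg: DGPConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    prev = cfg.cancer_prevalences
    p = [1.0 - sum(prev.values()), prev.get("solid", 0.0), prev.get("hematological", 0.0),
         prev.get("metastasized", 0.0)]
    return rng.choice(np.array(CANCER_CATEGORIES, dtype=object), size=n, p=p)


def _scaled(cfg: DGPConfig, X: pd.DataFrame, name: str) -> np.ndarray:
    spec = next(s for s in cfg.covariate_spec if s.name == name)
    return (X[name].to_numpy(dtype=float) - spec.center) / spec.scale


def _linear_predictor(cfg: DGPConfig, coefs: dict, X: pd.DataFrame, cancer: np.ndarray,
                      active: dict | None = None) -> np.ndarray:
    """Evaluate a log-odds linear predictor on centred covariates.

    ``active`` maps treatment name -> 0/1 array for the treatment main-effect
    and treatment x covariate interaction terms (outcome model only).
    """
    n = len(X)
    lp = np.zeros(n)
    for term, beta in coefs.items():
        if term == "intercept":
            lp += beta
        elif term.startswith("cancer_"):
            lp += beta * (cancer == term.removeprefix("cancer_")).astype(float)
        elif term.startswith("treat:"):
            parts = term.split(":")
            a = active[parts[1]] if active else np.zeros(n)
            if len(parts) == 2:
                lp += beta * a
            else:
                lp += beta * a * _scaled(cfg, X, parts[2])
        else:
            lp += beta * _scaled(cfg, X, term)
    return lp


def _mortality_prob(cfg: DGPConfig, X: pd.DataFrame, cancer: np.ndarray,
                    active: dict) -> np.ndarray:
    return expit(_linear_predictor(cfg, cfg.outcome_coefficients, X, cancer, active))


def _draw_los(cfg: DGPConfig, rng: np.random.Generator, X: pd.DataFrame,
              died: np.ndarray, normals: np.ndarray | None = None) -> np.ndarray:
    """LOS (days) = 1 + LogNormal; clean rows always satisfy the >= 1 day filter."""
    m = cfg.los_model
    if normals is None:
        normals = rng.standard_normal(len(X))
    sev = (_scaled(cfg, X, "severity_score") if "severity_score" in X.columns
           else np.zeros(len(X)))
    meanlog = m["base_meanlog"] + m["severity_coef"] * sev + m["died_shift"] * died
    return 1.0 + np.exp(meanlog + m["sdlog"] * normals)


def _hfd(los_days: np.ndarray, dead: np.ndarray, cap: int = 28) -> np.ndarray:
    out = np.maximum(0, cap - np.ceil(los_days)).astype(float)
    out[dead.astype(bool)] = 0.0
    return out


def _diagnosis_codes(rng: np.random.Generator, cancer: np.ndarray) -> list[str]:
    """Draw code lists consistent with the latent category.

    Lower-precedence codes are mixed in (a metastasized stay may also carry
    solid and hematologic codes; a hematologic stay may carry solid codes) so
    the hierarchical categorizer is genuinely exercised.
    """
    codes = []
    for cat in cancer:
        row = list(rng.choice(_NOISE_CODES, size=rng.integers(0, 3), replace=False))
        if cat == "solid":
            row += list(rng.choice(_SOLID_CODES, size=rng.integers(1, 3), replace=False))
        elif cat == "hematological":
            row.append(str(rng.choice(_HEME_CODES)))
            if rng.random() < 0.3:
                row.append(str(rng.choice(_SOLID_CODES)))
        elif cat == "metastasized":
            row.append(str(rng.choice(_META_CODES)))
            if rng.random() < 0.6:
                row.append(str(rng.choice(_SOLID_CODES)))
            if rng.random() < 0.15:
                row.append(str(rng.choice(_HEME_CODES)))
        rng.shuffle(row)
        codes.append(";".join(row))
    return codes


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def generate_cohort(config: DGPConfig) -> pd.DataFrame:
    """Simulate one stay-level table (one row per ICU stay).

    Returns a DataFrame with identifier, demographic, code, treatment-timing,
    outcome and covariate columns; diagnosis codes are ';'-joined strings so
    the table round-trips through delimited text unchanged.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_stays

    X = _draw_covariates(config, rng, n)
    cancer = _draw_cancer(config, rng, n)

    # latent ever-treated and initiation hour; effective exposure requires
    # initiation inside the 24 h eligibility window
    active: dict[str, np.ndarray] = {}
    start_hours: dict[str, np.ndarray] = {}
    for t in config.treatments:
        g = expit(_linear_predictor(config, config.propensity_coefficients.get(t, {}), X, cancer))
        ever = rng.random(n) < g
        sd = config.treatment_start_distribution[t]
        within = rng.random(n) < sd["p_within"]
        a, b = sd["within_beta"]
        hours = np.where(
            within,
            24.0 * rng.beta(a, b, n),
            np.minimum(24.0 + rng.exponential(sd["late_scale"], n), 240.0),
        )
        start = np.where(ever, hours, np.nan)
        active[t] = (ever & within).astype(float)
        start_hours[t] = start

    p_death = _mortality_prob(config, X, cancer, active)
    composite = rng.random(n) < p_death  # death-or-hospice composite
    hospice = composite & (rng.random(n) < config.hospice_frac)
    died = composite & ~hospice
    los = _draw_los(config, rng, X, composite.astype(float))

    event_hour = rng.integers(0, 24, n)
    if config.parity_adversarial:
        first = config.treatments[0]
        # force parity to equal the first treatment's effective arm
        # (treated stays get even event hours, controls odd)
        event_hour = (2 * rng.integers(0, 12, n) + 1 - active[first].astype(int)) % 24

    disposition = np.where(died, "DIED", np.where(hospice, "HOSPICE",
                           rng.choice(np.array(["HOME", "SNF"], dtype=object), n)))

    df = pd.DataFrame({
        "stay_id": np.arange(1, n + 1),
        "subject_id": 100_000 + np.arange(1, n + 1),
        "stay_index": np.ones(n, dtype=int),
        "sepsis3": np.ones(n, dtype=bool),
        "sex": rng.choice(np.array(["F", "M"], dtype=object), n, p=[0.456, 0.544]),
        "race": rng.choice(
            np.array(["White", "Black", "Hispanic", "Asian", "Other"], dtype=object),
            n, p=[0.736, 0.101, 0.042, 0.019, 0.102]),
        "cancer_latent": cancer,
        "diagnosis_codes": _diagnosis_codes(rng, cancer),
        "died_in_hospital": died,
        "discharged_to_hospice": hospice,
        "discharge_location": disposition,
        "los_days": los,
        "event_hour_of_day": event_hour,
        "code_status_admission": rng.random(n) < 0.92,
        "code_status_discharge": rng.random(n) < 0.82,
    })
    for t in config.treatments:
        df[f"{t}_start_hour"] = start_hours[t]
    df = pd.concat([df, X], axis=1)

    # contamination for the exclusion filters, each applied independently
    def _mask(rate: float) -> np.ndarray:
        return rng.random(n) < rate

    under18 = _mask(config.under18_rate)
    if "age" in df.columns:
        df.loc[under18, "age"] = rng.uniform(12.0, 18.0, int(under18.sum()))
    df.loc[_mask(config.non_sepsis_rate), "sepsis3"] = False
    repeat = _mask(config.repeat_stay_rate)
    df.loc[repeat, "stay_index"] = rng.integers(2, 5, int(repeat.sum()))
    df.loc[_mask(config.missing_discharge_rate), "discharge_location"] = np.nan
    short = _mask(config.short_stay_rate)
    df.loc[short, "los_days"] = rng.uniform(0.05, 0.95, int(short.sum()))
    return df


def compute_truth(config: DGPConfig, n_mc: int = 100_000, seed: int = 12345) -> TruthOracle:
    """Brute-force oracle: simulate potential outcomes with treatment forced.

    For each Monte-Carlo covariate draw the conditional death probabilities
    under forced treatment a in {0, 1} are evaluated exactly from the logistic
    structural equation (other treatments held at 0), so the mortality truth
    is Rao-Blackwellized over the outcome noise; hospital-free days are
    simulated with common random numbers across arms. Strata are the cancer
    categories and the PMP tertiles implied by the config calibration.
    """
    if n_mc < 10_000:
        raise ConfigurationError("n_mc must be >= 10^4 for a usable oracle")
    config.validate()
    rng = np.random.default_rng(seed)
    X = _draw_covariates(config, rng, n_mc)
    cancer = _draw_cancer(config, rng, n_mc)
    zeros = {t: np.zeros(n_mc) for t in config.treatments}

    strata: dict[str, np.ndarray] = {"overall": np.ones(n_mc, dtype=bool),
                                     "cancer:any": cancer != "none"}
    for cat in CANCER_CATEGORIES:
        strata[f"cancer:{cat}"] = cancer == cat
    if "severity_score" in X.columns:
        a, b = config.pmp_calibration
        pmp = expit(a + b * X["severity_score"].to_numpy(dtype=float))
        q1, q2 = np.quantile(pmp, [1 / 3, 2 / 3])
        pmp_lab = np.where(pmp <= q1, "pmp:low", np.where(pmp <= q2, "pmp:moderate", "pmp:high"))
        for lab in ("pmp:low", "pmp:moderate", "pmp:high"):
            strata[lab] = pmp_lab == lab

    u_death = rng.random(n_mc)
    los_norm = rng.standard_normal(n_mc)

    ate_m, ate_h, base, se = {}, {}, {}, {}
    p0_all = _mortality_prob(config, X, cancer, zeros)
    d0 = u_death < p0_all
    los0 = _draw_los(config, rng, X, d0.astype(float), normals=los_norm)
    hfd0 = _hfd(los0, d0)
    for name, mask in strata.items():
        m = int(mask.sum())
        if m:
            base[name] = float(p0_all[mask].mean())
            se[("baseline", name)] = float(p0_all[mask].std(ddof=1) / math.sqrt(m))

    for t in config.treatments:
        forced = dict(zeros)
        forced[t] = np.ones(n_mc)
        p1 = _mortality_prob(config, X, cancer, forced)
        d1 = u_death < p1
        los1 = _draw_los(config, rng, X, d1.astype(float), normals=los_norm)
        hfd1 = _hfd(los1, d1)
        diff_m = p1 - p0_all
        diff_h = hfd1 - hfd0
        for name, mask in strata.items():
            m = int(mask.sum())
            if m < 2:
                continue
            ate_m[(t, name)] = float(diff_m[mask].mean())
            ate_h[(t, name)] = float(diff_h[mask].mean())
            se[(t, name)] = float(diff_m[mask].std(ddof=1) / math.sqrt(m))
            se[(t, name, "hfd")] = float(diff_h[mask].std(ddof=1) / math.sqrt(m))
    return TruthOracle(ate_m, ate_h, base, se, n_mc)


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"diagnosis_codes": str})


def write_truth(oracle: TruthOracle, path) -> None:
    """Serialize the oracle as flat delimited text (one row per truth value)."""
    rows = []
    for (t, s), v in oracle.true_ate_mortality.items():
        rows.append((t, s, "ate_mortality", v, oracle.mc_se[(t, s)]))
    for (t, s), v in oracle.true_ate_hfd.items():
        rows.append((t, s, "ate_hfd", v, oracle.mc_se[(t, s, "hfd")]))
    for s, v in oracle.true_baseline_mean.items():
        rows.append(("none", s, "baseline_mortality", v, oracle.mc_se[("baseline", s)]))
    pd.DataFrame(rows, columns=["treatment", "stratum", "quantity", "value", "mc_se"]).to_csv(
        path, index=False)
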