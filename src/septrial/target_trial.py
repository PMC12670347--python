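"""Target-trial cohort construction for a septic ICU population.

Turns raw stay-level records into the analysis table of an emulated trial:
inclusion/exclusion filters with a reconciling log, treatment assignment over
a fixed 24 h eligibility window (late initiators stay in the control arm, so
no immortal person-time is excluded), hierarchical cancer categorization from
diagnosis codes, first-24h covariate aggregation, outcome derivation
(in-hospital death or hospice discharge; 28 hospital-free days; the
odd/even-hour negative control), predicted mortality probability (PMP) from a
logistic calibration of the severity score, and severity stratification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit

from .synthetic_cohort import ConfigurationError

__all__ = [
    "ExclusionLog",
    "apply_inclusion",
    "assign_treatment",
    "load_code_map",
    "categorize_cancer",
    "aggregate_covariates",
    "derive_outcomes",
    "compute_pmp",
    "assign_strata",
    "build_cohort",
    "CANCER_PRECEDENCE",
]

logger = logging.getLogger(__name__)

# total order: higher precedence wins when a stay carries multiple categories
CANCER_PRECEDENCE = ("metastasized", "hematological", "solid")

# fixed filter order; the log reports counts removed at each step in turn
_CRITERIA = ("under_18", "no_sepsis", "not_first_stay", "missing_discharge", "los_lt_1d")


class RecordError(ValueError):
    """A record-level contract violation, carrying the offending stay ids."""

    def __init__(self, message: str, stay_ids):
        super().__init__(f"{message}: stay_id {list(stay_ids)}")
        self.stay_ids = list(stay_ids)


@dataclass
class ExclusionLog:
    """Ordered counts of records removed per inclusion criterion."""

    n_input: int = 0
    removed: dict = field(default_factory=lambda: {c: 0 for c in _CRITERIA})

    @property
    def n_output(self) -> int:
        return self.n_input - sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(c, self.removed[c]) for c in _CRITERIA]
        rows.append(("output", self.n_output))
        return pd.DataFrame(rows, columns=["criterion", "n"])


def apply_inclusion(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the trial's inclusion criteria in a fixed order.

    Retained stays are adults (age strictly over 18), flagged septic, on
    their first ICU stay, with a documented discharge location and a length
    of stay of at least one day.
    """
    required = ("stay_id", "age", "sepsis3", "stay_index", "discharge_location", "los_days")
    missing_cols = [c for c in required if c not in records.columns]
    if missing_cols:
        raise ConfigurationError(f"records missing required columns: {missing_cols}")
    for col in ("age", "stay_index", "los_days"):
        bad = records.loc[records[col].isna(), "stay_id"]
        if len(bad):
            raise RecordError(f"missing {col}", bad.head(20))

    log = ExclusionLog(n_input=len(records))
    df = records
    masks = {
        "under_18": lambda d: d["age"] > 18,
        "no_sepsis": lambda d: d["sepsis3"].astype(bool),
        "not_first_stay": lambda d: d["stay_index"] == 1,
        "missing_discharge": lambda d: d["discharge_location"].notna(),
        "los_lt_1d": lambda d: d["los_days"] >= 1.0,
    }
    for criterion in _CRITERIA:
        keep = masks[criterion](df)
        log.removed[criterion] = int((~keep).sum())
        df = df[keep]
    return df.reset_index(drop=True), log


def assign_treatment(records: pd.DataFrame, treatment_name: str,
                     window_hours: float = 24.0) -> np.ndarray:
    """Arm assignment over the eligibility window; never drops a record.

    A = 1 iff initiation is documented and starts within ``window_hours`` of
    ICU admission (boundary inclusive); absent or later starts are control.
    Keeping late initiators in the control arm is what removes immortal-time
    bias from the emulated trial.
    """
    col = f"{treatment_name}_start_hour"
    if col not in records.columns:
        raise ConfigurationError(f"records have no column {col!r}")
    start = records[col].to_numpy(dtype=float)
    neg = records.loc[start < 0, "stay_id"] if np.any(start < 0) else []
    if len(neg):
        raise RecordError("negative treatment start hour", neg)
    return (np.nan_to_num(start, nan=np.inf) <= window_hours).astype(int)


def load_code_map(path=None) -> dict[str, str]:
    """Load a code -> cancer-category mapping table (two-column CSV).

    Without a path, the packaged toy mapping (a stand-in for an expert ICD-10
    grouping table) is used.
    """
    if path is None:
        src = resources.files("septrial.data").joinpath("cancer_codes_toy.csv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    if list(table.columns[:2]) != ["code", "category"]:
        raise ConfigurationError("code map must have columns (code, category)")
    bad = set(table["category"]) - set(CANCER_PRECEDENCE)
    if bad:
        raise ConfigurationError(f"code map has unknown categories: {sorted(bad)}")
    return dict(zip(table["code"], table["category"]))


def categorize_cancer(diagnosis_codes, code_map: dict[str, str]) -> str:
    """Hierarchical cancer category of one stay.

    Metastasized takes precedence over hematological, which takes precedence
    over solid; a stay with no mapped code is 'none'. Unmapped codes are
    ignored (logged at debug level), never fatal.
    """
    if isinstance(diagnosis_codes, str):
        diagnosis_codes = [c for c in diagnosis_codes.split(";") if c]
    elif diagnosis_codes is None or (isinstance(diagnosis_codes, float) and np.isnan(diagnosis_codes)):
        diagnosis_codes = []
    cats = set()
    for code in diagnosis_codes:
        cat = code_map.get(code)
        if cat is None:
            logger.debug("unmapped diagnosis code ignored: %s", code)
        else:
            cats.add(cat)
    for cat in CANCER_PRECEDENCE:
        if cat in cats:
            return cat
    return "none"


def aggregate_covariates(timed_values: dict, schema: dict) -> dict:
    """First-24h aggregation of time-stamped measurements.

    ``timed_values`` maps variable name -> sequence of (offset_hour, value);
    ``schema`` maps variable name -> aggregation tag in {max, min, mean,
    static}. Values recorded before ICU admission (offset < 0) or after the
    first 24 h are ignored; a variable with no in-window value aggregates to
    NaN (imputation happens downstream).
    """
    reducers = {"max": np.max, "min": np.min, "mean": np.mean, "static": lambda v: v[-1]}
    out = {}
    for name, tag in schema.items():
        if tag not in reducers:
            raise ConfigurationError(f"unknown aggregation tag {tag!r} for {name!r}")
        vals = [v for (h, v) in timed_values.get(name, []) if 0.0 <= h <= 24.0]
        out[name] = float(reducers[tag](np.asarray(vals, dtype=float))) if vals else float("nan")
    return out


def derive_outcomes(records: pd.DataFrame, cap_days: int = 28) -> pd.DataFrame:
    """Trial outcomes for each stay.

    Y_mortality is the composite of in-hospital death and hospice discharge.
    Hospital-free days are 0 on death, else max(0, cap - ceil(LOS)) — the
    prevailing clinical-trials convention for "days alive and out of
    hospital". Y_parity = 1 iff the death/discharge hour is even (negative
    control: treatment cannot plausibly shift event-hour parity).
    """
    y_mort = (records["died_in_hospital"].astype(bool)
              | records["discharged_to_hospice"].astype(bool)).astype(int)
    hfd = np.maximum(0, cap_days - np.ceil(records["los_days"].to_numpy(dtype=float)))
    hfd[y_mort.to_numpy() == 1] = 0
    parity = (records["event_hour_of_day"].astype(int) % 2 == 0).astype(int)
    return pd.DataFrame({"Y_mortality": y_mort, "Y_hfd": hfd.astype(int), "Y_parity": parity})


def compute_pmp(severity_score, calibration) -> np.ndarray:
    """Predicted mortality probability via a logistic link on severity points.

    ``calibration`` is the (intercept, slope) pair of the score's published
    prediction formula; it must be supplied explicitly — there is no default,
    because a silently wrong calibration would silently shuffle strata.
    """
    if calibration is None:
        raise ConfigurationError("PMP calibration (intercept, slope) is required")
    intercept, slope = calibration
    return expit(intercept + slope * np.asarray(severity_score, dtype=float))


def assign_strata(pmp, mode: str = "tertile", band_edges=None) -> np.ndarray:
    """Severity stratum labels from PMP values.

    Tertile mode labels low/moderate/high by the empirical 1/3 and 2/3
    quantiles. Bands mode uses half-open intervals [e_i, e_{i+1}) from
    ``band_edges``; labels render the edges as percentages.
    """
    pmp = np.asarray(pmp, dtype=float)
    if mode == "tertile":
        q1, q2 = np.quantile(pmp, [1 / 3, 2 / 3])
        if q1 == q2:
            warnings.warn("degenerate PMP distribution: all rows fall in one stratum")
            return np.full(len(pmp), "low", dtype=object)
        return np.where(pmp <= q1, "low", np.where(pmp <= q2, "moderate", "high")).astype(object)
    if mode == "bands":
        edges = list(band_edges)
        if edges != sorted(edges):
            raise ConfigurationError("band edges must be sorted ascending")
        labels = [f"{int(round(lo * 100))}%-{int(round(hi * 100))}%"
                  for lo, hi in zip(edges[:-1], edges[1:])]
        idx = np.clip(np.searchsorted(edges, pmp, side="right") - 1, 0, len(labels) - 1)
        return np.asarray(labels, dtype=object)[idx]
    raise ConfigurationError(f"unknown strata mode {mode!r}")


def build_cohort(records: pd.DataFrame, *, calibration, treatments=("imv", "vasopressors"),
                 window_hours: float = 24.0, covariate_names=None, code_map=None,
                 strata_mode: str = "tertile", band_edges=None,
                 ) -> tuple[pd.DataFrame, ExclusionLog]:
    """Full cohort construction: filters, arms, categories, outcomes, strata.

    Returns the analysis table (columns: stay_id, covariates, one ``A_<t>``
    arm indicator per treatment, Y_mortality / Y_hfd / Y_parity,
    cancer_category, pmp, severity_stratum) and the exclusion log. Missing
    covariates are median-imputed with a per-variable missingness indicator
    appended, keeping N intact while passing the missingness signal to the
    learners.
    """
    included, log = apply_inclusion(records)
    if code_map is None:
        code_map = load_code_map()
    if covariate_names is None:
        covariate_names = ["severity_score", "age", "lactate_max", "creatinine_max",
                           "map_min", "heart_rate_mean"]
        covariate_names = [c for c in covariate_names if c in included.columns]

    cohort = included[["stay_id"]].copy()
    for name in covariate_names:
        col = included[name].astype(float)
        if col.isna().any():
            cohort[f"{name}_missing"] = col.isna().astype(int)
            col = col.fillna(col.median())
        cohort[name] = col.to_numpy()
    for t in treatments:
        cohort[f"A_{t}"] = assign_treatment(included, t, window_hours)
    cohort = pd.concat([cohort, derive_outcomes(included)], axis=1)
    cohort["los_days"] = included["los_days"].to_numpy(dtype=float)  # for summaries only
    cohort["cancer_category"] = [categorize_cancer(c, code_map)
                                 for c in included["diagnosis_codes"]]
    cohort["pmp"] = compute_pmp(included["severity_score"], calibration)
    cohort["severity_stratum"] = assign_strata(cohort["pmp"].to_numpy(), strata_mode, band_edges)
    return cohort, log
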