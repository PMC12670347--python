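"""Validity diagnostics: positivity tabulation and the negative-control TMLE.

Positivity requires every cancer-category × severity-stratum cell to contain
both treated and control stays; the table below makes that checkable (and is
consulted by the stratified estimator before it commits to a stratum).

The negative control re-runs the full TMLE machinery with an outcome that
treatment cannot plausibly move — whether the hour of death or discharge was
odd or even. A confidence interval that excludes zero signals residual bias
(confounding, model misspecification, or a coding error) somewhere in the
pipeline; the check reports, it never aborts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stacking import DEFAULT_LIBRARY
from .tmle_engine import TMLEResult, estimate_ate

__all__ = ["PositivityTable", "positivity_table", "negative_control"]


@dataclass
class PositivityTable:
    table: pd.DataFrame  # treatment, cancer_category, severity_stratum, n_treated, n_control
    flag_empty: list  # [(treatment, cancer_category, severity_stratum, arm), ...]


def positivity_table(cohort: pd.DataFrame, treatments=("imv", "vasopressors")) -> pd.DataFrame:
    """Exhaustive cross-tabulation of arm counts per stratum (deterministic)."""
    rows = []
    cats = sorted(cohort["cancer_category"].unique())
    labs = sorted(cohort["severity_stratum"].unique())
    for t in treatments:
        a = cohort[f"A_{t}"].to_numpy()
        for cat in cats:
            cmask = (cohort["cancer_category"] == cat).to_numpy()
            for lab in labs:
                mask = cmask & (cohort["severity_stratum"] == lab).to_numpy()
                n1 = int(a[mask].sum())
                rows.append({"treatment": t, "cancer_category": cat,
                             "severity_stratum": lab, "n_treated": n1,
                             "n_control": int(mask.sum()) - n1})
    return pd.DataFrame(rows)


def positivity_check(cohort: pd.DataFrame, treatments=("imv", "vasopressors")) -> PositivityTable:
    tab = positivity_table(cohort, treatments)
    empty = []
    for r in tab.itertuples():
        if r.n_treated == 0:
            empty.append((r.treatment, r.cancer_category, r.severity_stratum, "treated"))
        if r.n_control == 0:
            empty.append((r.treatment, r.cancer_category, r.severity_stratum, "control"))
    return PositivityTable(tab, empty)


def negative_control(cohort: pd.DataFrame, treatment: str = "imv",
                     g_bounds=(0.025, 0.975), k: int = 5, seed: int = 0,
                     learners=DEFAULT_LIBRARY) -> TMLEResult:
    """TMLE ATE of the treatment on event-hour parity (expected: null)."""
    from .tmle_engine import covariate_columns

    xcols = covariate_columns(cohort)
    res = estimate_ate(cohort[xcols], cohort[f"A_{treatment}"].to_numpy(),
                       cohort["Y_parity"].to_numpy(dtype=float), "binomial",
                       g_bounds, k, seed, learners,
                       stratum=(treatment, "all", "0%-100%"), outcome="Y_parity")
    return res
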