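"""Clinical IHC stage: immunoreactive scoring, cohort dichotomization,
Table-1-style association testing, and Kaplan-Meier survival comparison.

IHC staining intensity (0-3) and positive-cell proportion (0-3) multiply
into a semiquantitative immunoreactive score (IRS, 0-9); patients with IRS
of at least 6 form the high-expression group. Categorical clinicopathological
variables are tested with Fisher's exact test (2x2) or Pearson chi-square
(larger tables); age by Mann-Whitney U; overall survival by the log-rank
test on the product-limit curves of the two expression groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats_kit

IRS_HIGH_CUTOFF = 6

#: Published group-wise counts of the 60-patient IHC cohort
#: (low expression n=33 / high expression n=27), one contingency table per
#: categorical variable, rows in the stated level order, columns (low, high).
TABLE1_COUNTS = {
    "sex": {"levels": ["male", "female"], "low": [18, 15], "high": [15, 12]},
    "differentiation": {"levels": ["well", "moderate", "poor"],
                        "low": [8, 17, 8], "high": [9, 17, 1]},
    "tnm_stage": {"levels": ["I", "II", "III", "IV"],
                  "low": [9, 13, 8, 3], "high": [2, 4, 14, 7]},
    "ln_metastasis": {"levels": ["no", "yes"], "low": [27, 6], "high": [13, 14]},
    "distant_metastasis": {"levels": ["no", "yes"], "low": [30, 3], "high": [18, 9]},
    "recurrence": {"levels": ["no", "yes"], "low": [25, 8], "high": [17, 10]},
    "vital_status": {"levels": ["alive", "dead"], "low": [20, 13], "high": [8, 19]},
}

CATEGORICAL_VARIABLES = list(TABLE1_COUNTS)


class ScoreValidationError(ValueError):
    """An IHC sub-score is outside the 0-3 integer range."""


def irs_score(intensity: int, proportion: int) -> tuple[int, str]:
    """Immunoreactive score: intensity x proportion, dichotomized at >= 6."""
    for name, v in (("intensity", intensity), ("proportion", proportion)):
        if not isinstance(v, (int, np.integer)) or not (0 <= v <= 3):
            raise ScoreValidationError(f"{name} score must be an integer in 0-3, got {v!r}")
    irs = int(intensity) * int(proportion)
    return irs, "high" if irs >= IRS_HIGH_CUTOFF else "low"


@dataclass
class PatientRecord:
    patient_id: str
    age: float
    sex: str                      # male | female
    differentiation: str          # well | moderate | poor
    tnm_stage: str                # I | II | III | IV
    ln_metastasis: str            # yes | no
    distant_metastasis: str       # yes | no
    recurrence: str               # yes | no
    vital_status: str             # alive | dead
    followup_months: float
    intensity_score: int
    proportion_score: int
    irs: int = field(init=False)
    group: str = field(init=False)

    def __post_init__(self) -> None:
        if self.followup_months < 0:
            raise ValueError(f"{self.patient_id}: negative follow-up")
        self.irs, self.group = irs_score(self.intensity_score, self.proportion_score)

    @property
    def event(self) -> int:
        """Death from any cause; censored at last follow-up otherwise."""
        return 1 if self.vital_status == "dead" else 0


def _counts_for(cohort: Sequence[PatientRecord], variable: str, levels: list[str]) -> np.ndarray:
    table = np.zeros((len(levels), 2), dtype=int)
    for p in cohort:
        value = getattr(p, variable)
        col = 0 if p.group == "low" else 1
        table[levels.index(value), col] += 1
    return table


def table_one(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Group comparison of clinicopathological characteristics.

    Categorical variables use the shared policy — Fisher's exact test for
    2x2 tables, Pearson chi-square otherwise; age is compared with the
    Mann-Whitney U test. Variables with a single observed level are flagged
    ``not-testable``. Output is one row per variable level with counts,
    column percentages, the test used and its p-value.
    """
    groups = {p.group for p in cohort}
    if groups != {"low", "high"}:
        raise ValueError("both expression groups must be nonempty")
    rows = []
    n_low = sum(1 for p in cohort if p.group == "low")
    n_high = len(cohort) - n_low

    age_low = [p.age for p in cohort if p.group == "low"]
    age_high = [p.age for p in cohort if p.group == "high"]
    _, age_p = stats_kit.mann_whitney_u(age_low, age_high)
    rows.append({"variable": "age", "level": "median(IQR)",
                 "low": f"{np.median(age_low):.1f}", "high": f"{np.median(age_high):.1f}",
                 "low_pct": float("nan"), "high_pct": float("nan"),
                 "test": "mann_whitney_u", "pvalue": age_p, "flag": ""})

    for var, spec in TABLE1_COUNTS.items():
        levels = spec["levels"]
        table = _counts_for(cohort, var, levels)
        observed_levels = int((table.sum(axis=1) > 0).sum())
        if observed_levels < 2:
            test_name, pvalue, flag = "", float("nan"), "not-testable"
        else:
            nz = table[table.sum(axis=1) > 0]
            result = stats_kit.contingency_test(nz)
            test_name, pvalue, flag = result.test, result.pvalue, ""
        for i, level in enumerate(levels):
            rows.append({
                "variable": var, "level": level,
                "low": int(table[i, 0]), "high": int(table[i, 1]),
                "low_pct": 100.0 * table[i, 0] / n_low,
                "high_pct": 100.0 * table[i, 1] / n_high,
                "test": test_name if i == 0 else "",
                "pvalue": pvalue if i == 0 else float("nan"),
                "flag": flag if i == 0 else "",
            })
    return pd.DataFrame(rows)


def survival_compare(cohort: Sequence[PatientRecord]):
    """Kaplan-Meier curves per expression group and the log-rank comparison.

    Returns (curves dict keyed by group, chi-square statistic, p-value);
    p = 1 with a degenerate statistic when neither group has any event.
    """
    by_group = {}
    for g in ("low", "high"):
        members = [p for p in cohort if p.group == g]
        if not members:
            raise ValueError(f"group {g!r} has no subjects")
        by_group[g] = (np.array([p.followup_months for p in members]),
                       np.array([p.event for p in members]))
    curves = {g: stats_kit.km_curve(t, e) for g, (t, e) in by_group.items()}
    chi2, pvalue = stats_kit.logrank([by_group["low"], by_group["high"]])
    return curves, chi2, pvalue


def synthetic_table1_cohort() -> list[PatientRecord]:
    """Synthetic 60-patient cohort matching the published per-variable
    group-wise margins.

    The joint covariate distribution of the real cohort is unpublished;
    variables are therefore assigned independently within each expression
    group so that every single-variable contingency table — and hence every
    categorical test — reproduces the published counts exactly. Follow-up
    times are nominal placeholders (survival inference is not meaningful on
    this fixture).
    """
    n_low, n_high = 33, 27
    assignments = {"low": {}, "high": {}}
    for var, spec in TABLE1_COUNTS.items():
        for grp, n_grp in (("low", n_low), ("high", n_high)):
            values = []
            for level, count in zip(spec["levels"], spec[grp]):
                values.extend([level] * count)
            assert len(values) == n_grp
            assignments[grp][var] = values
    cohort = []
    for grp, n_grp, scores in (("low", n_low, (1, 2)), ("high", n_high, (3, 3))):
        for i in range(n_grp):
            cohort.append(PatientRecord(
                patient_id=f"{grp}-{i:02d}",
                age=60.0,
                sex=assignments[grp]["sex"][i],
                differentiation=assignments[grp]["differentiation"][i],
                tnm_stage=assignments[grp]["tnm_stage"][i],
                ln_metastasis=assignments[grp]["ln_metastasis"][i],
                distant_metastasis=assignments[grp]["distant_metastasis"][i],
                recurrence=assignments[grp]["recurrence"][i],
                vital_status=assignments[grp]["vital_status"][i],
                followup_months=float(12 + i),
                intensity_score=scores[0],
                proportion_score=scores[1],
            ))
    return cohort


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": p.patient_id, "age": p.age, "sex": p.sex,
        "differentiation": p.differentiation, "tnm_stage": p.tnm_stage,
        "ln_metastasis": p.ln_metastasis, "distant_metastasis": p.distant_metastasis,
        "recurrence": p.recurrence, "vital_status": p.vital_status,
        "followup_months": p.followup_months, "event": p.event,
        "intensity_score": p.intensity_score, "proportion_score": p.proportion_score,
        "irs": p.irs, "group": p.group,
    } for p in cohort])


def cohort_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    return [PatientRecord(
        patient_id=str(r["patient_id"]), age=float(r["age"]), sex=str(r["sex"]),
        differentiation=str(r["differentiation"]), tnm_stage=str(r["tnm_stage"]),
        ln_metastasis=str(r["ln_metastasis"]),
        distant_metastasis=str(r["distant_metastasis"]),
        recurrence=str(r["recurrence"]), vital_status=str(r["vital_status"]),
        followup_months=float(r["followup_months"]),
        intensity_score=int(r["intensity_score"]),
        proportion_score=int(r["proportion_score"]),
    ) for _, r in df.iterrows()]
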