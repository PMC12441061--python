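"""Clinical cohort statistics and Kaplan-Meier renal survival.

Works on a tab-separated cohort table of ADTKD-MUC1 cases (one row per
patient; see the packaged example table).  Two kinds of output:

* descriptive statistics: median/IQR of age at diagnosis, sex ratio,
  family history, biopsy and medullary-cystic-kidney-disease (MCKD)
  findings, hypertension, hyperuricemia, renal replacement therapy (RRT)
  at diagnosis, and proteinuria among patients not yet on RRT;
* renal survival: age at ESKD onset as the event (RRT age), age at
  diagnosis as the censoring time, product-limit estimation with
  log-transformed Greenwood 95% confidence bounds (the default
  convention of standard survival software), and the median
  renal-survival age (smallest age with estimated survival <= 0.5).

Conventions: quantiles use linear interpolation of order statistics; at
tied times events precede censorings; "ND" (not determined) entries are
excluded from the affected denominators, never imputed.  Proteinuria is
counted for a numeric urinary protein >= 0.15 g/gCr; "negative", "0",
"auria" and "ND" do not count.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import ValidationError

PROTEINURIA_THRESHOLD = 0.15  # g/gCr

_RRT_RE = re.compile(r"RRT\s*\((\d+(?:\.\d+)?)\s*y\)", re.IGNORECASE)


@dataclass(frozen=True)
class PatientRecord:
    id: str
    age_at_diagnosis: float
    sex: str  # "M" | "F"
    family_history: str  # "positive" | "negative"
    pathology: Optional[str]  # None <=> no biopsy
    hypertension: str  # "positive" | "negative" | "ND"
    hyperuricemia: str  # "positive" | "negative" | "ND"
    egfr: Optional[float]  # None <=> on RRT
    rrt_age: Optional[float]
    urinary_protein: str  # numeric string, "negative", "ND", or "auria"
    potassium: Optional[float]

    def __post_init__(self) -> None:
        if self.age_at_diagnosis <= 0:
            raise ValidationError(f"{self.id}: age_at_diagnosis must be positive")
        if (self.rrt_age is None) != (self.egfr is not None):
            raise ValidationError(f"{self.id}: rrt_age present iff eGFR is the RRT marker")
        if self.rrt_age is not None and self.rrt_age <= 0:
            raise ValidationError(f"{self.id}: rrt_age must be positive")

    @property
    def on_rrt(self) -> bool:
        return self.rrt_age is not None

    @property
    def proteinuric(self) -> Optional[bool]:
        """True/False by the numeric threshold; None when not assessable."""
        v = self.urinary_protein.strip().lower()
        if v in {"nd", "auria", ""}:
            return None
        if v == "negative":
            return False
        return float(v) >= PROTEINURIA_THRESHOLD


@dataclass(frozen=True)
class SurvivalRecord:
    time: float  # years of age
    event: bool  # True = ESKD/RRT; False = censored at diagnosis

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValidationError("survival time must be positive")


def _tristate(value: str) -> str:
    v = value.strip()
    if v.upper() == "ND":
        return "ND"
    if v.startswith("+"):
        return "positive"
    return "negative"


def load_cohort(path: str | Path | None = None) -> list[PatientRecord]:
    """Parse a cohort TSV; with no path, the packaged example cohort."""
    if path is None:
        path = resources.files("vntrscan.data") / "table1_adtkd_muc1.tsv"
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    records = []
    for _, row in df.iterrows():
        egfr_raw = row["egfr"].strip()
        m = _RRT_RE.match(egfr_raw)
        pathology = row["pathology"].strip()
        potassium = row.get("serum_potassium", row.get("potassium"))
        records.append(
            PatientRecord(
                id=row["id"].strip(),
                age_at_diagnosis=float(row["age_at_diagnosis"]),
                sex=row["sex"].strip().upper(),
                family_history="positive" if row["family_history"].strip() == "+" else "negative",
                pathology=None if pathology in {"-", "–", ""} else pathology,
                hypertension=_tristate(row["hypertension"]),
                hyperuricemia=_tristate(row["hyperuricemia"]),
                egfr=None if m else float(egfr_raw),
                rrt_age=float(m.group(1)) if m else None,
                urinary_protein=str(row["urinary_protein"]).strip(),
                potassium=None if potassium is None else float(potassium),
            )
        )
    return records


def summarize(records: Sequence[PatientRecord]) -> dict:
    """Descriptive statistics of the cohort (counts and age quantiles)."""
    if not records:
        raise ValidationError("cannot summarize an empty cohort")
    ages = np.array([r.age_at_diagnosis for r in records], dtype=float)
    q25, q50, q75 = np.percentile(ages, [25, 50, 75])  # linear interpolation
    proteinuric_non_rrt = [
        r.proteinuric for r in records if not r.on_rrt and r.proteinuric is not None
    ]
    return {
        "n": len(records),
        "age_median": float(q50),
        "age_iqr": (float(q25), float(q75)),
        "males": sum(r.sex == "M" for r in records),
        "females": sum(r.sex == "F" for r in records),
        "family_history_positive": sum(r.family_history == "positive" for r in records),
        "biopsies": sum(r.pathology is not None for r in records),
        "mckd_findings": sum(
            r.pathology is not None and "MCKD" in r.pathology for r in records
        ),
        "hypertension_positive": sum(r.hypertension == "positive" for r in records),
        "hyperuricemia_positive": sum(r.hyperuricemia == "positive" for r in records),
        "rrt_at_diagnosis": sum(r.on_rrt for r in records),
        "non_rrt": sum(not r.on_rrt for r in records),
        "proteinuria_non_rrt": sum(bool(p) for p in proteinuric_non_rrt),
    }


def to_survival(records: Sequence[PatientRecord]) -> list[SurvivalRecord]:
    """Event at RRT age for patients on RRT, censoring at diagnosis age
    otherwise.  RRT age takes precedence even when below diagnosis age
    (ESKD predated diagnosis)."""
    out = []
    for r in records:
        if r.on_rrt:
            out.append(SurvivalRecord(time=r.rrt_age, event=True))
        else:
            out.append(SurvivalRecord(time=r.age_at_diagnosis, event=False))
    return out


@dataclass
class KaplanMeierResult:
    table: pd.DataFrame  # time, n_risk, n_event, n_censor, survival, ci_lower, ci_upper
    median: float  # NaN when the curve never reaches 0.5
    median_ci: tuple[float, float]  # bounds may be NaN/inf ("not attained")

    def median_is_defined(self) -> bool:
        return math.isfinite(self.median)


def _crossing_time(times: np.ndarray, curve: np.ndarray) -> float:
    """Smallest time at which ``curve`` drops to <= 0.5.

    NaN entries (bounds undefined once the estimate hits 0) never count
    as crossings; NaN is returned when the curve never crosses, meaning
    "not attained" (NA)."""
    for t, v in zip(times, curve):
        if np.isfinite(v) and v <= 0.5:
            return float(t)
    return float("nan")


def kaplan_meier(survival_records: Sequence[SurvivalRecord]) -> KaplanMeierResult:
    """Product-limit estimate, log-transformed Greenwood 95% CI, median age.

    At tied times events precede censorings (the standard convention).
    Confidence bounds use the log transform: S(t)*exp(+/- 1.96*sigma(t))
    with sigma^2(t) = sum d_i / (n_i (n_i - d_i)), undefined (NaN) once
    S(t) = 0.  The median is the smallest observed time with survival
    <= 0.5 (inf when unattained); each median CI bound is where the
    corresponding confidence curve crosses 0.5, NaN ("NA") when it never
    does -- the behaviour of standard survival software.
    """
    if not survival_records:
        raise ValidationError("need at least one survival record")
    times = [r.time for r in survival_records]
    events = [r.event for r in survival_records]
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    ev = kmf.event_table
    s = surv.to_numpy()
    n_risk = ev["at_risk"].to_numpy(dtype=float)
    n_event = ev["observed"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(
            n_event > 0, n_event / (n_risk * np.maximum(n_risk - n_event, 0)), 0.0
        )
        sigma = np.sqrt(np.cumsum(incr))
        z = 1.959963984540054  # two-sided 95%
        lower = s * np.exp(-z * sigma)
        upper = np.minimum(1.0, s * np.exp(z * sigma))
    undefined = (s <= 0) | ~np.isfinite(sigma)
    lower[undefined] = np.nan
    upper[undefined] = np.nan
    t = surv.index.to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            "time": t,
            "n_risk": ev["at_risk"].to_numpy(),
            "n_event": ev["observed"].to_numpy(),
            "n_censor": ev["censored"].to_numpy(),
            "survival": s,
            "ci_lower": lower,
            "ci_upper": upper,
        }
    )
    # smallest observed time with S(t) <= 0.5 (inf when unattained); a small
    # tolerance keeps an exact product-limit 0.5 from being missed to rounding
    attained = s <= 0.5 + 1e-12
    median = float(t[attained.argmax()]) if attained.any() else float("inf")
    lo = _crossing_time(t, lower)
    hi = _crossing_time(t, upper)
    return KaplanMeierResult(table=table, median=median, median_ci=(lo, hi))
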