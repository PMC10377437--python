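"""Patient-level cohort data model, CSV I/O and eligibility filtering.

A :class:`PatientRecord` carries one patient's demographics, history flags,
pre-summarized laboratory/observation medians (the medians over the 3-6-month
post-index feature window), treatment-course day offsets and TE event times.
All dates are integer day offsets from an arbitrary per-cohort epoch; months
are converted at 30.4375 days. Missing lab/observation medians are represented
as absent (``None`` in records, ``NaN`` in matrices) and never as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375
#: half-open feature window "3-6 months post-index", in days post-index
FEATURE_WINDOW_DAYS = (91, 183)
#: half-open prediction window "6-18 months post-index", in days post-index
PREDICTION_WINDOW_DAYS = (183, 548)

LAB_KEYS = ("NEP", "LYP", "RDW", "WBC", "Hct", "HGB", "Plt")
OBS_KEYS = ("BMI", "DBP", "SBP", "weight", "height", "HRT", "RSP", "PLS")

#: variables addressable by name in feature matrices, synergy screening and
#: landscapes: flags/demographics plus every lab and observation median
NAMED_VARIABLES = ("te_history", "anticoag", "age") + LAB_KEYS + OBS_KEYS


class CohortSchemaError(ValueError):
    """The CSV is missing mandatory columns or is structurally unreadable."""


class EligibilityError(KeyError):
    """Eligibility flags are unavailable for a patient."""


@dataclass
class PatientRecord:
    """One patient: demographics, history, summarized labs, dates, TE outcome."""

    patient_id: str
    age_at_index: float
    sex: str
    race: str
    region: str
    te_history: bool
    n_phlebotomy: int
    anticoag_antiplatelet: bool
    smoking: bool
    alcohol: bool
    lab_medians: dict = field(default_factory=dict)
    obs_medians: dict = field(default_factory=dict)
    index_date: int = 0
    hu_first: int | None = None
    hu_last: int | None = None
    rux_first: int | None = None
    rux_last: int | None = None
    record_start: int = 0
    record_end: int = 0
    te_times: list = field(default_factory=list)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errs: list[str] = []
        if not (self.record_start <= self.index_date <= self.record_end):
            errs.append("index_date outside [record_start, record_end]")
        if self.hu_first is not None and self.hu_first != self.index_date:
            errs.append("hu_first must equal index_date when present")
        ts = list(self.te_times)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            errs.append("te_times not strictly increasing")
        if any(t < self.record_start or t > self.record_end for t in ts):
            errs.append("te_time outside [record_start, record_end]")
        for name, vals in (("lab", self.lab_medians), ("obs", self.obs_medians)):
            for k, v in vals.items():
                if v is not None and not (v > 0):
                    errs.append(f"{name} median {k} not strictly positive")
        return errs

    @property
    def is_switcher(self) -> bool:
        return self.rux_first is not None

    def variable(self, name: str) -> float:
        """Value of a named analysis variable; NaN when absent."""
        if name == "te_history":
            return float(self.te_history)
        if name == "anticoag":
            return float(self.anticoag_antiplatelet)
        if name == "age":
            return float(self.age_at_index)
        if name in LAB_KEYS:
            v = self.lab_medians.get(name)
        elif name in OBS_KEYS:
            v = self.obs_medians.get(name)
        else:
            raise KeyError(f"unknown variable {name!r}")
        return math.nan if v is None else float(v)


@dataclass
class Cohort:
    """Ordered collection of patients with a provenance label."""

    patients: list = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate patient_id in cohort {self.label!r}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.patients[i]

    def subset(self, keep: Iterable[PatientRecord], label: str | None = None) -> "Cohort":
        return Cohort(list(keep), self.label if label is None else label)

    def variable(self, name: str) -> np.ndarray:
        return np.array([p.variable(name) for p in self.patients], dtype=float)


@dataclass
class EligibilityCriteria:
    """Cohort-selection rules on abstracted per-patient fields and flags."""

    min_age: float = 18.0
    min_hu_prescriptions: int = 2
    exclude_mf_et: bool = True
    exclude_other_cytoreductives: bool = True
    min_hu_months: float = 0.0
    min_followup_months: float = 0.0
    require_lab_and_obs_in_window: bool = False
    feature_window: tuple = (3.0, 6.0)

    def __post_init__(self) -> None:
        if not self.feature_window[0] < self.feature_window[1]:
            raise ValueError("feature_window start must precede end")
        if self.min_hu_prescriptions < 0 or self.min_hu_months < 0 or self.min_followup_months < 0:
            raise ValueError("criteria counts must be >= 0")

    @classmethod
    def risk_model(cls) -> "EligibilityCriteria":
        """Criteria for the risk-model cohort: >=6 months HU, >=18 months
        follow-up, and at least one lab and one observation median in the
        3-6-month feature window."""
        return cls(
            min_hu_months=6.0,
            min_followup_months=18.0,
            require_lab_and_obs_in_window=True,
        )

    @classmethod
    def from_yaml(cls, path) -> "EligibilityCriteria":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "feature_window" in raw:
            raw["feature_window"] = tuple(raw["feature_window"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# CSV I/O

_MANDATORY = [
    "patient_id", "age_at_index", "sex", "race", "region", "te_history",
    "n_phlebotomy", "anticoag_antiplatelet", "smoking", "alcohol",
    "index_date", "record_start", "record_end", "te_times",
]
_OPTIONAL_DATES = ["hu_first", "hu_last", "rux_first", "rux_last"]


def _columns() -> list[str]:
    return (
        _MANDATORY[:10]
        + [f"lab_{k}" for k in LAB_KEYS]
        + [f"obs_{k}" for k in OBS_KEYS]
        + ["index_date"] + _OPTIONAL_DATES
        + ["record_start", "record_end", "te_times"]
    )


def _parse_bool(s: str) -> bool:
    return s.strip() in ("1", "True", "true", "yes")


def write_cohort(cohort: Cohort, path) -> None:
    rows = []
    for p in cohort:
        row: dict = {
            "patient_id": p.patient_id,
            "age_at_index": p.age_at_index,
            "sex": p.sex,
            "race": p.race,
            "region": p.region,
            "te_history": int(p.te_history),
            "n_phlebotomy": p.n_phlebotomy,
            "anticoag_antiplatelet": int(p.anticoag_antiplatelet),
            "smoking": int(p.smoking),
            "alcohol": int(p.alcohol),
        }
        for k in LAB_KEYS:
            row[f"lab_{k}"] = p.lab_medians.get(k)
        for k in OBS_KEYS:
            row[f"obs_{k}"] = p.obs_medians.get(k)
        row["index_date"] = p.index_date
        for k in _OPTIONAL_DATES:
            row[k] = getattr(p, k)
        row["record_start"] = p.record_start
        row["record_end"] = p.record_end
        row["te_times"] = ";".join(str(t) for t in p.te_times)
        rows.append(row)
    pd.DataFrame(rows, columns=_columns()).to_csv(path, index=False)


def read_cohort(path, schema_version: str = "1", label: str = "") -> Cohort:
    """Read a cohort CSV, enforcing record invariants row by row.

    Rows violating an invariant or failing to parse are rejected with a logged
    diagnostic naming the patient; the remaining rows load. A missing
    mandatory column raises :class:`CohortSchemaError`.
    """
    if schema_version != "1":
        raise CohortSchemaError(f"unknown schema_version {schema_version!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory columns: {missing}")
    if df.empty:
        logger.warning("cohort file %s contains a header but no rows", path)
        return Cohort([], label)

    patients: list[PatientRecord] = []
    for i, row in df.iterrows():
        pid = row["patient_id"] or f"<row {i}>"
        try:
            labs = {
                k: (float(row[f"lab_{k}"]) if row.get(f"lab_{k}", "") != "" else None)
                for k in LAB_KEYS
            }
            obs = {
                k: (float(row[f"obs_{k}"]) if row.get(f"obs_{k}", "") != "" else None)
                for k in OBS_KEYS
            }
            rec = PatientRecord(
                patient_id=row["patient_id"],
                age_at_index=float(row["age_at_index"]),
                sex=row["sex"],
                race=row["race"],
                region=row["region"],
                te_history=_parse_bool(row["te_history"]),
                n_phlebotomy=int(float(row["n_phlebotomy"])),
                anticoag_antiplatelet=_parse_bool(row["anticoag_antiplatelet"]),
                smoking=_parse_bool(row["smoking"]),
                alcohol=_parse_bool(row["alcohol"]),
                lab_medians=labs,
                obs_medians=obs,
                index_date=int(float(row["index_date"])),
                hu_first=_opt_int(row.get("hu_first", "")),
                hu_last=_opt_int(row.get("hu_last", "")),
                rux_first=_opt_int(row.get("rux_first", "")),
                rux_last=_opt_int(row.get("rux_last", "")),
                record_start=int(float(row["record_start"])),
                record_end=int(float(row["record_end"])),
                te_times=[int(float(t)) for t in row["te_times"].split(";") if t != ""],
            )
        except (ValueError, TypeError) as exc:
            logger.warning("row rejected (patient_id=%s): unparsable field: %s", pid, exc)
            continue
        errs = rec.validate()
        if errs:
            logger.warning("row rejected (patient_id=%s): %s", pid, "; ".join(errs))
            continue
        patients.append(rec)
    return Cohort(patients, label)


def _opt_int(s: str) -> int | None:
    s = (s or "").strip()
    return None if s == "" else int(float(s))


# ---------------------------------------------------------------------------
# Eligibility

def apply_eligibility(
    cohort: Cohort,
    criteria: EligibilityCriteria,
    flags: Mapping[str, Mapping],
) -> Cohort:
    """Filter a cohort by the selection rules.

    ``flags`` maps patient_id to ``{has_mf_et, has_other_cytoreductive,
    n_hu_prescriptions, n_rux_prescriptions}``; a patient without flags raises
    :class:`EligibilityError`.
    """
    keep = []
    for p in cohort:
        try:
            f = flags[p.patient_id]
        except KeyError:
            raise EligibilityError(
                f"no eligibility flags for patient {p.patient_id!r}"
            ) from None
        if p.age_at_index < criteria.min_age:
            continue
        n_rx = max(int(f["n_hu_prescriptions"]), int(f["n_rux_prescriptions"]))
        if n_rx < criteria.min_hu_prescriptions:
            continue
        if criteria.exclude_mf_et and f["has_mf_et"]:
            continue
        if criteria.exclude_other_cytoreductives and f["has_other_cytoreductive"]:
            continue
        if criteria.min_hu_months > 0:
            if p.hu_first is None or p.hu_last is None:
                continue
            if p.hu_last - p.hu_first < criteria.min_hu_months * DAYS_PER_MONTH:
                continue
        if criteria.min_followup_months > 0:
            if p.record_end - p.index_date < criteria.min_followup_months * DAYS_PER_MONTH:
                continue
        if criteria.require_lab_and_obs_in_window:
            if not any(v is not None for v in p.lab_medians.values()):
                continue
            if not any(v is not None for v in p.obs_medians.values()):
                continue
        keep.append(p)
    return cohort.subset(keep)


def feature_matrix(cohort: Cohort, names: Iterable[str]) -> pd.DataFrame:
    """Numeric matrix of named variables (rows = patients, NaN = missing)."""
    names = list(names)
    data = {n: cohort.variable(n) for n in names}
    return pd.DataFrame(data, index=[p.patient_id for p in cohort], columns=names)


def stratum_subset(cohort: Cohort, stratum: str) -> Cohort:
    """Filter by TE-history stratum: ``all``, ``with_te_history`` or
    ``without_te_history``."""
    if stratum == "all":
        return cohort
    if stratum == "with_te_history":
        return cohort.subset([p for p in cohort if p.te_history])
    if stratum == "without_te_history":
        return cohort.subset([p for p in cohort if not p.te_history])
    raise ValueError(f"unknown stratum {stratum!r}")


__all__ = [
    "Cohort",
    "CohortSchemaError",
    "DAYS_PER_MONTH",
    "EligibilityCriteria",
    "EligibilityError",
    "FEATURE_WINDOW_DAYS",
    "LAB_KEYS",
    "NAMED_VARIABLES",
    "OBS_KEYS",
    "PatientRecord",
    "PREDICTION_WINDOW_DAYS",
    "apply_eligibility",
    "feature_matrix",
    "read_cohort",
    "stratum_subset",
    "write_cohort",
]
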