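"""Synthetic EHR-like PV cohort generator.

Emulates the variable set of an abstracted hydroxyurea-treated polycythemia
vera cohort: demographics, TE history, anticoagulant/antiplatelet use,
laboratory and observation medians from the 3-6-month post-index window, HU /
ruxolitinib treatment-course dates, and recurrent TE event times.

Model
-----
* Continuous labs/observations are log-normal, parameters solved from target
  median and IQR (mu = ln median, sigma = ln(q3/q1)/1.349); neutrophil and
  lymphocyte percentages share a Gaussian copula with negative correlation
  (they are complementary parts of the differential count). Percentage-scale
  variables are capped at 100.
* Age is truncated normal (solved from median/IQR, truncated to [30, 97]).
* TE events follow a homogeneous Poisson process per period: before the index
  at rate ``baseline_hazard * exp(b_hist * te_history)``; after the index at
  rate ``baseline_hazard * exp(lp)`` where the log-hazard ``lp`` adds the TE
  history effect, anticoagulant use, age per decade, and planted quadrant
  interaction effects (e.g. NEP >= 72.05 AND RDW < 14.3). Quadrant indicators
  use the *true* lab values; missingness is applied afterwards as a purely
  observational mask.
* Censoring is administrative at record_end, itself the minimum of an
  administrative follow-up draw and an exponential dropout time.

Count draws go through the Poisson quantile function applied to per-patient
uniforms, so holding the seed fixed while raising an effect size re-uses
common random numbers and can only increase each patient's event count.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import Cohort, LAB_KEYS, OBS_KEYS, PatientRecord

DAYS_PER_YEAR = 365.25

#: target (median, q1, q3) emulating the US EHR model-development cohort
US_EHR_MARGINALS = {
    "NEP": (70.0, 62.0, 78.0),
    "LYP": (19.5, 13.0, 26.3),
    "RDW": (17.0, 14.5, 19.3),
    "WBC": (7.7, 5.9, 10.3),
    "Plt": (278.0, 203.0, 381.0),
    "Hct": (43.0, 39.7, 46.3),
    "HGB": (140.0, 130.0, 151.0),
    "age": (73.0, 64.0, 80.0),
    # observation medians: no published targets; declared realistic values
    # for an elderly US cohort (see docs/methods.md)
    "BMI": (29.0, 25.0, 33.5),
    "DBP": (76.0, 70.0, 82.0),
    "SBP": (131.0, 122.0, 141.0),
    "weight": (84.0, 71.0, 98.0),
    "height": (170.0, 163.0, 178.0),
    "HRT": (78.0, 70.0, 87.0),
    "RSP": (16.5, 15.0, 18.0),
    "PLS": (78.0, 70.0, 87.0),
}

#: targets emulating the independent community-registry validation cohort
REGISTRY_MARGINALS = {
    **US_EHR_MARGINALS,
    "NEP": (68.0, 60.0, 78.0),
    "LYP": (22.0, 14.8, 30.0),
    "RDW": (16.0, 14.3, 17.5),
    "WBC": (7.2, 6.0, 11.7),
    "Plt": (269.0, 200.0, 454.0),
    "Hct": (42.0, 40.0, 46.0),
    "HGB": (144.0, 129.0, 154.0),
    "age": (65.0, 56.0, 72.0),
}

US_EHR_PREVALENCES = {
    "te_history": 0.161,
    "anticoag": 0.48,
    "smoking": 0.128,
    "alcohol": 0.05,
    "female": 0.51,
}
REGISTRY_PREVALENCES = {
    "te_history": 0.32,
    "anticoag": 0.81,
    "smoking": 0.17,
    "alcohol": 0.05,
    "female": 0.45,
}

_PERCENT_VARS = {"NEP", "LYP", "Hct"}
_Z_IQR = stats.norm.ppf(0.75) - stats.norm.ppf(0.25)  # 1.349


@dataclass(frozen=True)
class QuadrantEffect:
    """Planted threshold-interaction: the log-hazard increment applies to
    patients in the quadrant defined by both conditions."""

    var1: str
    threshold1: float
    direction1: str  # ">=" or "<"
    var2: str
    threshold2: float
    direction2: str
    log_hr: float

    def indicator(self, values: dict) -> np.ndarray:
        c1 = _cond(values[self.var1], self.threshold1, self.direction1)
        c2 = _cond(values[self.var2], self.threshold2, self.direction2)
        return c1 & c2


def _cond(x: np.ndarray, thr: float, direction: str) -> np.ndarray:
    if direction == ">=":
        return x >= thr
    if direction == "<":
        return x < thr
    raise ValueError(f"unknown direction {direction!r}")


DEFAULT_INTERACTIONS = (
    QuadrantEffect("NEP", 72.05, ">=", "RDW", 14.3, "<", 0.8),
    QuadrantEffect("LYP", 19.3, "<", "RDW", 14.05, "<", 0.8),
)


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults emulate the model-development
    cohort's marginals with the planted hazard structure."""

    n_patients: int = 2000
    seed: int = 0
    label: str = "synthetic"
    marginals: dict = field(default_factory=lambda: dict(US_EHR_MARGINALS))
    prevalences: dict = field(default_factory=lambda: dict(US_EHR_PREVALENCES))
    baseline_hazard: float = 0.087  # TE events per patient-year
    log_hr: dict = field(
        default_factory=lambda: {"te_history": 0.9, "anticoag": 0.2, "age_per_decade": 0.1}
    )
    interactions: tuple = DEFAULT_INTERACTIONS
    nep_lyp_rho: float = -0.8
    missing_rate: float = 0.05
    dropout_rate: float = 0.05          # per patient-year
    followup_median_years: float = 4.0  # administrative, lognormal
    followup_sigma: float = 0.4
    pre_index_median_years: float = 3.0
    pre_index_sigma: float = 0.5
    pre_index_min_years: float = 1.1
    switcher_fraction: float = 0.0
    hu_duration_median_years: float = 2.0
    hu_duration_sigma: float = 0.6
    rux_duration_median_years: float = 1.5
    rux_duration_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        for name, p in self.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {name} outside [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate outside [0, 1]")
        known = set(LAB_KEYS) | set(OBS_KEYS)
        for q in self.interactions:
            for v, t in ((q.var1, q.threshold1), (q.var2, q.threshold2)):
                if v not in known:
                    raise ValueError(f"interaction references unknown variable {v!r}")
                lo, hi = 0.0, 10.0 * self.marginals[v][2]
                if not lo < t < hi:
                    raise ValueError(f"interaction threshold {t} implausible for {v}")


def validation_config(n_patients: int = 100, seed: int = 0, **overrides) -> GeneratorConfig:
    """Defaults switched to the external-registry marginals (higher TE-history
    prevalence, lower RDW), same planted interaction structure."""
    kw = dict(
        n_patients=n_patients,
        seed=seed,
        label="validation",
        marginals=dict(REGISTRY_MARGINALS),
        prevalences=dict(REGISTRY_PREVALENCES),
        followup_median_years=6.0,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    return float(np.log(median)), float(np.log(q3 / q1) / _Z_IQR)


def _draw_durations(rng, n, median_years, sigma) -> np.ndarray:
    if sigma == 0:
        return np.full(n, median_years * DAYS_PER_YEAR)
    mu, s = np.log(median_years), sigma
    return np.exp(rng.normal(mu, s, size=n)) * DAYS_PER_YEAR


def _poisson_counts(u: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Poisson counts via the quantile function (common random numbers)."""
    return stats.poisson.ppf(u, np.maximum(mean, 0.0)).astype(int)


def generate_cohort(config: GeneratorConfig, with_truth: bool = False):
    """Draw a reproducible synthetic cohort.

    With ``with_truth=True`` also returns a dict of the true (pre-missingness)
    variable arrays plus the post-index log-hazard ``lp`` — useful as an
    oracle in recovery experiments.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # --- continuous variables via Gaussian copula ------------------------
    cont_vars = [v for v in US_EHR_MARGINALS if v != "age"]
    z = rng.standard_normal((n, len(cont_vars)))
    i_nep, i_lyp = cont_vars.index("NEP"), cont_vars.index("LYP")
    rho = config.nep_lyp_rho
    z[:, i_lyp] = rho * z[:, i_nep] + np.sqrt(1 - rho**2) * z[:, i_lyp]
    values: dict[str, np.ndarray] = {}
    for j, v in enumerate(cont_vars):
        mu, s = _lognormal_params(*config.marginals[v])
        x = np.exp(mu + s * z[:, j])
        if v in _PERCENT_VARS:
            x = np.minimum(x, 100.0)
        values[v] = x

    med, q1, q3 = config.marginals["age"]
    s_age = (q3 - q1) / _Z_IQR
    a, b = (30.0 - med) / s_age, (97.0 - med) / s_age
    age = stats.truncnorm.rvs(a, b, loc=med, scale=s_age, size=n, random_state=rng)

    # --- flags -----------------------------------------------------------
    prev = config.prevalences
    te_history = rng.random(n) < prev["te_history"]
    anticoag = rng.random(n) < prev["anticoag"]
    smoking = rng.random(n) < prev["smoking"]
    alcohol = rng.random(n) < prev["alcohol"]
    female = rng.random(n) < prev["female"]
    race = rng.choice(
        ["White", "Black", "Asian", "Other"], size=n, p=[0.80, 0.10, 0.03, 0.07]
    )
    region = rng.choice(
        ["Northeast", "Midwest", "South", "West"], size=n, p=[0.22, 0.26, 0.33, 0.19]
    )
    n_phleb = rng.poisson(1.5, size=n)

    # --- record timeline -------------------------------------------------
    pre_days = np.maximum(
        _draw_durations(rng, n, config.pre_index_median_years, config.pre_index_sigma),
        config.pre_index_min_years * DAYS_PER_YEAR,
    )
    admin = _draw_durations(rng, n, config.followup_median_years, config.followup_sigma)
    if config.dropout_rate > 0:
        dropout = rng.exponential(1.0 / config.dropout_rate, size=n) * DAYS_PER_YEAR
        post_days = np.minimum(admin, dropout)
    else:
        post_days = admin
    post_days = np.maximum(post_days, 30.0)
    index_date = np.round(pre_days).astype(int)
    record_end = index_date + np.round(post_days).astype(int)

    switcher = rng.random(n) < config.switcher_fraction
    hu_dur = _draw_durations(rng, n, config.hu_duration_median_years, config.hu_duration_sigma)
    rux_dur = _draw_durations(rng, n, config.rux_duration_median_years, config.rux_duration_sigma)
    hu_last = np.minimum(index_date + np.round(hu_dur).astype(int), record_end)
    rux_first = np.minimum(hu_last + 1, record_end)
    rux_last = np.minimum(rux_first + np.round(rux_dur).astype(int), record_end)

    # --- planted hazard --------------------------------------------------
    lhr = config.log_hr
    lp = (
        lhr.get("te_history", 0.0) * te_history
        + lhr.get("anticoag", 0.0) * anticoag
        + lhr.get("age_per_decade", 0.0) * (age - med) / 10.0
    )
    for q in config.interactions:
        lp = lp + q.log_hr * q.indicator(values)

    rate_pre = config.baseline_hazard * np.exp(lhr.get("te_history", 0.0) * te_history)
    rate_post = config.baseline_hazard * np.exp(lp)

    u_pre = rng.random(n)
    u_post = rng.random(n)
    n_pre = _poisson_counts(u_pre, rate_pre * index_date / DAYS_PER_YEAR)
    n_post = _poisson_counts(u_post, rate_post * (record_end - index_date) / DAYS_PER_YEAR)

    # --- missingness mask (observation only, after the hazard is set) ----
    missing = {
        v: rng.random(n) < config.missing_rate for v in cont_vars
    }

    patients = []
    for i in range(n):
        te: set[int] = set()
        if n_pre[i] > 0:
            te.update(rng.integers(0, index_date[i], size=n_pre[i]).tolist())
        if n_post[i] > 0:
            te.update(
                rng.integers(index_date[i], record_end[i], size=n_post[i]).tolist()
            )
        labs = {
            k: (None if missing[k][i] else round(float(values[k][i]), 2))
            for k in LAB_KEYS
        }
        obs = {
            k: (None if missing[k][i] else round(float(values[k][i]), 2))
            for k in OBS_KEYS
        }
        patients.append(
            PatientRecord(
                patient_id=f"{config.label}-{i:06d}",
                age_at_index=round(float(age[i]), 1),
                sex="F" if female[i] else "M",
                race=str(race[i]),
                region=str(region[i]),
                te_history=bool(te_history[i]),
                n_phlebotomy=int(n_phleb[i]),
                anticoag_antiplatelet=bool(anticoag[i]),
                smoking=bool(smoking[i]),
                alcohol=bool(alcohol[i]),
                lab_medians=labs,
                obs_medians=obs,
                index_date=int(index_date[i]),
                hu_first=int(index_date[i]),
                hu_last=int(hu_last[i]),
                rux_first=int(rux_first[i]) if switcher[i] else None,
                rux_last=int(rux_last[i]) if switcher[i] else None,
                record_start=0,
                record_end=int(record_end[i]),
                te_times=sorted(te),
            )
        )
    cohort = Cohort(patients, config.label)
    if not with_truth:
        return cohort
    truth = {**{k: values[k] for k in cont_vars}, "age": age, "lp": lp,
             "te_history": te_history, "rate_post": rate_post}
    return cohort, truth


def generate_validation_cohort(config: GeneratorConfig | None = None, **overrides):
    """Cohort with the external-registry defaults (n=100 unless overridden)."""
    if config is None:
        config = validation_config(**overrides)
    return generate_cohort(config)


def default_flags(cohort: Cohort) -> dict:
    """Plausible eligibility flags for a synthetic cohort (deterministic):
    roughly monthly prescriptions over each treatment course, no competing
    diagnoses."""
    flags = {}
    for p in cohort:
        hu_months = 0.0
        if p.hu_first is not None and p.hu_last is not None:
            hu_months = (p.hu_last - p.hu_first) / 30.4375
        rux_months = 0.0
        if p.rux_first is not None and p.rux_last is not None:
            rux_months = (p.rux_last - p.rux_first) / 30.4375
        flags[p.patient_id] = {
            "has_mf_et": False,
            "has_other_cytoreductive": False,
            "n_hu_prescriptions": max(2, int(hu_months)),
            "n_rux_prescriptions": max(2, int(rux_months)) if p.rux_first is not None else 0,
        }
    return flags


def planted_parameters(config: GeneratorConfig) -> dict:
    """JSON-serializable record of the true planted parameters (sidecar)."""
    d = dataclasses.asdict(config)
    d["interactions"] = [dataclasses.asdict(q) for q in config.interactions]
    return d


def write_sidecar(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(planted_parameters(config), fh, indent=2)


__all__ = [
    "REGISTRY_MARGINALS",
    "REGISTRY_PREVALENCES",
    "DEFAULT_INTERACTIONS",
    "GeneratorConfig",
    "US_EHR_MARGINALS",
    "US_EHR_PREVALENCES",
    "QuadrantEffect",
    "default_flags",
    "generate_cohort",
    "generate_validation_cohort",
    "planted_parameters",
    "validation_config",
    "write_sidecar",
]
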