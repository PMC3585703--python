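"""Synthetic perinatal cohort generator.

Emulates the error structure of a public-sector antenatal cohort in which GA
must be reconstructed from imperfect sources:

* **True GA at birth** is drawn from a three-component mixture (preterm /
  term / postterm) of truncated normals; the true LMP date follows from the
  birth date.
* **LMP recall**: available for ~97.4% of women, reported as *certain* by
  ~76.9% of those. Certain dates carry a small symmetric day error;
  uncertain dates carry a wider error and, with some probability, a
  whole-month slip — predominantly toward a *later* reported LMP (the woman
  recalls the first month her period failed to occur rather than her actual
  last period), which underestimates GA and inflates the apparent preterm
  rate. Month slips move the date by the actual calendar month length, not
  a fixed 30 days.
* **Ultrasound**: each gestational window (7-20 w, 21-28 w, 29+ w) is
  independently available with its own probability; the exam is scheduled
  uniformly inside the window (truncated below the birth) and the
  clinician's GA at exam is the true GA plus a window-specific Gaussian
  error — small early, large in the third trimester.
* **Capurro exam**: available for ~87.5%; its estimate is pulled toward a
  term target (shrink × (target − true GA)) plus noise, reproducing the
  characteristic overestimation of GA for preterm and underestimation for
  post-term newborns.
* **Birth weight** is drawn from the same growth reference used for
  Z-scoring (mean + Gaussian with the reference SD), so the outlier
  machinery is self-consistent; rare gross transcription errors replace the
  weight with an implausible value.

Determinism: one top-level seed; each record's draws come from a substream
derived from (seed, record index), so cohort size and insertion order never
perturb the draws of other records.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from calendar import monthrange
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from gestage.dating import US_29P_START, WINDOW_BOUNDS
from gestage.errors import JoinError
from gestage.growth import GrowthReference, default_reference
from gestage.records import (
    COVARIATE_LEVELS,
    MaturityClass,
    Method,
    PregnancyRecord,
    Sex,
    UltrasoundExam,
    Window,
)

_WINDOWS = (Window.US_7_20, Window.US_21_28, Window.US_29P)


class MixtureComponent(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean_days: float
    sd_days: float = Field(ge=0)
    lo_days: int
    hi_days: int


class GADistribution(BaseModel):
    """True GA-at-birth mixture; proportions must sum to 1."""

    model_config = ConfigDict(extra="forbid")
    p_preterm: float = Field(ge=0, le=1, default=0.125)
    p_term: float = Field(ge=0, le=1, default=0.855)
    p_postterm: float = Field(ge=0, le=1, default=0.020)
    preterm: MixtureComponent = MixtureComponent(
        mean_days=247, sd_days=16, lo_days=168, hi_days=258
    )
    term: MixtureComponent = MixtureComponent(
        mean_days=276, sd_days=8, lo_days=259, hi_days=293
    )
    postterm: MixtureComponent = MixtureComponent(
        mean_days=297, sd_days=3, lo_days=294, hi_days=308
    )

    @model_validator(mode="after")
    def _props_sum(self) -> "GADistribution":
        total = self.p_preterm + self.p_term + self.p_postterm
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, not 1")
        return self


class LMPError(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sd_sure_days: float = Field(ge=0, default=3.0)
    sd_unsure_days: float = Field(ge=0, default=7.0)
    month_slip_p: float = Field(ge=0, le=1, default=0.25)
    #: probability a slip is toward a *later* reported LMP (GA underestimated)
    slip_late_p: float = Field(ge=0, le=1, default=0.8)


class CapurroError(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shrink: float = Field(ge=0, le=1, default=0.4)
    target_days: int = 273
    noise_sd_days: float = Field(ge=0, default=6.0)


class SimulationConfig(BaseModel):
    """All knobs of the cohort generator; probabilities in [0,1], SDs in
    days unless noted. Defaults mirror the packaged
    ``data/default_config.yaml``."""

    model_config = ConfigDict(extra="forbid")

    n: int = Field(ge=0, default=1483)
    seed: int = 0
    ga: GADistribution = GADistribution()
    lmp_available_p: float = Field(ge=0, le=1, default=0.974)
    lmp_certain_p: float = Field(ge=0, le=1, default=0.769)
    lmp_error: LMPError = LMPError()
    #: availability per ultrasound window (7-20 w, 21-28 w, 29+ w)
    us_window_p: tuple[float, float, float] = (0.786, 0.598, 0.617)
    #: clinician GA error SD per window, days
    us_error_sd_days: tuple[float, float, float] = (4.0, 8.0, 14.0)
    capurro_available_p: float = Field(ge=0, le=1, default=0.875)
    capurro: CapurroError = CapurroError()
    weight_noise_sd_multiplier: float = Field(ge=0, default=1.0)
    gross_error_p: float = Field(ge=0, le=1, default=0.01)
    sex_male_p: float = Field(ge=0, le=1, default=0.51)
    #: per-covariate category probabilities (same order as the level tuples)
    covariate_p: dict[str, list[float]] = {
        "city": [0.58, 0.42],
        "age_group": [0.22, 0.69, 0.09],
        "ethnicity": [0.36, 0.42, 0.22],
        "schooling": [0.13, 0.44, 0.43],
        "marital": [0.75, 0.25],
        "parity": [0.45, 0.42, 0.13],
    }
    lmp_start: dt.date = dt.date(2007, 3, 1)
    lmp_span_days: int = 365

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for p in self.us_window_p:
            if not 0 <= p <= 1:
                raise ValueError(f"us_window_p entry {p} outside [0,1]")
        for sd in self.us_error_sd_days:
            if sd < 0:
                raise ValueError("us_error_sd_days must be >= 0")
        for name, probs in self.covariate_p.items():
            levels = COVARIATE_LEVELS.get(name)
            if levels is None:
                raise ValueError(f"unknown covariate '{name}'")
            if len(probs) != len(levels):
                raise ValueError(
                    f"covariate '{name}' needs {len(levels)} probabilities"
                )
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"covariate '{name}' probabilities must sum to 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.pop("schema_version", None)
        return cls.model_validate(payload)

    @classmethod
    def default(cls, **overrides) -> "SimulationConfig":
        """The packaged default configuration with optional overrides."""
        cfg = cls.from_yaml(Path(__file__).parent / "data" / "default_config.yaml")
        if not overrides:
            return cfg
        payload = cfg.model_dump()
        payload.update(overrides)
        return cls.model_validate(payload)

    @classmethod
    def noiseless(cls, n: int = 500, seed: int = 0) -> "SimulationConfig":
        """Degenerate zero-error limit: every source available, every error
        SD and slip probability zero — each method's estimate equals the
        true GA exactly."""
        return cls.default(
            n=n,
            seed=seed,
            lmp_available_p=1.0,
            lmp_certain_p=1.0,
            lmp_error=LMPError(sd_sure_days=0, sd_unsure_days=0, month_slip_p=0),
            us_window_p=(1.0, 1.0, 1.0),
            us_error_sd_days=(0.0, 0.0, 0.0),
            capurro_available_p=1.0,
            capurro=CapurroError(shrink=0.0, noise_sd_days=0.0),
            weight_noise_sd_multiplier=0.0,
            gross_error_p=0.0,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _add_months(day: dt.date, months: int) -> dt.date:
    """Shift a date by whole calendar months, clamping the day-of-month to
    the target month's length (so the slip distance is the actual month
    length, 28-31 days)."""
    month_index = day.month - 1 + months
    year = day.year + month_index // 12
    month = month_index % 12 + 1
    dom = min(day.day, monthrange(year, month)[1])
    return dt.date(year, month, dom)


def _truncated_normal_int(
    rng: np.random.Generator, comp: MixtureComponent
) -> int:
    for _ in range(1000):
        x = int(round(rng.normal(comp.mean_days, comp.sd_days)))
        if comp.lo_days <= x <= comp.hi_days:
            return x
    return int(np.clip(round(comp.mean_days), comp.lo_days, comp.hi_days))


def _record_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def generate(
    config: SimulationConfig,
    growth_ref: GrowthReference | None = None,
) -> tuple[list[PregnancyRecord], pd.DataFrame]:
    """Generate a cohort and its hidden truth table.

    Returns the records and a frame ``id,true_ga_days,true_class``. Same
    config (including seed) ⇒ bit-identical output.
    """
    ref = growth_ref if growth_ref is not None else default_reference()
    records: list[PregnancyRecord] = []
    truth_rows = []
    cov_levels = {k: COVARIATE_LEVELS[k] for k in config.covariate_p}

    for i in range(config.n):
        rng = _record_rng(config.seed, i)
        rid = f"P{i:05d}"

        u = rng.random()
        ga_dist = config.ga
        if u < ga_dist.p_preterm:
            comp, true_class = ga_dist.preterm, MaturityClass.PRETERM
        elif u < ga_dist.p_preterm + ga_dist.p_term:
            comp, true_class = ga_dist.term, MaturityClass.TERM
        else:
            comp, true_class = ga_dist.postterm, MaturityClass.POSTTERM
        true_ga = _truncated_normal_int(rng, comp)

        true_lmp = config.lmp_start + dt.timedelta(
            days=int(rng.integers(0, config.lmp_span_days))
        )
        birth_date = true_lmp + dt.timedelta(days=true_ga)

        sex = Sex.MALE if rng.random() < config.sex_male_p else Sex.FEMALE
        covariates = {
            name: cov_levels[name][
                int(rng.choice(len(probs), p=np.asarray(probs) / sum(probs)))
            ]
            for name, probs in config.covariate_p.items()
        }

        # --- LMP recall -----------------------------------------------------
        lmp_date: dt.date | None = None
        lmp_certain: bool | None = None
        if rng.random() < config.lmp_available_p:
            lmp_certain = rng.random() < config.lmp_certain_p
            err_cfg = config.lmp_error
            sd = err_cfg.sd_sure_days if lmp_certain else err_cfg.sd_unsure_days
            observed = true_lmp
            if not lmp_certain and rng.random() < err_cfg.month_slip_p:
                direction = 1 if rng.random() < err_cfg.slip_late_p else -1
                observed = _add_months(observed, direction)
            if sd > 0:
                observed = observed + dt.timedelta(
                    days=int(round(rng.normal(0.0, sd)))
                )
            # keep the report biologically interpretable (GA >= 20 w)
            latest = birth_date - dt.timedelta(days=140)
            lmp_date = min(observed, latest)

        # --- ultrasound exams ----------------------------------------------
        exams: list[UltrasoundExam] = []
        for w_index, window in enumerate(_WINDOWS):
            if rng.random() >= config.us_window_p[w_index]:
                continue
            lo, hi = (
                WINDOW_BOUNDS[window]
                if window in WINDOW_BOUNDS
                else (US_29P_START, US_29P_START + 77)
            )
            hi = min(hi, true_ga - 1)
            if hi < lo:
                continue  # birth occurred before this window
            exam_true_ga = int(rng.integers(lo, hi + 1))
            sd = config.us_error_sd_days[w_index]
            reported = exam_true_ga + (
                int(round(rng.normal(0.0, sd))) if sd > 0 else 0
            )
            reported = int(np.clip(reported, 0, 315))
            exam_date = birth_date - dt.timedelta(days=true_ga - exam_true_ga)
            exams.append(
                UltrasoundExam(exam_date=exam_date, ga_at_exam_days=reported)
            )

        # --- Capurro exam ---------------------------------------------------
        capurro_ga: int | None = None
        if rng.random() < config.capurro_available_p:
            cap = config.capurro
            value = true_ga + cap.shrink * (cap.target_days - true_ga)
            if cap.noise_sd_days > 0:
                value += rng.normal(0.0, cap.noise_sd_days)
            capurro_ga = int(np.clip(round(value), 140, 315))

        # --- birth weight ---------------------------------------------------
        mean, sd_w = ref.lookup(sex, true_ga // 7)
        weight = mean + (
            rng.normal(0.0, sd_w * config.weight_noise_sd_multiplier)
            if config.weight_noise_sd_multiplier > 0
            else 0.0
        )
        if rng.random() < config.gross_error_p:
            weight = float(rng.uniform(250.0, 6000.0))
        weight = float(max(weight, 250.0))

        records.append(
            PregnancyRecord(
                id=rid,
                birth_date=birth_date,
                birth_weight_g=round(weight, 1),
                infant_sex=sex,
                lmp_date=lmp_date,
                lmp_certain=lmp_certain,
                us_exams=exams,
                capurro_ga_days=capurro_ga,
                covariates=covariates,
            )
        )
        truth_rows.append(
            {"id": rid, "true_ga_days": true_ga, "true_class": true_class.value}
        )

    truth = pd.DataFrame(truth_rows, columns=["id", "true_ga_days", "true_class"])
    return records, truth


def truth_join(
    records: list[PregnancyRecord],
    truth: pd.DataFrame,
    assignments: list | None = None,
) -> pd.DataFrame:
    """Evaluation table joining observed records with the hidden truth.

    One row per record: true GA/class, per-method GA estimate error in days
    (estimate − truth; NaN where the source is absent), and — when
    ``assignments`` (a list of AlgorithmResult) is given — the assigned GA
    and whether the assigned maturity class matches the true class.

    Raises JoinError when ids do not align exactly.
    """
    from gestage.dating import classify_maturity, gather_estimates

    truth_ids = set(truth["id"])
    record_ids = {r.id for r in records}
    if truth_ids != record_ids:
        missing = sorted(record_ids - truth_ids)[:5]
        extra = sorted(truth_ids - record_ids)[:5]
        raise JoinError(
            f"id mismatch between cohort and truth (missing from truth: "
            f"{missing}; extra in truth: {extra})"
        )
    truth_map = truth.set_index("id")

    assign_map = {}
    if assignments is not None:
        assign_map = {a.id: a for a in assignments}
        if set(assign_map) != record_ids:
            raise JoinError("id mismatch between cohort and assignments")

    rows = []
    for r in records:
        true_ga = int(truth_map.loc[r.id, "true_ga_days"])
        ests, _ = gather_estimates(r)
        row: dict = {
            "id": r.id,
            "true_ga_days": true_ga,
            "true_class": truth_map.loc[r.id, "true_class"],
        }
        for m in Method:
            est = ests.get(m)
            row[f"err_{m.value}"] = (
                est.ga_at_birth_days - true_ga if est is not None else np.nan
            )
        if assignments is not None:
            a = assign_map[r.id]
            row["assigned_ga_days"] = (
                a.ga_at_birth_days if a.ga_at_birth_days is not None else np.nan
            )
            row["assigned_class"] = (
                classify_maturity(a.ga_at_birth_days).value
                if a.ga_at_birth_days is not None
                else None
            )
            row["class_correct"] = (
                row["assigned_class"] == row["true_class"]
                if row["assigned_class"] is not None
                else None
            )
        rows.append(row)
    return pd.DataFrame(rows)
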