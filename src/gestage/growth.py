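"""Birthweight-for-GA Z-scores against a sex-specific intrauterine growth
reference, and the ±3 SD outlier rule used to flag implausible GA/weight
combinations.

The reference is a table keyed by (sex, completed GA week 22-44) giving the
mean and SD of birth weight in grams. Any table in the documented CSV schema
(``sex,week,mean_g,sd_g``) can be supplied; the bundled default is a
SYNTHETIC parametric stand-in (per-sex logistic-shaped median curve with SD a
fixed coefficient of variation of the mean), intended for simulation and
testing, not for clinical scoring against a published standard.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from gestage.errors import DomainError, ReferenceValidationError
from gestage.records import Sex

logger = logging.getLogger(__name__)

WEEK_MIN = 22
WEEK_MAX = 44
OUTLIER_SD = 3.0

#: Default parametric stand-in: mean(w) = limit / (1 + exp(-rate*(w - midpoint)))
DEFAULT_CURVE_PARAMS = {
    Sex.MALE: {"limit_g": 3900.0, "rate": 0.22, "midpoint_week": 31.0},
    Sex.FEMALE: {"limit_g": 3750.0, "rate": 0.22, "midpoint_week": 31.0},
}
DEFAULT_CV = 0.12


class WeightCategory(str, Enum):
    LOW_OUTLIER = "low_outlier"  # z < -3
    INTERIOR = "interior"
    HIGH_OUTLIER = "high_outlier"  # z > +3


@dataclass(frozen=True)
class ZScoreResult:
    """Birthweight-for-GA Z-score with its ±3 SD category."""

    z: float
    category: WeightCategory


@dataclass
class GrowthReference:
    """Sex × completed-GA-week table of birthweight mean and SD (grams).

    ``table`` is indexed by (sex value, week) with columns ``mean_g`` and
    ``sd_g``. Construct through :func:`load_reference` or
    :func:`default_reference`, which validate the invariants.
    """

    table: pd.DataFrame
    source: str = "unspecified"
    _week_range: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for sex in self.table.index.get_level_values(0).unique():
            weeks = self.table.loc[sex].index
            self._week_range[sex] = (int(weeks.min()), int(weeks.max()))

    def lookup(self, sex: Sex, week: int) -> tuple[float, float]:
        """(mean_g, sd_g) at a completed week, clamping out-of-range weeks
        to the nearest table row with a logged warning."""
        lo, hi = self._week_range[sex.value]
        clamped = min(max(week, lo), hi)
        if clamped != week:
            logger.warning(
                "GA week %d outside reference range [%d, %d] for %s; "
                "clamped to %d",
                week, lo, hi, sex.value, clamped,
            )
        row = self.table.loc[(sex.value, clamped)]
        return float(row["mean_g"]), float(row["sd_g"])


def _validate(table: pd.DataFrame, source: str) -> None:
    bad: list[tuple] = []
    for sex in table.index.get_level_values(0).unique():
        sub = table.loc[sex].sort_index()
        for week, row in sub.iterrows():
            if not row["sd_g"] > 0:
                bad.append((sex, int(week), "sd_g must be > 0"))
            if not row["mean_g"] > 0:
                bad.append((sex, int(week), "mean_g must be > 0"))
        # mean strictly increasing over weeks 22-42 for each sex
        core = sub.loc[(sub.index >= WEEK_MIN) & (sub.index <= 42), "mean_g"]
        diffs = core.diff().dropna()
        for week in diffs.index[diffs <= 0]:
            bad.append((sex, int(week), "mean_g not strictly increasing"))
    if bad:
        raise ReferenceValidationError(
            f"growth reference '{source}' failed validation "
            f"({len(bad)} offending rows)",
            rows=bad,
        )


def default_reference(cv: float = DEFAULT_CV) -> GrowthReference:
    """The bundled synthetic stand-in reference.

    Per-sex logistic median weight over weeks 22-44, SD = ``cv`` × mean.
    Shape parameters give ~470 g at 22 w and ~3430 g at 40 w for males,
    which is in the plausible range for a liveborn intrauterine curve.
    """
    rows = []
    for sex, p in DEFAULT_CURVE_PARAMS.items():
        for week in range(WEEK_MIN, WEEK_MAX + 1):
            mean = p["limit_g"] / (
                1.0 + math.exp(-p["rate"] * (week - p["midpoint_week"]))
            )
            rows.append(
                {
                    "sex": sex.value,
                    "week": week,
                    "mean_g": round(mean, 1),
                    "sd_g": round(cv * mean, 1),
                }
            )
    table = pd.DataFrame(rows).set_index(["sex", "week"])
    _validate(table, "synthetic-default")
    return GrowthReference(table=table, source="synthetic-default")


def load_reference(path: str | Path | None = None) -> GrowthReference:
    """Load a reference table from CSV, or the bundled default if ``path``
    is ``None``. Schema: header ``sex,week,mean_g,sd_g``; sex in
    {male, female}; week integer. Raises ReferenceValidationError listing
    every offending row if an invariant fails."""
    if path is None:
        return default_reference()
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    expected = {"sex", "week", "mean_g", "sd_g"}
    if set(df.columns) != expected:
        raise ReferenceValidationError(
            f"growth reference '{path}': columns {sorted(df.columns)} != "
            f"{sorted(expected)}"
        )
    unknown_sex = set(df["sex"]) - {s.value for s in Sex}
    if unknown_sex:
        raise ReferenceValidationError(
            f"growth reference '{path}': unknown sex values {sorted(unknown_sex)}"
        )
    df["week"] = df["week"].astype(int)
    table = df.set_index(["sex", "week"]).sort_index()
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].tolist()
        raise ReferenceValidationError(
            f"growth reference '{path}': duplicate rows", rows=dups
        )
    _validate(table, str(path))
    return GrowthReference(table=table, source=str(path))


def save_reference(ref: GrowthReference, path: str | Path) -> None:
    """Write a reference as CSV in the documented schema; save/load
    round-trips bit-identically."""
    ref.table.sort_index().reset_index().to_csv(path, index=False)


def zscore(
    weight_g: float, ga_days: int, sex: Sex, ref: GrowthReference
) -> ZScoreResult:
    """Birthweight-for-GA Z-score: (weight − mean(sex, week)) / sd(sex, week).

    The completed week is ``ga_days // 7``, clamped into the reference range.
    Category is strict-threshold: low if z < −3, high if z > +3.
    """
    if weight_g <= 0:
        raise DomainError(f"non-positive birth weight: {weight_g}")
    if ga_days < 0:
        raise DomainError(f"negative GA: {ga_days}")
    mean, sd = ref.lookup(sex, ga_days // 7)
    z = (weight_g - mean) / sd
    if z < -OUTLIER_SD:
        category = WeightCategory.LOW_OUTLIER
    elif z > OUTLIER_SD:
        category = WeightCategory.HIGH_OUTLIER
    else:
        category = WeightCategory.INTERIOR
    return ZScoreResult(z=z, category=category)


def is_excluded_outlier(result: ZScoreResult, strict: bool = False) -> bool:
    """Whether a Z-score triggers analysis exclusion.

    Default (inclusive) rule: |z| >= 3, matching the exclusion convention
    "<= −3 SD and >= +3 SD". With ``strict=True`` the boundary values ±3.0
    are kept (|z| > 3).
    """
    if strict:
        return abs(result.z) > OUTLIER_SD
    return abs(result.z) >= OUTLIER_SD
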