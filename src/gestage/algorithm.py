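"""Hierarchical best-estimate assignment of GA at birth.

Dating sources are walked in a fixed priority order — early ultrasound
(7-20 w), then 21-28 w ultrasound, then 29+ w ultrasound, then LMP; the
Capurro exam is excluded from the default priority because of its poor
agreement on prematurity. For each candidate source the newborn's
birthweight-for-GA Z-score is computed *under that source's GA*; the first
candidate whose Z-score is not an excluded outlier is assigned. A record
whose every available source is missing, invalid, or an outlier remains
unclassified — a valid outcome, not an error.

The outlier rule is re-checked at each fall-through step: a birthweight can
be implausible under one source's GA and plausible under another's, which is
exactly the misdating signal the Z-score screen is meant to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from gestage.dating import gather_estimates
from gestage.growth import GrowthReference, is_excluded_outlier, zscore
from gestage.records import Method, PregnancyRecord

DEFAULT_PRIORITY: tuple[Method, ...] = (
    Method.US_7_20,
    Method.US_21_28,
    Method.US_29P,
    Method.LMP,
)

#: exclusion-trail reasons
REASON_MISSING = "missing"
REASON_OUTLIER = "outlier"
REASON_INVALID = "invalid"


@dataclass(frozen=True)
class AlgorithmResult:
    """Outcome of the hierarchical assignment for one record."""

    id: str
    status: str  # "classified" | "unclassified"
    assigned_method: Method | None
    ga_at_birth_days: int | None
    exclusion_trail: tuple[tuple[Method, str], ...]

    @property
    def classified(self) -> bool:
        return self.status == "classified"


@dataclass
class EntranceTally:
    """Counts of records admitted via each entrance criterion."""

    n: int = 0
    by_method: dict[Method, int] = field(default_factory=dict)
    unclassified: int = 0

    def percent(self, method: Method) -> float:
        return 100.0 * self.by_method.get(method, 0) / self.n if self.n else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "criterion": m.value,
                "count": self.by_method.get(m, 0),
                "percent": round(self.percent(m), 1),
            }
            for m in self.by_method
        ]
        rows.append(
            {
                "criterion": "unclassified",
                "count": self.unclassified,
                "percent": round(100.0 * self.unclassified / self.n, 1)
                if self.n
                else 0.0,
            }
        )
        return pd.DataFrame(rows, columns=["criterion", "count", "percent"])


def assign(
    record: PregnancyRecord,
    ref: GrowthReference,
    priority: tuple[Method, ...] = DEFAULT_PRIORITY,
    *,
    check_outliers: bool = True,
    strict_outliers: bool = False,
    require_certain_lmp: bool = False,
) -> AlgorithmResult:
    """Walk the priority list and assign the first non-outlier estimate.

    Parameters
    ----------
    priority
        Ordered method labels; must be non-empty. Capurro may be appended
        for sensitivity analyses.
    check_outliers
        If False the first available estimate is always assigned.
    require_certain_lmp
        If True the LMP step only admits records whose LMP was reported
        as certain; uncertain/unknown LMPs count as missing.
    """
    if not priority:
        raise ValueError("priority list must be non-empty")
    estimates, invalid = gather_estimates(record)
    trail: list[tuple[Method, str]] = []
    for method in priority:
        if method in invalid:
            trail.append((method, REASON_INVALID))
            continue
        if method is Method.LMP and require_certain_lmp and not record.lmp_certain:
            trail.append((method, REASON_MISSING))
            continue
        estimate = estimates.get(method)
        if estimate is None:
            trail.append((method, REASON_MISSING))
            continue
        if check_outliers:
            result = zscore(
                record.birth_weight_g,
                estimate.ga_at_birth_days,
                record.infant_sex,
                ref,
            )
            if is_excluded_outlier(result, strict=strict_outliers):
                trail.append((method, REASON_OUTLIER))
                continue
        return AlgorithmResult(
            id=record.id,
            status="classified",
            assigned_method=method,
            ga_at_birth_days=estimate.ga_at_birth_days,
            exclusion_trail=tuple(trail),
        )
    return AlgorithmResult(
        id=record.id,
        status="unclassified",
        assigned_method=None,
        ga_at_birth_days=None,
        exclusion_trail=tuple(trail),
    )


def assign_cohort(
    records: list[PregnancyRecord],
    ref: GrowthReference,
    priority: tuple[Method, ...] = DEFAULT_PRIORITY,
    **kwargs,
) -> tuple[list[AlgorithmResult], EntranceTally]:
    """Per-record assignment plus the entrance tally.

    The tally counts, for each entrance criterion, how many newborns were
    admitted through it, and how many remained unclassified; counts always
    sum to the cohort size.
    """
    results = [assign(r, ref, priority, **kwargs) for r in records]
    tally = EntranceTally(n=len(records), by_method={m: 0 for m in priority})
    for res in results:
        if res.classified:
            assert res.assigned_method is not None
            tally.by_method[res.assigned_method] = (
                tally.by_method.get(res.assigned_method, 0) + 1
            )
        else:
            tally.unclassified += 1
    return results, tally


def results_to_frame(results: list[AlgorithmResult]) -> pd.DataFrame:
    """Tidy frame of assignments: id, status, assigned_method, ga_days,
    ga_weeks, excluded_methods (semicolon-joined ``method:reason`` pairs)."""
    rows = []
    for r in results:
        rows.append(
            {
                "id": r.id,
                "status": r.status,
                "assigned_method": r.assigned_method.value
                if r.assigned_method
                else "",
                "ga_days": r.ga_at_birth_days if r.ga_at_birth_days is not None else "",
                "ga_weeks": r.ga_at_birth_days // 7
                if r.ga_at_birth_days is not None
                else "",
                "excluded_methods": ";".join(
                    f"{m.value}:{reason}" for m, reason in r.exclusion_trail
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "status",
            "assigned_method",
            "ga_days",
            "ga_weeks",
            "excluded_methods",
        ],
    )
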