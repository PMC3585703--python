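"""Method-vs-reference agreement statistics and report tables.

Each dating method is compared against the reference estimate (earliest
7-20-week ultrasound) on the preterm and postterm dichotomies:

* unweighted Cohen's kappa, banded with the Landis-Koch interpretation
  intervals (almost perfect 0.81-1.00, substantial 0.61-0.80, moderate
  0.41-0.60, fair 0.21-0.40, slight 0-0.20, poor < 0);
* sensitivity, specificity, PPV and NPV treating the reference as truth;
* a Pearson chi-square (no continuity correction) comparing the two
  methods' positive rates as an unpaired 2×2 — this mirrors the
  conventional presentation; a McNemar test on the paired table is
  available for methodological honesty;
* the comparator-minus-reference GA difference in days, summarised as
  mean (SD) and as proportions in five clinically motivated discrepancy
  bands (<−14, −14..−8, ±7, +8..+14, >+14 days), overall and within strata
  of maternal or infant characteristics.

All comparisons are pairwise-complete: a record enters a comparison only if
it has both the reference and the comparator estimate. Every comparison can
be run including or excluding birthweight-for-GA outliers (|Z| >= 3 under
either estimate's GA).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from gestage.dating import classify_maturity, gather_estimates
from gestage.errors import (
    DegenerateTableError,
    DomainError,
    EmptyComparisonError,
    UndefinedKappaError,
)
from gestage.growth import GrowthReference, is_excluded_outlier, zscore
from gestage.records import GAEstimate, MaturityClass, Method, PregnancyRecord


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# 2x2 confusion machinery


@dataclass(frozen=True)
class ConfusionTable2x2:
    """Test-vs-reference 2×2 counts for one dichotomy."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def transpose(self) -> "ConfusionTable2x2":
        """Swap the roles of test and reference."""
        return ConfusionTable2x2(tp=self.tp, fp=self.fn, fn=self.fp, tn=self.tn)


def confusion(
    reference_labels: Sequence,
    test_labels: Sequence,
    positive_class,
) -> ConfusionTable2x2:
    """Build the 2×2 table of test vs reference on a dichotomy.

    Pairs with either label missing (``None`` or NaN) are dropped
    (pairwise-complete). Raises EmptyComparisonError if no usable pair
    remains.
    """
    if len(reference_labels) != len(test_labels):
        raise ValueError("label lists must have equal length")
    tp = fp = fn = tn = 0
    for ref, test in zip(reference_labels, test_labels):
        if _missing(ref) or _missing(test):
            continue
        ref_pos = ref == positive_class
        test_pos = test == positive_class
        if test_pos and ref_pos:
            tp += 1
        elif test_pos and not ref_pos:
            fp += 1
        elif not test_pos and ref_pos:
            fn += 1
        else:
            tn += 1
    table = ConfusionTable2x2(tp=tp, fp=fp, fn=fn, tn=tn)
    if table.total == 0:
        raise EmptyComparisonError("no pairwise-complete observations")
    return table


def _missing(x) -> bool:
    if x is None:
        return True
    return isinstance(x, float) and np.isnan(x)


class KappaBand(str, Enum):
    ALMOST_PERFECT = "almost_perfect"
    SUBSTANTIAL = "substantial"
    MODERATE = "moderate"
    FAIR = "fair"
    SLIGHT = "slight"
    POOR = "poor"


def kappa_band(kappa: float) -> KappaBand:
    """Landis-Koch qualitative band for a kappa value."""
    if kappa < 0:
        return KappaBand.POOR
    if kappa <= 0.20:
        return KappaBand.SLIGHT
    if kappa <= 0.40:
        return KappaBand.FAIR
    if kappa <= 0.60:
        return KappaBand.MODERATE
    if kappa <= 0.80:
        return KappaBand.SUBSTANTIAL
    return KappaBand.ALMOST_PERFECT


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    band: KappaBand


def cohen_kappa(t: ConfusionTable2x2) -> KappaResult:
    """Unweighted Cohen's kappa: (p_o − p_e) / (1 − p_e), with expected
    agreement from the marginal products.

    Raises UndefinedKappaError when chance agreement p_e = 1 (both raters
    put everything in one and the same cell)."""
    n = t.total
    if n == 0:
        raise EmptyComparisonError("empty confusion table")
    p_o = (t.tp + t.tn) / n
    test_pos, ref_pos = t.tp + t.fp, t.tp + t.fn
    p_e = (test_pos * ref_pos + (n - test_pos) * (n - ref_pos)) / (n * n)
    if p_e == 1.0:
        raise UndefinedKappaError("degenerate single-cell marginals")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=kappa, band=kappa_band(kappa))


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV; ``None`` marks a metric whose
    denominator is zero (not defined), distinct from a true 0.0."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def diagnostic_metrics(t: ConfusionTable2x2) -> DiagnosticMetrics:
    """sens = tp/(tp+fn), spec = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn); zero denominators yield ``None``."""
    if t.total == 0:
        raise EmptyComparisonError("empty confusion table")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return DiagnosticMetrics(
        sensitivity=ratio(t.tp, t.tp + t.fn),
        specificity=ratio(t.tn, t.tn + t.fp),
        ppv=ratio(t.tp, t.tp + t.fp),
        npv=ratio(t.tn, t.tn + t.fn),
    )


def rate_chi_square(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2×2 of
    method × class counts, e.g. ``[[pos_A, rest_A], [pos_B, rest_B]]``.

    Raises DegenerateTableError if any expected cell is zero (a zero row or
    column sum)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if obs.sum() == 0:
        raise EmptyComparisonError("empty contingency table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero marginal: an expected cell is 0")
    chi2, p, _, _ = chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def mcnemar_chi_square(t: ConfusionTable2x2) -> tuple[float, float]:
    """McNemar test on the paired 2×2 (exact binomial on the discordant
    pairs); offered as the statistically appropriate alternative to the
    unpaired rate comparison."""
    from statsmodels.stats.contingency_tables import mcnemar

    res = mcnemar([[t.tp, t.fp], [t.fn, t.tn]], exact=True)
    return float(res.statistic), float(res.pvalue)


def preterm_rate(positive: int, total: int) -> float:
    """Percentage positive/total to one decimal, half-up."""
    if total <= 0:
        raise DomainError("rate needs a positive total")
    return round_half_up(100.0 * positive / total, 1)


# ---------------------------------------------------------------------------
# GA differences


class DiscrepancyCategory(str, Enum):
    """Five clinically motivated bands of the day difference (±7 days is the
    first-trimester redating threshold, ±14 the second-trimester one)."""

    LT_M14 = "lt_m14"  # < -14
    M14_TO_M8 = "m14_to_m8"  # -14 .. -8
    WITHIN_7 = "within_7"  # -7 .. +7
    P8_TO_P14 = "p8_to_p14"  # +8 .. +14
    GT_P14 = "gt_p14"  # > +14


def ga_difference_days(comparator: GAEstimate, reference: GAEstimate) -> int:
    """Comparator GA minus reference GA, in days. Positive means the
    comparator dates the pregnancy further along (earlier implied
    conception)."""
    return comparator.ga_at_birth_days - reference.ga_at_birth_days


def categorize_difference(days: int) -> DiscrepancyCategory:
    if days < -14:
        return DiscrepancyCategory.LT_M14
    if days <= -8:
        return DiscrepancyCategory.M14_TO_M8
    if days <= 7:
        return DiscrepancyCategory.WITHIN_7
    if days <= 14:
        return DiscrepancyCategory.P8_TO_P14
    return DiscrepancyCategory.GT_P14


# ---------------------------------------------------------------------------
# cohort-level helpers

REFERENCE_METHOD = Method.US_7_20


def cohort_estimates(
    records: Iterable[PregnancyRecord],
) -> dict[str, dict[Method, GAEstimate]]:
    """Per-record method → estimate maps for a cohort."""
    return {r.id: gather_estimates(r)[0] for r in records}


def outlier_flags(
    record: PregnancyRecord,
    estimates: dict[Method, GAEstimate],
    ref: GrowthReference,
    strict: bool = False,
) -> dict[Method, bool]:
    """Per-method flag: is the birthweight an excluded outlier under this
    method's GA estimate?"""
    return {
        m: is_excluded_outlier(
            zscore(record.birth_weight_g, e.ga_at_birth_days, record.infant_sex, ref),
            strict=strict,
        )
        for m, e in estimates.items()
    }


# ---------------------------------------------------------------------------
# report tables


@dataclass(frozen=True)
class Comparator:
    """One comparison column: a label, the method compared, and whether it
    is restricted to records with a certain LMP date."""

    label: str
    method: Method
    certain_lmp_only: bool = False


DEFAULT_COMPARATORS: tuple[Comparator, ...] = (
    Comparator("us_21_28", Method.US_21_28),
    Comparator("us_29p", Method.US_29P),
    Comparator("capurro", Method.CAPURRO),
    Comparator("lmp_sure", Method.LMP, certain_lmp_only=True),
    Comparator("lmp_all", Method.LMP),
)

_CLASS_ORDER = (MaturityClass.PRETERM, MaturityClass.TERM, MaturityClass.POSTTERM)


def _class_counts(classes: Sequence[MaturityClass]) -> dict[str, int]:
    return {c.value: sum(1 for x in classes if x is c) for c in _CLASS_ORDER}


def _dichotomy_stats(
    ref_classes: list[MaturityClass],
    cmp_classes: list[MaturityClass],
    positive: MaturityClass,
    use_mcnemar: bool,
) -> dict[str, float | str | None]:
    out: dict[str, float | str | None] = {}
    t = confusion(ref_classes, cmp_classes, positive)
    ref_pos = t.tp + t.fn
    cmp_pos = t.tp + t.fp
    n = t.total
    try:
        if use_mcnemar:
            chi2, p = mcnemar_chi_square(t)
        else:
            chi2, p = rate_chi_square(
                [[ref_pos, n - ref_pos], [cmp_pos, n - cmp_pos]]
            )
        out["chi2"], out["p"] = chi2, p
    except DegenerateTableError:
        out["chi2"], out["p"] = None, None
    try:
        kr = cohen_kappa(t)
        out["kappa"], out["band"] = kr.kappa, kr.band.value
    except UndefinedKappaError:
        out["kappa"], out["band"] = None, None
    metrics = diagnostic_metrics(t)
    out["sens"] = metrics.sensitivity
    out["spec"] = metrics.specificity
    out["ppv"] = metrics.ppv
    out["npv"] = metrics.npv
    return out


def method_comparison_report(
    records: list[PregnancyRecord],
    growth_ref: GrowthReference,
    ref_method: Method = REFERENCE_METHOD,
    comparators: tuple[Comparator, ...] = DEFAULT_COMPARATORS,
    *,
    strict_outliers: bool = False,
    use_mcnemar: bool = False,
) -> pd.DataFrame:
    """Preterm/term/postterm distribution per method, with the full
    agreement battery against the reference, including and excluding
    birthweight-for-GA outliers.

    One row per (comparison, variant). The reference rows carry the class
    distribution only; comparator rows add chi2/p/kappa/band and the
    diagnostic metrics for both dichotomies, prefixed ``pre_``/``post_``.
    The excluding-outliers variant keeps only pairs where *neither*
    estimate flags the birthweight.
    """
    per_record: list[tuple[PregnancyRecord, dict[Method, GAEstimate], dict[Method, bool]]] = []
    for r in records:
        ests, _ = gather_estimates(r)
        flags = outlier_flags(r, ests, growth_ref, strict=strict_outliers)
        per_record.append((r, ests, flags))

    rows = []

    def class_of(est: GAEstimate) -> MaturityClass:
        return classify_maturity(est.ga_at_birth_days)

    # reference column
    for variant in ("all", "excluding_outliers"):
        classes = [
            class_of(ests[ref_method])
            for _, ests, flags in per_record
            if ref_method in ests
            and (variant == "all" or not flags[ref_method])
        ]
        counts = _class_counts(classes)
        row: dict = {"comparison": "reference_" + ref_method.value, "variant": variant,
                     "n": len(classes)}
        for cls, cnt in counts.items():
            row[f"{cls}_n"] = cnt
            row[f"{cls}_pct"] = (
                preterm_rate(cnt, len(classes)) if classes else None
            )
        rows.append(row)

    for comp in comparators:
        for variant in ("all", "excluding_outliers"):
            ref_classes: list[MaturityClass] = []
            cmp_classes: list[MaturityClass] = []
            for r, ests, flags in per_record:
                if ref_method not in ests or comp.method not in ests:
                    continue
                if comp.certain_lmp_only and not r.lmp_certain:
                    continue
                if variant == "excluding_outliers" and (
                    flags[ref_method] or flags[comp.method]
                ):
                    continue
                ref_classes.append(class_of(ests[ref_method]))
                cmp_classes.append(class_of(ests[comp.method]))
            row = {"comparison": comp.label, "variant": variant, "n": len(cmp_classes)}
            counts = _class_counts(cmp_classes)
            for cls, cnt in counts.items():
                row[f"{cls}_n"] = cnt
                row[f"{cls}_pct"] = (
                    preterm_rate(cnt, len(cmp_classes)) if cmp_classes else None
                )
            if cmp_classes:
                for prefix, positive in (
                    ("pre", MaturityClass.PRETERM),
                    ("post", MaturityClass.POSTTERM),
                ):
                    stats = _dichotomy_stats(
                        ref_classes, cmp_classes, positive, use_mcnemar
                    )
                    for key, val in stats.items():
                        row[f"{prefix}_{key}"] = val
            rows.append(row)
    return pd.DataFrame(rows)


# --- stratified GA-difference table (maternal / infant characteristics) ----

#: infant birthweight strata (grams), label -> (lo, hi]
BIRTHWEIGHT_STRATA = (
    ("<2500", 0, 2499),
    ("2500-3499", 2500, 3499),
    ("3500-3999", 3500, 3999),
    (">=4000", 4000, 10**9),
)
#: reference-GA strata (completed weeks)
GA_STRATA = (
    ("<=36", 0, 36),
    ("37", 37, 37),
    ("38-39", 38, 39),
    ("40-41", 40, 41),
    (">=42", 42, 200),
)

_CAT_ORDER = tuple(DiscrepancyCategory)


def _stratum_of(
    record: PregnancyRecord, stratifier: str, ref_est: GAEstimate
) -> str | None:
    if stratifier == "lmp_certain":
        if record.lmp_certain is None:
            return None
        return "sure" if record.lmp_certain else "not_sure"
    if stratifier == "birth_weight":
        for label, lo, hi in BIRTHWEIGHT_STRATA:
            if lo <= record.birth_weight_g <= hi:
                return label
        return None
    if stratifier == "ga_at_birth":
        weeks = ref_est.ga_at_birth_weeks
        for label, lo, hi in GA_STRATA:
            if lo <= weeks <= hi:
                return label
        return None
    return record.covariates.get(stratifier)


def stratified_difference_table(
    records: list[PregnancyRecord],
    comparator_method: Method,
    stratifier: str,
    *,
    ref_method: Method = REFERENCE_METHOD,
    certain_lmp_only: bool = False,
) -> tuple[pd.DataFrame, float | None]:
    """Mean (SD) of the comparator−reference GA difference and the
    percentage in each of the five discrepancy bands, per stratum.

    ``stratifier`` is a covariate name (city, age_group, ethnicity,
    schooling, marital, parity), ``lmp_certain``, or one of the derived
    infant stratifiers ``birth_weight`` / ``ga_at_birth`` (the latter by the
    reference estimate's completed weeks). Returns the table and the
    p-value of the chi-square on the strata × category contingency table
    (``None`` when fewer than two usable strata or categories).

    A stratum with zero pairwise-complete pairs is emitted with n=0 and
    blank statistics.
    """
    diffs_by_stratum: dict[str, list[int]] = {}
    for r in records:
        ests, _ = gather_estimates(r)
        if ref_method not in ests or comparator_method not in ests:
            continue
        if certain_lmp_only and not r.lmp_certain:
            continue
        stratum = _stratum_of(r, stratifier, ests[ref_method])
        if stratum is None:
            continue
        diffs_by_stratum.setdefault(stratum, []).append(
            ga_difference_days(ests[comparator_method], ests[ref_method])
        )

    known_order = {
        "birth_weight": [s[0] for s in BIRTHWEIGHT_STRATA],
        "ga_at_birth": [s[0] for s in GA_STRATA],
        "lmp_certain": ["sure", "not_sure"],
    }
    strata = known_order.get(stratifier, sorted(diffs_by_stratum))
    rows = []
    cont: list[list[int]] = []
    for stratum in strata:
        diffs = np.asarray(diffs_by_stratum.get(stratum, []), dtype=float)
        n = len(diffs)
        row: dict = {"stratum": stratum, "n": n}
        if n:
            row["mean_diff"] = float(diffs.mean())
            row["sd_diff"] = float(diffs.std(ddof=1)) if n > 1 else None
            cats = [categorize_difference(int(d)) for d in diffs]
            counts = [sum(1 for c in cats if c is cat) for cat in _CAT_ORDER]
            cont.append(counts)
            for cat, cnt in zip(_CAT_ORDER, counts):
                row[f"pct_{cat.value}"] = preterm_rate(cnt, n)
        else:
            row["mean_diff"] = None
            row["sd_diff"] = None
            for cat in _CAT_ORDER:
                row[f"pct_{cat.value}"] = None
        rows.append(row)
    table = pd.DataFrame(rows)

    p_value: float | None = None
    obs = np.asarray([c for c in cont if sum(c) > 0], dtype=float)
    if len(obs) >= 2:
        obs = obs[:, obs.sum(axis=0) > 0]  # drop empty categories
        if obs.shape[1] >= 2:
            _, p_value, _, _ = chi2_contingency(obs, correction=False)
            p_value = float(p_value)
    return table, p_value


# --- per-week GA distribution (reference vs algorithm comparison) ----------

_WEEK_FLOOR = 29  # rows below are pooled into "<=29"
_WEEK_CEIL = 43  # rows at or above are pooled into ">=43"


def ga_distribution_table(ga_days: Iterable[int]) -> pd.DataFrame:
    """Per-completed-week distribution of GA at birth with cumulative
    percents and a preterm subtotal.

    Rows: "<=29", "30" … "42", ">=43". Percents to one decimal (half-up);
    the cumulative percent is computed on the exact proportions and ends at
    100.0. The table's ``attrs`` carry ``preterm_n`` and ``preterm_pct``
    (births before 37 completed weeks).
    """
    weeks = [d // 7 for d in ga_days]
    n_total = len(weeks)
    labels = ["<=29"] + [str(w) for w in range(30, 43)] + [">=43"]
    counts = {label: 0 for label in labels}
    for w in weeks:
        if w <= _WEEK_FLOOR:
            counts["<=29"] += 1
        elif w >= _WEEK_CEIL:
            counts[">=43"] += 1
        else:
            counts[str(w)] += 1
    rows = []
    cum = 0
    for label in labels:
        cnt = counts[label]
        cum += cnt
        rows.append(
            {
                "weeks": label,
                "n": cnt,
                "pct": preterm_rate(cnt, n_total) if n_total else None,
                "cum_pct": preterm_rate(cum, n_total) if n_total else None,
            }
        )
    table = pd.DataFrame(rows, columns=["weeks", "n", "pct", "cum_pct"])
    if n_total == 0:
        table = table.iloc[0:0]
        table.attrs["preterm_n"] = 0
        table.attrs["preterm_pct"] = None
        return table
    preterm_n = sum(1 for w in weeks if w < 37)
    table.attrs["preterm_n"] = preterm_n
    table.attrs["preterm_pct"] = preterm_rate(preterm_n, n_total)
    return table
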