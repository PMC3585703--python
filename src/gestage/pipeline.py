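"""End-to-end analysis pipeline: cohort in, report bundle out.

Stages: read cohort → per-method GA estimates → hierarchical assignment →
agreement reports (method-comparison table, stratified GA-difference tables
for LMP and Capurro, per-week GA distribution of reference vs algorithm) →
run manifest. Any stage failure aborts with a stage-named error; the
manifest records the config hash, seed, package and library versions, and
row counts, which is sufficient to re-run the bundle byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import pandas as pd

from gestage import __version__
from gestage.agreement import (
    ga_distribution_table,
    method_comparison_report,
    stratified_difference_table,
)
from gestage.algorithm import assign_cohort, results_to_frame
from gestage.dating import gather_estimates
from gestage.errors import GestageError, StageError
from gestage.growth import GrowthReference, load_reference
from gestage.io import read_cohort, write_report_csv
from gestage.records import Method, PregnancyRecord
from gestage.simulate import SimulationConfig

#: Table-2-style stratifiers, per comparator
LMP_STRATIFIERS = (
    "city",
    "age_group",
    "ethnicity",
    "schooling",
    "marital",
    "parity",
    "lmp_certain",
)
CAPURRO_STRATIFIERS = ("birth_weight", "ga_at_birth")


def estimates_frame(records: list[PregnancyRecord]) -> pd.DataFrame:
    """Wide per-record frame of GA estimates: one column per method."""
    rows = []
    for r in records:
        ests, _ = gather_estimates(r)
        row: dict = {"id": r.id}
        for m in Method:
            est = ests.get(m)
            row[f"{m.value}_ga_days"] = (
                est.ga_at_birth_days if est is not None else ""
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    cohort_path: str | Path,
    out_dir: str | Path,
    *,
    config: SimulationConfig | None = None,
    growth_ref_path: str | Path | None = None,
    seed: int = 0,
    strict_outliers: bool = False,
) -> dict:
    """Run the full analysis on a cohort file and write the report bundle.

    Outputs in ``out_dir``: ``estimates.csv``, ``assignments.csv``,
    ``entrance_tally.csv``, ``table1_method_comparison.csv``,
    ``table2_lmp_strata.csv`` / ``table2_capurro_strata.csv``,
    ``table3_ga_distribution.csv`` and ``manifest.json``. Returns the
    manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config if config is not None else SimulationConfig.default()
    config_hash = cfg.config_hash()

    def stage(name: str, fn):
        try:
            return fn()
        except GestageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError(name, str(exc)) from exc

    def _read():
        records, issues = read_cohort(cohort_path)
        if not records:
            raise StageError("read_cohort", "no usable records")
        return records, issues

    records, issues = stage("read_cohort", _read)

    def _load_ref() -> GrowthReference:
        return load_reference(growth_ref_path)

    growth_ref = stage("growth_reference", _load_ref)

    est_frame = stage("estimates", lambda: estimates_frame(records))
    write_report_csv(
        est_frame, out / "estimates.csv", config_hash=config_hash, seed=seed
    )

    def _assign():
        return assign_cohort(records, growth_ref, strict_outliers=strict_outliers)

    results, tally = stage("assignment", _assign)
    write_report_csv(
        results_to_frame(results),
        out / "assignments.csv",
        config_hash=config_hash,
        seed=seed,
    )
    write_report_csv(
        tally.to_frame(), out / "entrance_tally.csv", config_hash=config_hash, seed=seed
    )

    table1 = stage(
        "method_comparison",
        lambda: method_comparison_report(
            records, growth_ref, strict_outliers=strict_outliers
        ),
    )
    write_report_csv(
        table1, out / "table1_method_comparison.csv", config_hash=config_hash, seed=seed
    )

    def _strata(method: Method, stratifiers) -> pd.DataFrame:
        parts = []
        for stratifier in stratifiers:
            table, p = stratified_difference_table(records, method, stratifier)
            table.insert(0, "stratifier", stratifier)
            table["p_value"] = p
            parts.append(table)
        return pd.concat(parts, ignore_index=True)

    table2_lmp = stage(
        "lmp_strata", lambda: _strata(Method.LMP, LMP_STRATIFIERS)
    )
    write_report_csv(
        table2_lmp, out / "table2_lmp_strata.csv", config_hash=config_hash, seed=seed
    )
    table2_cap = stage(
        "capurro_strata", lambda: _strata(Method.CAPURRO, CAPURRO_STRATIFIERS)
    )
    write_report_csv(
        table2_cap, out / "table2_capurro_strata.csv", config_hash=config_hash, seed=seed
    )

    def _table3() -> pd.DataFrame:
        ref_ga = []
        for r in records:
            ests, _ = gather_estimates(r)
            est = ests.get(Method.US_7_20)
            if est is not None:
                ref_ga.append(est.ga_at_birth_days)
        algo_ga = [
            res.ga_at_birth_days for res in results if res.ga_at_birth_days is not None
        ]
        ref_table = ga_distribution_table(ref_ga)
        algo_table = ga_distribution_table(algo_ga)
        merged = ref_table.merge(
            algo_table, on="weeks", suffixes=("_reference", "_algorithm")
        )
        merged.attrs["preterm_n_reference"] = ref_table.attrs["preterm_n"]
        merged.attrs["preterm_n_algorithm"] = algo_table.attrs["preterm_n"]
        return merged

    table3 = stage("ga_distribution", _table3)
    write_report_csv(
        table3, out / "table3_ga_distribution.csv", config_hash=config_hash, seed=seed
    )

    manifest = {
        "tool": "gestage",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config_hash": config_hash,
        "config": cfg.model_dump(mode="json"),
        "growth_reference": str(growth_ref.source),
        "cohort_path": str(cohort_path),
        "n_records": len(records),
        "n_skipped_rows": len(issues),
        "n_classified": sum(1 for r in results if r.classified),
        "n_unclassified": tally.unclassified,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
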