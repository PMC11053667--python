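"""Stage orchestration: each stage is a pure function of (inputs, config, seed)
writing CSV outputs plus a human-readable summary under an output directory."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as dio
from .comparison import compare_dbs_plasma
from .datamodel import Analyte, RunConfig
from .errors import InsufficientDataError
from .mpr import summarize_cohort
from .synthetic import (
    SyntheticConfig,
    generate_calibration_run,
    generate_cohort,
    generate_paired,
    generate_qc_run,
    paired_records,
)
from .validation import fit_calibration, matrix_effect_slopes, qc_stats


def stage_simulate(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate cohort, paired, calibration and QC tables plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    cohort = generate_cohort(config, rng)
    paired = generate_paired(cohort, config, rng)
    cal = generate_calibration_run(config, n_lots=5, n_days=3, rng=rng)
    qc = generate_qc_run(config, rng=rng)

    paths = {
        "cohort": out / "cohort.csv",
        "paired": out / "paired.csv",
        "calibration_runs": out / "calibration_runs.csv",
        "qc_runs": out / "qc_runs.csv",
        "manifest": out / "manifest.json",
    }
    cohort.to_csv(paths["cohort"], index=False)
    dio.write_paired_table(paired_records(paired), paths["paired"])
    dio.write_calibration_table(cal, paths["calibration_runs"])
    qc.to_csv(paths["qc_runs"], index=False)
    manifest = {k: (v if not isinstance(v, dict) else {a.value: x for a, x in v.items()})
                for k, v in asdict(config).items()}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths


def stage_validate(
    calibration_csv: str | Path,
    qc_csv: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Fit per-lot/day calibration curves, QC accuracy/precision, matrix-effect RSD."""
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs = dio.read_calibration_table(calibration_csv)
    qc = pd.read_csv(qc_csv)

    cal_rows, curves_by_analyte = [], {}
    groups: dict[tuple, list] = {}
    for o in obs:
        groups.setdefault((o.analyte, o.lot, o.day), []).append(o)
    for (analyte, lot, day), grp in sorted(
        groups.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2])
    ):
        curve = fit_calibration(grp)
        curves_by_analyte.setdefault((analyte, lot), curve)
        cal_rows.append(
            {
                "analyte": analyte.value,
                "lot": lot,
                "day": day,
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r2": curve.r2,
            }
        )
    cal_df = pd.DataFrame(cal_rows)

    effect_rows = []
    for analyte in Analyte:
        lot_curves = [c for (a, _), c in curves_by_analyte.items() if a == analyte]
        if len(lot_curves) >= 3:
            rsd, ok = matrix_effect_slopes(
                lot_curves, threshold_pct=config.matrix_slope_rsd_pct
            )
            effect_rows.append(
                {
                    "factor": "MATRIX",
                    "analyte": analyte.value,
                    "metric": "slope_rsd_pct",
                    "value": rsd,
                    "threshold_pct": config.matrix_slope_rsd_pct,
                    "passed": ok,
                }
            )

    qc_df = pd.DataFrame(
        [
            {
                "analyte": s.analyte.value,
                "level": s.level,
                "scope": s.scope,
                "day": s.day,
                "n": s.n,
                "mean_found": s.mean_found,
                "cv_pct": s.cv_pct,
                "bias_pct": s.bias_pct,
                "threshold_pct": (
                    config.lloq_bias_cv_pct
                    if abs(s.level - config.lloq) < 1e-12
                    else config.acceptance_bias_cv_pct
                ),
            }
            for s in qc_stats(qc)
        ]
    )
    if not qc_df.empty:
        qc_df["passed"] = (qc_df["bias_pct"].abs() <= qc_df["threshold_pct"]) & (
            qc_df["cv_pct"] <= qc_df["threshold_pct"]
        )

    paths = {
        "calibration": out / "calibration.csv",
        "qc_stats": out / "qc_stats.csv",
        "effects": out / "effects.csv",
    }
    cal_df.to_csv(paths["calibration"], index=False)
    qc_df.to_csv(paths["qc_stats"], index=False)
    pd.DataFrame(effect_rows).to_csv(paths["effects"], index=False)
    return paths


def stage_compare(
    paired_csv: str | Path,
    out_dir: str | Path,
    k_source: str = "fit",
) -> dict[str, Path]:
    """Deming + Bland-Altman cross-validation per analyte, with partition fit."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = dio.read_paired_table(paired_csv)

    deming_rows, ba_rows, part_rows, calc_rows = [], [], [], []
    for analyte in Analyte:
        try:
            rep = compare_dbs_plasma(records, analyte, k_source=k_source)
        except InsufficientDataError:
            continue
        for panel, fit in (("blood_vs_plasma", rep.deming_raw),
                           ("converted_vs_plasma", rep.deming_converted)):
            deming_rows.append(
                {
                    "analyte": analyte.value,
                    "panel": panel,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "slope_ci_low": fit.slope_ci[0],
                    "slope_ci_high": fit.slope_ci[1],
                    "intercept_ci_low": fit.intercept_ci[0],
                    "intercept_ci_high": fit.intercept_ci[1],
                    "n": fit.n,
                }
            )
        for panel, ba in (("blood_vs_plasma", rep.ba_raw),
                          ("converted_vs_plasma", rep.ba_converted)):
            ba_rows.append(
                {
                    "analyte": analyte.value,
                    "panel": panel,
                    "mean_diff": ba.mean_diff,
                    "sd_diff": ba.sd_diff,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "ci_mean_diff_low": ba.ci_mean_diff[0],
                    "ci_mean_diff_high": ba.ci_mean_diff[1],
                    "n": ba.n,
                }
            )
        if rep.partition is not None:
            part_rows.append(
                {
                    "analyte": analyte.value,
                    "k_bcpl": rep.partition.k_bcpl,
                    "ci_low": rep.partition.ci_low,
                    "ci_high": rep.partition.ci_high,
                    "se": rep.partition.se,
                    "sse": rep.partition.sse,
                    "n": rep.partition.n,
                }
            )
        calc_rows.append(
            pd.DataFrame(
                {
                    "analyte": analyte.value,
                    "c_b": rep.blood,
                    "c_pl_measured": rep.measured_plasma,
                    "c_pl_calculated": rep.calculated_plasma,
                    "k_used": rep.k_used,
                }
            )
        )

    if not deming_rows:
        raise InsufficientDataError("no analyte had >= 3 complete paired records")
    paths = {
        "deming": out / "deming.csv",
        "bland_altman": out / "bland_altman.csv",
        "partition_fit": out / "partition_fit.csv",
        "calculated_plasma": out / "calculated_plasma.csv",
    }
    pd.DataFrame(deming_rows).to_csv(paths["deming"], index=False)
    pd.DataFrame(ba_rows).to_csv(paths["bland_altman"], index=False)
    pd.DataFrame(part_rows).to_csv(paths["partition_fit"], index=False)
    pd.concat(calc_rows, ignore_index=True).to_csv(
        paths["calculated_plasma"], index=False
    )
    return paths


def stage_mpr(
    trough_csv: str | Path,
    out_dir: str | Path,
    fence_k: float = 1.5,
    grubbs_scale: str = "log",
) -> dict[str, Path]:
    """MPR table, cohort summary, fences, flags and Grubbs evidence."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = dio.read_trough_table(trough_csv)
    res = summarize_cohort(table, fence_k=fence_k, grubbs_scale=grubbs_scale)

    paths = {"mpr_table": out / "mpr_table.csv", "flags": out / "flags.csv"}
    res.per_subject.to_csv(paths["mpr_table"], index=False)
    pd.DataFrame(
        {
            "subject_id": res.per_subject["subject_id"],
            "mpr": res.per_subject["mpr"],
            "outlier": res.per_subject["outlier"],
            "fence_low": res.fence_low,
            "fence_high": res.fence_high,
            "grubbs_g": res.grubbs_g,
            "grubbs_p": res.grubbs_p,
            "grubbs_scale": res.grubbs_scale,
        }
    ).to_csv(paths["flags"], index=False)
    return paths


def run_pipeline(
    synth_config: SyntheticConfig,
    out_dir: str | Path,
    run_config: RunConfig | None = None,
) -> dict[str, Path]:
    """Simulate, then validate, compare and screen MPRs on the simulated data.

    Identical (config, seed) produce byte-identical numeric outputs.
    """
    out = Path(out_dir)
    paths = stage_simulate(synth_config, out)
    paths |= stage_validate(
        paths["calibration_runs"], paths["qc_runs"], out, run_config
    )
    paths |= stage_compare(paths["paired"], out)

    cohort = pd.read_csv(paths["cohort"])
    paired = pd.read_csv(paths["paired"])
    trough = _trough_from_paired(paired)
    trough_path = out / "trough_table.csv"
    trough.merge(cohort[["subject_id", "dose"]].astype({"subject_id": str}),
                 on="subject_id")[
        ["subject_id", "dose", "parent_conc", "metabolite_conc"]
    ].to_csv(trough_path, index=False)
    paths["trough_table"] = trough_path
    paths |= stage_mpr(trough_path, out)

    summary = out / "summary.txt"
    summary.write_text(_summary_text(out))
    paths["summary"] = summary
    return paths


def _trough_from_paired(paired: pd.DataFrame) -> pd.DataFrame:
    trough = paired[paired["timepoint"] == "TROUGH"]
    wide = trough.pivot_table(
        index="subject_id", columns="analyte", values="c_b", aggfunc="first"
    ).reset_index()
    wide["subject_id"] = wide["subject_id"].astype(str)
    return wide.rename(
        columns={"PARENT": "parent_conc", "METABOLITE": "metabolite_conc"}
    )[["subject_id", "parent_conc", "metabolite_conc"]]


def _summary_text(out: Path) -> str:
    lines = ["DBS-TDM pipeline summary", "=" * 24]
    for name in ("calibration", "qc_stats", "effects", "partition_fit",
                 "deming", "bland_altman", "flags"):
        f = out / f"{name}.csv"
        if f.exists():
            df = pd.read_csv(f)
            lines.append(f"\n[{name}] {len(df)} rows")
            lines.append(df.to_string(index=False, max_rows=12))
    return "\n".join(lines) + "\n"
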