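"""Config-driven orchestration of the full coagulation-marker analysis.

Runs the study workflow end to end on a cohort CSV (or a freshly simulated
registry): group-comparison tables, per-marker ROC analyses for the three
binary contrasts, the CI mediation model on grade, VIF screening plus
stepwise logistic models for stage and grade, stepwise linear models for the
R and MA values, four-group trend tests, optional propensity matching, and
the classifier benchmark.  Every artifact embeds the configuration hash,
seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import biostats, cohort, harness, mediation, selection

logger = logging.getLogger("tegcoag")

__all__ = ["RunConfig", "cmd_simulate", "cmd_analyze", "cmd_benchmark",
           "cmd_report", "PipelineError"]

#: Markers screened in the ROC tables.
ROC_VARIABLES = cohort.TEG_FIVE + cohort.COAG_NINE + [
    "Albumin", "Erythrocyte", "Hemoglobin",
]

#: Candidate predictors for the stepwise logistic stage/grade models.
LOGISTIC_CANDIDATES = cohort.TEG_FIVE + cohort.COAG_NINE + [
    "Albumin", "Globulin", "Platelet", "WBC", "Neutrophils", "Lymphocyte",
]

#: Candidate predictors for the stepwise linear R/MA models.
LINEAR_CANDIDATES = cohort.COAG_NINE + [
    "Albumin", "Globulin", "Platelet", "WBC", "Neutrophils", "Lymphocyte",
    "Erythrocyte", "Hemoglobin", "Tumor_length", "Tumor_area", "AFP", "CEA",
    "CA19_9", "CA72_4", "Age", "BMI", "VTE_score", "Nutritional_screening",
]

DEFAULT_PSM_COVARIATES = ["Age", "Sex_male", "BMI", "Smoking"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    input: str = "simulate"  # path to a cohort CSV, or "simulate"
    output_dir: str = "tegcoag_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "roc": True, "mediation": True, "stepwise": True,
        "psm": False, "benchmark": True, "trend": True,
    })
    cohort_config: str | None = None  # YAML path; None -> published defaults
    stratify_by: str = "g"
    n_boot: int = 1000
    benchmark: dict = field(default_factory=lambda: {
        "feature_sets": ["teg_five", "thromboelastogram_nine"],
        "target_label": "g_binary",
        "cv_folds": 5,
        "repeats": 2,
    })
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise PipelineError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("output_dir", "log_level")}
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def _load_cohort_config(config: RunConfig) -> cohort.CohortConfig:
    if config.cohort_config:
        return cohort.read_config_yaml(config.cohort_config)
    return cohort.default_config()


def _obtain_cohort(config: RunConfig) -> pd.DataFrame:
    """Simulate or read the cohort, with exclusions already applied."""
    if config.input == "simulate":
        cc = _load_cohort_config(config)
        registry = cohort.generate_cohort(cc, seed=config.seed,
                                          stratify_by=config.stratify_by)
        eligible, report = cohort.apply_exclusions(registry)
        logger.info("simulated registry: %d records, %d retained",
                    len(registry), report.retained)
        return eligible.to_dataframe()
    df = cohort.read_cohort_csv(config.input)
    required = {"malignancy"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"input CSV missing columns: {sorted(missing)}")
    flag_cols = [c for c in df.columns if c.startswith("flag_")]
    if flag_cols:
        df = df[~df[flag_cols].any(axis=1)]
    return df


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {"provenance": _provenance(config), **payload}
    path.write_text(json.dumps(payload, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Subcommand implementations
# ---------------------------------------------------------------------------


def cmd_simulate(config: RunConfig) -> Path:
    """Write the simulated registry CSV and a config echo; returns the CSV path."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cc = _load_cohort_config(config)
    registry = cohort.generate_cohort(cc, seed=config.seed,
                                      stratify_by=config.stratify_by)
    csv_path = out / "cohort.csv"
    cohort.write_cohort_csv(registry, csv_path)
    cohort.write_config_yaml(cc, out / "cohort_config.yaml")
    eligible, report = cohort.apply_exclusions(registry)
    _write_json(out / "simulate_summary.json", {
        "registry_size": len(registry),
        "retained": report.retained,
        "removed": report.total_removed,
        "per_flag": report.per_flag,
        "group_counts": {
            "malignant": sum(
                r.labels["malignancy"] == "malignant" for r in eligible.records
            ),
            "benign": sum(
                r.labels["malignancy"] == "benign" for r in eligible.records
            ),
        },
    }, config)
    return csv_path


def _contrast_frames(df: pd.DataFrame) -> dict:
    """The three binary contrasts: (frame, positive-group mask, name)."""
    mal = df[df["malignancy"] == "malignant"]
    out = {
        "benign_vs_malignant": (df, df["malignancy"] == "malignant"),
    }
    if mal["tnm_binary"].notna().any():
        out["tnm"] = (mal, mal["tnm_binary"] == "tnm_late")
    if mal["g_binary"].notna().any():
        out["g"] = (mal, mal["g_binary"] == "g_high")
    return out


def _group_comparison_table(df: pd.DataFrame, mask, variables) -> list:
    rows = []
    for var in variables:
        if var not in df.columns:
            continue
        x = df.loc[mask, var].dropna().to_numpy(dtype=float)
        y = df.loc[~mask, var].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            continue
        res = biostats.compare_groups(x, y, method="t_test")
        rows.append({
            "variable": var,
            "group1_mean": float(x.mean()), "group1_sd": float(x.std(ddof=1)),
            "group2_mean": float(y.mean()), "group2_sd": float(y.std(ddof=1)),
            "p": res.p_value, "ci_95": list(res.ci_95),
        })
    return rows


def cmd_analyze(config: RunConfig) -> Path:
    """Run the enabled analysis stages; artifacts land in output_dir/analysis.

    Output is atomic: everything is staged in a temporary directory and moved
    into place only when every enabled stage has succeeded.
    """
    df = _obtain_cohort(config)  # validate input before writing anything
    out = Path(config.output_dir) / "analysis"
    stage_dir = Path(tempfile.mkdtemp(prefix="tegcoag_analyze_"))
    try:
        _run_analysis_stages(df, config, stage_dir)
        if out.exists():
            shutil.rmtree(out)
        out.parent.mkdir(parents=True, exist_ok=True)
        shutil.move(str(stage_dir), str(out))
    finally:
        if stage_dir.exists():
            shutil.rmtree(stage_dir, ignore_errors=True)
    return out


def _run_analysis_stages(df: pd.DataFrame, config: RunConfig,
                         out: Path) -> None:
    contrasts = _contrast_frames(df)
    stages = config.stages

    comparison = {
        name: _group_comparison_table(frame, mask, ROC_VARIABLES)
        for name, (frame, mask) in contrasts.items()
    }
    _write_json(out / "group_comparisons.json", {"tables": comparison}, config)

    if stages.get("roc", True):
        roc = {}
        for name, (frame, mask) in contrasts.items():
            labels = mask.to_numpy(dtype=int)
            table = {}
            for var in ROC_VARIABLES:
                if var not in frame.columns or frame[var].isna().all():
                    continue
                scores = frame[var].to_numpy(dtype=float)
                result = biostats.empirical_auc(scores, labels)
                table[var] = result.to_dict()
                curve = biostats.roc_curve_table(
                    scores if result.direction == "higher_is_positive"
                    else -scores, labels
                )
                pd.DataFrame(curve, columns=["fpr", "tpr", "threshold"]).to_csv(
                    out / f"roc_curve_{name}_{var}.csv", index=False
                )
            roc[name] = table
        _write_json(out / "roc.json", {"roc": roc}, config)

    mediation_complete = False
    if stages.get("mediation", True) and "g" in contrasts:
        frame, mask = contrasts["g"]
        y = mask.to_numpy(dtype=int)
        med = {}
        for exposure in ("R", "MA"):
            result = mediation.fit_mediation(
                frame[exposure].to_numpy(dtype=float),
                frame["CI"].to_numpy(dtype=float),
                y, n_boot=config.n_boot, seed=config.seed,
            )
            med[exposure] = result.to_dict()
            mediation_complete |= result.classification == "complete"
        _write_json(out / "mediation.json", {"mediation": med}, config)

    if stages.get("stepwise", True):
        stepwise_out = {}
        for name in ("tnm", "g"):
            if name not in contrasts:
                continue
            frame, mask = contrasts[name]
            candidates = [v for v in LOGISTIC_CANDIDATES if v in frame.columns]
            design = frame[candidates].dropna()
            y = mask.loc[design.index].to_numpy(dtype=int)
            vif = selection.vif_screen(design, threshold=10.0)
            kept = list(vif.retained)
            # pipeline rule: a complete mediator is excluded from the
            # multivariate grade model
            if name == "g" and mediation_complete and "CI" in kept:
                kept.remove("CI")
            result = selection.stepwise_logistic(design[kept], y)
            stepwise_out[name] = {
                "vif": {
                    "initial": vif.initial_vif, "final": vif.vif,
                    "dropped": [list(d) for d in vif.dropped],
                },
                "mediator_excluded": name == "g" and mediation_complete,
                "selected": result.selected,
                "table": result.to_frame().to_dict(orient="records"),
                "trace": [list(t) for t in result.step_trace],
            }
            result.to_frame().to_csv(out / f"stepwise_logistic_{name}.csv",
                                     index=False)
        _write_json(out / "stepwise_logistic.json", stepwise_out, config)

        linear_out = {}
        mal = df[df["malignancy"] == "malignant"]
        for target in ("R", "MA"):
            candidates = [v for v in LINEAR_CANDIDATES if v in mal.columns]
            design = mal[candidates + [target]].dropna()
            result = selection.stepwise_linear(
                design[candidates], design[target].to_numpy(dtype=float)
            )
            linear_out[target] = {
                "selected": result.selected,
                "table": result.to_frame().to_dict(orient="records"),
            }
            result.to_frame().to_csv(out / f"stepwise_linear_{target}.csv",
                                     index=False)
        _write_json(out / "stepwise_linear.json", linear_out, config)

    if stages.get("trend", True) and "g_binary" in df.columns:
        # four-group trend proxy: order malignant patients by the two binary
        # partitions (g_low/early .. g_high/late)
        trend = {}
        mal = df[df["malignancy"] == "malignant"]
        for var in ("R", "MA"):
            for part, order in (("g_binary", ["g_low", "g_high"]),
                                ("tnm_binary", ["tnm_early", "tnm_late"])):
                groups = ["benign"] + order
                labels = np.where(
                    df["malignancy"] == "benign", "benign", df[part]
                )
                keep = pd.Series(labels).isin(groups).to_numpy()
                res = biostats.trend_test(
                    df.loc[keep, var].to_numpy(dtype=float),
                    labels[keep], ordered_groups=groups,
                )
                trend[f"{var}_{part}"] = {
                    "statistic": res.statistic, "p": res.p_value,
                    **res.extra,
                }
        _write_json(out / "trend.json", {"trend": trend}, config)

    if stages.get("psm", False):
        covs = [c for c in DEFAULT_PSM_COVARIATES if c in df.columns]
        work = df.copy()
        work["_treated"] = (work["malignancy"] == "malignant").astype(int)
        matched = selection.propensity_match(work, "_treated", covs)
        balance = {
            c: {
                "smd_before": selection.standardized_mean_difference(
                    work, "_treated", c
                ),
                "smd_after": selection.standardized_mean_difference(
                    matched, "_treated", c
                ) if len(matched) else None,
            }
            for c in covs
        }
        _write_json(out / "psm.json", {
            "n_matched_pairs": int(len(matched) // 2), "balance": balance,
        }, config)


def cmd_benchmark(config: RunConfig) -> Path:
    """Run the classifier benchmark for each configured feature set."""
    df = _obtain_cohort(config)
    out = Path(config.output_dir) / "benchmark"
    out.mkdir(parents=True, exist_ok=True)
    bench = config.benchmark
    target = bench.get("target_label", "g_binary")
    if target in ("tnm_binary", "g_binary"):
        df = df[df["malignancy"] == "malignant"]
    if df[target].nunique() < 2:
        raise PipelineError(f"target {target!r} is single-class")
    for fs in bench.get("feature_sets", ["teg_five"]):
        if isinstance(fs, str) and fs not in harness.FEATURE_SETS:
            raise PipelineError(
                f"unknown feature set {fs!r}; valid: {sorted(harness.FEATURE_SETS)}"
            )
        report = harness.run_benchmark(
            df, fs, target,
            cv_folds=bench.get("cv_folds", 5),
            repeats=bench.get("repeats", 2),
            seed=config.seed,
        )
        name = fs if isinstance(fs, str) else "custom"
        _write_json(out / f"benchmark_{name}.json", report.to_dict(), config)
        report.fold_frame().to_csv(out / f"benchmark_{name}_folds.csv",
                                   index=False)
        harness.plot_benchmark(report, out / f"benchmark_{name}.png")
    return out


def cmd_report(config: RunConfig) -> Path:
    """Collate every JSON artifact under output_dir into one summary file."""
    base = Path(config.output_dir)
    summary = {}
    for path in sorted(base.rglob("*.json")):
        if path.name == "report.json":
            continue
        rel = str(path.relative_to(base))
        try:
            summary[rel] = json.loads(path.read_text())
        except json.JSONDecodeError:
            summary[rel] = {"error": "unreadable"}
    out = base / "report.json"
    _write_json(out, {"artifacts": summary}, config)
    return out
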