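"""Pipeline orchestration: configuration, stage runners, artifacts.

Stages communicate through plain CSV/JSON files in an output directory:

* ``screening.csv`` — one row per screening subject (score, severity
  class, outcome times/flags, PCP-HF covariate);
* ``scores.csv`` — long-format trajectory table (subject_id,
  time_years_before_procedure, score);
* ``subjects.csv`` — per-subject survival + covariates + latent truth;
* ``clusters.csv`` / ``centroids.csv`` / ``cluster_diagnostics.json``;
* ``screening_report.json`` / ``table1.csv``;
* ``cox_models.json`` / ``reclassification.json`` / ``calibration.csv``;
* ``timing_report.json``; plus a ``manifest.json`` with the config
  hash, seeds, package version and input checksums.

``run("all", config)`` chains simulate -> screen -> cluster ->
survival -> timing -> report deterministically for a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from astraj import __version__
from astraj.clustering import (
    bic,
    fit_em,
    label_clusters,
    select_k,
    silhouette,
    stability,
    trajectories_from_frame,
    trajectory_distance,
)
from astraj.cohorts import (
    ScreeningGeneratorConfig,
    TrajectoryGeneratorConfig,
    generate_screening_cohort,
    generate_trajectory_cohort,
)
from astraj.errors import ConfigError, DataError
from astraj.screening import auroc, confusion_at, fp_prognosis, prevalence_adjusted, youden_cutpoint
from astraj.survival import (
    calibration_table,
    fit_cox_ladder,
    predicted_mortality,
    reclassification_analysis,
)
from astraj.timing import first_crossing, proportion_above

log = logging.getLogger("astraj")

SCORES_COLUMNS = ["subject_id", "time_years_before_procedure", "score"]
SCREENING_COLUMNS = ["subject_id", "score", "severity_class",
                     "time_to_as_hosp", "as_hosp_event",
                     "time_to_hf", "hf_event", "pcp_hf"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 20260921,
    "outdir": "results",
    "simulate": {
        "screening": {},          # ScreeningGeneratorConfig overrides
        "trajectory": {},         # TrajectoryGeneratorConfig overrides
    },
    "screen": {
        "prevalence_grid": [0.01, 0.02, 0.03, 0.04, 0.05],
        "auroc_boot": 2000,
    },
    "cluster": {
        "k": 3,                   # the three-phenotype model; None -> select
                                  # over k_range by silhouette
        "k_range": [2, 6],
        "seeds_per_k": 10,
        "n_restarts": 10,
        "min_obs": 1,
        "spline_dof": 8,
        "stability_restarts": 10,
        "stability_boot": 20,
    },
    "survival": {
        "horizons": [1.0, 3.0],
        "categories": [0.05, 0.075, 0.10],
        "n_boot": 1000,
        "base_scores": ["sts_score", "euroscore2"],
        "mode": "face_value",
    },
    "timing": {
        "thresholds": [0.60, 0.70, 0.80],
        "min_obs": 5,
        "proportion_thresholds": [0.50, 0.70],
        "proportion_times": [0.5, 5.0],
        "window": 0.5,
    },
}


def _merge_validate(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in override:
            oval = override[key]
            if isinstance(dval, dict) and path != ".simulate":
                if not isinstance(oval, dict):
                    raise ConfigError(f"config field {path}.{key} must be a mapping")
                out[key] = _merge_validate(dval, oval, f"{path}.{key}")
            else:
                out[key] = oval
        else:
            out[key] = dval
    unknown = set(override) - set(defaults)
    if unknown:
        raise ConfigError(
            f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    return out


def load_config(overrides: dict | None = None) -> dict:
    """Merge user overrides into the default config, rejecting unknown keys.

    ``simulate.screening`` / ``simulate.trajectory`` blocks take any
    generator-config field; they are validated against the dataclasses.
    """
    cfg = _merge_validate(DEFAULT_CONFIG, overrides or {})
    for block, cls in (("screening", ScreeningGeneratorConfig),
                       ("trajectory", TrajectoryGeneratorConfig)):
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg["simulate"][block]) - fields
        if unknown:
            raise ConfigError(
                f"unknown simulate.{block} keys: {sorted(unknown)}")
    return cfg


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{name} is missing column(s): {missing}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return v
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, payload: dict) -> None:
    def clean(x):
        if isinstance(x, float) and not np.isfinite(x):
            return None
        return x
    path.write_text(json.dumps(payload, indent=2, default=_json_default,
                               allow_nan=True) + "\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> dict:
    """Generate both cohorts and write screening.csv, scores.csv, subjects.csv."""
    seed = cfg["seed"]
    sc = ScreeningGeneratorConfig(**{"seed": seed,
                                     **cfg["simulate"]["screening"]})
    tc = TrajectoryGeneratorConfig(**{"seed": seed + 1,
                                      **cfg["simulate"]["trajectory"]})
    screening = generate_screening_cohort(sc)
    trajectory = generate_trajectory_cohort(tc)
    screening.records.to_csv(outdir / "screening.csv", index=False)
    trajectory.scores.to_csv(outdir / "scores.csv", index=False)
    trajectory.subjects.to_csv(outdir / "subjects.csv", index=False)
    return {"screening_n": len(screening.records),
            "trajectory_n": len(trajectory.subjects),
            "trajectory_observations": len(trajectory.scores)}


def stage_screen(cfg: dict, outdir: Path) -> dict:
    """Screening validation: AUROC, cutpoint, projections, FP prognosis."""
    path = outdir / "screening.csv"
    if not path.exists():
        raise DataError(f"missing input {path}; run simulate first")
    records = pd.read_csv(path)
    _require_columns(records, SCREENING_COLUMNS, "screening.csv")
    labels = (records["severity_class"] == "moderate_severe").astype(int)
    scores = records["score"].to_numpy()

    roc = auroc(scores, labels, n_boot=cfg["screen"]["auroc_boot"],
                seed=cfg["seed"])
    cut, confusion = youden_cutpoint(scores, labels)
    prevalence = float(labels.mean())

    rows = [{"population_prevalence": prevalence, "observed": True,
             **prevalence_adjusted(confusion.sensitivity,
                                   confusion.specificity,
                                   prevalence).to_dict()}]
    for p in cfg["screen"]["prevalence_grid"]:
        rows.append({"population_prevalence": p, "observed": False,
                     **prevalence_adjusted(confusion.sensitivity,
                                           confusion.specificity,
                                           p).to_dict()})
    table1 = pd.DataFrame(rows)
    table1.to_csv(outdir / "table1.csv", index=False)

    prognosis = {}
    for outcome in ("as_hosp", "hf"):
        for adjusted in (False, True):
            key = f"{outcome}_{'adjusted' if adjusted else 'unadjusted'}"
            prognosis[key] = fp_prognosis(records, cut, outcome,
                                          adjusted=adjusted).to_dict()
    report = {
        "n": len(records),
        "prevalence": prevalence,
        "auroc": {"value": roc.value, "ci": [roc.ci_low, roc.ci_high]},
        "cutpoint": cut,
        "confusion": confusion.to_dict(),
        "projections": [r for r in rows],
        "fp_prognosis": prognosis,
    }
    _write_json(outdir / "screening_report.json", report)
    return report


def stage_cluster(cfg: dict, outdir: Path) -> dict:
    """Trajectory clustering: fit/select k, label, write assignments."""
    path = outdir / "scores.csv"
    if not path.exists():
        raise DataError(f"missing input {path}; run simulate first")
    scores = pd.read_csv(path)
    _require_columns(scores, SCORES_COLUMNS, "scores.csv")
    ccfg = cfg["cluster"]
    trajs = trajectories_from_frame(scores, min_obs=ccfg["min_obs"])

    diagnostics: dict = {"seed": cfg["seed"], "min_obs": ccfg["min_obs"]}
    if ccfg["k"] is None:
        lo, hi = ccfg["k_range"]
        chosen, table, models = select_k(
            trajs, k_range=range(lo, hi + 1),
            seeds_per_k=ccfg["seeds_per_k"], base_seed=cfg["seed"],
            spline_dof=ccfg["spline_dof"])
        model = models[chosen]
        diagnostics["selection"] = table.to_dict(orient="records")
        diagnostics["bic_silhouette_disagree"] = table.attrs[
            "bic_silhouette_disagree"]
    else:
        chosen = int(ccfg["k"])
        fits = [fit_em(trajs, chosen, seed=cfg["seed"] * 1000 + s,
                       spline_dof=ccfg["spline_dof"])
                for s in range(ccfg["n_restarts"])]
        model = min(fits, key=lambda m: m.within_mse)
    diagnostics["k"] = chosen
    diagnostics["bic"] = bic(model, trajs)
    diagnostics["within_mse"] = model.within_mse
    diagnostics["converged"] = model.converged
    diagnostics["n_iterations"] = model.n_iterations
    if chosen >= 2:
        diagnostics["silhouette"] = silhouette(model, trajs)[0]

    rep = stability(trajs, chosen, n_restarts=ccfg["stability_restarts"],
                    n_boot=ccfg["stability_boot"], seed=cfg["seed"],
                    spline_dof=ccfg["spline_dof"])
    diagnostics["stability"] = {
        "summary_ari": rep.summary_ari,
        "restart_mean_ari": rep.restart_mean,
        "bootstrap_mean_ari": rep.bootstrap_mean,
    }

    labels = label_clusters(model)
    out = pd.DataFrame({
        "subject_id": model.subject_ids,
        "cluster_index": model.assignments,
        "semantic_label": [str(labels[a]) for a in model.assignments],
        "distance_to_centroid": [
            trajectory_distance(t, model.centroids[a])
            for t, a in zip(trajs, model.assignments)],
    })
    out.to_csv(outdir / "clusters.csv", index=False)

    grid_rows = []
    for j, c in enumerate(model.centroids):
        xs, ys = c.grid(101)
        grid_rows.append(pd.DataFrame({
            "cluster_index": j, "semantic_label": str(labels[j]),
            "time_years_before_procedure": xs, "value": ys}))
    pd.concat(grid_rows).to_csv(outdir / "centroids.csv", index=False)
    counts = out["semantic_label"].value_counts(normalize=True)
    diagnostics["cluster_proportions"] = counts.to_dict()
    _write_json(outdir / "cluster_diagnostics.json", diagnostics)
    return diagnostics


def stage_survival(cfg: dict, outdir: Path) -> dict:
    """Cox ladder, reclassification and calibration from subjects + clusters."""
    for fname in ("subjects.csv", "clusters.csv"):
        if not (outdir / fname).exists():
            raise DataError(f"missing input {outdir / fname}")
    subjects = pd.read_csv(outdir / "subjects.csv")
    clusters = pd.read_csv(outdir / "clusters.csv")
    _require_columns(subjects, ["subject_id", "survival_time_years", "event"],
                     "subjects.csv")
    _require_columns(clusters, ["subject_id", "semantic_label"], "clusters.csv")
    df = subjects.merge(
        clusters[["subject_id", "semantic_label"]].rename(
            columns={"semantic_label": "cluster_label"}),
        on="subject_id", how="inner")

    scfg = cfg["survival"]
    cox_out = {}
    for model_id in (1, 2, 3):
        _, table = fit_cox_ladder(df, model_id)
        cox_out[f"model_{model_id}"] = table.to_dict(orient="records")
    _write_json(outdir / "cox_models.json", cox_out)

    reclass = {}
    for score_col in scfg["base_scores"]:
        for horizon in scfg["horizons"]:
            res = reclassification_analysis(
                df, score_col, horizon, categories=tuple(scfg["categories"]),
                n_boot=scfg["n_boot"], seed=cfg["seed"], mode=scfg["mode"])
            reclass[f"{score_col}_{horizon:g}y"] = res.to_dict()
    _write_json(outdir / "reclassification.json", reclass)

    # calibration of the primary base score at the longest horizon
    horizon = max(scfg["horizons"])
    from astraj.survival import _risk_model_probs
    probs = _risk_model_probs(df, scfg["base_scores"][0], cluster=False,
                              horizon=horizon, mode=scfg["mode"])
    calib = calibration_table(probs, df["survival_time_years"], df["event"],
                              horizon)
    calib.to_csv(outdir / "calibration.csv", index=False)
    _plot_calibration(calib, outdir / "calibration.svg", horizon)
    return {"cox_models": cox_out, "reclassification": reclass}


def _plot_calibration(calib: pd.DataFrame, path: Path, horizon: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(calib["predicted_mean"], calib["observed_km"], "o-",
            label="model")
    lim = max(calib[["predicted_mean", "observed_km"]].max().max(), 0.05)
    ax.plot([0, lim], [0, lim], "--", color="grey", label="ideal")
    ax.set_xlabel(f"mean predicted {horizon:g}-year mortality")
    ax.set_ylabel("observed (Kaplan-Meier)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def stage_timing(cfg: dict, outdir: Path) -> dict:
    """Threshold-crossing summaries from scores.csv."""
    path = outdir / "scores.csv"
    if not path.exists():
        raise DataError(f"missing input {path}; run simulate first")
    scores = pd.read_csv(path)
    _require_columns(scores, SCORES_COLUMNS, "scores.csv")
    tcfg = cfg["timing"]
    trajs = trajectories_from_frame(scores)
    report = {
        "first_crossings": [
            first_crossing(trajs, th, min_obs=tcfg["min_obs"]).to_dict()
            for th in tcfg["thresholds"]],
        "proportions_above": [
            proportion_above(trajs, th, at, window=tcfg["window"]).to_dict()
            for th in tcfg["proportion_thresholds"]
            for at in tcfg["proportion_times"]],
    }
    _write_json(outdir / "timing_report.json", report)
    return report


def stage_report(cfg: dict, outdir: Path) -> dict:
    """Collate stage JSONs into one summary document."""
    summary = {"version": __version__, "seed": cfg["seed"]}
    for name in ("screening_report", "cluster_diagnostics",
                 "reclassification", "timing_report"):
        p = outdir / f"{name}.json"
        if p.exists():
            summary[name] = json.loads(p.read_text())
    lines = ["# Pipeline summary", ""]
    if "screening_report" in summary:
        s = summary["screening_report"]
        lines += [f"- Screening n={s['n']}, AUROC {s['auroc']['value']:.3f} "
                  f"({s['auroc']['ci'][0]:.3f}-{s['auroc']['ci'][1]:.3f}), "
                  f"cutpoint {s['cutpoint']:.3f}"]
    if "cluster_diagnostics" in summary:
        c = summary["cluster_diagnostics"]
        lines += [f"- Clustering k={c['k']}, within-MSE {c['within_mse']:.4f}, "
                  f"stability ARI {c['stability']['summary_ari']:.3f}"]
    if "timing_report" in summary:
        for fc in summary["timing_report"]["first_crossings"]:
            if fc["mean_years_before"] is not None:
                lines += [f"- Score >{fc['threshold']} first detected "
                          f"{fc['mean_years_before']:.2f} y before procedure "
                          f"({fc['n_crossed']}/{fc['n_eligible']} subjects)"]
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
    _write_json(outdir / "summary.json", summary)
    return summary


STAGES = {
    "simulate": stage_simulate,
    "screen": stage_screen,
    "cluster": stage_cluster,
    "survival": stage_survival,
    "timing": stage_timing,
    "report": stage_report,
}
PIPELINE_ORDER = ["simulate", "screen", "cluster", "survival", "timing",
                  "report"]


def _config_hash(cfg: dict) -> str:
    # the output location is not an analysis parameter
    cfg = {k: v for k, v in cfg.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _file_checksums(outdir: Path) -> dict:
    out = {}
    for p in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json")):
        if p.name == "manifest.json":
            continue
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def run(command: str, config: dict | None = None,
        outdir: str | Path | None = None) -> dict:
    """Run one stage or the whole pipeline.

    ``command`` is one of simulate/screen/cluster/survival/timing/
    report/all.  Writes every stage artifact plus ``manifest.json``
    (config hash, seed, version, artifact checksums, wall times).
    """
    cfg = load_config(config)
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    if command != "all" and command not in STAGES:
        raise ConfigError(f"unknown command {command!r}")
    names = PIPELINE_ORDER if command == "all" else [command]
    results = {}
    timings = {}
    for name in names:
        t0 = time.perf_counter()
        log.info("stage %s starting", name)
        results[name] = STAGES[name](cfg, out)
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, timings[name])
    manifest = {"version": __version__, "seed": cfg["seed"],
                "config_hash": _config_hash(cfg), "stages": names,
                "wall_times_s": timings, "checksums": _file_checksums(out)}
    _write_json(out / "manifest.json", manifest)
    return results
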