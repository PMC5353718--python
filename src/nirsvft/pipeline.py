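"""End-to-end pipeline: simulate -> extract -> compare -> classify -> report.

Each stage reads and writes plain files (CSV/JSON/markdown), so the stages
compose on disk exactly as the single `run` entry point chains them; a rerun
with the same configuration reproduces byte-identical outputs.  The manifest
lists every artifact with its SHA-256 hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as classify_mod
from . import cohortstats, io, synthgen, waveform
from .config import ConfigError, PipelineConfig, WaveformConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage_simulate", "stage_extract", "stage_compare",
           "stage_classify", "stage_report"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_json_default,
                               sort_keys=True))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out_dir: Path) -> dict:
    sim = config.simulation
    sim.seed = config.seed if sim.seed == 0 else sim.seed
    cohort, recordings = synthgen.generate_study(sim)
    manifest = io.write_fixture_set(cohort, recordings, out_dir, config=sim)
    logger.info("simulate: wrote %d subjects to %s", len(cohort), out_dir)
    return manifest


def stage_extract(recordings_dir: Path, cohort_path: Path, out_path: Path,
                  wf_config: WaveformConfig) -> pd.DataFrame:
    cohort = io.read_cohort(cohort_path)
    rows = []
    for sid in cohort["id"]:
        rec_path = recordings_dir / f"{sid}.csv"
        if not rec_path.exists():
            raise FileNotFoundError(f"recording not found: {rec_path}")
        rec = io.read_recording(rec_path)
        rows.append(waveform.extract_features(rec, config=wf_config))
    features = waveform.features_frame(rows)
    features.to_csv(out_path, index=False)
    n_excluded = int((~features["qc_pass"]).sum())
    logger.info("extract: %d subjects, %d excluded by QC",
                len(features), n_excluded)
    return features


def stage_compare(features_path: Path, cohort_path: Path, out_dir: Path,
                  covariates) -> dict:
    features = pd.read_csv(features_path)
    subjects = io.read_cohort(cohort_path)
    results: dict = {"models": [], "demographics": None}

    demo = cohortstats.demographic_table(subjects)
    results["demographics"] = {
        "tests": demo.tests.to_dict(orient="records"),
        "summaries": demo.summaries.to_dict(orient="records"),
    }

    designs = [("diagnosis", "diagnosis")]
    diagnoses = [d for d in ("SCZ", "MDD", "BIP")
                 if d in set(subjects["diagnosis"])]
    if diagnoses:
        designs.append(("fh_any_pooled",
                        cohortstats.fh_grouping(subjects, level="any")))
        for dx in diagnoses:
            designs.append((f"fh_any_{dx}",
                            cohortstats.fh_grouping(subjects, level="any",
                                                    diagnosis=dx)))
    for dependent in ("integral_value", "centroid_value_s"):
        for name, grouping in designs:
            try:
                res = cohortstats.ancova(features, subjects, dependent,
                                         grouping, covariates)
            except ValueError as exc:
                logger.warning("compare: skipping %s/%s (%s)",
                               dependent, name, exc)
                continue
            posthoc = cohortstats.lsd_posthoc(res)
            results["models"].append({
                "dependent": dependent,
                "design": name,
                "levels": res.factor_levels,
                "F": res.F, "df_num": res.df_num, "df_den": res.df_den,
                "p": res.p, "n_used": res.n_used, "n_dropped": res.n_dropped,
                "posthoc": [{
                    "pair": list(ph.pair),
                    "adjusted_mean_diff": ph.adjusted_mean_diff,
                    "lsd_p": ph.lsd_p,
                    "cohens_d": ph.cohens_d,
                } for ph in posthoc],
            })

    clinical = [v for v in ("cpz_eq_mg_day", "onset_age_years",
                            "illness_duration_years", "vft_performance")
                if v in subjects.columns]
    corr = cohortstats.spearman_correlations(features, subjects, clinical)
    results["correlations"] = corr.to_dict(orient="records")

    _write_json(out_dir / "group_stats.json", results)
    return results


def stage_classify(features_path: Path, cohort_path: Path, out_dir: Path,
                   integral_threshold: float, centroid_threshold_s: float) -> dict:
    features = pd.read_csv(features_path)
    subjects = io.read_cohort(cohort_path)
    per_subject = classify_mod.classify_features(
        features, integral_threshold, centroid_threshold_s)
    per_subject = per_subject.merge(
        subjects[["id", "diagnosis"]], left_on="subject_id", right_on="id",
        how="left").drop(columns="id")
    per_subject.to_csv(out_dir / "classification.csv", index=False)
    summary = classify_mod.summarize_classification(
        features, subjects, "diagnosis",
        integral_threshold, centroid_threshold_s)
    summary_dict = summary.to_dict(orient="records")
    _write_json(out_dir / "classification_summary.json", {
        "integral_threshold": integral_threshold,
        "centroid_threshold_s": centroid_threshold_s,
        "groups": summary_dict,
    })
    return {"groups": summary_dict}


def stage_report(out_dir: Path) -> Path:
    """Human-readable markdown digest of the compare and classify outputs."""
    stats = json.loads((out_dir / "group_stats.json").read_text())
    cls = json.loads((out_dir / "classification_summary.json").read_text())
    lines = ["# Frontal activation analysis report", ""]
    lines += ["## Group models (ANCOVA)", "",
              "| dependent | design | F | df | p |", "|---|---|---|---|---|"]
    for m in stats["models"]:
        lines.append(f"| {m['dependent']} | {m['design']} | {m['F']:.2f} | "
                     f"{m['df_num']},{m['df_den']} | {m['p']:.3g} |")
    lines += ["", "## Pairwise contrasts (LSD, Cohen's d)", "",
              "| dependent | design | pair | adj. diff | p | d |",
              "|---|---|---|---|---|---|"]
    for m in stats["models"]:
        for ph in m["posthoc"]:
            lines.append(
                f"| {m['dependent']} | {m['design']} | {' vs '.join(ph['pair'])} "
                f"| {ph['adjusted_mean_diff']:.2f} | {ph['lsd_p']:.3g} "
                f"| {ph['cohens_d']:.2f} |")
    lines += ["", "## Threshold classification", "",
              f"Integral threshold {cls['integral_threshold']}, centroid "
              f"threshold {cls['centroid_threshold_s']} s.", "",
              "| group | n | % patient | % psychosis-spectrum |",
              "|---|---|---|---|"]
    for g in cls["groups"]:
        lines.append(f"| {g['group']} | {g['n']} | "
                     f"{g['pct_classified_patient']:.1f} | "
                     f"{g['pct_classified_psychosis_spectrum']:.1f} |")
    path = out_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return a manifest of outputs with hashes."""
    config.validate(check_paths=True)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    timings = {}
    t0 = time.perf_counter()
    if config.cohort_path is None:
        sim_dir = out_dir / "simulated"
        stage_simulate(config, sim_dir)
        cohort_path = sim_dir / "cohort.csv"
        recordings_dir = sim_dir / "recordings"
    else:
        cohort_path = Path(config.cohort_path)
        recordings_dir = Path(config.recordings_dir)
        if not cohort_path.exists() or not recordings_dir.exists():
            raise ConfigError(f"input paths missing: {cohort_path}, "
                              f"{recordings_dir}")
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    features_path = out_dir / "features.csv"
    stage_extract(recordings_dir, cohort_path, features_path, config.waveform)
    timings["extract"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stage_compare(features_path, cohort_path, out_dir, config.covariates)
    timings["compare"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stage_classify(features_path, cohort_path, out_dir,
                   config.integral_threshold, config.centroid_threshold_s)
    timings["classify"] = time.perf_counter() - t0

    stage_report(out_dir)
    for stage, sec in timings.items():
        logger.info("stage %s: %.2f s", stage, sec)

    artifacts = ["features.csv", "group_stats.json", "classification.csv",
                 "classification_summary.json", "report.md"]
    if config.cohort_path is None:
        artifacts += ["simulated/cohort.csv", "simulated/ground_truth.json",
                      "simulated/manifest.json"]
    manifest = {
        "outputs": {a: _sha256(out_dir / a) for a in artifacts},
        "seed": config.seed,
    }
    _write_json(out_dir / "pipeline_manifest.json", manifest)
    return manifest
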