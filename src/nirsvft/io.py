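"""Reading and writing the fixture-set layout.

A fixture set is a directory with::

    cohort.csv            one row per subject (column dictionary in README)
    recordings/<id>.csv   time_s plus one column per channel
    ground_truth.json     generator truth: amplitude, latency, bad channels
    manifest.json         subject ids, file names, config echo

Recording CSVs have a ``time_s`` column followed by ``ch01..chNN``; values
round-trip through text at 10 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PRE_TASK_S, TASK_S, TOTAL_S, SimulationConfig
from .synthgen import Recording, Subject

_FH_COLS = ("fh_any_psychiatric", "fh_major_psychiatric", "fh_same_disorder")
_SYMPTOM_PREFIX = "symptom_"


def cohort_to_frame(cohort: Sequence[Subject]) -> pd.DataFrame:
    """Tabulate a cohort; FH flags are object columns holding True/False/None."""
    rows = []
    for s in cohort:
        d = dataclasses.asdict(s)
        scores = d.pop("symptom_scores") or {}
        for k, v in scores.items():
            d[f"{_SYMPTOM_PREFIX}{k}"] = v
        rows.append(d)
    frame = pd.DataFrame(rows)
    for col in _FH_COLS:
        frame[col] = frame[col].astype(object)
    return frame


def frame_to_cohort(frame: pd.DataFrame) -> list[Subject]:
    subjects = []
    for _, row in frame.iterrows():
        scores = {
            c[len(_SYMPTOM_PREFIX):]: float(row[c])
            for c in frame.columns
            if c.startswith(_SYMPTOM_PREFIX) and pd.notna(row[c])
        }
        kw = {}
        for fieldname in ("cpz_eq_mg_day", "onset_age_years",
                          "illness_duration_years"):
            v = row.get(fieldname)
            kw[fieldname] = None if pd.isna(v) else float(v)
        subjects.append(Subject(
            id=str(row["id"]),
            diagnosis=str(row["diagnosis"]),
            fh_any_psychiatric=_parse_flag(row["fh_any_psychiatric"]),
            fh_major_psychiatric=_parse_flag(row["fh_major_psychiatric"]),
            fh_same_disorder=_parse_flag(row["fh_same_disorder"]),
            age_years=float(row["age_years"]),
            gender=str(row["gender"]),
            education_years=float(row["education_years"]),
            premorbid_iq=float(row["premorbid_iq"]),
            handedness=str(row["handedness"]),
            vft_performance=int(row["vft_performance"]),
            symptom_scores=scores,
            **kw,
        ))
    return subjects


def _parse_flag(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "yes", "1")


def write_cohort(cohort: Sequence[Subject], path: Path) -> None:
    frame = cohort_to_frame(cohort)
    for col in _FH_COLS:
        frame[col] = frame[col].map(
            lambda v: "" if v is None else ("yes" if v else "no"))
    frame.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, keep_default_na=True)
    for col in _FH_COLS:
        frame[col] = frame[col].map(
            lambda v: None if pd.isna(v) else str(v).strip().lower() == "yes"
        ).astype(object)
    return frame


def write_recording(recording: Recording, path: Path) -> None:
    n_ch = recording.n_channels
    header = "time_s," + ",".join(f"ch{i + 1:02d}" for i in range(n_ch))
    data = np.column_stack([recording.times(), recording.channels.T])
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt="%.10g")


def read_recording(
    path: str | Path,
    task_onset_s: float = PRE_TASK_S,
    task_offset_s: float = PRE_TASK_S + TASK_S,
    end_s: float = TOTAL_S,
) -> Recording:
    """Load a recording CSV (or TSV); channel columns are all but ``time_s``."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    if "time_s" not in frame.columns or frame.shape[1] < 2 or frame.shape[0] < 2:
        raise ValueError(f"malformed recording file: {path}")
    times = frame["time_s"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(times)))
    channels = frame.drop(columns="time_s").to_numpy(dtype=float).T
    return Recording(
        subject_id=path.stem,
        sampling_interval_s=dt,
        channels=channels,
        task_onset_s=task_onset_s,
        task_offset_s=task_offset_s,
        end_s=end_s,
    )


def write_fixture_set(
    cohort: Sequence[Subject],
    recordings: Sequence[Recording],
    directory: str | Path,
    config: SimulationConfig | None = None,
) -> dict:
    """Write cohort table, per-subject recording CSVs, ground truth, manifest.

    Requires exactly one recording per subject; returns the manifest dict.
    """
    if len(cohort) != len(recordings):
        raise ValueError(
            f"{len(cohort)} subjects but {len(recordings)} recordings")
    directory = Path(directory)
    rec_dir = directory / "recordings"
    try:
        rec_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc

    write_cohort(cohort, directory / "cohort.csv")

    truth = {}
    files = {}
    by_id = {r.subject_id: r for r in recordings}
    for subject in cohort:
        rec = by_id[subject.id]
        fname = f"recordings/{subject.id}.csv"
        write_recording(rec, directory / fname)
        files[subject.id] = fname
        if rec.ground_truth is not None:
            truth[subject.id] = rec.ground_truth
    (directory / "ground_truth.json").write_text(json.dumps(truth, indent=1))

    manifest = {
        "n_subjects": len(cohort),
        "cohort": "cohort.csv",
        "recordings": files,
        "ground_truth": "ground_truth.json",
        "config": dataclasses.asdict(config) if config is not None else None,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_manifest(directory: str | Path) -> dict:
    return json.loads((Path(directory) / "manifest.json").read_text())
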