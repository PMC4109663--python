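"""Protocol emulation and accuracy statistics.

Covers three things: (a) the offline day-by-day evaluation loop — before
each testing day the whole pipeline (γ*, feature standardization, SVM) is
recalibrated on every preceding session, then every flash of that day is
classified with the fixed γ*; (b) the closed-loop "circle game" session
dynamics (one step per detected P300, four steps to reach an image, 92-flash
timeout); (c) the published accuracy tables of the reference study (21 ALS
patients and 9 controls × 4 testing days × multichannel/single-channel
systems), packaged as fixtures, with the summary statistics computed from
them: medians, Hazen quartiles, per-day maxima and paired Wilcoxon tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .pipeline import make_single_channel_pipeline
from .simulate import Study, SubjectData, epochs_to_array
from .stats import median, percentile, wilcoxon_paired

__all__ = [
    "SessionState",
    "simulate_session",
    "run_day_evaluation",
    "evaluate_study",
    "load_accuracy_tables",
    "reproduce_headline_stats",
]

TESTING_DAYS = ("T1", "T2", "T3", "T4")
MAX_FLASHES = 92
STEPS_TO_REACH = 4

_AXES = {"up": (0, 1), "down": (0, -1), "right": (1, 0), "left": (-1, 0)}


@dataclass
class SessionState:
    """Outcome of one closed-loop session of the circle game."""

    position: tuple
    flash_count: int
    desired_direction: str
    terminated: str  # "reached", "timeout" or "running"
    reached_direction: str | None = None


def simulate_session(predictions_stream, desired_direction: str, max_flashes: int = MAX_FLASHES) -> SessionState:
    """Play the circle game from a stream of (flashed_direction, prediction).

    A predicted target moves the circle one step toward the flashed arrow —
    whether or not that arrow was the desired one, so false positives move
    the circle toward a wrong image.  The session ends when any image is
    reached (4 steps out along its axis) or after ``max_flashes`` flashes.
    """
    if desired_direction not in _AXES:
        raise ValueError(f"unknown direction {desired_direction!r}")
    x = y = 0
    flashes = 0
    for direction, prediction in predictions_stream:
        if flashes >= max_flashes:
            break
        dx, dy = _AXES[direction]
        flashes += 1
        if prediction == "target":
            x += dx
            y += dy
        if abs(x) >= STEPS_TO_REACH or abs(y) >= STEPS_TO_REACH:
            reached = (
                ("right" if x > 0 else "left")
                if abs(x) >= STEPS_TO_REACH
                else ("up" if y > 0 else "down")
            )
            return SessionState((x, y), flashes, desired_direction, "reached", reached)
    status = "timeout" if flashes >= max_flashes else "running"
    return SessionState((x, y), flashes, desired_direction, status, None)


def _training_days(day: str) -> tuple:
    i = TESTING_DAYS.index(day)
    return ("calibration",) + TESTING_DAYS[:i]


def run_day_evaluation(subject: SubjectData, day: str, pipeline=None, random_state=0) -> dict:
    """Train on all sessions preceding ``day`` and classify its flashes.

    Returns a dict with the per-stimulus accuracy (percent), the fitted γ*,
    predictions and labels.  T1 trains on the 8 calibration sessions only;
    T3 on calibration + T1 + T2; and so on.
    """
    if day not in TESTING_DAYS:
        raise ValueError(f"day must be one of {TESTING_DAYS}, got {day!r}")
    train_sessions = subject.sessions_for(_training_days(day))
    test_sessions = subject.sessions_for(day)
    if not train_sessions:
        raise ValueError(f"no calibration sessions precede {day}")
    X_train, y_train = epochs_to_array([e for s in train_sessions for e in s.epochs])
    X_test, y_test = epochs_to_array([e for s in test_sessions for e in s.epochs])
    if pipeline is None:
        pipeline = make_single_channel_pipeline(random_state=random_state)
    pipeline.fit(X_train, y_train)
    y_pred = pipeline.predict(X_test)
    return {
        "subject_id": subject.subject_id,
        "day": day,
        "accuracy_percent": 100.0 * float(np.mean(y_pred == y_test)),
        "n_flashes": int(y_test.size),
        "gamma_star": float(pipeline.named_steps["smoother"].gamma_star_),
        "predictions": y_pred,
        "labels": y_test,
    }


def evaluate_study(study: Study, days=TESTING_DAYS, random_state=0, pipeline_factory=None) -> pd.DataFrame:
    """Per-subject, per-day single-channel accuracy over a whole study."""
    rows = []
    for subject in study.subjects:
        for day in days:
            pipeline = None if pipeline_factory is None else pipeline_factory()
            res = run_day_evaluation(subject, day, pipeline=pipeline, random_state=random_state)
            rows.append({k: res[k] for k in ("subject_id", "day", "accuracy_percent", "n_flashes", "gamma_star")})
    return pd.DataFrame(rows)


def load_accuracy_tables() -> pd.DataFrame:
    """Packaged per-subject accuracy tables of the reference study, tidy form.

    Columns: subject, group ("ALS"/"control"), day ("T1".."T4"), system
    ("MC"/"SC"), accuracy_percent.  Cells are transcribed verbatim (comma
    decimals in the files, normalized here; the one three-decimal cell 79,12
    is kept as 79.12).
    """
    frames = []
    for fname, group in (("table1_als.csv", "ALS"), ("table2_controls.csv", "control")):
        with resources.files("bayeserp.data").joinpath(fname).open("r") as fh:
            wide = pd.read_csv(fh, sep=";", decimal=",")
        long = wide.melt(id_vars="subject", var_name="col", value_name="accuracy_percent")
        long[["day", "system"]] = long["col"].str.split("_", expand=True)
        long["group"] = group
        frames.append(long.drop(columns="col"))
    df = pd.concat(frames, ignore_index=True)
    if not ((df["accuracy_percent"] >= 0) & (df["accuracy_percent"] <= 100)).all():
        raise ValueError("accuracy outside [0, 100] in fixture tables")
    return df[["subject", "group", "day", "system", "accuracy_percent"]]


def _column(df: pd.DataFrame, group: str, day: str, system: str) -> np.ndarray:
    sel = (df["group"] == group) & (df["day"] == day) & (df["system"] == system)
    return df.loc[sel, "accuracy_percent"].to_numpy()


def reproduce_headline_stats(tables: pd.DataFrame | None = None) -> dict:
    """Recompute the headline statistics from the packaged tables.

    Returns a nested dict with, per group/day/system: median, Hazen 25th and
    75th percentiles and maximum; plus the per-day paired Wilcoxon p-values
    (MC vs SC within group), the largest |median difference| between the two
    systems, and the best per-day improvement of the single-channel maximum
    over the multichannel maximum for the patient group.
    """
    df = load_accuracy_tables() if tables is None else tables
    out: dict = {"by_cell": {}, "wilcoxon": {}, "max_abs_median_difference": 0.0}
    max_diff = 0.0
    for group in ("ALS", "control"):
        for day in TESTING_DAYS:
            medians = {}
            for system in ("MC", "SC"):
                col = _column(df, group, day, system)
                out["by_cell"][(group, day, system)] = {
                    "median": median(col),
                    "p25": percentile(col, 25.0),
                    "p75": percentile(col, 75.0),
                    "max": float(np.max(col)),
                }
                medians[system] = out["by_cell"][(group, day, system)]["median"]
            max_diff = max(max_diff, abs(medians["SC"] - medians["MC"]))
            stat, p = wilcoxon_paired(
                _column(df, group, day, "SC"), _column(df, group, day, "MC")
            )
            out["wilcoxon"][(group, day)] = {"statistic": stat, "p_value": p}
    out["max_abs_median_difference"] = max_diff
    improvements = {
        day: out["by_cell"][("ALS", day, "SC")]["max"] - out["by_cell"][("ALS", day, "MC")]["max"]
        for day in TESTING_DAYS
    }
    best_day = max(improvements, key=improvements.get)
    out["als_max_improvement"] = {"day": best_day, "value": improvements[best_day]}
    return out
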