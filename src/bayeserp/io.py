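"""Plain-text session serialization.

One CSV per session (columns epoch, sample, value — prestimulus samples are
indices 0–99, poststimulus 100–299) plus a JSON sidecar with labels, flash
directions and subject/day metadata, and an aggregate manifest per study.
Round-trips are lossless (values written with repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import FS_HZ, N_PRE, RawEpoch, SessionData, Study, SubjectData

__all__ = ["save_session", "load_session", "save_study", "load_study"]


def _session_stem(subject_id: str, day: str, index: int) -> str:
    return f"{subject_id}_{day}_s{index:02d}"


def save_session(session: SessionData, subject: SubjectData, out_dir) -> tuple:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = _session_stem(subject.subject_id, session.day, session.index)
    rows = []
    for i, epoch in enumerate(session.epochs):
        sweep = np.concatenate([epoch.pre, epoch.post])
        for j, v in enumerate(sweep):
            rows.append((i, j, repr(float(v))))
    csv_path = out_dir / f"{stem}.csv"
    pd.DataFrame(rows, columns=["epoch", "sample", "value"]).to_csv(csv_path, index=False)
    meta = {
        "subject_id": subject.subject_id,
        "day": session.day,
        "session": session.index,
        "fs_hz": FS_HZ,
        "n_pre": N_PRE,
        "desired_direction": session.desired_direction,
        "flashed_directions": list(session.flashed_directions),
        "labels": [e.label for e in session.epochs],
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path, json_path


def load_session(csv_path) -> SessionData:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    epochs = []
    for i, label in enumerate(meta["labels"]):
        sweep = df.loc[df["epoch"] == i].sort_values("sample")["value"].to_numpy(dtype=float)
        epochs.append(
            RawEpoch(
                pre=sweep[: meta["n_pre"]],
                post=sweep[meta["n_pre"] :],
                label=label,
                subject_id=meta["subject_id"],
                day=meta["day"],
                session=meta["session"],
            )
        )
    return SessionData(
        day=meta["day"],
        index=meta["session"],
        desired_direction=meta["desired_direction"],
        flashed_directions=meta["flashed_directions"],
        epochs=epochs,
    )


def save_study(study: Study, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": study.seed, "subjects": []}
    for subject in study.subjects:
        entry = {
            "subject_id": subject.subject_id,
            "snr_db": subject.snr_db,
            "template": {
                "peak_latency_ms": subject.template.peak_latency_ms,
                "peak_amplitude": subject.template.peak_amplitude,
                "fwhm_ms": subject.template.fwhm_ms,
            },
            "noise": {
                "ar_coeffs": list(subject.noise.ar_coeffs),
                "innovation_var": subject.noise.innovation_var,
                "drift_amplitude": subject.noise.drift_amplitude,
            },
            "sessions": [],
        }
        for session in subject.sessions:
            csv_path, _ = save_session(session, subject, out_dir)
            entry["sessions"].append(csv_path.name)
        manifest["subjects"].append(entry)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_study(manifest_path) -> Study:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    from .simulate import NoiseSpec, make_erp_template

    subjects = []
    for entry in manifest["subjects"]:
        t = entry["template"]
        subject = SubjectData(
            subject_id=entry["subject_id"],
            template=make_erp_template(
                t["peak_latency_ms"], t["peak_amplitude"], t["fwhm_ms"]
            ),
            noise=NoiseSpec(
                ar_coeffs=tuple(entry["noise"]["ar_coeffs"]),
                innovation_var=entry["noise"]["innovation_var"],
                drift_amplitude=entry["noise"]["drift_amplitude"],
            ),
            snr_db=entry["snr_db"],
        )
        for name in entry["sessions"]:
            subject.sessions.append(load_session(manifest_path.parent / name))
        subjects.append(subject)
    return Study(subjects=subjects, seed=manifest.get("seed"))
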