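"""Plain-text persistence for pipeline inputs and outputs.

All formats are UTF-8 CSV with a header row and "." decimal separator, plus
JSON for nested reports: tracking series, event logs, long-format feature
rows (subject, variable, session, value, class) and ground-truth records.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import Bout, GroomingLog, TrackingSeries
from .discriminant import FeatureMatrix
from .synthetic import GroundTruth


def write_tracking_csv(series: TrackingSeries, path: str | Path) -> None:
    df = series.to_frame()
    df.insert(0, "subject", series.subject)
    df.insert(1, "fps", series.fps)
    df.to_csv(path, index=False)


def read_tracking_csv(path: str | Path) -> TrackingSeries:
    df = pd.read_csv(path)
    nose = "nose_x" in df.columns
    return TrackingSeries(
        subject=str(df["subject"].iloc[0]),
        fps=float(df["fps"].iloc[0]),
        t=df["t"].to_numpy(),
        body_x=df["body_x"].to_numpy(),
        body_y=df["body_y"].to_numpy(),
        nose_x=df["nose_x"].to_numpy() if nose else None,
        nose_y=df["nose_y"].to_numpy() if nose else None,
    )


def write_event_log_csv(log: GroomingLog, path: str | Path) -> None:
    rows = [
        {
            "subject": log.subject,
            "behavior": b.behavior,
            "start_s": b.start,
            "stop_s": b.stop,
        }
        for b in log.bouts
    ]
    df = pd.DataFrame(rows, columns=["subject", "behavior", "start_s", "stop_s"])
    df.attrs["session_duration"] = log.session_duration
    df.to_csv(path, index=False)


def read_event_log_csv(
    path: str | Path, session_duration: float
) -> GroomingLog:
    df = pd.read_csv(path)
    bouts = [
        Bout(float(r.start_s), float(r.stop_s), str(r.behavior))
        for r in df.itertuples()
    ]
    subject = str(df["subject"].iloc[0]) if len(df) else "unknown"
    return GroomingLog(subject, bouts, session_duration)


def write_feature_rows_csv(fm: FeatureMatrix, path: str | Path) -> None:
    """Long-format feature rows: subject, variable, session, value, class."""
    sessions = fm.meta_col("session")
    groups = fm.meta_col("group")
    rows = []
    for col in fm.data.columns:
        base = groups.get(col)
        base = col if base is None or (isinstance(base, float) and np.isnan(base)) else base
        sess = sessions.get(col)
        sess = "" if sess is None or (isinstance(sess, float) and np.isnan(sess)) else int(sess)
        for subject, value in fm.data[col].items():
            rows.append(
                {
                    "subject": subject,
                    "variable": base,
                    "session": sess,
                    "value": value,
                    "class": fm.labels[subject],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_rows_csv(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, keep_default_na=True)
    labels = df.drop_duplicates("subject").set_index("subject")["class"]
    multi = df["session"].notna() & (df["session"].astype(str) != "")
    meta_rows = {}
    wide = {}
    for (variable, session), sub in df.groupby(
        ["variable", "session"], dropna=False, sort=False
    ):
        is_multi = bool(pd.notna(session) and str(session) != "")
        col = f"{variable}::s{int(session)}" if is_multi else str(variable)
        wide[col] = sub.set_index("subject")["value"]
        meta_rows[col] = {
            "multi_session": is_multi,
            "group": variable,
            "session": int(session) if is_multi else None,
        }
    data = pd.DataFrame(wide).reindex(labels.index)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").reindex(data.columns)
    del multi
    return FeatureMatrix(data, labels, meta)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return obj


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(truth), indent=1))


def write_report_json(report, path: str | Path) -> None:
    """Serialize any report dataclass (PreprocessReport, ShuffleReport, ...)."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=1))
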