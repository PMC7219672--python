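"""CSV readers and writers for accelerometer streams and feature tables.

Two plain-text interchange formats:

* accelerometer CSV — header ``time,ax,ay,az`` (an optional ``label`` and
  ``window_id`` column mark synthetic labelled windows), values in g;
* feature CSV — header ``start_index,a4_1..a4_8,mu,var,fd1..fd4,label``
  with the 14 features in the fixed order the classifier expects.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from fracfall.classify import FEATURE_NAMES, FeatureVector
from fracfall.preprocess import TriaxialSegment

ACCEL_COLUMNS = ("time", "ax", "ay", "az")


def read_accel_csv(path: str | Path, fs: float = 32.0) -> TriaxialSegment:
    """Read a triaxial accelerometer CSV into a segment.

    Requires the header columns ``ax, ay, az`` (``time`` is accepted and
    ignored for the segment itself).  Non-numeric cells are reported with
    their line number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("ax", "ay", "az") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    for col in ("ax", "ay", "az"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: non-numeric value in column {col} at line {line}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ValueError(f"{path}: empty value in column {col} at line {line}")
        df[col] = coerced
    return TriaxialSegment(
        ax=df["ax"].to_numpy(), ay=df["ay"].to_numpy(), az=df["az"].to_numpy(), fs=fs
    )


def write_accel_csv(
    seg: TriaxialSegment, path: str | Path, label: str | None = None
) -> None:
    """Write a segment as ``time,ax,ay,az[,label]``."""
    n = len(seg)
    df = pd.DataFrame(
        {
            "time": np.arange(n) / seg.fs,
            "ax": seg.ax,
            "ay": seg.ay,
            "az": seg.az,
        }
    )
    if label is not None:
        df["label"] = label
    df.to_csv(path, index=False)


def write_dataset_csv(
    segments: list[TriaxialSegment], labels: list[str], path: str | Path
) -> None:
    """Write labelled windows as one long CSV with a ``window_id`` column."""
    frames = []
    for wid, (seg, lab) in enumerate(zip(segments, labels)):
        n = len(seg)
        frames.append(
            pd.DataFrame(
                {
                    "time": np.arange(n) / seg.fs,
                    "ax": seg.ax,
                    "ay": seg.ay,
                    "az": seg.az,
                    "label": lab,
                    "window_id": wid,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dataset_csv(
    path: str | Path, fs: float = 32.0
) -> tuple[list[TriaxialSegment], list[str]]:
    """Read a labelled-window CSV written by :func:`write_dataset_csv`."""
    df = pd.read_csv(path)
    required = {"ax", "ay", "az", "label", "window_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(sorted(missing))}")
    segments, labels = [], []
    for _, grp in df.groupby("window_id", sort=True):
        segments.append(
            TriaxialSegment(
                ax=grp["ax"].to_numpy(),
                ay=grp["ay"].to_numpy(),
                az=grp["az"].to_numpy(),
                fs=fs,
            )
        )
        labels.append(str(grp["label"].iloc[0]))
    return segments, labels


def write_features_csv(features: list[FeatureVector], path: str | Path) -> None:
    """Write feature vectors in the fixed 14-column order plus label/start."""
    rows = []
    for fv in features:
        row = dict(zip(FEATURE_NAMES, fv.to_array()))
        row["start_index"] = fv.start_index
        row["label"] = fv.label if fv.label is not None else ""
        rows.append(row)
    cols = ["start_index", *FEATURE_NAMES, "label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read a feature CSV; returns (X matrix, labels, start indices)."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature column(s) {', '.join(missing)}")
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    labels = [str(v) for v in df.get("label", pd.Series([""] * len(df)))]
    starts = df.get("start_index", pd.Series(np.zeros(len(df)))).to_numpy(dtype=int)
    return X, labels, starts
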