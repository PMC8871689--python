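"""Reading and writing signals and artifact annotations.

Signals travel as CSV with a header row, one sample per row; the sampling
rate is supplied by the caller (it is not inferred from the file).
Annotations are written twice: a human-readable CSV in seconds and a JSON
mirror that also keeps the exact sample indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import ArtifactAnnotation, ArtifactSegment
from .timeseries import TimeSeries

#: float format preserving full double precision on round trips
FLOAT_FMT = "%.17g"


def read_timeseries(
    path: str | Path,
    fs: float,
    column: str | None = None,
    label: str | None = None,
    kind: str = "hemoglobin",
) -> TimeSeries:
    """Read one column of a delimited text file as a :class:`TimeSeries`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row (delimiter sniffed by pandas).
    fs
        Declared sampling rate in Hz.
    column
        Column name to read; default is the first column.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: file is empty")
    sep = "\t" if "\t" in header else ","
    try:
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise ValueError(f"{path}: no data rows found")
    if column is None:
        column = str(frame.columns[0])
    if column not in frame.columns:
        raise ValueError(
            f"{path}: column {column!r} not found; available: "
            f"{list(frame.columns)}"
        )
    raw = pd.to_numeric(frame[column], errors="coerce")
    bad = np.flatnonzero(raw.isna().to_numpy() & frame[column].notna().to_numpy())
    if raw.isna().any():
        row = int(np.flatnonzero(raw.isna().to_numpy())[0]) if bad.size == 0 else int(bad[0])
        raise ValueError(
            f"{path}: non-numeric or missing value in column {column!r} "
            f"at data row {row}"
        )
    return TimeSeries(
        values=raw.to_numpy(dtype=float),
        fs=fs,
        label=label if label is not None else column,
        kind=kind,
    )


def write_timeseries(path: str | Path, ts: TimeSeries) -> Path:
    """Write a series to CSV with 17 significant digits (lossless)."""
    path = Path(path)
    name = ts.label or "value"
    pd.DataFrame({name: ts.values}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )
    return path


def write_table(path: str | Path, frame: pd.DataFrame) -> Path:
    """Write a multi-column table (e.g. dual-wavelength OD) losslessly."""
    path = Path(path)
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def _json_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def write_annotation(
    path: str | Path, annotation: ArtifactAnnotation, fs: float
) -> Path:
    """Write an annotation as CSV (seconds) plus a JSON mirror (samples).

    The CSV has one record per segment with half-open ``start_seconds`` /
    ``end_seconds`` bounds; the JSON sidecar keeps exact sample indices so
    read-back is lossless.
    """
    path = Path(path)
    annotation.validate()
    rows = [
        {
            "start_seconds": s.start / fs,
            "end_seconds": s.end / fs,
            "category": s.category,
            "source": s.source,
        }
        for s in annotation.segments
    ]
    pd.DataFrame(
        rows, columns=["start_seconds", "end_seconds", "category", "source"]
    ).to_csv(path, index=False, float_format=FLOAT_FMT)
    mirror = {
        "n_samples": annotation.n_samples,
        "fs": fs,
        "segments": [
            {
                "start": s.start,
                "end": s.end,
                "category": s.category,
                "source": s.source,
            }
            for s in annotation.segments
        ],
    }
    _json_sidecar(path).write_text(json.dumps(mirror, indent=1))
    return path


def read_annotation(path: str | Path) -> ArtifactAnnotation:
    """Read an annotation from the JSON mirror written by ``write_annotation``."""
    path = Path(path)
    data = json.loads(_json_sidecar(path).read_text())
    segments = [
        ArtifactSegment(
            start=int(s["start"]),
            end=int(s["end"]),
            category=s["category"],
            source=s.get("source", "fnirs"),
        )
        for s in data["segments"]
    ]
    return ArtifactAnnotation(
        segments=segments, n_samples=int(data["n_samples"])
    ).validate()
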