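"""Time-course containers, delimited-text I/O, and temporal band-pass filtering.

The analysis consumes per-subject component time-course matrices
(timepoints x components), typically back-reconstructed ICA time courses
from resting-state fMRI. Image-domain preprocessing (motion correction,
normalisation, smoothing) and the ICA decomposition itself happen upstream;
here we only load matrices, validate them, and apply the 0.01-0.10 Hz
band-pass that precedes partial-correlation estimation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SubjectTimecourses",
    "read_timecourses",
    "write_timecourses",
    "read_manifest",
    "write_manifest",
    "bandpass",
]


@dataclass(frozen=True)
class SubjectTimecourses:
    """One subject's component time courses.

    Parameters
    ----------
    data : ndarray, shape (n_timepoints, n_components)
        One column per component, one row per scan volume.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    subject_id : str
        Identifier used in manifests and output files.
    group : str
        Group label (e.g. ``"HC"`` / ``"SZ"``).
    component_ids : tuple of str
        Column labels; defaults to ``IC1..ICn``.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = "subject"
    group: str = ""
    component_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D, got shape {data.shape}")
        if data.shape[0] <= 3:
            raise ValueError(
                f"need more than 3 timepoints, got {data.shape[0]}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("time courses contain missing/non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", data)
        ids = tuple(self.component_ids) or tuple(
            f"IC{i + 1}" for i in range(data.shape[1])
        )
        if len(ids) != data.shape[1]:
            raise ValueError("component_ids length must match column count")
        object.__setattr__(self, "component_ids", ids)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()[0] if path.stat().st_size else ""
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_timecourses(
    path: str | Path,
    tr_seconds: float,
    subject_id: str | None = None,
    group: str = "",
) -> SubjectTimecourses:
    """Load a timepoints x components matrix from TSV/CSV.

    The delimiter is auto-detected (tab or comma). A header row of
    component ids is optional. A non-numeric body cell raises a parse
    error naming the offending row and column; a constant column raises
    a validation error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time-course file not found: {path}")
    sep = _sniff_delimiter(path)
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = not all(
        isinstance(v, (int, float, np.integer, np.floating))
        for v in first.iloc[0]
    )
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    component_ids = (
        tuple(str(c) for c in df.columns) if has_header else ()
    )
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell in {path.name} at row {row + 1}, "
                f"column {j + 1} ({df[col].iloc[row]!r})"
            )
        df[col] = numeric
    if df.isna().any().any():
        raise ValueError(f"missing values in {path.name}")
    dead = np.flatnonzero(df.to_numpy(dtype=float).var(axis=0) == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance (constant) column(s) {dead.tolist()} in "
            f"{path.name}: constant signals cannot enter correlation"
        )
    return SubjectTimecourses(
        data=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        subject_id=subject_id or path.stem,
        group=group,
        component_ids=component_ids,
    )


def write_timecourses(tc: SubjectTimecourses, path: str | Path) -> Path:
    """Write a subject's matrix as TSV with a component-id header."""
    path = Path(path)
    pd.DataFrame(tc.data, columns=list(tc.component_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path


MANIFEST_COLUMNS = ["subject_id", "group", "score_positive", "score_negative"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest TSV (subject_id, group, optional PANSS scores)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str})
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_csv(path, sep="\t", index=False)
    return path


def bandpass(
    tc: SubjectTimecourses,
    f_low: float = 0.01,
    f_high: float = 0.10,
    method: str = "fft",
    butter_order: int = 4,
) -> SubjectTimecourses:
    """Temporal band-pass filter each component time course.

    Default passband 0.01 < f < 0.10 Hz (the resting-state low-frequency
    band). Columns are mean-centered first, so the DC component is removed
    regardless of the passband edge.

    Parameters
    ----------
    method : {"fft", "butterworth"}
        ``"fft"`` applies an ideal (rectangular, zero-phase) filter in the
        rFFT domain: bins with f_low <= f <= f_high are kept exactly, all
        others zeroed. ``"butterworth"`` applies a zero-phase (forward-
        backward) Butterworth band-pass of the given order.
    """
    if not 0 <= f_low < f_high:
        raise ValueError("need 0 <= f_low < f_high")
    if f_high >= tc.nyquist_hz:
        raise ValueError(
            f"f_high={f_high} Hz must be below Nyquist "
            f"{tc.nyquist_hz:.4g} Hz for TR={tc.tr_seconds}s"
        )
    x = tc.data - tc.data.mean(axis=0, keepdims=True)
    if method == "fft":
        n = x.shape[0]
        freqs = np.fft.rfftfreq(n, d=tc.tr_seconds)
        spectrum = np.fft.rfft(x, axis=0)
        keep = (freqs >= f_low) & (freqs <= f_high)
        spectrum[~keep, :] = 0.0
        filtered = np.fft.irfft(spectrum, n=n, axis=0)
    elif method == "butterworth":
        sos = signal.butter(
            butter_order,
            [f_low, f_high],
            btype="bandpass",
            fs=1.0 / tc.tr_seconds,
            output="sos",
        )
        filtered = signal.sosfiltfilt(sos, x, axis=0)
    else:
        raise ValueError(f"unknown filter method {method!r}")
    return replace(tc, data=filtered)
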