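"""Sensor and annotation I/O.

Recordings pair a tri-axial acceleration stream (default 50 Hz, ±4 g) with a
barometric pressure stream (default 25 Hz).  Annotations are lists of labeled
half-open time intervals ``[start_s, end_s)``; per-second label series are the
common currency of the fusion stage and of validation against video
observation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: labels an annotation event may carry
EVENT_LABELS = (
    "sitting",
    "standing",
    "walking",
    "lying",
    "sit_to_stand",
    "stand_to_sit",
    "active",
    "inactive",
    "other",
)

#: the four categories a video observer scores
VIDEO_LABELS = ("sitting", "standing", "walking", "lying")

UNLABELED = "unlabeled"

ACCEL_RANGE_G = 4.0


class FormatError(ValueError):
    """A sensor/annotation file does not match the expected layout."""


class DataError(ValueError):
    """File contents violate a recording invariant (e.g. non-monotone time)."""


class AnnotationError(ValueError):
    """An annotation track violates the non-overlap invariant."""


@dataclass(frozen=True)
class FormatConfig:
    """Column mapping and unit conversion for delimited sensor files.

    ``accel_unit`` may be ``"g"`` or ``"m/s2"``; ``pressure_unit`` may be
    ``"hPa"`` or ``"Pa"``.  Values are converted to g and hPa on read.
    """

    time_col: str = "time_s"
    accel_cols: tuple[str, str, str] = ("ax_g", "ay_g", "az_g")
    pressure_col: str = "pressure_hpa"
    accel_unit: str = "g"
    pressure_unit: str = "hPa"
    sep: str = ","

    def accel_scale(self) -> float:
        if self.accel_unit == "g":
            return 1.0
        if self.accel_unit in ("m/s2", "m/s^2"):
            return 1.0 / 9.80665
        raise FormatError(f"unknown acceleration unit {self.accel_unit!r}")

    def pressure_scale(self) -> float:
        if self.pressure_unit in ("hPa", "hpa", "mbar"):
            return 1.0
        if self.pressure_unit in ("Pa", "pa"):
            return 0.01
        raise FormatError(f"unknown pressure unit {self.pressure_unit!r}")


@dataclass
class SensorRecording:
    """Paired acceleration and barometric-pressure streams.

    Acceleration is in g (three channels, shape ``(n, 3)``), pressure in hPa.
    Time axes are seconds from recording start, uniformly sampled.
    """

    accel_time: np.ndarray
    accel_xyz: np.ndarray
    pressure_time: np.ndarray
    pressure: np.ndarray
    accel_rate: float = 50.0
    pressure_rate: float = 25.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accel_time = np.asarray(self.accel_time, dtype=float)
        self.accel_xyz = np.asarray(self.accel_xyz, dtype=float)
        self.pressure_time = np.asarray(self.pressure_time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.validate()

    @property
    def duration_s(self) -> float:
        return float(self.accel_time[-1] + 1.0 / self.accel_rate)

    def validate(self) -> None:
        for name, t, rate in (
            ("acceleration", self.accel_time, self.accel_rate),
            ("pressure", self.pressure_time, self.pressure_rate),
        ):
            if t.ndim != 1 or t.size < 2:
                raise DataError(f"{name} stream needs at least two samples")
            dt = np.diff(t)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise DataError(
                    f"{name} time not strictly increasing at row {row}"
                )
            if np.max(np.abs(dt - 1.0 / rate)) > 1e-6:
                row = int(np.argmax(np.abs(dt - 1.0 / rate) > 1e-6)) + 1
                raise DataError(
                    f"{name} time not uniform at {rate} Hz near row {row}"
                )
        if self.accel_xyz.shape != (self.accel_time.size, 3):
            raise DataError("acceleration must have shape (n_samples, 3)")
        if self.pressure.shape != self.pressure_time.shape:
            raise DataError("pressure and its time axis differ in length")
        if np.max(np.abs(self.accel_xyz)) > ACCEL_RANGE_G + 1e-9:
            raise DataError(
                f"acceleration outside the ±{ACCEL_RANGE_G:g} g sensor range"
            )
        # both streams must cover the same span within one sample period
        span_a = (self.accel_time[0], self.accel_time[-1])
        span_p = (self.pressure_time[0], self.pressure_time[-1])
        tol = max(1.0 / self.accel_rate, 1.0 / self.pressure_rate) + 1e-9
        if abs(span_a[0] - span_p[0]) > tol or abs(span_a[1] - span_p[1]) > tol:
            raise DataError("acceleration and pressure spans disagree")


@dataclass(frozen=True)
class ActivityEvent:
    """A labeled half-open interval ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise AnnotationError(
                f"event end {self.end_s} must exceed start {self.start_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AnnotationTrack:
    """Sorted, non-overlapping sequence of :class:`ActivityEvent`."""

    events: list[ActivityEvent]

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.start_s)
        for a, b in zip(self.events, self.events[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise AnnotationError(f"overlapping events: {a} and {b}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def total_seconds(self, label: str | None = None) -> float:
        return sum(
            e.duration_s for e in self.events if label is None or e.label == label
        )


@dataclass
class SecondLabelSeries:
    """One activity label per whole second, starting at ``origin_s``."""

    labels: np.ndarray
    origin_s: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.size < 1:
            raise ValueError("a label series needs at least one second")

    def __len__(self) -> int:
        return int(self.labels.size)

    def counts(self) -> dict[str, int]:
        values, n = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(values.tolist(), n.tolist()))


# ---------------------------------------------------------------------------
# file I/O


def _accel_path(stem: Path) -> Path:
    return stem.with_suffix(".accel.csv")


def _pressure_path(stem: Path) -> Path:
    return stem.with_suffix(".baro.csv")


def write_recording(rec: SensorRecording, stem: str | Path,
                    config: FormatConfig | None = None) -> tuple[Path, Path]:
    """Write a recording as two delimited text files ``<stem>.accel.csv`` and
    ``<stem>.baro.csv``; returns the two paths."""
    cfg = config or FormatConfig()
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    ap, pp = _accel_path(stem), _pressure_path(stem)
    adf = pd.DataFrame({cfg.time_col: rec.accel_time})
    for i, col in enumerate(cfg.accel_cols):
        adf[col] = rec.accel_xyz[:, i] / cfg.accel_scale()
    adf.to_csv(ap, sep=cfg.sep, index=False, float_format="%.6f")
    pdf = pd.DataFrame(
        {cfg.time_col: rec.pressure_time,
         cfg.pressure_col: rec.pressure / cfg.pressure_scale()}
    )
    pdf.to_csv(pp, sep=cfg.sep, index=False, float_format="%.6f")
    return ap, pp


def read_recording(stem: str | Path, config: FormatConfig | None = None,
                   accel_rate: float = 50.0, pressure_rate: float = 25.0,
                   meta: Mapping | None = None) -> SensorRecording:
    """Read a recording written by :func:`write_recording`.

    ``stem`` may be the common stem or either of the two file paths.
    Raises :class:`FormatError` for missing columns and :class:`DataError`
    for invariant violations (naming the first offending row).
    """
    cfg = config or FormatConfig()
    stem = Path(stem)
    name = stem.name
    for suffix in (".accel.csv", ".baro.csv"):
        if name.endswith(suffix):
            stem = stem.parent / name[: -len(suffix)]
            break
    ap, pp = _accel_path(stem), _pressure_path(stem)
    for p in (ap, pp):
        if not p.exists():
            raise FileNotFoundError(p)
    adf = pd.read_csv(ap, sep=cfg.sep)
    pdf = pd.read_csv(pp, sep=cfg.sep)
    want_a = [cfg.time_col, *cfg.accel_cols]
    missing = [c for c in want_a if c not in adf.columns]
    if missing:
        raise FormatError(f"{ap}: missing columns {missing}")
    missing = [c for c in (cfg.time_col, cfg.pressure_col) if c not in pdf.columns]
    if missing:
        raise FormatError(f"{pp}: missing columns {missing}")
    return SensorRecording(
        accel_time=adf[cfg.time_col].to_numpy(),
        accel_xyz=adf[list(cfg.accel_cols)].to_numpy() * cfg.accel_scale(),
        pressure_time=pdf[cfg.time_col].to_numpy(),
        pressure=pdf[cfg.pressure_col].to_numpy() * cfg.pressure_scale(),
        accel_rate=accel_rate,
        pressure_rate=pressure_rate,
        meta=dict(meta or {}),
    )


def write_annotations(track: AnnotationTrack, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "start_s": [e.start_s for e in track],
            "end_s": [e.end_s for e in track],
            "label": [e.label for e in track],
        }
    ).to_csv(path, index=False, float_format="%.3f")
    return path


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read an annotation event list (columns start_s, end_s, label).

    Unknown labels are mapped to ``"other"`` with a logged warning;
    overlapping events raise :class:`AnnotationError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("start_s", "end_s", "label") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    events = []
    for row in df.itertuples(index=False):
        label = str(row.label)
        if label not in EVENT_LABELS:
            logger.warning("unknown label %r mapped to 'other'", label)
            warnings.warn(f"unknown annotation label {label!r} mapped to 'other'")
            label = "other"
        events.append(ActivityEvent(float(row.start_s), float(row.end_s), label))
    return AnnotationTrack(events)


def write_label_series(series: SecondLabelSeries, tol_mask: np.ndarray | None,
                       path: str | Path) -> Path:
    """Write per-second labels (and an optional ToL flag) as delimited text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "second_index": np.arange(series.origin_s, series.origin_s + len(series)),
            "label": series.labels.astype(str),
        }
    )
    if tol_mask is not None:
        df["tol_flag"] = np.asarray(tol_mask, dtype=int)
    df.to_csv(path, index=False)
    return path


def read_label_series(path: str | Path) -> SecondLabelSeries:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    origin = int(df["second_index"].iloc[0]) if "second_index" in df.columns else 0
    return SecondLabelSeries(df["label"].to_numpy(dtype=object), origin_s=origin)


# ---------------------------------------------------------------------------
# interval → second conversion


def events_to_seconds(track: AnnotationTrack | Iterable[ActivityEvent],
                      span: tuple[int, int]) -> SecondLabelSeries:
    """Convert interval annotations to one label per whole second.

    Second ``k`` receives the label of the event covering the largest share
    of ``[k, k+1)``; an exact tie goes to the earlier-starting event; seconds
    with no coverage are ``"unlabeled"``.
    """
    t0, t1 = span
    if not (float(t0).is_integer() and float(t1).is_integer() and t1 > t0):
        raise ValueError("span must be integer seconds with t1 > t0")
    t0, t1 = int(t0), int(t1)
    events = list(track)
    labels = np.full(t1 - t0, UNLABELED, dtype=object)
    best = np.zeros(t1 - t0)
    for ev in events:  # sorted: later events only win strict majorities
        lo = max(int(np.floor(ev.start_s)), t0)
        hi = min(int(np.ceil(ev.end_s)), t1)
        for k in range(lo, hi):
            cov = min(ev.end_s, k + 1) - max(ev.start_s, k)
            if cov > best[k - t0] + 1e-12:
                best[k - t0] = cov
                labels[k - t0] = ev.label
    return SecondLabelSeries(labels, origin_s=t0)
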