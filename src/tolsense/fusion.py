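"""Heuristic fusion of the detector outputs into per-second labels and ToL.

The detector interval sets are assembled onto a one-second grid; seconds
carrying several labels are resolved by a descending priority of sit/stand
transfers, walking, lying.  Remaining active/inactive runs are then
relabeled standing or sitting from their flanking events: a run succeeding
a sit-to-stand transfer or walking and preceding a stand-to-sit transfer or
walking becomes standing; a run succeeding a stand-to-sit transfer and
preceding a sit-to-stand transfer or lying becomes sitting.  Time-on-legs
(ToL) finally collects transfers, walking, standing and the un-labeled
active seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .detectors import DetectionIntervals, TransferModel, run_detectors
from .io import SecondLabelSeries, SensorRecording, UNLABELED
from .signals import compute_derived

#: label priority when one second carries several detector labels
PRIORITY = ("sit_to_stand", "stand_to_sit", "walking", "lying")

#: labels counted as time-on-legs
TOL_LABELS = frozenset({"sit_to_stand", "stand_to_sit", "walking",
                        "standing", "active"})


class InputError(ValueError):
    pass


@dataclass
class LabelGrid:
    """Per second: the set of detector labels asserted for that second."""

    sets: list[set]

    def __len__(self) -> int:
        return len(self.sets)


def _coverage_seconds(intervals: list[tuple[float, float]],
                      duration_s: int) -> np.ndarray:
    """Boolean mask over seconds: interval covers a majority of the second."""
    cov = np.zeros(duration_s)
    for s, e in intervals:
        lo = max(int(np.floor(s)), 0)
        hi = min(int(np.ceil(e)), duration_s)
        for k in range(lo, hi):
            cov[k] += min(e, k + 1) - max(s, k)
    return cov >= 0.5


def assemble(detections: dict[str, DetectionIntervals],
             duration_s: int) -> LabelGrid:
    """Assemble detector intervals onto the one-second grid.

    Each second carries every label whose interval covers the majority of
    that second (the same majority-coverage convention used for
    annotations).
    """
    sets: list[set] = [set() for _ in range(int(duration_s))]
    for kind, det in detections.items():
        mask = _coverage_seconds(det.intervals, int(duration_s))
        for k in np.flatnonzero(mask):
            sets[k].add(kind)
    return LabelGrid(sets)


def resolve(grid: LabelGrid) -> SecondLabelSeries:
    """One label per second by descending priority; pointwise in the grid.

    Transfers beat walking, walking beats lying.  Seconds with none of the
    posture/movement labels keep "active" or "inactive" pending the context
    rules.
    """
    labels = np.empty(len(grid), dtype=object)
    for k, s in enumerate(grid.sets):
        for lab in PRIORITY:
            if lab in s:
                labels[k] = lab
                break
        else:
            labels[k] = "active" if "active" in s else "inactive"
    return SecondLabelSeries(labels)


def _flank_runs(labels: np.ndarray) -> list[tuple[int, int, object, object]]:
    """Maximal active/inactive runs with their flanking labels (None at the
    recording boundaries)."""
    runs = []
    n = labels.size
    k = 0
    while k < n:
        if labels[k] in ("active", "inactive"):
            j = k
            while j < n and labels[j] in ("active", "inactive"):
                j += 1
            prev = labels[k - 1] if k > 0 else None
            nxt = labels[j] if j < n else None
            runs.append((k, j, prev, nxt))
            k = j
        else:
            k += 1
    return runs


def context_rules(series: SecondLabelSeries) -> SecondLabelSeries:
    """Relabel active/inactive runs to standing or sitting from their flanks.

    A missing flank at the very start or end of a recording matches either
    rule vacuously (the device in the field records continuously; a desk
    recording truncates the context), but a run that matches both rules —
    e.g. one with no flanks at all — keeps its active/inactive label.
    Seconds already labeled transfer/walking/lying are never altered.
    """
    labels = series.labels.copy()
    for k, j, prev, nxt in _flank_runs(labels):
        standing = ((prev in ("sit_to_stand", "walking") or prev is None)
                    and (nxt in ("stand_to_sit", "walking") or nxt is None))
        sitting = ((prev == "stand_to_sit" or prev is None)
                   and (nxt in ("sit_to_stand", "lying") or nxt is None))
        if standing and not sitting:
            labels[k:j] = "standing"
        elif sitting and not standing:
            labels[k:j] = "sitting"
    return SecondLabelSeries(labels, origin_s=series.origin_s)


def compute_tol(series: SecondLabelSeries) -> tuple[np.ndarray, int]:
    """Time-on-legs mask and second count.

    ToL is true exactly for seconds labeled sit-to-stand, stand-to-sit,
    walking, standing, or (un-labeled) active.
    """
    mask = np.array([lab in TOL_LABELS for lab in series.labels], dtype=bool)
    return mask, int(mask.sum())


def to_video_vocabulary(series: SecondLabelSeries) -> SecondLabelSeries:
    """Collapse fusion labels to the four video-observation categories.

    Transfer seconds are attributed to the destination posture (sit-to-stand
    → standing, stand-to-sit → sitting); residual active/inactive seconds
    have no video counterpart and become "unlabeled".
    """
    mapping = {"sit_to_stand": "standing", "stand_to_sit": "sitting",
               "active": UNLABELED, "inactive": UNLABELED}
    labels = np.array([mapping.get(lab, lab) for lab in series.labels],
                      dtype=object)
    return SecondLabelSeries(labels, origin_s=series.origin_s)


@dataclass
class ClassificationResult:
    """End-to-end output for one recording."""

    labels: SecondLabelSeries          # fusion vocabulary
    video_labels: SecondLabelSeries    # collapsed to the video vocabulary
    tol_mask: np.ndarray
    tol_seconds: int
    detections: dict[str, DetectionIntervals] = field(default_factory=dict)

    def category_seconds(self) -> dict[str, int]:
        return self.labels.counts()

    def summary(self) -> dict:
        return {"duration_s": len(self.labels),
                "tol_seconds": self.tol_seconds,
                "category_seconds": self.category_seconds()}


def classify_recording(rec: SensorRecording,
                       config: PipelineConfig | None = None,
                       model: TransferModel | None = None
                       ) -> ClassificationResult:
    """Run the whole chain: condition → detect → assemble → resolve →
    context rules → ToL.  Deterministic for a fixed config and model."""
    if rec.duration_s < 5.0:
        raise InputError("recording shorter than 5 s")
    cfg = config or PipelineConfig()
    derived = compute_derived(rec, cfg)
    detections = run_detectors(derived, cfg, model)
    duration = int(np.floor(rec.duration_s + 1e-9))
    grid = assemble(detections, duration)
    series = context_rules(resolve(grid))
    tol_mask, tol_seconds = compute_tol(series)
    return ClassificationResult(
        labels=series,
        video_labels=to_video_vocabulary(series),
        tol_mask=tol_mask,
        tol_seconds=tol_seconds,
        detections=detections,
    )
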