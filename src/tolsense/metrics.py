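"""Second-by-second validation statistics against video observation.

Sensitivity, specificity and overall agreement are duration-ratio
definitions over aligned per-second label series; qualitative grades follow
the Fleiss benchmark cut-offs (≤40 insufficient, ≤60 moderate, ≤80 good,
>80 excellent).  Inter-rater reliability uses the two-way random-effects,
average-measures intraclass correlation (ICC(2,k), absolute agreement by
default), and group comparability uses an independent-samples t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SecondLabelSeries, VIDEO_LABELS

GRADES = ("insufficient", "moderate", "good", "excellent")

#: video-vocabulary categories counted as time-on-legs in the reference
REF_TOL_LABELS = frozenset({"standing", "walking", "sit_to_stand", "stand_to_sit"})

#: fusion-vocabulary labels counted as time-on-legs in the prediction
PRED_TOL_LABELS = frozenset({"sit_to_stand", "stand_to_sit", "walking",
                             "standing", "active"})


class UndefinedMetricError(ValueError):
    """The metric's denominator is empty (category absent from the series)."""


class DegenerateInputError(ValueError):
    pass


def _as_labels(x) -> np.ndarray:
    if isinstance(x, SecondLabelSeries):
        return x.labels
    return np.asarray(x, dtype=object)


def _pair(ref, pred) -> tuple[np.ndarray, np.ndarray]:
    r, p = _as_labels(ref), _as_labels(pred)
    if r.size != p.size:
        raise ValueError(f"series lengths differ: {r.size} vs {p.size}")
    if r.size < 1:
        raise ValueError("empty series")
    return r, p


def sensitivity(ref, pred, category: str) -> float:
    """Percent of reference seconds of ``category`` also predicted as it."""
    r, p = _pair(ref, pred)
    pos = r == category
    if not pos.any():
        raise UndefinedMetricError(f"category {category!r} absent from reference")
    return 100.0 * float(np.sum(pos & (p == category))) / float(np.sum(pos))


def specificity(ref, pred, category: str) -> float:
    """Percent of reference non-``category`` seconds predicted as not it."""
    r, p = _pair(ref, pred)
    neg = r != category
    if not neg.any():
        raise UndefinedMetricError(f"reference is entirely {category!r}")
    return 100.0 * float(np.sum(neg & (p != category))) / float(np.sum(neg))


def overall_agreement(ref, pred) -> float:
    """Percent of seconds on which the two series agree exactly."""
    r, p = _pair(ref, pred)
    return 100.0 * float(np.mean(r == p))


def tol_metrics(ref, pred,
                ref_tol_labels: frozenset = REF_TOL_LABELS,
                pred_tol_labels: frozenset = PRED_TOL_LABELS) -> dict[str, float]:
    """ToL-based sensitivity/specificity/agreement.

    The reference (video vocabulary) reduces to ToL via standing/walking
    (and transfer labels where present); the prediction via the same
    membership rule the fusion stage uses.
    """
    r, p = _pair(ref, pred)
    rb = np.where(np.isin(r, list(ref_tol_labels)), "tol", "non_tol").astype(object)
    pb = np.where(np.isin(p, list(pred_tol_labels)), "tol", "non_tol").astype(object)
    return {
        "sensitivity": sensitivity(rb, pb, "tol"),
        "specificity": specificity(rb, pb, "tol"),
        "overall_agreement": overall_agreement(rb, pb),
    }


def grade(percent: float) -> str:
    """Fleiss benchmark grade for an agreement percentage."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percentage out of range: {percent}")
    if percent <= 40.0:
        return "insufficient"
    if percent <= 60.0:
        return "moderate"
    if percent <= 80.0:
        return "good"
    return "excellent"


def icc_2k(matrix, absolute_agreement: bool = True) -> tuple[float, bool]:
    """ICC, two-way random effects, average measures (Shrout–Fleiss 2,k).

    ``matrix`` is n_targets × k_raters with no missing cells.  Returns the
    ICC value and a flag for the conventional 0.8 reliability threshold.
    With ``absolute_agreement=False`` the consistency form ICC(3,k)-style
    denominator (ignoring rater mean differences) is used instead.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 1e-12:
        raise DegenerateInputError("zero between-target variance")
    if absolute_agreement:
        denom = msr + (msc - mse) / n
    else:
        denom = msr
    value = float((msr - mse) / denom)
    return value, value > 0.8


def group_compare(values_a: Sequence[float], values_b: Sequence[float],
                  equal_var: bool = False) -> tuple[float, float]:
    """Independent-samples t-test between two groups of per-subject values.

    Welch's unequal-variance form by default; the pooled-variance form via
    ``equal_var=True``.  Returns (t, p).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise UndefinedMetricError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def duration_summary(total_seconds: float, n_subjects: int) -> dict[str, float]:
    """Recorded-duration bookkeeping: total seconds, hours (2 dp), mean per
    subject — the arithmetic summaries a validation report prints."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    return {
        "total_seconds": float(total_seconds),
        "hours": round(total_seconds / 3600.0, 2),
        "mean_duration_s": total_seconds / n_subjects,
    }


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class ValidationReport:
    """Per-category and ToL validity table, mirroring the study layout:
    rows TOL, Sitting, Standing, Walking, Lying; columns sensitivity,
    specificity, overall agreement plus their qualitative grades."""

    rows: dict[str, dict] = field(default_factory=dict)
    group_rows: dict[str, dict] = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for name, r in self.rows.items():
            rec = {"category": name}
            for key in ("sensitivity", "specificity", "overall_agreement"):
                v = r.get(key)
                rec[key] = np.nan if v is None else round(v, 1)
                rec[f"{key}_grade"] = "n/a" if v is None else grade(v)
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="n/a")
        return path


def _safe(fn, *args) -> float | None:
    try:
        return fn(*args)
    except UndefinedMetricError:
        return None


def validation_report(ref, pred) -> ValidationReport:
    """Build the full validity table for one (possibly concatenated) pair of
    reference/prediction series.  ``ref`` is in the video vocabulary, ``pred``
    in the fusion vocabulary (it is collapsed internally for category rows).
    Undefined metrics (absent category) are reported as not-applicable."""
    from .fusion import to_video_vocabulary  # late import to avoid a cycle

    r = _as_labels(ref)
    p_raw = _as_labels(pred)
    p_vid = to_video_vocabulary(SecondLabelSeries(p_raw)).labels
    report = ValidationReport(notes={"icc_form": "ICC(2,k) absolute agreement"})
    tol = tol_metrics(r, p_raw)
    report.rows["TOL"] = tol
    for cat in VIDEO_LABELS:
        report.rows[cat.capitalize()] = {
            "sensitivity": _safe(sensitivity, r, p_vid, cat),
            "specificity": _safe(specificity, r, p_vid, cat),
            "overall_agreement": overall_agreement(r, p_vid),
        }
    return report
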