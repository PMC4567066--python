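"""Per-modality detectors: active periods, sit/stand transfers, walking, lying.

Active periods come from a dispersion threshold on movement intensity;
walking from repetitive cadence-locked peaks in the acceleration norm;
lying from sustained trunk tilt; sit/stand transfers from candidate windows
around transient extrema that show a concurrent barometric altitude change,
classified by a linear support-vector machine over a six-dimensional feature
vector (template cross-correlation, peak–valley timing, orientation,
intensity before/after, altitude change).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import signal as sps
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .config import DetectorConfig, PipelineConfig
from .signals import DerivedSignals

TEMPLATE_DURATION_S = 2.5
TEMPLATE_RATE = 50.0

TRANSFER_LABELS = ("sit_to_stand", "stand_to_sit", "none")


class FeatureError(ValueError):
    pass


class ModelStateError(RuntimeError):
    """The transfer classifier was used before being trained/loaded."""


def transfer_template(duration_s: float = TEMPLATE_DURATION_S,
                      rate: float = TEMPLATE_RATE) -> np.ndarray:
    """Canonical biphasic sit-to-stand waveform (unit peak amplitude).

    One acceleration peak followed by a deceleration valley, tapered by a
    Hann window.  A stand-to-sit transient is its negation.
    """
    n = int(round(duration_s * rate))
    u = np.arange(n) / n
    w = np.sin(2 * np.pi * u) * np.hanning(n)
    return w / np.max(np.abs(w))


@dataclass
class DetectionIntervals:
    """Sorted non-overlapping intervals of one detection kind."""

    kind: str
    intervals: list[tuple[float, float]] = field(default_factory=list)
    attributes: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = sorted(range(len(self.intervals)),
                       key=lambda i: self.intervals[i][0])
        self.intervals = [self.intervals[i] for i in order]
        if self.attributes:
            self.attributes = [self.attributes[i] for i in order]
        else:
            self.attributes = [{} for _ in self.intervals]
        for (s0, e0), (s1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0 - 1e-9:
                raise ValueError(f"overlapping {self.kind} intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    def total_seconds(self) -> float:
        return sum(e - s for s, e in self.intervals)


@dataclass(frozen=True)
class TransferFeatures:
    """Feature vector for one candidate transfer window."""

    template_xcorr: float      # signed peak normalized cross-correlation
    peak_valley_dt: float      # s between band-signal peak and valley
    orientation_deg: float     # trunk tilt at the window centre
    intensity_before: float    # g, just before the window
    intensity_after: float     # g, just after the window
    altitude_delta_m: float    # altitude at window end minus start

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.template_xcorr <= 1.0 + 1e-9:
            raise FeatureError("template_xcorr must lie in [-1, 1]")
        if self.peak_valley_dt < 0:
            raise FeatureError("peak_valley_dt must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.template_xcorr, self.peak_valley_dt, self.orientation_deg,
            self.intensity_before, self.intensity_after, self.altitude_delta_m,
        ])


# ---------------------------------------------------------------------------
# run-length helpers


def _mask_runs(mask: np.ndarray, rate: float) -> list[tuple[float, float]]:
    """Maximal True runs of a sample mask as [start_s, end_s) intervals."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], m, [False])).astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return [(s / rate, e / rate) for s, e in zip(starts, ends)]


def _merge_gaps(intervals: list[tuple[float, float]],
                max_gap_s: float) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] <= max_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# active / walking / lying


def detect_active(intensity: np.ndarray, rate: float, threshold_g: float = 0.03,
                  min_bout_s: float = 1.0, merge_gap_s: float = 2.0
                  ) -> DetectionIntervals:
    """Active periods: sustained movement intensity above a threshold.

    Maximal supra-threshold runs are found, runs separated by gaps no longer
    than ``merge_gap_s`` are merged, and merged runs shorter than
    ``min_bout_s`` are dropped.  The complement is the inactive time.
    """
    if threshold_g <= 0:
        raise ValueError("threshold must be positive")
    runs = _mask_runs(np.asarray(intensity) >= threshold_g, rate)
    runs = _merge_gaps(runs, merge_gap_s)
    runs = [(s, e) for s, e in runs if e - s >= min_bout_s]
    return DetectionIntervals("active", runs)


def detect_walking(norm_lp: np.ndarray, rate: float,
                   min_peaks: int = 2, min_peak_height_g: float = 0.10,
                   peak_interval_min_s: float = 0.35,
                   peak_interval_max_s: float = 1.4) -> DetectionIntervals:
    """Walking bouts from repetitive step peaks in the acceleration norm.

    Peaks rising ``min_peak_height_g`` above the 1 g gravity level are
    grouped into bouts wherever consecutive peak intervals stay within the
    plausible cadence range; a bout needs at least ``min_peaks`` peaks
    (walking is defined from two steps upward).  Each bout carries a
    ``step_count`` attribute.
    """
    if min_peaks < 1 or min_peak_height_g <= 0:
        raise ValueError("peak parameters must be positive")
    distance = max(int(peak_interval_min_s * rate * 0.8), 1)
    peaks, _ = sps.find_peaks(np.asarray(norm_lp, float),
                              height=1.0 + min_peak_height_g,
                              distance=distance)
    t = peaks / rate
    bouts: list[tuple[float, float]] = []
    attrs: list[dict] = []
    if t.size:
        group = [t[0]]
        for dt, tk in zip(np.diff(t), t[1:]):
            if peak_interval_min_s <= dt <= peak_interval_max_s:
                group.append(tk)
            else:
                _close_bout(group, bouts, attrs, min_peaks)
                group = [tk]
        _close_bout(group, bouts, attrs, min_peaks)
    return DetectionIntervals("walking", bouts, attrs)


def _close_bout(group: list[float], bouts: list, attrs: list, min_peaks: int) -> None:
    if len(group) < min_peaks:
        return
    half = float(np.median(np.diff(group))) / 2.0
    start = max(group[0] - half, 0.0)
    if bouts and start < bouts[-1][1]:
        start = bouts[-1][1]
    bouts.append((start, group[-1] + half))
    attrs.append({"step_count": len(group)})


def detect_lying(tilt_deg: np.ndarray, rate: float,
                 angle_threshold_deg: float = 60.0,
                 min_duration_s: float = 10.0) -> DetectionIntervals:
    """Lying: trunk tilted beyond the threshold for a sustained period."""
    if angle_threshold_deg <= 0 or min_duration_s <= 0:
        raise ValueError("thresholds must be positive")
    runs = _mask_runs(np.asarray(tilt_deg) > angle_threshold_deg, rate)
    runs = [(s, e) for s, e in runs if e - s >= min_duration_s]
    return DetectionIntervals("lying", runs)


# ---------------------------------------------------------------------------
# sit/stand transfers


def candidate_transfers(derived: DerivedSignals,
                        config: DetectorConfig | None = None
                        ) -> list[tuple[float, float]]:
    """Propose candidate transfer windows.

    Windows are centred on extrema of the transient-band norm where both the
    barometric altitude and the trunk tilt change within the window — the
    signature of a seat-height change with a forward lean.  Walking on level
    ground produces band extrema without an altitude change and is filtered
    out here.
    """
    cfg = config or DetectorConfig()
    rate = derived.accel_rate
    half = cfg.transfer_window_s / 2.0
    peaks, _ = sps.find_peaks(np.abs(derived.band),
                              height=cfg.transfer_peak_height_g,
                              distance=max(int(cfg.transfer_min_separation_s * rate), 1))
    t_end = derived.accel_time[-1]
    windows: list[tuple[float, float]] = []
    for p in peaks:
        tc = derived.accel_time[p]
        w0, w1 = max(tc - half, 0.0), min(tc + half, t_end)
        if w1 - w0 < 2.0:
            continue
        grid = np.linspace(w0, w1, 32)
        alt = derived.altitude_at(grid)
        tl = derived.tilt_at(grid)
        if np.ptp(alt) < cfg.transfer_min_altitude_range_m:
            continue
        if np.ptp(tl) < cfg.transfer_min_tilt_range_deg:
            continue
        windows.append((w0, w1))
    return windows


def normalized_xcorr_peak(x: np.ndarray, template: np.ndarray) -> float:
    """Signed peak of the normalized cross-correlation of ``x`` with the
    template over all full-overlap lags; the extremum of largest magnitude
    is returned (so an inverted transient correlates near −1)."""
    x = np.asarray(x, float)
    t = np.asarray(template, float)
    if x.size < t.size:
        raise FeatureError("window too short for template correlation")
    t = t - t.mean()
    tn = np.linalg.norm(t)
    if tn < 1e-12:
        return 0.0
    num = np.correlate(x, t, mode="valid")
    # rolling L2 norm of mean-removed x windows via cumulative sums
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    n = t.size
    s1 = c1[n:] - c1[:-n]
    s2 = c2[n:] - c2[:-n]
    xn = np.sqrt(np.clip(s2 - s1 * s1 / n, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(xn > 1e-9, num / (xn * tn), 0.0)
    c = np.clip(c, -1.0, 1.0)
    return float(c[np.argmax(np.abs(c))])


def transfer_features(window: tuple[float, float], derived: DerivedSignals,
                      template: np.ndarray | None = None) -> TransferFeatures:
    """Compute the six-feature vector for one candidate window."""
    if template is None:
        template = transfer_template(rate=derived.accel_rate)
    w0, w1 = window
    rate = derived.accel_rate
    i0 = max(int(round(w0 * rate)), 0)
    i1 = min(int(round(w1 * rate)), derived.band.size)
    seg = derived.band[i0:i1]
    if seg.size < template.size:
        raise FeatureError("window too short for template correlation")
    xc = normalized_xcorr_peak(seg, template)
    dt = abs(int(np.argmax(seg)) - int(np.argmin(seg))) / rate
    centre = 0.5 * (w0 + w1)
    tilt_mid = float(derived.tilt_at(centre))
    margin = 1.5
    before = _median_intensity(derived, w0 - margin, w0)
    after = _median_intensity(derived, w1, w1 + margin)
    alt_delta = float(derived.altitude_at(w1) - derived.altitude_at(w0))
    return TransferFeatures(xc, dt, tilt_mid, before, after, alt_delta)


def _median_intensity(derived: DerivedSignals, t0: float, t1: float) -> float:
    rate = derived.accel_rate
    i0 = max(int(round(t0 * rate)), 0)
    i1 = min(int(round(t1 * rate)), derived.intensity.size)
    if i1 <= i0:
        return 0.0
    return float(np.median(derived.intensity[i0:i1]))


# ---------------------------------------------------------------------------
# the transfer classifier


MODEL_VERSION = "transfer_svm_v1"
_FEATURE_NAMES = ("template_xcorr", "peak_valley_dt", "orientation_deg",
                  "intensity_before", "intensity_after", "altitude_delta_m")


@dataclass
class TransferModel:
    """Linear SVM over :class:`TransferFeatures`, JSON-serialisable."""

    classes: list[str] | None = None
    coef: np.ndarray | None = None
    intercept: np.ndarray | None = None
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    version: str = MODEL_VERSION
    training_seed: int | None = None
    n_training_samples: int | None = None

    @property
    def trained(self) -> bool:
        return self.coef is not None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0,
            C: float = 1.0) -> "TransferModel":
        """Train on labeled feature rows (labels from ``TRANSFER_LABELS``)."""
        X = np.asarray(X, float)
        scaler = StandardScaler().fit(X)
        svc = LinearSVC(C=C, random_state=seed, max_iter=20000)
        svc.fit(scaler.transform(X), y)
        self.classes = [str(c) for c in svc.classes_]
        self.coef = np.atleast_2d(svc.coef_)
        self.intercept = np.atleast_1d(svc.intercept_)
        self.scaler_mean = scaler.mean_
        self.scaler_scale = scaler.scale_
        self.training_seed = seed
        self.n_training_samples = int(X.shape[0])
        return self

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise ModelStateError("transfer model is not trained")
        Z = (np.atleast_2d(X) - self.scaler_mean) / self.scaler_scale
        return Z @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X)
        if len(self.classes) == 2:   # binary: sign of the single margin
            idx = (d[:, 0] > 0).astype(int)
        else:
            idx = np.argmax(d, axis=1)
        return np.array([self.classes[i] for i in idx], dtype=object)

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        if not self.trained:
            raise ModelStateError("cannot serialise an untrained model")
        return json.dumps({
            "version": self.version,
            "feature_names": list(_FEATURE_NAMES),
            "classes": self.classes,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "training_seed": self.training_seed,
            "n_training_samples": self.n_training_samples,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TransferModel":
        d = json.loads(text)
        return cls(
            classes=d["classes"],
            coef=np.asarray(d["coef"], float),
            intercept=np.asarray(d["intercept"], float),
            scaler_mean=np.asarray(d["scaler_mean"], float),
            scaler_scale=np.asarray(d["scaler_scale"], float),
            version=d.get("version", MODEL_VERSION),
            training_seed=d.get("training_seed"),
            n_training_samples=d.get("n_training_samples"),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TransferModel":
        return cls.from_json(Path(path).read_text())


_default_model: TransferModel | None = None


def default_transfer_model() -> TransferModel:
    """The packaged trained model fixture (see scripts/train_transfer_model.py)."""
    global _default_model
    if _default_model is None:
        text = (resources.files("tolsense") / "data" / f"{MODEL_VERSION}.json").read_text()
        _default_model = TransferModel.from_json(text)
    return _default_model


def classify_transfer(features: TransferFeatures,
                      model: TransferModel | None = None) -> str:
    """Label one candidate window: sit_to_stand, stand_to_sit, or none."""
    if model is None:
        model = default_transfer_model()
    if not model.trained:
        raise ModelStateError("transfer model is not trained")
    return str(model.predict(features.as_array()[None, :])[0])


def threshold_classify_transfer(features: TransferFeatures,
                                min_abs_xcorr: float = 0.4,
                                min_abs_altitude_m: float = 0.2) -> str:
    """Deterministic rule-based fallback: the sign of the altitude change,
    gated by the template correlation magnitude."""
    if abs(features.template_xcorr) < min_abs_xcorr:
        return "none"
    if features.altitude_delta_m >= min_abs_altitude_m:
        return "sit_to_stand"
    if features.altitude_delta_m <= -min_abs_altitude_m:
        return "stand_to_sit"
    return "none"


def detect_transfers(derived: DerivedSignals,
                     config: DetectorConfig | None = None,
                     model: TransferModel | None = None
                     ) -> tuple[DetectionIntervals, DetectionIntervals]:
    """Full transfer chain: propose candidates, extract features, classify.

    Returns (sit_to_stand, stand_to_sit) interval sets.  The reported event
    interval spans the peak-to-valley excursion of the transient (padded by
    0.3 s each side), not the full analysis window.
    """
    cfg = config or DetectorConfig()
    if model is None:
        model = default_transfer_model()
    template = transfer_template(rate=derived.accel_rate)
    rate = derived.accel_rate
    found: dict[str, list[tuple[float, float]]] = {"sit_to_stand": [], "stand_to_sit": []}
    for w0, w1 in candidate_transfers(derived, cfg):
        try:
            feats = transfer_features((w0, w1), derived, template)
        except FeatureError:
            continue
        label = classify_transfer(feats, model)
        if label == "none":
            continue
        i0, i1 = int(round(w0 * rate)), int(round(w1 * rate))
        seg = derived.band[i0:i1]
        tp = w0 + int(np.argmax(seg)) / rate
        tv = w0 + int(np.argmin(seg)) / rate
        # the biphasic transient's peak-valley span is about half the
        # transfer duration; pad by half the span each side to report the
        # full event extent
        pad = max(0.3, 0.5 * abs(tp - tv))
        s = max(min(tp, tv) - pad, 0.0)
        e = max(tp, tv) + pad
        lst = found[label]
        if lst and s < lst[-1][1]:
            s = lst[-1][1]
            if e <= s:
                continue
        lst.append((s, e))
    return (DetectionIntervals("sit_to_stand", found["sit_to_stand"]),
            DetectionIntervals("stand_to_sit", found["stand_to_sit"]))


def run_detectors(derived: DerivedSignals,
                  config: PipelineConfig | DetectorConfig | None = None,
                  model: TransferModel | None = None
                  ) -> dict[str, DetectionIntervals]:
    """Run all four detection modules on conditioned signals."""
    if config is None:
        config = DetectorConfig()
    cfg = config.detectors if isinstance(config, PipelineConfig) else config
    active = detect_active(derived.intensity, derived.accel_rate,
                           cfg.active_threshold_g, cfg.active_min_bout_s,
                           cfg.active_merge_gap_s)
    walking = detect_walking(derived.norm_lp, derived.accel_rate,
                             cfg.walk_min_peaks, cfg.walk_min_peak_height_g,
                             cfg.walk_peak_interval_min_s,
                             cfg.walk_peak_interval_max_s)
    lying = detect_lying(derived.tilt_deg, derived.accel_rate,
                         cfg.lying_angle_threshold_deg, cfg.lying_min_duration_s)
    if model is None and cfg.model_path:
        model = TransferModel.load(cfg.model_path)
    sts, stst = detect_transfers(derived, cfg, model)
    return {"active": active, "walking": walking, "lying": lying,
            "sit_to_stand": sts, "stand_to_sit": stst}
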