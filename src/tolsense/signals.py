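"""Signal conditioning: filtering, norm, intensity, orientation, altitude.

All filters are zero-phase (forward-backward Butterworth) so that the
per-second alignment between detector output and video annotation is not
shifted by filter delay.  Every operation is length-preserving on its native
sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .config import PipelineConfig, SignalConfig
from .io import SensorRecording

#: below this acceleration magnitude the orientation estimate is unreliable
MIN_GRAVITY_G = 0.2

_AXES = {"x": 0, "y": 1, "z": 2}


class ParameterError(ValueError):
    pass


def lowpass(x: np.ndarray, rate: float, cutoff_hz: float,
            order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth low-pass; same length as the input."""
    if cutoff_hz >= rate / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {rate / 2} Hz"
        )
    if cutoff_hz <= 0:
        raise ParameterError("cutoff must be positive")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def accel_norm(accel_xyz: np.ndarray) -> np.ndarray:
    """Euclidean norm of the tri-axial acceleration, per sample (g)."""
    a = np.asarray(accel_xyz, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected shape (n_samples, 3)")
    return np.linalg.norm(a, axis=1)


def moving_std(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred moving standard deviation (edge-replicated)."""
    window_samples = max(int(window_samples), 1)
    x = np.asarray(x, dtype=float)
    m = uniform_filter1d(x, window_samples, mode="nearest")
    m2 = uniform_filter1d(x * x, window_samples, mode="nearest")
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


def intensity(norm_g: np.ndarray, rate: float, window_s: float = 1.0,
              gravity_cutoff_hz: float = 0.25, order: int = 4) -> np.ndarray:
    """Movement intensity: moving std of the gravity-removed norm (g).

    The slowly varying gravity level is removed by subtracting a low-pass
    estimate of the norm; dispersion of the residual over a centred window
    is the conventional reading of accelerometric "signal intensity".
    """
    if window_s < 0.5:
        raise ParameterError("intensity window must be at least 0.5 s")
    resid = np.asarray(norm_g, float) - lowpass(norm_g, rate, gravity_cutoff_hz, order)
    return moving_std(resid, round(window_s * rate))


def tilt(accel_xyz_lowpassed: np.ndarray,
         upright_axis: str = "z") -> tuple[np.ndarray, np.ndarray]:
    """Angle (degrees, in [0, 180]) between the upright device axis and the
    measured gravity vector, plus a per-sample reliability mask.

    The input should be the gravity-band (strongly low-passed) acceleration.
    Samples whose magnitude falls below ``MIN_GRAVITY_G`` are flagged
    unreliable.  Invariant to the overall scale of the vector.
    """
    a = np.asarray(accel_xyz_lowpassed, dtype=float)
    if upright_axis not in _AXES:
        raise ParameterError(f"upright_axis must be one of {sorted(_AXES)}")
    mag = np.linalg.norm(a, axis=1)
    reliable = mag >= MIN_GRAVITY_G
    safe = np.where(mag > 1e-12, mag, 1.0)
    cosang = a[:, _AXES[upright_axis]] / safe
    deg = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return deg, reliable


def relative_altitude(pressure_hpa_lowpassed: np.ndarray,
                      metres_per_hpa: float = 8.43) -> np.ndarray:
    """Altitude in metres relative to the first sample.

    A pressure drop maps to an altitude gain (≈ 8.43 m per hPa near sea
    level); linear in the pressure deviation, and zero at the first sample
    by construction.
    """
    p = np.asarray(pressure_hpa_lowpassed, dtype=float)
    return -(p - p[0]) * metres_per_hpa


@dataclass
class DerivedSignals:
    """All conditioned signals the detectors consume, on their native grids."""

    accel_time: np.ndarray
    accel_rate: float
    norm: np.ndarray              # raw norm, g
    norm_lp: np.ndarray           # detection-band norm, g
    norm_gravity: np.ndarray      # gravity-band norm, g
    band: np.ndarray              # norm_lp - norm_gravity: transient band, g
    intensity: np.ndarray         # g, at accel_rate
    tilt_deg: np.ndarray          # degrees, at accel_rate
    tilt_ok: np.ndarray           # bool, orientation reliability
    pressure_time: np.ndarray
    pressure_rate: float
    altitude_m: np.ndarray        # relative altitude, at pressure_rate

    def altitude_at(self, t: float | np.ndarray) -> np.ndarray:
        return np.interp(t, self.pressure_time, self.altitude_m)

    def tilt_at(self, t: float | np.ndarray) -> np.ndarray:
        return np.interp(t, self.accel_time, self.tilt_deg)


def compute_derived(rec: SensorRecording,
                    config: PipelineConfig | SignalConfig | None = None
                    ) -> DerivedSignals:
    """Condition a raw recording into the signals the detectors consume."""
    if config is None:
        config = SignalConfig()
    cfg = config.signal if isinstance(config, PipelineConfig) else config
    norm = accel_norm(rec.accel_xyz)
    norm_lp = lowpass(norm, rec.accel_rate, cfg.cutoff_detect_hz, cfg.filter_order)
    gravity_vec = lowpass(rec.accel_xyz, rec.accel_rate, cfg.cutoff_gravity_hz,
                          cfg.filter_order, axis=0)
    norm_gravity = lowpass(norm, rec.accel_rate, cfg.cutoff_gravity_hz,
                           cfg.filter_order)
    tilt_deg, tilt_ok = tilt(gravity_vec, cfg.upright_axis)
    # intensity on the detection-band residual: sensor noise above the
    # detection cutoff does not leak into the active/inactive decision
    inten = moving_std(norm_lp - norm_gravity,
                       round(cfg.intensity_window_s * rec.accel_rate))
    p_lp = lowpass(rec.pressure, rec.pressure_rate, cfg.cutoff_pressure_hz,
                   cfg.filter_order)
    return DerivedSignals(
        accel_time=rec.accel_time,
        accel_rate=rec.accel_rate,
        norm=norm,
        norm_lp=norm_lp,
        norm_gravity=norm_gravity,
        band=norm_lp - norm_gravity,
        intensity=inten,
        tilt_deg=tilt_deg,
        tilt_ok=tilt_ok,
        pressure_time=rec.pressure_time,
        pressure_rate=rec.pressure_rate,
        altitude_m=relative_altitude(p_lp, cfg.metres_per_hpa),
    )
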