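"""Training routine for the sit/stand-transfer classifier.

The study trained its transfer SVM on separate pilot recordings; here the
pilot data are synthetic: short scripted scenes containing stand-ups,
sit-downs and the classic confounders (walking bouts, bend-and-pick
gestures, quiet postures), rendered at several noise levels.  Feature
windows are centred on the known event midpoints with a small jitter, so
the classifier is trained on the same feature distribution the candidate
proposer produces at detection time.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .detectors import FeatureError, TransferModel, transfer_features, transfer_template
from .signals import compute_derived
from .synthetic import ProtocolScript, make_profile, script_standardized, synthesize, build_script


def _scenes(profile) -> list[tuple[ProtocolScript, list[tuple[float, str]]]]:
    """Mini-scripts plus (window-centre, label) pairs for each."""
    td = profile.transfer_duration_s
    out = []

    a = build_script([("sitting", 8.0), ("sit_to_stand", td), ("standing", 6.0),
                ("stand_to_sit", td), ("sitting", 8.0)])
    out.append((a, [(8.0 + td / 2, "sit_to_stand"),
                    (14.0 + td + td / 2, "stand_to_sit"),
                    (4.0, "none"), (8.0 + td + 3.0, "none")]))

    b = build_script([("sitting", 6.0), ("sit_to_stand", td), ("walking", 10.0),
                ("stand_to_sit", td), ("sitting", 6.0)])
    out.append((b, [(6.0 + td / 2, "sit_to_stand"),
                    (16.0 + td + td / 2, "stand_to_sit"),
                    (6.0 + td + 5.0, "none")]))

    c = build_script([("standing", 5.0), ("other", 3.0), ("standing", 4.0),
                ("walking", 8.0), ("standing", 4.0)])
    out.append((c, [(6.5, "none"), (16.0, "none"), (3.0, "none")]))
    return out


def make_transfer_training_set(n_draws: int = 60, seed: int = 0,
                               config: PipelineConfig | None = None
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Labeled transfer-feature rows from synthetic pilot scenes.

    Each draw samples a profile (alternating frail/non-frail), a noise level
    in [0, 0.12] g and a ±0.5 s window-centre jitter.  Returns (X, y) with
    labels in {sit_to_stand, stand_to_sit, none}.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    half = cfg.detectors.transfer_window_s / 2.0
    rows, labels = [], []
    for d in range(n_draws):
        profile = make_profile(frail=bool(d % 2), seed=rng)
        noise = rng.uniform(0.0, 0.12)
        for script, marks in _scenes(profile):
            rec, _ = synthesize(script, profile, noise, rng)
            derived = compute_derived(rec, cfg)
            template = transfer_template(rate=rec.accel_rate)
            for centre, label in marks:
                tc = centre + rng.uniform(-0.5, 0.5)
                w0 = max(tc - half, 0.0)
                w1 = min(tc + half, script.end_s)
                try:
                    f = transfer_features((w0, w1), derived, template)
                except FeatureError:
                    continue
                rows.append(f.as_array())
                labels.append(label)
    return np.vstack(rows), np.array(labels, dtype=object)


def train_transfer_model(n_draws: int = 60, seed: int = 0,
                         config: PipelineConfig | None = None) -> TransferModel:
    """Train the linear transfer SVM on a fresh synthetic training set."""
    X, y = make_transfer_training_set(n_draws, seed, config)
    return TransferModel().fit(X, y, seed=seed)
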