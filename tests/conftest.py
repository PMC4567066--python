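import numpy as np
import pytest

from tolsense.config import PipelineConfig
from tolsense.fusion import classify_recording
from tolsense.signals import compute_derived
from tolsense.synthetic import build_script, make_profile, script_standardized, synthesize


@pytest.fixture(scope="session")
def nonfrail_profile():
    return make_profile(frail=False, seed=11)


@pytest.fixture(scope="session")
def frail_profile():
    return make_profile(frail=True, seed=12)


@pytest.fixture(scope="session")
def transfer_scene(nonfrail_profile):
    """Zero-noise scene with one stand-up at ~30 s and one sit-down at ~50 s."""
    td = nonfrail_profile.transfer_duration_s
    script = build_script([
        ("sitting", 30.0), ("sit_to_stand", td), ("standing", 20.0 - td),
        ("stand_to_sit", td), ("sitting", 20.0 - td),
    ])
    rec, ann = synthesize(script, nonfrail_profile, noise_std_g=0.0, seed=3)
    derived = compute_derived(rec, PipelineConfig())
    return script, rec, derived


@pytest.fixture(scope="session")
def std_run(nonfrail_profile):
    """Zero-noise standardized-protocol recording plus its classification."""
    script = script_standardized(nonfrail_profile)
    rec, ann = synthesize(script, nonfrail_profile, noise_std_g=0.0, seed=21)
    result = classify_recording(rec)
    return script, rec, ann, result
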