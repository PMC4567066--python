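"""Synthetic activity protocols and hybrid-sensor signal synthesis.

Emulates the validation design the detection chain is meant for: a
standardized in-home mobility protocol (timed-up-and-go at three speeds,
five-times chair rise, single stand, bend-and-pick, bed and floor lying,
an aided 10 m walk for aid users) and a 30-minute free-movement session,
for frail (GFI ≥ 4) and non-frail subject profiles.

The signal model is phenomenological, not biomechanical: gravity-dominated
tri-axial acceleration whose orientation follows posture, cadence-locked
step peaks during walking (asymmetric alternate steps for cane/walker
users), a biphasic transient plus a seat-height barometric step at each
sit/stand transfer, sustained tilt during lying, and additive white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ActivityEvent, AnnotationTrack, SecondLabelSeries, SensorRecording, events_to_seconds

ACCEL_RATE = 50.0
PRESSURE_RATE = 25.0
BASE_PRESSURE_HPA = 1013.25
METRES_PER_HPA = 8.43

SIT_HEIGHT_M = 0.95     # necklace height when seated
BED_HEIGHT_M = 0.60     # necklace height lying on a bed
FLOOR_HEIGHT_M = 0.15
LIE_ANGLE_DEG = 85.0
LIE_RAMP_S = 2.0
TRANSFER_AMP_G = 0.35
TRANSFER_LEAN_DEG = 25.0
STEP_WIDTH_S = 0.30
BEND_DIP_M = 0.50
BEND_ANGLE_DEG = 65.0

#: script label for the bend-to-pick gesture (upright, not a posture change)
BEND_LABEL = "other"


@dataclass(frozen=True)
class SubjectProfile:
    """Kinematic parameters of one synthetic subject.

    Frailty follows the 15-item frailty-indicator rule (total score ≥ 4);
    frail profiles walk slower, sway more, transfer more slowly and mostly
    use a cane or walker (introducing alternate-step asymmetry).
    """

    subject_id: str
    gfi_score: int
    cadence_hz: float          # step frequency
    step_peak_g: float         # step peak above the gravity level
    sway_std_g: float          # mediolateral sway amplitude while walking
    transfer_duration_s: float
    seat_height_m: float       # sit→stand necklace height change
    uses_walking_aid: bool
    aid_asymmetry: float       # alternate-step amplitude factor (1 = symmetric)
    duration_factor: float     # scales movement durations (slower = larger)
    does_floor_lie: bool       # optional floor-lying protocol item

    def __post_init__(self) -> None:
        if not 0 <= self.gfi_score <= 15:
            raise ValueError("GFI score must lie in 0..15")

    @property
    def frail(self) -> bool:
        return self.gfi_score >= 4


def make_profile(frail: bool, seed: int | np.random.Generator = 0,
                 subject_id: str | None = None) -> SubjectProfile:
    """Draw a subject profile; reproducible for a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if frail:
        gfi = int(np.clip(round(rng.normal(6.0, 2.6)), 4, 15))
        cadence = rng.uniform(1.0, 1.4)
        step_peak = rng.uniform(0.20, 0.30)
        sway = rng.uniform(0.04, 0.08)
        transfer = rng.uniform(2.2, 3.0)
        aid = True                      # every frail subject in the cohort used one
        asym = rng.uniform(0.65, 0.85)
        durf = rng.uniform(1.2, 1.5)
        floor = rng.random() < 0.2      # floor lying is optional, often skipped
    else:
        gfi = int(np.clip(round(rng.normal(1.4, 1.1)), 0, 3))
        cadence = rng.uniform(1.5, 2.0)
        step_peak = rng.uniform(0.28, 0.45)
        sway = rng.uniform(0.02, 0.04)
        transfer = rng.uniform(1.5, 2.2)
        aid = rng.random() < 0.18
        asym = rng.uniform(0.75, 0.9) if aid else 1.0
        durf = rng.uniform(0.9, 1.1)
        floor = rng.random() < 0.7
    return SubjectProfile(
        subject_id=subject_id or f"synth-{'F' if frail else 'N'}{int(rng.integers(1e6)):06d}",
        gfi_score=gfi, cadence_hz=float(cadence), step_peak_g=float(step_peak),
        sway_std_g=float(sway), transfer_duration_s=float(transfer),
        seat_height_m=float(rng.uniform(0.42, 0.48)),
        uses_walking_aid=bool(aid), aid_asymmetry=float(asym),
        duration_factor=float(durf), does_floor_lie=bool(floor),
    )


@dataclass
class ProtocolScript:
    """Contiguous, fine-grained activity events starting at 0 s."""

    events: list[ActivityEvent]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("empty script")
        if abs(self.events[0].start_s) > 1e-9:
            raise ValueError("script must start at 0")
        for a, b in zip(self.events, self.events[1:]):
            if abs(b.start_s - a.end_s) > 1e-9:
                raise ValueError("script events must be contiguous")

    @property
    def end_s(self) -> float:
        return self.events[-1].end_s

    def to_track(self) -> AnnotationTrack:
        return AnnotationTrack(list(self.events))

    def second_labels(self) -> SecondLabelSeries:
        """Fine-grained ground-truth labels per second (bend → standing)."""
        series = events_to_seconds(self.events, (0, int(np.floor(self.end_s))))
        series.labels[series.labels == BEND_LABEL] = "standing"
        return series

    def total_seconds(self, label: str) -> float:
        return sum(e.duration_s for e in self.events if e.label == label)


def build_script(seq: list[tuple[str, float]]) -> ProtocolScript:
    t = 0.0
    events = []
    for label, dur in seq:
        events.append(ActivityEvent(t, t + dur, label))
        t += dur
    return ProtocolScript(events)


def script_standardized(profile: SubjectProfile) -> ProtocolScript:
    """The standardized in-home protocol, scaled by the profile's speed.

    Order: 5 s standing; sit down; timed-up-and-go slow, 3× normal, fast;
    five-times chair rise (five full up–down cycles, ending seated); a
    single stand-up; bend to pick an object; lie on the bed and get up;
    optional floor lying; and a final aided 10 m walk for aid users.
    Seated rests separate the exercises.
    """
    df = profile.duration_factor
    td = profile.transfer_duration_s
    seq: list[tuple[str, float]] = [("standing", 5.0), ("stand_to_sit", td),
                                    ("sitting", 20.0)]

    def tug(walk_s: float, rest_s: float) -> None:
        seq.extend([("sit_to_stand", td), ("walking", walk_s * df),
                    ("stand_to_sit", td), ("sitting", rest_s)])

    tug(12.0, 18.0)                      # slow condition
    for _ in range(3):                   # normal condition, 3 repetitions
        tug(8.0, 15.0)
    tug(6.0, 18.0)                       # fast condition
    for i in range(5):                   # five-times chair rise
        seq.extend([("sit_to_stand", td), ("standing", 2.0),
                    ("stand_to_sit", td),
                    ("sitting", 18.0 if i == 4 else 2.0)])
    seq.extend([("sit_to_stand", td), ("standing", 3.0)])   # single stand
    seq.extend([(BEND_LABEL, 3.0), ("standing", 2.0)])      # bend and pick
    seq.extend([("walking", 5.0 * df), ("lying", 25.0), ("standing", 3.0)])
    if profile.does_floor_lie:
        seq.extend([("lying", 16.0), ("standing", 3.0)])
    seq.append(("walking", 4.0 * df))
    if profile.uses_walking_aid:
        seq.extend([("standing", 2.0), ("walking", 12.0 * df)])
    seq.extend([("stand_to_sit", td), ("sitting", 20.0)])
    return build_script(seq)


_FREE_TRANSITIONS = {
    "sitting": (("standing", 0.9), ("lying", 0.1)),
    "standing": (("walking", 0.55), ("sitting", 0.35), ("lying", 0.10)),
    "walking": (("standing", 0.55), ("sitting", 0.45)),
    "lying": (("sitting", 0.5), ("standing", 0.5)),
}

_FREE_DWELL_S = {  # (low, high) uniform ranges; daily-life dwells are long
    "sitting": (40.0, 150.0),
    "standing": (10.0, 45.0),
    "walking": (8.0, 35.0),
    "lying": (20.0, 50.0),
}


def script_free(profile: SubjectProfile, duration_s: float = 1800.0,
                seed: int | np.random.Generator = 0) -> ProtocolScript:
    """A free-movement session: a semi-Markov walk over the four postures
    with a transfer inserted at every seated↔upright boundary; total
    scripted time equals ``duration_s`` exactly."""
    if duration_s < 60:
        raise ValueError("free protocol needs at least 60 s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq: list[tuple[str, float]] = []
    state = "sitting"
    t = 0.0
    while t < duration_s:
        lo, hi = _FREE_DWELL_S[state]
        dwell = rng.uniform(lo, hi)
        if state == "sitting" and profile.frail:
            dwell *= 1.2
        if state == "walking":
            dwell *= profile.duration_factor
        seq.append((state, dwell))
        t += dwell
        nxt_states, probs = zip(*[(s, p) for s, p in _FREE_TRANSITIONS[state]])
        nxt = str(rng.choice(nxt_states, p=np.array(probs) / sum(probs)))
        if {state, nxt} & {"sitting"} and nxt != state:
            if state == "sitting" and nxt in ("standing", "walking"):
                seq.append(("sit_to_stand", profile.transfer_duration_s))
                t += profile.transfer_duration_s
            elif nxt == "sitting" and state in ("standing", "walking"):
                seq.append(("stand_to_sit", profile.transfer_duration_s))
                t += profile.transfer_duration_s
        state = nxt
    # truncate to the exact session length
    out: list[tuple[str, float]] = []
    acc = 0.0
    for label, dur in seq:
        if acc + dur >= duration_s:
            if duration_s - acc > 1e-6:
                out.append((label, duration_s - acc))
            break
        out.append((label, dur))
        acc += dur
    return build_script(out)


# ---------------------------------------------------------------------------
# signal synthesis


def _smoothstep(n: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n)
    return u * u * (3 - 2 * u)


def _biphasic(n: int) -> np.ndarray:
    u = np.arange(n) / max(n, 1)
    w = np.sin(2 * np.pi * u) * np.hanning(n)
    m = np.max(np.abs(w))
    return w / m if m > 0 else w


def synthesize(script: ProtocolScript, profile: SubjectProfile,
               noise_std_g: float = 0.0, seed: int | np.random.Generator = 0,
               ) -> tuple[SensorRecording, AnnotationTrack]:
    """Render a script into a sensor recording plus its video-style
    annotation track (four categories; transfer seconds attributed to the
    destination posture).  Bit-identical for a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = script.end_s
    n_a = int(round(duration * ACCEL_RATE))
    n_p = n_a // int(ACCEL_RATE / PRESSURE_RATE)
    t_a = np.arange(n_a) / ACCEL_RATE
    stand_h = SIT_HEIGHT_M + profile.seat_height_m

    height = np.full(n_a, stand_h)
    theta = np.zeros(n_a)          # trunk tilt from vertical, degrees
    phi = np.zeros(n_a)            # azimuth of the tilt, degrees
    dyn = np.zeros(n_a)            # dynamic acceleration along the trunk axis
    sway = np.zeros(n_a)

    def sl(ev: ActivityEvent) -> slice:
        return slice(int(round(ev.start_s * ACCEL_RATE)),
                     int(round(ev.end_s * ACCEL_RATE)))

    # pass 1: postures, transfers, gestures
    for ev in script.events:
        s = sl(ev)
        n = s.stop - s.start
        if n <= 0:
            continue
        if ev.label == "sitting":
            height[s] = SIT_HEIGHT_M
        elif ev.label in ("standing", "walking"):
            height[s] = stand_h
        elif ev.label == "sit_to_stand":
            height[s] = SIT_HEIGHT_M + profile.seat_height_m * _smoothstep(n)
            dyn[s] += TRANSFER_AMP_G * _biphasic(n)
            theta[s] += TRANSFER_LEAN_DEG * np.hanning(n)
        elif ev.label == "stand_to_sit":
            height[s] = stand_h - profile.seat_height_m * _smoothstep(n)
            dyn[s] -= TRANSFER_AMP_G * _biphasic(n)
            theta[s] += TRANSFER_LEAN_DEG * np.hanning(n)
        elif ev.label == BEND_LABEL:
            height[s] = stand_h - BEND_DIP_M * np.hanning(n)
            theta[s] += BEND_ANGLE_DEG * np.hanning(n)
            dyn[s] += 0.15 * _biphasic(n)
        if ev.label == "walking":
            period = 1.0 / profile.cadence_hz
            amps = []
            tk = ev.start_s + 0.3
            i = 0
            while tk < ev.end_s - 0.3:
                amp = profile.step_peak_g * (1.0 + rng.normal(0, 0.05))
                if profile.uses_walking_aid and i % 2 == 1:
                    amp *= profile.aid_asymmetry
                k0 = int(round((tk - STEP_WIDTH_S / 2) * ACCEL_RATE))
                k1 = int(round((tk + STEP_WIDTH_S / 2) * ACCEL_RATE))
                k0c, k1c = max(k0, 0), min(k1, n_a)
                if k1c > k0c:
                    u = (np.arange(k0c, k1c) - k0) / max(k1 - k0, 1)
                    dyn[k0c:k1c] += amp * 0.5 * (1 - np.cos(2 * np.pi * u))
                tk += period
                i += 1
            tt = t_a[s]
            sway[s] += profile.sway_std_g * np.sin(
                np.pi * profile.cadence_hz * tt + rng.uniform(0, 2 * np.pi))

    # pass 2: lying (ramps from/to the neighbouring posture heights)
    lie_count = 0
    for ev in script.events:
        if ev.label != "lying":
            continue
        s = sl(ev)
        n = s.stop - s.start
        if n <= 0:
            continue
        lie_count += 1
        target_h = BED_HEIGHT_M if lie_count == 1 or not profile.does_floor_lie \
            else FLOOR_HEIGHT_M
        h_prev = height[s.start - 1] if s.start > 0 else stand_h
        h_next = height[s.stop] if s.stop < n_a else stand_h
        nr = min(int(LIE_RAMP_S * ACCEL_RATE), n // 3)
        prof_h = np.full(n, target_h)
        prof_t = np.full(n, LIE_ANGLE_DEG)
        if nr > 0:
            prof_h[:nr] = h_prev + (target_h - h_prev) * _smoothstep(nr)
            prof_h[-nr:] = target_h + (h_next - target_h) * _smoothstep(nr)
            prof_t[:nr] = LIE_ANGLE_DEG * _smoothstep(nr)
            prof_t[-nr:] = LIE_ANGLE_DEG * (1 - _smoothstep(nr))
            # lowering onto and rising from the bed is a movement burst that
            # spills into the adjacent upright seconds
            nb = int(2.5 * ACCEL_RATE)
            for k0 in (max(s.start - nb // 2, 0), max(s.stop - nb // 2, 0)):
                k1 = min(k0 + nb, n_a)
                if k1 > k0:
                    u = np.arange(k1 - k0) / ACCEL_RATE
                    dyn[k0:k1] += (0.08 * np.sin(2 * np.pi * 2.5 * u)
                                   * np.hanning(k1 - k0))
        height[s] = prof_h
        theta[s] = prof_t
        if ev.duration_s > 12.0:       # turn onto the side halfway through
            mid = s.start + n // 2
            ntr = int(2.0 * ACCEL_RATE)
            k1 = min(mid + ntr, s.stop - nr)
            if k1 > mid:
                phi[mid:k1] = 90.0 * _smoothstep(k1 - mid)
                phi[k1:s.stop] = 90.0
                dyn[mid:k1] += 0.06 * np.sin(
                    2 * np.pi * 2.0 * np.arange(k1 - mid) / ACCEL_RATE)

    th = np.radians(theta)
    ph = np.radians(phi)
    accel = np.empty((n_a, 3))
    accel[:, 0] = np.sin(th) * np.cos(ph) + sway
    accel[:, 1] = np.sin(th) * np.sin(ph)
    accel[:, 2] = np.cos(th) + dyn
    if noise_std_g > 0:
        accel += rng.normal(0.0, noise_std_g, accel.shape)
    np.clip(accel, -4.0, 4.0, out=accel)

    h_p = height[::int(ACCEL_RATE / PRESSURE_RATE)][:n_p]
    t_p = np.arange(n_p) / PRESSURE_RATE
    pressure = BASE_PRESSURE_HPA - (h_p - h_p[0]) / METRES_PER_HPA
    pressure += 0.02 * np.sin(2 * np.pi * t_p / 600.0 + rng.uniform(0, 2 * np.pi))
    if noise_std_g > 0:
        pressure += rng.normal(0.0, noise_std_g * 0.1, n_p)

    rec = SensorRecording(
        accel_time=t_a, accel_xyz=accel,
        pressure_time=t_p, pressure=pressure,
        accel_rate=ACCEL_RATE, pressure_rate=PRESSURE_RATE,
        meta={"subject_id": profile.subject_id, "frail": profile.frail,
              "gfi_score": profile.gfi_score, "noise_std_g": noise_std_g},
    )
    return rec, collapse_to_video(script)


def collapse_to_video(script: ProtocolScript) -> AnnotationTrack:
    """Collapse the fine-grained script to the four video categories.

    Transfer seconds go to the destination posture (sit-to-stand → standing,
    stand-to-sit → sitting); the bend gesture stays standing; adjacent
    events with equal labels merge.
    """
    mapping = {"sit_to_stand": "standing", "stand_to_sit": "sitting",
               BEND_LABEL: "standing"}
    merged: list[ActivityEvent] = []
    for ev in script.events:
        label = mapping.get(ev.label, ev.label)
        if merged and merged[-1].label == label:
            merged[-1] = ActivityEvent(merged[-1].start_s, ev.end_s, label)
        else:
            merged.append(ActivityEvent(ev.start_s, ev.end_s, label))
    return AnnotationTrack(merged)


def simulate_subject(frail: bool, protocol: str = "standardized",
                     seed: int = 0, noise_std_g: float = 0.0,
                     duration_s: float = 1800.0,
                     ) -> tuple[SubjectProfile, ProtocolScript,
                                SensorRecording, AnnotationTrack]:
    """Convenience wrapper: profile → script → signals, all from one seed."""
    rng = np.random.default_rng(seed)
    profile = make_profile(frail, rng)
    if protocol == "standardized":
        script = script_standardized(profile)
    elif protocol == "free":
        script = script_free(profile, duration_s, rng)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    rec, ann = synthesize(script, profile, noise_std_g, rng)
    return profile, script, rec, ann
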