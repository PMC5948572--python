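"""Mechanistic generator of labeled multi-position accelerometer trials.

Each movement type is described by a :class:`MovementTemplate`: an
ordered list of phases shaping the signal-magnitude profile (in g) plus
a gravity-tilt schedule. A trace is synthesized as the profile times a
unit gravity direction that starts along the device's vertical axis and
tilts according to the schedule, with additive sensor jitter and, on
limb positions, spurious motion bursts. Falls follow the canonical
phenomenology: a sub-second free-fall valley (SMV well below 1 g), an
impact spike of several g, and a persistent change of body orientation.

Per-trial RNG streams are derived from ``(seed, trial_index)`` so a
dataset is reproducible and stable under count changes elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fallban.types import (
    ADL_TYPES,
    DEFAULT_EXECUTIONS,
    DEFAULT_FS,
    FALL_TYPES,
    MOVEMENT_TYPES,
    POSITIONS,
    DeviceKind,
    Position,
    SensorTrace,
    Subject,
    TrialRecord,
    VERTICAL_AXIS,
    label_for,
)

#: Reference roster of experimental subjects (19 volunteers; the two
#: participants older than 65 perform no fall trials).
SUBJECT_ROSTER: tuple[Subject, ...] = tuple(
    Subject(f"Subject {i + 1}", g, a, h, w)
    for i, (g, a, h, w) in enumerate(
        [
            ("Female", 67, 156, 76),
            ("Female", 22, 167, 63),
            ("Male", 68, 168, 97),
            ("Male", 27, 173, 90),
            ("Male", 24, 179, 68),
            ("Male", 24, 175, 79),
            ("Male", 28, 195, 81),
            ("Female", 22, 167, 57),
            ("Male", 55, 170, 83),
            ("Male", 19, 178, 68),
            ("Male", 26, 176, 73),
            ("Female", 51, 155, 55),
            ("Female", 18, 159, 50),
            ("Female", 22, 164, 52),
            ("Male", 26, 179, 67),
            ("Male", 21, 173, 77),
            ("Female", 27, 166, 66),
            ("Male", 24, 177, 66),
            ("Female", 23, 163, 93),
        ]
    )
)

PHASE_SHAPES = ("constant", "sinusoid", "valley_then_spike", "ramp", "spike_train")

#: Fraction of a valley_then_spike phase spent in the free-fall valley.
_VALLEY_FRACTION = 0.75
#: Width of one spike in a spike_train, seconds.
_SPIKE_WIDTH = 0.15


@dataclass(frozen=True)
class Phase:
    """One segment of the SMV profile.

    ``level`` is the baseline SMV in g; ``amplitude`` the peak (or, for
    ``valley_then_spike``, the impact-spike) level in g; ``freq`` in Hz
    for oscillatory shapes. ``target_angle`` (degrees), when set, tilts
    the gravity direction linearly to that value across the phase.
    """

    duration: float
    shape: str = "constant"
    level: float = 1.0
    amplitude: float = 0.0
    freq: float = 1.0
    target_angle: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in PHASE_SHAPES:
            raise ValueError(f"unknown phase shape {self.shape!r}")
        if self.duration < 0 or self.amplitude < 0:
            raise ValueError("phase duration and amplitude must be >= 0")


@dataclass(frozen=True)
class MovementTemplate:
    """Qualitative signal model for one movement type."""

    name: str
    phases: tuple[Phase, ...]
    orientation_change: float = 0.0  # final gravity tilt, degrees
    azimuth: float = 0.0  # tilt direction in the non-vertical plane, degrees
    jitter: float = 0.03  # additive noise sigma, g
    onset_range: tuple[float, float] = (0.0, 0.0)  # random idle lead, s

    def __post_init__(self) -> None:
        if not 0.0 <= self.orientation_change <= 180.0:
            raise ValueError("orientation_change must lie in [0, 180] degrees")
        final = 0.0
        for ph in self.phases:
            if ph.target_angle is not None:
                final = ph.target_angle
        if abs(final - self.orientation_change) > 1e-9:
            raise ValueError(
                "orientation_change must equal the last phase target angle"
            )


def _fall_template(name: str, azimuth: float) -> MovementTemplate:
    return MovementTemplate(
        name=name,
        phases=(
            # free-fall valley (0.3 s at 0.2 g) then impact spike (0.1 s, 4 g)
            Phase(0.4, "valley_then_spike", level=0.2, amplitude=4.0,
                  target_angle=90.0),
            # post-impact settling on the ground
            Phase(0.8, "sinusoid", level=1.0, amplitude=0.3, freq=3.0,
                  target_angle=90.0),
        ),
        orientation_change=90.0,
        azimuth=azimuth,
        onset_range=(4.0, 8.0),
    )


def default_templates() -> dict[str, MovementTemplate]:
    """Templates for the 14 movement types of the reference design."""
    t: dict[str, MovementTemplate] = {}
    t["Forwards fall"] = _fall_template("Forwards fall", azimuth=90.0)
    t["Backwards fall"] = _fall_template("Backwards fall", azimuth=270.0)
    t["Lateral fall"] = _fall_template("Lateral fall", azimuth=0.0)
    t["Applauding"] = MovementTemplate(
        "Applauding", (Phase(4.0, "sinusoid", 1.0, 0.2, 3.0),), onset_range=(1, 3)
    )
    t["Raising both arms"] = MovementTemplate(
        "Raising both arms",
        (Phase(3.0, "sinusoid", 1.0, 0.25, 0.5),),
        onset_range=(1, 3),
    )
    t["Emulating a phone call"] = MovementTemplate(
        "Emulating a phone call",
        (Phase(6.0, "sinusoid", 1.0, 0.15, 0.5),),
        onset_range=(1, 3),
    )
    t["Opening a door"] = MovementTemplate(
        "Opening a door", (Phase(2.0, "sinusoid", 1.0, 0.2, 1.0),), onset_range=(1, 3)
    )
    t["Sitting on a chair and getting up"] = MovementTemplate(
        "Sitting on a chair and getting up",
        (
            Phase(2.0, "sinusoid", 1.0, 0.5, 0.5),
            Phase(3.0, "constant", 1.0),
            Phase(2.0, "sinusoid", 1.0, 0.5, 0.5),
        ),
        onset_range=(1, 2),
    )
    t["Walking"] = MovementTemplate(
        "Walking", (Phase(15.0, "sinusoid", 1.0, 0.3, 2.0),)
    )
    t["Bending"] = MovementTemplate(
        "Bending",
        (
            Phase(1.5, "ramp", 1.0, 0.2, target_angle=45.0),
            Phase(1.0, "constant", 1.0, target_angle=45.0),
            Phase(1.5, "ramp", 1.0, 0.2, target_angle=0.0),
        ),
        onset_range=(1, 3),
    )
    t["Hopping"] = MovementTemplate(
        "Hopping",
        (Phase(8.0, "spike_train", 1.0, 2.5, 1.25),),
        onset_range=(1, 3),
    )
    t["Lying down on/standing up from a bed"] = MovementTemplate(
        "Lying down on/standing up from a bed",
        (
            Phase(2.0, "sinusoid", 1.0, 0.3, 1.0, target_angle=90.0),
            Phase(4.0, "constant", 1.0, target_angle=90.0),
            Phase(2.0, "sinusoid", 1.0, 0.3, 1.0, target_angle=0.0),
        ),
        onset_range=(1, 3),
    )
    t["Going upstairs and downstairs"] = MovementTemplate(
        "Going upstairs and downstairs",
        (Phase(15.0, "sinusoid", 1.0, 0.45, 1.8),),
    )
    t["Jogging"] = MovementTemplate(
        "Jogging", (Phase(15.0, "sinusoid", 1.0, 0.8, 2.5),)
    )
    return t


@dataclass
class GeneratorConfig:
    """Study conditions for dataset synthesis.

    Defaults reproduce the reference testbed design: per-type execution
    counts summing to 746 trials, five positions, 20 Hz motes with a
    200 Hz phone in the trouser pocket, 15 s trials.

    Position-dependent realism: a trunk-mounted node (chest, waist)
    sees the whole-body movement almost verbatim, whereas limb nodes
    see an attenuated and more variable version of it
    (``dynamic_scale``: per-trace multiplicative factor drawn uniformly
    from the given range), transfer only part of the trunk orientation
    change (``orientation_scale``), and additionally pick up spurious
    limb-motion bursts (``burst_rate`` expected events per trial with
    amplitudes from ``burst_amp``). These mechanisms make the limb
    positions genuinely harder sensing points, reproducing the
    chest/waist-best ordering qualitatively.
    """

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_EXECUTIONS))
    positions: tuple[Position, ...] = POSITIONS
    fs: dict[DeviceKind, float] = field(default_factory=lambda: dict(DEFAULT_FS))
    duration: float = 15.0
    seed: int = 0
    templates: dict[str, MovementTemplate] = field(default_factory=default_templates)
    dynamic_scale: dict[Position, tuple[float, float]] = field(
        default_factory=lambda: {
            Position.CHEST: (0.85, 1.10),
            Position.WAIST: (0.80, 1.10),
            Position.WRIST: (0.50, 1.10),
            Position.ANKLE: (0.35, 1.00),
            Position.POCKET: (0.45, 1.05),
        }
    )
    orientation_scale: dict[Position, tuple[float, float]] = field(
        default_factory=lambda: {
            Position.CHEST: (1.0, 1.0),
            Position.WAIST: (0.95, 1.0),
            Position.WRIST: (0.40, 1.0),
            Position.ANKLE: (0.30, 1.0),
            Position.POCKET: (0.50, 1.0),
        }
    )
    burst_rate: dict[Position, float] = field(
        default_factory=lambda: {
            Position.CHEST: 0.0,
            Position.WAIST: 0.1,
            Position.WRIST: 1.5,
            Position.ANKLE: 3.0,
            Position.POCKET: 2.2,
        }
    )
    burst_amp: dict[Position, tuple[float, float]] = field(
        default_factory=lambda: {
            Position.WAIST: (0.3, 1.0),
            Position.WRIST: (0.8, 3.5),
            Position.ANKLE: (1.0, 4.5),
            Position.POCKET: (1.0, 4.0),
        }
    )
    jitter_scale: dict[Position, float] = field(
        default_factory=lambda: {
            Position.CHEST: 1.0,
            Position.WAIST: 1.0,
            Position.WRIST: 2.0,
            Position.ANKLE: 3.0,
            Position.POCKET: 2.5,
        }
    )
    subjects: tuple[Subject, ...] = SUBJECT_ROSTER

    def __post_init__(self) -> None:
        for name, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {name!r}")
            if name not in MOVEMENT_TYPES:
                raise ValueError(f"unknown movement type {name!r}")

    def device_kind(self, position: Position) -> DeviceKind:
        return DeviceKind.PHONE if position is Position.POCKET else DeviceKind.MOTE


def _profile_and_angle(
    template: MovementTemplate, t: np.ndarray, onset: float
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the SMV profile (g) and gravity tilt (rad) at times t."""
    s = np.ones_like(t)
    angle = np.zeros_like(t)
    start = onset
    prev_angle = 0.0
    for ph in template.phases:
        end = start + ph.duration
        m = (t >= start) & (t < end)
        tau = t[m] - start
        frac = tau / ph.duration if ph.duration > 0 else tau
        if ph.shape == "constant":
            s[m] = ph.level
        elif ph.shape == "sinusoid":
            s[m] = ph.level + ph.amplitude * np.sin(2 * np.pi * ph.freq * tau)
        elif ph.shape == "ramp":
            s[m] = ph.level + ph.amplitude * frac
        elif ph.shape == "valley_then_spike":
            s[m] = np.where(frac < _VALLEY_FRACTION, ph.level, ph.amplitude)
        elif ph.shape == "spike_train":
            period = 1.0 / ph.freq
            phase_t = np.mod(tau, period)
            tri = np.clip(1.0 - np.abs(phase_t - _SPIKE_WIDTH) / _SPIKE_WIDTH, 0, 1)
            s[m] = ph.level + (ph.amplitude - ph.level) * tri
        tgt = ph.target_angle
        if tgt is None:
            angle[m] = prev_angle
        else:
            angle[m] = prev_angle + (tgt - prev_angle) * frac
            prev_angle = tgt
        # tail after this phase (overwritten by later phases where covered)
        tail = t >= end
        s[tail] = 1.0 if ph.shape != "constant" else ph.level
        angle[tail] = prev_angle
        start = end
    np.clip(s, 0.0, None, out=s)
    return s, np.deg2rad(angle)


def synth_trace(
    template: MovementTemplate,
    position: Position,
    device_kind: DeviceKind,
    rng: np.random.Generator,
    fs: float | None = None,
    duration: float = 15.0,
    dynamic_scale: float | tuple[float, float] = 1.0,
    orientation_scale: float | tuple[float, float] = 1.0,
    burst_rate: float = 0.0,
    burst_amp: tuple[float, float] = (0.5, 2.5),
    jitter_scale: float = 1.0,
) -> SensorTrace:
    """Synthesize one position's trace for one movement execution.

    ``dynamic_scale`` and ``orientation_scale`` may be ranges, in which
    case a per-trace factor is drawn uniformly; they model how much of
    the whole-body movement (SMV deviation from 1 g, gravity tilt)
    reaches this mounting point.
    """
    fs = DEFAULT_FS[device_kind] if fs is None else fs
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("fs x duration must yield at least 2 samples")
    t = np.arange(n) / fs
    onset = rng.uniform(*template.onset_range)
    s, angle = _profile_and_angle(template, t, onset)
    if np.ndim(dynamic_scale):
        dynamic_scale = rng.uniform(*dynamic_scale)
    if np.ndim(orientation_scale):
        orientation_scale = rng.uniform(*orientation_scale)
    # attenuate the movement's dynamic part away from the trunk
    s = 1.0 + dynamic_scale * (s - 1.0)
    np.clip(s, 0.0, None, out=s)
    angle = orientation_scale * angle

    v = VERTICAL_AXIS[device_kind]
    u1, u2 = [i for i in range(3) if i != v]
    az = np.deg2rad(template.azimuth)
    a = np.zeros((n, 3))
    a[:, v] = s * np.cos(angle)
    a[:, u1] = s * np.sin(angle) * np.cos(az)
    a[:, u2] = s * np.sin(angle) * np.sin(az)

    n_bursts = rng.poisson(burst_rate)
    for _ in range(n_bursts):
        center = rng.uniform(0.0, duration)
        width = 0.25
        amp = rng.uniform(*burst_amp)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        m = np.abs(t - center) < width / 2
        bump = amp * np.cos(np.pi * (t[m] - center) / width) ** 2
        a[m] += bump[:, None] * direction
    if template.jitter > 0:
        a += rng.normal(0.0, template.jitter * jitter_scale, size=a.shape)
    return SensorTrace(position=position, device_kind=device_kind, fs=fs, t=t, a=a)


def synth_trial(
    movement_type: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    trial_id: str = "trial",
) -> TrialRecord:
    """Generate one labeled trial with one trace per configured position."""
    if movement_type not in config.templates:
        raise ValueError(f"unknown movement type {movement_type!r}")
    template = config.templates[movement_type]
    is_fall = label_for(movement_type) == "fall"
    pool = [s for s in config.subjects if not (is_fall and s.age > 65)]
    subject = pool[int(rng.integers(0, len(pool)))]
    traces: dict[Position, SensorTrace] = {}
    for pos in config.positions:
        kind = config.device_kind(pos)
        traces[pos] = synth_trace(
            template,
            pos,
            kind,
            rng,
            fs=config.fs[kind],
            duration=config.duration,
            dynamic_scale=config.dynamic_scale.get(pos, 1.0),
            orientation_scale=config.orientation_scale.get(pos, 1.0),
            burst_rate=config.burst_rate.get(pos, 0.0),
            burst_amp=config.burst_amp.get(pos, (0.5, 2.5)),
            jitter_scale=config.jitter_scale.get(pos, 1.0),
        )
    return TrialRecord(
        trial_id=trial_id,
        movement_type=movement_type,
        traces=traces,
        subject=subject,
        duration=config.duration,
    )


def synth_dataset(config: GeneratorConfig) -> list[TrialRecord]:
    """Generate the full dataset (default: 746 trials across 14 types).

    Each trial gets an independent RNG stream keyed by
    ``(config.seed, trial_index)``; the stream of a given trial does not
    depend on the counts of other movement types.
    """
    trials: list[TrialRecord] = []
    index = 0
    for movement in MOVEMENT_TYPES:
        for _ in range(config.counts.get(movement, 0)):
            rng = np.random.default_rng([config.seed, index])
            slug = movement.lower().replace(" ", "-").replace("/", "-")
            trials.append(
                synth_trial(movement, config, rng, trial_id=f"{slug}_{index:04d}")
            )
            index += 1
    return trials
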