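"""Core domain types: traces, trials, subjects and feature vectors.

Acceleration is expressed in g throughout; timestamps in seconds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Position(str, enum.Enum):
    """Body placement of a sensing node."""

    POCKET = "pocket"
    CHEST = "chest"
    WAIST = "waist"
    WRIST = "wrist"
    ANKLE = "ankle"


#: Canonical ordering of positions used for sensor-combination masks.
POSITIONS: tuple[Position, ...] = (
    Position.POCKET,
    Position.CHEST,
    Position.WAIST,
    Position.WRIST,
    Position.ANKLE,
)


class DeviceKind(str, enum.Enum):
    """Hardware class of a node: low-rate wireless mote or smartphone."""

    MOTE = "mote"
    PHONE = "phone"


#: Index of the gravity-aligned axis in the initial upright posture.
#: Motes are mounted with X pointing down the body axis; the phone rides
#: in a trouser pocket with Y along the thigh.
VERTICAL_AXIS: dict[DeviceKind, int] = {DeviceKind.MOTE: 0, DeviceKind.PHONE: 1}

#: Default sampling rates in Hz per device class.
DEFAULT_FS: dict[DeviceKind, float] = {DeviceKind.MOTE: 20.0, DeviceKind.PHONE: 200.0}

#: The three emulated fall classes.
FALL_TYPES: tuple[str, ...] = ("Forwards fall", "Backwards fall", "Lateral fall")

#: The eleven activities of daily living.
ADL_TYPES: tuple[str, ...] = (
    "Applauding",
    "Raising both arms",
    "Emulating a phone call",
    "Opening a door",
    "Sitting on a chair and getting up",
    "Walking",
    "Bending",
    "Hopping",
    "Lying down on/standing up from a bed",
    "Going upstairs and downstairs",
    "Jogging",
)

MOVEMENT_TYPES: tuple[str, ...] = ADL_TYPES + FALL_TYPES

#: Number of recorded executions per movement type in the reference
#: testbed design (746 trials in total).
DEFAULT_EXECUTIONS: dict[str, int] = {
    "Applauding": 42,
    "Raising both arms": 43,
    "Emulating a phone call": 46,
    "Opening a door": 43,
    "Sitting on a chair and getting up": 64,
    "Walking": 63,
    "Bending": 59,
    "Hopping": 53,
    "Lying down on/standing up from a bed": 57,
    "Going upstairs and downstairs": 40,
    "Jogging": 28,
    "Forwards fall": 71,
    "Backwards fall": 73,
    "Lateral fall": 64,
}

#: Number of trials per movement type reserved for classifier training
#: (183 in total; the remaining 563 form the test blocks).
DEFAULT_TRAINING_COUNTS: dict[str, int] = {
    "Applauding": 14,
    "Raising both arms": 14,
    "Emulating a phone call": 14,
    "Opening a door": 14,
    "Sitting on a chair and getting up": 14,
    "Walking": 14,
    "Bending": 14,
    "Hopping": 14,
    "Lying down on/standing up from a bed": 14,
    "Going upstairs and downstairs": 7,
    "Jogging": 9,
    "Forwards fall": 13,
    "Backwards fall": 14,
    "Lateral fall": 14,
}

#: Canonical ordering of the six candidate features. The conventional
#: factor letters A..F map onto this order.
FEATURE_NAMES: tuple[str, ...] = (
    "mu_smv",
    "awdiff_max",
    "sigma_smv",
    "mu_theta",
    "mu_smvdiff",
    "mu_ap",
)


def label_for(movement_type: str) -> str:
    """Class label ('fall' or 'adl') implied by a movement type."""
    if movement_type in FALL_TYPES:
        return "fall"
    if movement_type in ADL_TYPES:
        return "adl"
    raise ValueError(f"unknown movement type: {movement_type!r}")


@dataclass(frozen=True)
class Subject:
    id: str
    gender: str
    age: float
    height_cm: float
    weight_kg: float


@dataclass
class SensorTrace:
    """One position's triaxial acceleration series for one trial.

    Parameters
    ----------
    position : Position
        Body placement of the node.
    device_kind : DeviceKind
        Mote or phone; fixes the gravity-aligned axis convention.
    fs : float
        Sampling rate in Hz.
    t : ndarray, shape (N,)
        Timestamps in seconds, non-decreasing.
    a : ndarray, shape (N, 3)
        Acceleration components (AX, AY, AZ) in g.
    """

    position: Position
    device_kind: DeviceKind
    fs: float
    t: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.t.ndim != 1 or self.a.shape != (self.t.size, 3):
            raise ValueError("t must be (N,) and a must be (N, 3)")
        if self.t.size and np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if not np.all(np.isfinite(self.a)):
            raise ValueError("acceleration components must be finite")

    def __len__(self) -> int:
        return self.t.size

    @property
    def vertical_axis(self) -> int:
        return VERTICAL_AXIS[self.device_kind]


@dataclass
class TrialRecord:
    """A labeled movement execution bundling up to five traces."""

    trial_id: str
    movement_type: str
    traces: dict[Position, SensorTrace]
    subject: Subject
    duration: float = 15.0
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        implied = label_for(self.movement_type)
        if self.label and self.label != implied:
            raise ValueError(
                f"label {self.label!r} inconsistent with movement "
                f"{self.movement_type!r}"
            )
        self.label = implied
        if not 1 <= len(self.traces) <= len(POSITIONS):
            raise ValueError("a trial carries between 1 and 5 traces")
        for pos, tr in self.traces.items():
            if tr.position != pos:
                raise ValueError(f"trace filed under {pos} reports {tr.position}")


@dataclass(frozen=True)
class FeatureVector:
    """The six per-trace statistics of the analysis window.

    ``mu_smv``, ``sigma_smv``, ``mu_smvdiff``, ``mu_ap`` and
    ``awdiff_max`` are in g; ``mu_theta`` is in radians.
    """

    mu_smv: float
    awdiff_max: float
    sigma_smv: float
    mu_theta: float
    mu_smvdiff: float
    mu_ap: float

    def __post_init__(self) -> None:
        if self.sigma_smv < 0 or self.mu_ap < 0 or self.mu_smv < 0:
            raise ValueError("magnitude features must be non-negative")
        if not 0 <= self.mu_theta <= np.pi:
            raise ValueError("mean rotation angle must lie in [0, pi]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}
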