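"""Impact-window localization and the six candidate acceleration features.

The analysis focuses on the sliding window of duration ``t_w`` (default
0.5 s) that maximizes Awdiff, the Euclidean norm of the per-axis
(max - min) acceleration ranges. Within that window six statistics are
computed from the triaxial samples (all in g, angles in radians):

- ``mu_smv``     mean signal-magnitude vector (SMV, the sample norm)
- ``sigma_smv``  population standard deviation of the SMV
- ``mu_smvdiff`` mean absolute difference of consecutive SMV samples
- ``mu_theta``   mean rotation angle between consecutive samples
- ``mu_ap``      mean norm of the two non-vertical components
- ``awdiff_max`` the maximal Awdiff value itself

The pairwise sums in ``mu_smvdiff`` and ``mu_theta`` run over the
``Nw - 1`` strictly in-window consecutive pairs but keep a ``1/Nw``
normalization; the arccos argument is clamped to [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from fallban.types import FEATURE_NAMES, FeatureVector, SensorTrace, TrialRecord

logger = logging.getLogger(__name__)

#: Default sliding-window duration in seconds.
DEFAULT_T_W = 0.5


@dataclass(frozen=True)
class AnalysisWindow:
    """Location of the maximal-variation window (0-based start index)."""

    k0: int
    nw: int
    awdiff_max: float

    def __post_init__(self) -> None:
        if self.k0 < 0 or self.nw < 1 or self.awdiff_max < 0:
            raise ValueError("invalid analysis window")


def window_length(t_w: float, fs: float) -> int:
    """Window length in samples: round(t_w * fs), at least 1."""
    if t_w <= 0 or fs <= 0:
        raise ValueError("t_w and fs must be positive")
    return max(1, int(np.floor(t_w * fs + 0.5)))


def sliding_awdiff(a: np.ndarray | SensorTrace, nw: int) -> np.ndarray:
    """Awdiff(j) for every window start j.

    Awdiff(j) = sqrt(sum over axes of (max - min within window)^2),
    an (N - nw + 1)-vector of non-negative values.
    """
    arr = a.a if isinstance(a, SensorTrace) else np.asarray(a, dtype=float)
    n = arr.shape[0]
    if nw < 1:
        raise ValueError("window length must be >= 1")
    if n < nw:
        raise ValueError(f"trace of length {n} shorter than window {nw}")
    win = sliding_window_view(arr, nw, axis=0)  # (N - nw + 1, 3, nw)
    rng = win.max(axis=2) - win.min(axis=2)
    return np.sqrt((rng**2).sum(axis=1))


def locate_analysis_window(trace: SensorTrace, t_w: float = DEFAULT_T_W) -> AnalysisWindow:
    """Find the earliest window maximizing Awdiff at the trace's rate."""
    nw = window_length(t_w, trace.fs)
    aw = sliding_awdiff(trace, nw)
    k0 = int(np.argmax(aw))  # argmax returns the earliest maximizer
    return AnalysisWindow(k0=k0, nw=nw, awdiff_max=float(aw[k0]))


def smv(ax: float, ay: float, az: float) -> float:
    """Signal-magnitude vector: Euclidean norm of one sample."""
    return float(np.sqrt(ax * ax + ay * ay + az * az))


def feature_vector(
    trace: SensorTrace, window: AnalysisWindow, vertical_axis: int | None = None
) -> FeatureVector:
    """Compute the six features over the analysis window.

    ``vertical_axis`` is the index (0/1/2) of the gravity-aligned axis
    in the upright posture; defaults to the trace's device convention
    (X for motes, Y for the phone).
    """
    if window.k0 + window.nw > len(trace):
        raise ValueError("analysis window does not fit the trace")
    if vertical_axis is None:
        vertical_axis = trace.vertical_axis
    w = trace.a[window.k0 : window.k0 + window.nw]
    nw = window.nw

    smv_w = np.linalg.norm(w, axis=1)
    mu_smv = float(smv_w.mean())
    sigma_smv = float(np.sqrt(((smv_w - mu_smv) ** 2).mean()))
    mu_smvdiff = float(np.abs(np.diff(smv_w)).sum() / nw)

    if nw >= 2:
        dots = (w[:-1] * w[1:]).sum(axis=1)
        norms = smv_w[:-1] * smv_w[1:]
        ok = norms > 0
        if not np.all(ok):
            logger.warning(
                "zero-norm sample in rotation-angle pairs; contributing 0"
            )
        cosang = np.ones_like(dots)
        np.divide(dots, norms, out=cosang, where=ok)
        angles = np.arccos(np.clip(cosang, -1.0, 1.0))
        mu_theta = float(angles.sum() / nw)
    else:
        mu_theta = 0.0

    perp = [i for i in range(3) if i != vertical_axis]
    mu_ap = float(np.linalg.norm(w[:, perp], axis=1).mean())

    return FeatureVector(
        mu_smv=mu_smv,
        awdiff_max=window.awdiff_max,
        sigma_smv=sigma_smv,
        mu_theta=mu_theta,
        mu_smvdiff=mu_smvdiff,
        mu_ap=mu_ap,
    )


def extract_trace_features(trace: SensorTrace, t_w: float = DEFAULT_T_W) -> FeatureVector:
    """Locate the analysis window and compute features in one step."""
    return feature_vector(trace, locate_analysis_window(trace, t_w))


def feature_table(trials: list[TrialRecord], t_w: float = DEFAULT_T_W) -> pd.DataFrame:
    """Batch extraction: one row per (trial, position).

    Columns: trial_id, movement_type, label, position, then the six
    features in canonical order.
    """
    rows = []
    for trial in trials:
        for pos, trace in trial.traces.items():
            fv = extract_trace_features(trace, t_w)
            row = {
                "trial_id": trial.trial_id,
                "movement_type": trial.movement_type,
                "label": trial.label,
                "position": pos.value,
            }
            row.update(fv.as_dict())
            rows.append(row)
    return pd.DataFrame(rows, columns=["trial_id", "movement_type", "label", "position", *FEATURE_NAMES])
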