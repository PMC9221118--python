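"""Instantaneous arousal/valence estimation, epoching, normalization.

Arousal is the ratio of beta to alpha band power summed over the four
prefrontal channels:

    arousal = (beta_F3 + beta_F4 + beta_AF3 + beta_AF4)
              / (alpha_F3 + alpha_F4 + alpha_AF3 + alpha_AF4)

Valence is the frontal alpha asymmetry:

    valence = alpha_F4 - alpha_F3

(larger right-hemisphere alpha, i.e. relative left activation, reads as
positive/approach affect).  Arousal is dimensionless; valence is in uV^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import ArtifactMask, BandPowerSeries
from .protocol import StimulusSchedule
from .synth import FRONTAL_CHANNELS

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "participant_id", "group", "session_index", "condition",
    "stimulus_id", "emotion", "window_center_s", "arousal", "valence",
]


@dataclass
class AffectSeries:
    """Arousal/valence time series on the band-power window grid."""

    window_centers: np.ndarray
    arousal: np.ndarray
    valence: np.ndarray
    participant_id: str
    group: str
    session_index: int
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        self.arousal = np.asarray(self.arousal, dtype=float)
        self.valence = np.asarray(self.valence, dtype=float)
        if not (len(self.window_centers) == len(self.arousal) == len(self.valence)):
            raise ValueError("misaligned affect series")


def compute_affect(
    alpha: BandPowerSeries,
    beta: BandPowerSeries,
    mask: ArtifactMask | None = None,
    participant_id: str = "",
    group: str = "EG",
    session_index: int = 1,
) -> AffectSeries:
    """Apply the arousal-ratio and alpha-asymmetry definitions per window.

    Windows in ``mask`` are omitted; windows with a zero alpha denominator
    are dropped (with a log note) rather than clamped, so the ratio stays
    interpretable.
    """
    if not np.array_equal(alpha.window_centers, beta.window_centers):
        raise ValueError("alpha and beta series must share the window grid")
    for name, series in (("alpha", alpha), ("beta", beta)):
        for ch in FRONTAL_CHANNELS:
            if ch not in series.power:
                raise ValueError(f"{name} band power missing required channel {ch}")

    alpha_sum = sum(alpha.power[ch] for ch in FRONTAL_CHANNELS)
    beta_sum = sum(beta.power[ch] for ch in FRONTAL_CHANNELS)
    keep = np.ones(len(alpha.window_centers), dtype=bool)
    if mask is not None:
        keep &= ~mask.is_rejected(alpha.window_centers)
    zero_den = alpha_sum == 0
    if np.any(zero_den & keep):
        logger.warning(
            "%d windows dropped for zero alpha denominator", int(np.sum(zero_den & keep))
        )
    keep &= ~zero_den

    centers = alpha.window_centers[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        arousal = beta_sum[keep] / alpha_sum[keep]
    valence = alpha.power["F4"][keep] - alpha.power["F3"][keep]
    return AffectSeries(
        window_centers=centers, arousal=arousal, valence=valence,
        participant_id=participant_id, group=group, session_index=session_index,
    )


def epoch_affect(affect: AffectSeries, schedule: StimulusSchedule) -> pd.DataFrame:
    """Segment an affect series by stimulus.

    Keeps exactly the windows whose centers fall inside an event's
    [onset, onset + duration) span; transition windows are excluded.
    Returns one row per kept window with the event's labels joined on.
    """
    if affect.participant_id and affect.participant_id != schedule.participant_id:
        raise ValueError(
            f"affect series for {affect.participant_id!r} does not match "
            f"schedule for {schedule.participant_id!r}"
        )
    if affect.session_index != schedule.session_index:
        raise ValueError("affect series and schedule session indices differ")

    rows = []
    for ev in schedule.events:
        in_event = (
            (affect.window_centers >= ev.onset_s)
            & (affect.window_centers < ev.onset_s + ev.duration_s)
        )
        if not np.any(in_event):
            logger.info("stimulus %s fully masked or uncovered; zero rows", ev.stimulus_id)
            continue
        for c, a, v in zip(
            affect.window_centers[in_event],
            affect.arousal[in_event],
            affect.valence[in_event],
        ):
            rows.append((
                schedule.participant_id, schedule.group, schedule.session_index,
                ev.condition, ev.stimulus_id, ev.emotion, c, a, v,
            ))
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.attrs["normalization"] = affect.normalization
    return df


_SCOPE_KEYS = {
    "participant_session": ["participant_id", "session_index"],
    "participant_study": ["participant_id"],
}


def normalize_affect(
    features: pd.DataFrame, scope: str = "participant_session"
) -> pd.DataFrame:
    """Z-score arousal and valence independently within each scope group.

    The default scope (per participant-session) removes inter-session
    gain/impedance drift so sessions are comparable.
    """
    if scope not in _SCOPE_KEYS:
        raise ValueError(f"scope must be one of {sorted(_SCOPE_KEYS)}, got {scope!r}")
    keys = _SCOPE_KEYS[scope]
    if features.empty:
        raise ValueError("cannot normalize an empty feature set")
    out = features.copy()
    for col in ("arousal", "valence"):
        grouped = out.groupby(keys, sort=False)[col]
        sd = grouped.transform("std", ddof=0)
        if (grouped.transform("size") < 2).any():
            raise ValueError("every scope group needs >= 2 rows to normalize")
        if (sd == 0).any():
            bad = out.loc[sd == 0, keys].drop_duplicates().to_records(index=False)
            raise ValueError(f"zero variance in {col} within group(s) {list(bad)}")
        out[col] = (out[col] - grouped.transform("mean")) / sd
    out.attrs["normalization"] = "zscored"
    return out
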