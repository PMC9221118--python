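"""Band-pass filtering, windowed band power, and artifact-window rejection.

Band definitions follow the acquisition pipeline being modeled: alpha
8-12 Hz and beta 12-28 Hz, 4th-order Butterworth applied forward-backward
(zero phase) so stimulus-locked epochs stay aligned.  "Instantaneous" band
power is a sliding-window mean square of the band-filtered signal: 1 s
windows (>= 8 alpha cycles) hopped every 0.25 s.

Artifact handling replaces manual visual inspection with two reproducible
rules: an absolute-amplitude veto on the prefrontal channels and a z-score
veto on total (alpha+beta) frontal power across the recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synth import EEGRecording, FRONTAL_CHANNELS

logger = logging.getLogger(__name__)

BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 12.0),
    "beta": (12.0, 28.0),
}

DEFAULT_WINDOW_S = 1.0
DEFAULT_HOP_S = 0.25
#: filter warm-up margin dropped at each end of a recording
EDGE_S = 1.0
DEFAULT_ABS_UV = 100.0
DEFAULT_Z_THRESH = 5.0


@dataclass
class BandPowerSeries:
    """Windowed band power per channel, one frequency band.

    ``power[channel]`` aligns with ``window_centers`` (seconds, absolute).
    Powers are in uV^2.
    """

    band: str
    window_centers: np.ndarray
    power: dict[str, np.ndarray]
    window_s: float
    hop_s: float

    def __post_init__(self) -> None:
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        for ch, p in self.power.items():
            p = np.asarray(p, dtype=float)
            if p.shape != self.window_centers.shape:
                raise ValueError(f"power for {ch} misaligned with window grid")
            if not np.all(np.isfinite(p)) or np.any(p < 0):
                raise ValueError(f"powers for {ch} must be finite and >= 0")
            self.power[ch] = p
        if len(self.window_centers) > 1:
            steps = np.diff(self.window_centers)
            if not np.allclose(steps, self.hop_s):
                raise ValueError("window centers must increase by hop_s")

    @property
    def n_windows(self) -> int:
        return len(self.window_centers)


@dataclass
class ArtifactMask:
    """Rejected window centers with reason codes ('amplitude', 'power_z')."""

    window_centers: np.ndarray
    reasons: dict[float, list[str]]

    @property
    def n_rejected(self) -> int:
        return len(self.window_centers)

    def is_rejected(self, centers: np.ndarray) -> np.ndarray:
        if self.n_rejected == 0:
            return np.zeros(len(centers), dtype=bool)
        rejected = np.asarray(self.window_centers)
        return np.isclose(np.asarray(centers)[:, None], rejected[None, :]).any(axis=1)


def _butter_sos(low_hz: float, high_hz: float, fs: float, order: int):
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(f"band edge {high_hz} Hz at or above Nyquist ({nyq} Hz)")
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(
    rec: EEGRecording, low_hz: float, high_hz: float, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    order and cancels phase delay, preserving epoch alignment.
    """
    sos = _butter_sos(low_hz, high_hz, rec.device.sampling_rate_hz, order)
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered, artifact_intervals=list(rec.artifact_intervals))


def window_grid(
    rec: EEGRecording,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    edge_s: float = EDGE_S,
) -> np.ndarray:
    """Centers of analysis windows fully inside the recording, with the
    filter warm-up margin (``edge_s`` per side) excluded."""
    t0 = rec.start_time_s
    first = t0 + max(window_s / 2.0, edge_s)
    last = t0 + rec.duration_s - max(window_s / 2.0, edge_s)
    if last < first:
        return np.array([])
    n = int(np.floor((last - first) / hop_s + 1e-9)) + 1
    return first + hop_s * np.arange(n)


def band_power(
    rec: EEGRecording,
    band: str,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    order: int = 4,
    channels: tuple[str, ...] | None = None,
    edge_s: float = EDGE_S,
) -> BandPowerSeries:
    """Sliding-window band power (uV^2) of the band-filtered signal.

    Per window, power is the mean of squared band-filtered samples over
    [center - window_s/2, center + window_s/2).
    """
    if band not in BANDS:
        raise ValueError(f"band must be one of {sorted(BANDS)}, got {band!r}")
    low, high = BANDS[band]
    min_window = 2.0 / low
    if window_s < min_window:
        raise ValueError(
            f"window_s={window_s} shorter than two cycles of {low} Hz ({min_window:.3f} s)"
        )
    centers = window_grid(rec, window_s, hop_s, edge_s)
    if centers.size == 0:
        logger.warning(
            "recording %s shorter than one analysis window; empty band-power series",
            rec.participant_id,
        )
    channels = rec.device.channel_names if channels is None else channels
    fs = rec.device.sampling_rate_hz
    filtered = bandpass(rec, low, high, order)
    half = window_s / 2.0
    power: dict[str, np.ndarray] = {}
    starts = np.round((centers - half - rec.start_time_s) * fs).astype(int)
    stops = np.round((centers + half - rec.start_time_s) * fs).astype(int)
    for ch in channels:
        x = filtered.channel(ch)
        p = np.array([np.mean(x[i0:i1] ** 2) for i0, i1 in zip(starts, stops)])
        power[ch] = p if p.size else np.array([])
    return BandPowerSeries(
        band=band, window_centers=centers, power=power,
        window_s=window_s, hop_s=hop_s,
    )


def reject_artifact_windows(
    rec: EEGRecording,
    series: BandPowerSeries | list[BandPowerSeries],
    abs_uv: float = DEFAULT_ABS_UV,
    z_thresh: float = DEFAULT_Z_THRESH,
) -> ArtifactMask:
    """Flag analysis windows contaminated by transient artifacts.

    A window is rejected if any prefrontal channel (AF3/AF4/F3/F4) exceeds
    +-``abs_uv`` within it, or if its total frontal band power (summed over
    the given series) has a z-score above ``z_thresh`` across the recording.
    """
    if abs_uv <= 0 or z_thresh <= 0:
        raise ValueError("thresholds must be positive")
    series_list = [series] if isinstance(series, BandPowerSeries) else list(series)
    if not series_list:
        raise ValueError("need at least one band-power series")
    centers = series_list[0].window_centers
    for s in series_list[1:]:
        if not np.array_equal(s.window_centers, centers):
            raise ValueError("band-power series must share the window grid")
    fs = rec.device.sampling_rate_hz
    half = series_list[0].window_s / 2.0

    reasons: dict[float, list[str]] = {}
    if np.isfinite(abs_uv):
        frontal = np.vstack([rec.channel(ch) for ch in FRONTAL_CHANNELS])
        for c in centers:
            i0 = int(round((c - half - rec.start_time_s) * fs))
            i1 = int(round((c + half - rec.start_time_s) * fs))
            if np.any(np.abs(frontal[:, max(i0, 0):i1]) > abs_uv):
                reasons.setdefault(float(c), []).append("amplitude")

    if np.isfinite(z_thresh) and centers.size > 1:
        total = np.zeros(len(centers))
        for s in series_list:
            for ch in FRONTAL_CHANNELS:
                if ch in s.power:
                    total += s.power[ch]
        sd = total.std()
        if sd > 0:
            z = (total - total.mean()) / sd
            for c in centers[z > z_thresh]:
                reasons.setdefault(float(c), []).append("power_z")

    rejected = np.array(sorted(reasons))
    if centers.size:
        logger.info(
            "artifact rejection: %d/%d windows rejected (%.1f%%)",
            len(rejected), len(centers), 100.0 * len(rejected) / len(centers),
        )
    return ArtifactMask(window_centers=rejected, reasons=reasons)
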