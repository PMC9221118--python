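"""Synthetic multichannel EEG with planted affective structure.

The simulator emits 14-channel recordings that mimic a consumer EEG headset
(10-20 montage, 128 Hz, 16-bit ADC).  During each stimulus presentation the
four prefrontal channels (AF3, AF4, F3, F4) carry narrowband alpha (10 Hz)
and beta (20 Hz) oscillators whose band powers are solved analytically from
per-emotion arousal/valence targets, so that the downstream estimators

    arousal = (beta_F3 + beta_F4 + beta_AF3 + beta_AF4)
              / (alpha_F3 + alpha_F4 + alpha_AF3 + alpha_AF4)
    valence = alpha_F4 - alpha_F3

recover the planted ground truth.  All channels additionally carry 1/f
background noise; inter-stimulus transitions carry background only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

EMOTIONS = ("happy", "sad", "angry", "fear")

#: channel order of the 14-channel consumer headset, 10-20 labels
EMOTIV_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: prefrontal channels entering the arousal/valence estimators
FRONTAL_CHANNELS = ("AF3", "AF4", "F3", "F4")

ALPHA_CENTER_HZ = 10.0
BETA_CENTER_HZ = 20.0


@dataclass(frozen=True)
class DeviceProfile:
    """Acquisition device metadata: montage, sampling rate, ADC depth."""

    channel_names: tuple[str, ...] = EMOTIV_CHANNELS
    sampling_rate_hz: float = 128.0
    adc_bits: int = 16
    reference_labels: tuple[str, ...] = ("P3", "P4")

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None


@dataclass(frozen=True)
class EmotionTarget:
    """Planted affective coordinates for one emotion.

    ``arousal`` is a dimensionless beta/alpha power ratio (> 0);
    ``valence`` is a signed frontal alpha-power difference in uV^2.
    """

    arousal: float
    valence: float


class AffectGroundTruth(Mapping[str, EmotionTarget]):
    """Per-emotion planted (arousal, valence) targets, keyed by emotion."""

    def __init__(self, targets: Mapping[str, EmotionTarget]):
        if set(targets) != set(EMOTIONS):
            raise ValueError(
                f"ground truth must key exactly {set(EMOTIONS)}, got {set(targets)}"
            )
        for emo, t in targets.items():
            if t.arousal <= 0:
                raise ValueError(
                    f"target arousal for {emo} must be > 0 (power ratio), got {t.arousal}"
                )
        self._targets = dict(targets)

    def __getitem__(self, key: str) -> EmotionTarget:
        return self._targets[key]

    def __iter__(self):
        return iter(self._targets)

    def __len__(self) -> int:
        return len(self._targets)

    @classmethod
    def default(cls) -> "AffectGroundTruth":
        """Thayer-plane layout: happy/angry/fear high arousal, sad low;
        happy positive valence, the rest negative."""
        return cls({
            "happy": EmotionTarget(arousal=2.0, valence=+1.0),
            "sad": EmotionTarget(arousal=0.5, valence=-0.5),
            "angry": EmotionTarget(arousal=2.5, valence=-1.0),
            "fear": EmotionTarget(arousal=2.2, valence=-0.8),
        })


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise settings: 1/f^exponent spectrum, RMS in uV."""

    background_uv: float = 10.0
    exponent: float = 1.0
    #: random-walk phase-drift step of the oscillators, rad/sample
    phase_drift_rad: float = 0.02

    def __post_init__(self) -> None:
        if self.background_uv < 0:
            raise ValueError("background_uv must be >= 0")


@dataclass
class EEGRecording:
    """A participant-session multichannel signal in uV.

    ``data`` is channels x samples, row order = ``device.channel_names``.
    ``artifact_intervals`` holds ground-truth (start_s, stop_s) spans of any
    injected transient artifacts, for test assertions.
    """

    participant_id: str
    group: str
    session_index: int
    data: np.ndarray
    device: DeviceProfile
    start_time_s: float = 0.0
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.device.n_channels:
            raise ValueError(
                f"data must be ({self.device.n_channels}, n_samples), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("all samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.device.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.device.sampling_rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.device.channel_index(name)]


def _solve_band_powers(
    target: EmotionTarget, alpha_f_sum_uv2: float
) -> tuple[dict[str, float], dict[str, float]]:
    """Invert the arousal/valence definitions into per-channel band powers.

    The inversion is under-determined; it is made unique by fixing the
    F3+F4 alpha-power sum and setting each AF-channel alpha power to the
    mean of the F-channel powers.  Beta power is spread equally over the
    four channels.
    """
    s = alpha_f_sum_uv2
    v = target.valence
    if abs(v) >= s:
        raise ValueError(
            f"valence target {v} uV^2 incompatible with F-channel alpha sum {s} uV^2 "
            "(a channel power would be non-positive); raise alpha_f_sum_uv2"
        )
    alpha = {
        "F4": (s + v) / 2.0,
        "F3": (s - v) / 2.0,
        "AF3": s / 2.0,
        "AF4": s / 2.0,
    }
    beta_total = target.arousal * sum(alpha.values())
    beta = {ch: beta_total / 4.0 for ch in FRONTAL_CHANNELS}
    return alpha, beta


def _oscillator(
    n: int, fs: float, f0: float, power_uv2: float, drift_rad: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Amplitude-stable sinusoid at f0 with slow random phase drift.

    A sinusoid of amplitude A has mean-square power A^2/2, so the amplitude
    is solved as sqrt(2 * power).  The phase random walk has a linewidth of
    roughly drift^2 * fs / (2 pi) Hz — negligible against the band widths.
    """
    if power_uv2 < 0:
        raise ValueError("band power must be >= 0")
    amp = np.sqrt(2.0 * power_uv2)
    t = np.arange(n) / fs
    phase0 = rng.uniform(0, 2 * np.pi)
    drift = np.cumsum(rng.normal(0.0, drift_rad, size=n))
    return amp * np.sin(2 * np.pi * f0 * t + phase0 + drift)


def one_over_f_noise(
    n: int, fs: float, rms_uv: float, exponent: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise, scaled to RMS.

    The shaping flattens below 1 Hz to keep the spectrum integrable.
    """
    if rms_uv == 0:
        return np.zeros(n)
    rng = np.random.default_rng() if rng is None else rng
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = np.maximum(freqs[nonzero], 1.0) ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n)
    x *= rms_uv / np.sqrt(np.mean(x**2))
    return x


def generate_recording(
    schedule,
    truth: AffectGroundTruth,
    device: DeviceProfile | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    alpha_f_sum_uv2: float = 2.0,
    tail_s: float | None = None,
) -> EEGRecording:
    """Synthesize a participant-session recording for a stimulus schedule.

    For every event the four prefrontal channels receive alpha+beta
    oscillators whose powers encode ``truth[event.emotion]``; all channels
    receive independent 1/f background.  Fully deterministic in ``seed``.

    Parameters
    ----------
    schedule
        A :class:`~eegaffect.protocol.StimulusSchedule`; events must be
        sorted and non-overlapping.
    alpha_f_sum_uv2
        Planted F3+F4 alpha-power sum (uV^2); sets the oscillator scale.
    tail_s
        Recording tail after the last event; defaults to the schedule's
        transition length.
    """
    device = DeviceProfile() if device is None else device
    noise = NoiseSpec() if noise is None else noise
    fs = device.sampling_rate_hz

    events = list(schedule.events)
    for a, b in zip(events, events[1:]):
        if b.onset_s < a.onset_s:
            raise ValueError("schedule events must be sorted by onset")
        if b.onset_s < a.onset_s + a.duration_s:
            raise ValueError(
                f"overlapping events at onsets {a.onset_s} and {b.onset_s}"
            )

    tail = schedule.transition_s if tail_s is None else tail_s
    if events:
        duration = events[-1].onset_s + events[-1].duration_s + tail
    else:
        duration = max(tail, 10.0)
    n = int(round(duration * fs))

    rng = np.random.default_rng(seed)
    data = np.empty((device.n_channels, n))
    for ci in range(device.n_channels):
        data[ci] = one_over_f_noise(n, fs, noise.background_uv, noise.exponent, rng)

    for ev in events:
        alpha_p, beta_p = _solve_band_powers(truth[ev.emotion], alpha_f_sum_uv2)
        i0 = int(round(ev.onset_s * fs))
        i1 = min(int(round((ev.onset_s + ev.duration_s) * fs)), n)
        span = i1 - i0
        for ch in FRONTAL_CHANNELS:
            ci = device.channel_index(ch)
            data[ci, i0:i1] += _oscillator(
                span, fs, ALPHA_CENTER_HZ, alpha_p[ch], noise.phase_drift_rad, rng
            )
            data[ci, i0:i1] += _oscillator(
                span, fs, BETA_CENTER_HZ, beta_p[ch], noise.phase_drift_rad, rng
            )

    return EEGRecording(
        participant_id=schedule.participant_id,
        group=schedule.group,
        session_index=schedule.session_index,
        data=data,
        device=device,
    )


#: absolute amplitude above which the default artifact rejector fires (uV)
DEFAULT_ABS_THRESHOLD_UV = 100.0


def inject_artifacts(
    rec: EEGRecording,
    rate_per_min: float,
    amplitude_uv: float = 300.0,
    seed: int = 0,
    min_width_s: float = 0.25,
    max_width_s: float = 1.0,
) -> EEGRecording:
    """Add transient high-amplitude excursions at Poisson-distributed times.

    Each artifact is a half-cosine bump of 0.25-1 s added to every channel,
    emulating gross movement/electrode pops.  The injected intervals are
    recorded on the returned copy (``artifact_intervals``) so tests can
    compare them with automatically rejected windows.
    """
    if rate_per_min < 0:
        raise ValueError("artifact rate must be >= 0")
    if amplitude_uv < DEFAULT_ABS_THRESHOLD_UV:
        logger.warning(
            "artifact amplitude %.1f uV is below the default rejection "
            "threshold (%.0f uV); artifacts may go undetected",
            amplitude_uv, DEFAULT_ABS_THRESHOLD_UV,
        )
    out = replace(rec, data=rec.data.copy(), artifact_intervals=list(rec.artifact_intervals))
    if rate_per_min == 0:
        return out

    rng = np.random.default_rng(seed)
    fs = rec.device.sampling_rate_hz
    duration_min = rec.duration_s / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    for _ in range(n_events):
        width = rng.uniform(min_width_s, max_width_s)
        start = rng.uniform(0, max(rec.duration_s - width, 0))
        i0 = int(round(start * fs))
        i1 = min(int(round((start + width) * fs)), rec.n_samples)
        if i1 <= i0:
            continue
        bump = amplitude_uv * np.sin(np.linspace(0, np.pi, i1 - i0))
        out.data[:, i0:i1] += bump[None, :]
        out.artifact_intervals.append(
            (rec.start_time_s + start, rec.start_time_s + start + width)
        )
    return out
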