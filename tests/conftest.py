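import numpy as np
import pytest

from eegaffect.protocol import StimulusEvent, StimulusSchedule
from eegaffect.synth import (
    AffectGroundTruth,
    DeviceProfile,
    EmotionTarget,
    NoiseSpec,
    generate_recording,
)


@pytest.fixture(scope="session")
def device():
    return DeviceProfile()


@pytest.fixture(scope="session")
def truth():
    return AffectGroundTruth.default()


def make_single_event_schedule(
    emotion="happy", onset=5.0, duration=10.0, transition=5.0, pid="EG01"
):
    return StimulusSchedule(
        participant_id=pid,
        group="EG",
        session_index=1,
        events=[StimulusEvent(
            onset_s=onset, duration_s=duration, emotion=emotion,
            condition="NM1", face_sex="male", stimulus_id=f"{pid}-x",
        )],
        transition_s=transition,
    )


@pytest.fixture(scope="session")
def single_happy_schedule():
    return make_single_event_schedule("happy")


@pytest.fixture(scope="session")
def noiseless_happy_recording(single_happy_schedule, truth, device):
    """One 10 s happy event, zero background: planted arousal 2.0, valence +1."""
    return generate_recording(
        single_happy_schedule, truth, device,
        noise=NoiseSpec(background_uv=0.0), seed=7,
    )


def constant_truth(arousal=2.0, valence=1.0):
    return AffectGroundTruth({
        emo: EmotionTarget(arousal, valence)
        for emo in ("happy", "sad", "angry", "fear")
    })


def sine_recording(freq_hz, amp_uv=1.0, duration_s=20.0, device=None, n_channels=None):
    """All channels carry the same pure sinusoid; helper for filter tests."""
    device = device or DeviceProfile()
    fs = device.sampling_rate_hz
    t = np.arange(int(duration_s * fs)) / fs
    x = amp_uv * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(x, (device.n_channels, 1))
    from eegaffect.synth import EEGRecording

    return EEGRecording(
        participant_id="SINE", group="EG", session_index=1,
        data=data, device=device,
    )
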