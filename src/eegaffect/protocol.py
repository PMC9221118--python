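"""Study protocol: groups, sessions, stimulus schedules, verbal responses.

The design models a four-week intervention with a fifth assessment visit:
each weekly session presents three blocks ("conditions") of 12 emotional
face stimuli (3 per emotion, 6 male + 6 female faces, randomized order,
10 s each with 5 s transitions).  The experimental group's middle block
pairs each face with emotion-congruent music (condition ``M``); the control
group sees faces only (``NM1``/``NM2``/``NM3``).  A post-study visit
(session index ``n_sessions + 1``) repeats a single no-music block, which is
what the across-session accuracy comparison uses.

Verbal responses ("how is this person feeling?") are simulated with a
configurable session-over-session accuracy gain in the experimental group
only, so the statistics stage can be exercised under both the null and an
effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import EMOTIONS

GROUPS = ("EG", "CG")
EG_CONDITIONS = ("NM1", "M", "NM3")
CG_CONDITIONS = ("NM1", "NM2", "NM3")
FACE_SEXES = ("male", "female")

RESPONSE_COLUMNS = [
    "participant_id", "group", "session_index", "condition",
    "stimulus_id", "true_emotion", "responded_emotion", "correct",
]


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float
    duration_s: float
    emotion: str
    condition: str
    face_sex: str
    stimulus_id: str

    @property
    def with_music(self) -> bool:
        return self.condition == "M"

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        if self.face_sex not in FACE_SEXES:
            raise ValueError(f"unknown face sex {self.face_sex!r}")


@dataclass
class StimulusSchedule:
    participant_id: str
    group: str
    session_index: int
    events: list[StimulusEvent]
    transition_s: float = 5.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for ev in self.events:
            if ev.condition not in seen:
                seen.append(ev.condition)
        return seen

    def validate(self) -> None:
        """Raise if ordering, spacing, balance or uniqueness is violated."""
        evs = self.events
        for a, b in zip(evs, evs[1:]):
            if b.onset_s < a.onset_s:
                raise ValueError("events not sorted by onset")
            if b.onset_s - (a.onset_s + a.duration_s) < self.transition_s - 1e-9:
                raise ValueError("events closer than the transition length")
        ids = [ev.stimulus_id for ev in evs]
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus_id repeated within a schedule")
        for cond in self.conditions:
            cond_evs = [ev for ev in evs if ev.condition == cond]
            if len(cond_evs) != 12:
                raise ValueError(f"condition {cond} has {len(cond_evs)} events, expected 12")
            for emo in EMOTIONS:
                k = sum(ev.emotion == emo for ev in cond_evs)
                if k != 3:
                    raise ValueError(f"condition {cond}: {k} {emo} events, expected 3")
            males = sum(ev.face_sex == "male" for ev in cond_evs)
            if males != 6:
                raise ValueError(f"condition {cond}: {males} male faces, expected 6")


@dataclass(frozen=True)
class DesignConfig:
    """Counts and timing of the study design."""

    n_sessions: int = 4
    post_assessment: bool = True
    stimuli_per_condition: int = 12
    per_emotion: int = 3
    stimulus_duration_s: float = 10.0
    transition_s: float = 5.0
    n_eg: int = 14
    n_cg: int = 11
    #: number of participants per group with EEG acquisition
    eeg_per_group: int = 6

    @property
    def post_session_index(self) -> int:
        return self.n_sessions + 1

    def conditions_for(self, group: str, session_index: int) -> tuple[str, ...]:
        if self.post_assessment and session_index == self.post_session_index:
            return ("NM1",)
        return EG_CONDITIONS if group == "EG" else CG_CONDITIONS


@dataclass(frozen=True)
class ResponseEffectSpec:
    """Response model: P(correct) = clamp(p0 + delta * (session - 1)) for the
    experimental group, p0 for controls; errors uniform over the other three
    emotions."""

    p0: float = 0.5
    delta_per_session: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"baseline accuracy p0 must lie in [0, 1], got {self.p0}")

    def p_correct(self, group: str, session_index: int) -> float:
        if group == "EG":
            return float(np.clip(self.p0 + self.delta_per_session * (session_index - 1), 0, 1))
        return self.p0


def build_schedule(
    participant_id: str,
    group: str,
    session_index: int,
    design: DesignConfig | None = None,
    seed: int = 0,
) -> StimulusSchedule:
    """Build one participant-session schedule satisfying the design balance.

    Emotion counts (3 each) and face-sex counts (6 + 6) per condition are
    exact; presentation order and emotion-to-sex pairing are randomized by
    ``seed`` only.  Stimulus identifiers embed participant, session and
    condition, so no identifier repeats anywhere in a participant's study.
    """
    design = DesignConfig() if design is None else design
    if design.stimuli_per_condition != design.per_emotion * len(EMOTIONS):
        raise ValueError(
            f"{design.stimuli_per_condition} stimuli/condition cannot hold "
            f"{design.per_emotion} of each of {len(EMOTIONS)} emotions"
        )
    if design.stimuli_per_condition % 2 != 0:
        raise ValueError("stimuli_per_condition must split evenly into two face sexes")

    rng = np.random.default_rng(seed)
    events: list[StimulusEvent] = []
    t = 0.0
    for cond in design.conditions_for(group, session_index):
        emotions = np.repeat(EMOTIONS, design.per_emotion)
        emotions = rng.permutation(emotions)
        half = design.stimuli_per_condition // 2
        sexes = rng.permutation(np.array(["male"] * half + ["female"] * half))
        for i, (emo, sex) in enumerate(zip(emotions, sexes)):
            onset = t + design.transition_s
            events.append(StimulusEvent(
                onset_s=onset,
                duration_s=design.stimulus_duration_s,
                emotion=str(emo),
                condition=cond,
                face_sex=str(sex),
                stimulus_id=f"{participant_id}-s{session_index}-{cond}-{i:02d}",
            ))
            t = onset + design.stimulus_duration_s
    sched = StimulusSchedule(
        participant_id=participant_id,
        group=group,
        session_index=session_index,
        events=events,
        transition_s=design.transition_s,
    )
    sched.validate()
    return sched


def participant_ids(design: DesignConfig | None = None) -> list[tuple[str, str]]:
    """(participant_id, group) pairs for the default cohort."""
    design = DesignConfig() if design is None else design
    ids = [(f"EG{i + 1:02d}", "EG") for i in range(design.n_eg)]
    ids += [(f"CG{i + 1:02d}", "CG") for i in range(design.n_cg)]
    return ids


def build_study(design: DesignConfig | None = None, seed: int = 0) -> list[StimulusSchedule]:
    """Schedules for every participant and session (including the post visit)."""
    design = DesignConfig() if design is None else design
    sessions = list(range(1, design.n_sessions + 1))
    if design.post_assessment:
        sessions.append(design.post_session_index)
    ss = np.random.SeedSequence(seed)
    schedules = []
    pairs = participant_ids(design)
    child_seeds = ss.spawn(len(pairs) * len(sessions))
    k = 0
    for pid, group in pairs:
        for s in sessions:
            sub_seed = int(child_seeds[k].generate_state(1)[0] % (2**31))
            schedules.append(build_schedule(pid, group, s, design, seed=sub_seed))
            k += 1
    return schedules


def simulate_verbal_responses(
    schedules: list[StimulusSchedule],
    effect: ResponseEffectSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one verbal response per stimulus under the group response model.

    Returns a table with one row per stimulus: participant, group, session,
    condition, stimulus id, true and responded emotion, and a correctness
    flag.  Each response is independent given the schedule.
    """
    effect = ResponseEffectSpec() if effect is None else effect
    rows = []
    for sched in schedules:
        p = effect.p_correct(sched.group, sched.session_index)
        for ev in sched.events:
            rows.append((
                sched.participant_id, sched.group, sched.session_index,
                ev.condition, ev.stimulus_id, ev.emotion, p,
            ))
    frame = pd.DataFrame(rows, columns=[
        "participant_id", "group", "session_index", "condition",
        "stimulus_id", "true_emotion", "p_correct",
    ])
    rng = np.random.default_rng(seed)
    n = len(frame)
    correct = rng.random(n) < frame["p_correct"].to_numpy()
    # wrong answers: uniform over the three remaining emotions
    responded = frame["true_emotion"].to_numpy().copy()
    wrong_idx = np.flatnonzero(~correct)
    if wrong_idx.size:
        emo_sorted = np.sort(np.array(EMOTIONS))
        true_pos = np.searchsorted(emo_sorted, responded[wrong_idx])
        # cyclic offset 1..3 from the true emotion => uniform over the rest
        offsets = rng.integers(1, len(EMOTIONS), size=wrong_idx.size)
        responded[wrong_idx] = emo_sorted[(true_pos + offsets) % len(EMOTIONS)]
    out = frame.drop(columns=["p_correct"]).copy()
    out["responded_emotion"] = responded
    out["correct"] = out["responded_emotion"] == out["true_emotion"]
    return out[RESPONSE_COLUMNS]
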