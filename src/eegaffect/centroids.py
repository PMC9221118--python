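"""Per-emotion arousal-valence centroids and Thayer-plane agreement.

For one condition and session, the centroid of an emotion is the mean
(valence, arousal) over every feature window of that emotion pooled across
participants.  The four centroids are then jointly rescaled by their
maximum absolute coordinate into the unit square, which preserves both the
geometry and the rank order on each axis.  Agreement scoring checks each
centroid's quadrant sign pattern against an expected plane layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import EMOTIONS

#: session tags used for the first-vs-last comparison
SESSION_TAGS = {"session1": 1, "post_session4": 5}

#: expected Thayer-plane sign layout (valence sign, arousal sign) under the
#: default planted ground truth after per-session z-scoring
DEFAULT_LAYOUT: dict[str, tuple[int, int]] = {
    "happy": (+1, +1),
    "sad": (-1, -1),
    "angry": (-1, +1),
    "fear": (-1, +1),
}

EmotionLayout = dict[str, tuple[int, int]]


@dataclass
class CentroidSet:
    """Normalized per-emotion (valence, arousal) centroids for one cell."""

    coordinates: dict[str, tuple[float, float]]  # emotion -> (valence, arousal)
    n_windows: dict[str, int]
    condition: str
    session_tag: str

    def __post_init__(self) -> None:
        if set(self.coordinates) != set(EMOTIONS):
            raise ValueError("centroid set must cover exactly the four emotions")
        for emo, (v, a) in self.coordinates.items():
            if not (-1.0 - 1e-9 <= v <= 1.0 + 1e-9 and -1.0 - 1e-9 <= a <= 1.0 + 1e-9):
                raise ValueError(f"normalized centroid for {emo} outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (emo, v, a, self.n_windows[emo])
            for emo, (v, a) in self.coordinates.items()
        ]
        return pd.DataFrame(
            rows, columns=["emotion", "valence_norm", "arousal_norm", "n_windows"]
        )


@dataclass
class AgreementReport:
    """Quadrant match of a centroid set against an expected layout."""

    matches: dict[str, bool | None]  # None = indeterminate (on an axis)

    @property
    def n_matched(self) -> int:
        return sum(1 for m in self.matches.values() if m is True)

    @property
    def n_indeterminate(self) -> int:
        return sum(1 for m in self.matches.values() if m is None)


def compute_centroids(
    features: pd.DataFrame,
    condition: str = "NM1",
    session_tag: str = "session1",
    group: str | None = "EG",
) -> CentroidSet:
    """Pool feature windows across participants and average per emotion.

    ``features`` should be z-scored; ``session_tag`` selects the session
    index via :data:`SESSION_TAGS` (or pass an integer).  ``group=None``
    pools both groups.
    """
    if isinstance(session_tag, str):
        if session_tag not in SESSION_TAGS:
            raise ValueError(f"unknown session tag {session_tag!r}")
        session_index = SESSION_TAGS[session_tag]
        tag = session_tag
    else:
        session_index = int(session_tag)
        tag = f"session{session_index}"

    sel = (features["condition"] == condition) & (
        features["session_index"] == session_index
    )
    if group is not None:
        sel &= features["group"] == group
    sub = features.loc[sel]
    if sub.empty:
        raise ValueError(
            f"no feature rows for condition {condition!r}, session {session_index}"
        )

    raw: dict[str, tuple[float, float]] = {}
    counts: dict[str, int] = {}
    for emo in EMOTIONS:
        rows = sub.loc[sub["emotion"] == emo]
        if rows.empty:
            raise ValueError(f"emotion {emo!r} has zero feature windows")
        raw[emo] = (float(rows["valence"].mean()), float(rows["arousal"].mean()))
        counts[emo] = len(rows)

    scale = max(abs(c) for vs in raw.values() for c in vs)
    if scale == 0:
        coords = {emo: (0.0, 0.0) for emo in EMOTIONS}
    else:
        coords = {emo: (v / scale, a / scale) for emo, (v, a) in raw.items()}
    return CentroidSet(
        coordinates=coords, n_windows=counts, condition=condition, session_tag=tag
    )


def quadrant_agreement(
    c: CentroidSet, expected: EmotionLayout | None = None
) -> AgreementReport:
    """Score each centroid's quadrant against the expected sign layout.

    A centroid lying exactly on an axis is flagged indeterminate and counted
    as neither match nor mismatch.
    """
    expected = DEFAULT_LAYOUT if expected is None else expected
    matches: dict[str, bool | None] = {}
    for emo, (v, a) in c.coordinates.items():
        ev, ea = expected[emo]
        if v == 0.0 or a == 0.0:
            matches[emo] = None
        else:
            matches[emo] = bool(
                np.sign(v) == np.sign(ev) and np.sign(a) == np.sign(ea)
            )
    return AgreementReport(matches=matches)


def plot_centroids(centroid_sets: list[CentroidSet], path: str) -> None:
    """Scatter the centroid sets on the valence (x) / arousal (y) plane."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(centroid_sets), figsize=(5 * len(centroid_sets), 5))
    if len(centroid_sets) == 1:
        axes = [axes]
    for ax, cs in zip(axes, centroid_sets):
        for emo, (v, a) in cs.coordinates.items():
            ax.scatter([v], [a], label=emo)
            ax.annotate(emo, (v, a))
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlim(-1.1, 1.1)
        ax.set_ylim(-1.1, 1.1)
        ax.set_xlabel("valence (normalized)")
        ax.set_ylabel("arousal (normalized)")
        ax.set_title(f"{cs.condition} {cs.session_tag}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
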