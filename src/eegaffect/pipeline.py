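"""End-to-end orchestration: simulate -> preprocess -> features -> decode
-> centroids -> stats.

EEG is simulated (and analyzed) for the configured per-group participant
subset, for the first session and the post-study visit — the two cells the
decoding and centroid comparisons use.  Verbal responses are simulated for
the whole cohort across all sessions.  Everything is deterministic given
``config.seed``; every serialized result embeds the config hash and seed.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .centroids import (
    DEFAULT_LAYOUT, CentroidSet, compute_centroids, quadrant_agreement,
)
from .config import PipelineConfig
from .decoding import CVResult, train_eval_ann, train_eval_linear_svm
from .features import compute_affect, epoch_affect, normalize_affect
from .preprocessing import band_power, reject_artifact_windows
from .protocol import build_schedule, participant_ids, simulate_verbal_responses
from .stats import TestReport, accuracy_table, across_session_test, within_session_test
from .synth import generate_recording

logger = logging.getLogger(__name__)


@dataclass
class ResultBundle:
    """In-memory results of a pipeline run (also serialized to out_dir)."""

    config: PipelineConfig
    features: pd.DataFrame
    cv_results: dict[tuple[str, int, str], CVResult]
    centroid_sets: dict[str, CentroidSet]
    agreement: dict[str, int]
    response_stats: dict[str, TestReport | dict[str, TestReport]]
    accuracy: pd.DataFrame
    failures: list[str] = field(default_factory=list)


def _eeg_participants(config: PipelineConfig) -> list[tuple[str, str]]:
    per_group = config.design.eeg_per_group
    pairs = participant_ids(config.design)
    eg = [p for p in pairs if p[1] == "EG"][:per_group]
    cg = [p for p in pairs if p[1] == "CG"][:per_group]
    return eg + cg


def extract_session_features(
    config: PipelineConfig,
    participant_id: str,
    group: str,
    session_index: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate and process one participant-session: recording ->
    band powers -> artifact mask -> affect -> epochs (raw scale)."""
    schedule = build_schedule(
        participant_id, group, session_index, config.design, seed=seed
    )
    rec = generate_recording(
        schedule, config.truth, config.device, config.noise, seed=seed
    )
    w = config.windows
    alpha = band_power(rec, "alpha", w.window_s, w.hop_s, config.filters.order,
                       edge_s=w.edge_s)
    beta = band_power(rec, "beta", w.window_s, w.hop_s, config.filters.order,
                      edge_s=w.edge_s)
    mask = reject_artifact_windows(
        rec, [alpha, beta], config.artifacts.abs_uv, config.artifacts.z_thresh
    )
    affect = compute_affect(
        alpha, beta, mask,
        participant_id=participant_id, group=group, session_index=session_index,
    )
    return epoch_affect(affect, schedule)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> ResultBundle:
    """Run the full analysis; write artifacts under ``out_dir``.

    Stages: verbal-response simulation and statistics for the whole cohort;
    EEG simulation, affect features, per-participant decoding (network and
    linear SVM) and pooled centroids for the EEG subset.  A participant
    whose EEG stage fails is logged and skipped.
    """
    out = Path(config.out_dir if out_dir is None else out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    config.to_yaml(out / "config.yaml")

    stage_base = [
        int(x % (2**31))
        for x in np.random.SeedSequence(config.seed).generate_state(4)
    ]

    def sub_seed(stage: int, *keys) -> int:
        # process-independent: crc32 of the key string, mixed with the stage base
        h = zlib.crc32("|".join(map(str, keys)).encode())
        return int((stage_base[stage] * 1000003 + h) % (2**31))

    # ---- verbal responses and statistics (whole cohort, all sessions)
    design = config.design
    sessions = list(range(1, design.n_sessions + 1))
    if design.post_assessment:
        sessions.append(design.post_session_index)
    schedules = []
    for pid, group in participant_ids(design):
        for s in sessions:
            schedules.append(build_schedule(
                pid, group, s, design, seed=sub_seed(0, pid, s)
            ))
    responses = simulate_verbal_responses(
        schedules, config.response_effect,
        seed=sub_seed(1, 'responses'),
    )
    eio.write_responses_tsv(responses, out / "responses.tsv")
    acc = accuracy_table(responses)

    within = {
        grp: within_session_test(acc, group=grp) for grp in ("EG", "CG")
    }
    across = across_session_test(
        acc, first=(1, "NM1"), last=(design.post_session_index, "NM1")
    )
    stats_payload = {
        **meta,
        "within_session": {g: r.to_dict() for g, r in within.items()},
        "across_session": {g: r.to_dict() for g, r in across.items()},
    }
    eio.write_json(stats_payload, out / "response_stats.json")

    # ---- EEG subset: features for session 1 and the post visit
    eeg_sessions = [1, design.post_session_index]
    frames: list[pd.DataFrame] = []
    failures: list[str] = []
    for pid, group in _eeg_participants(config):
        for s in eeg_sessions:
            t0 = time.perf_counter()
            try:
                f = extract_session_features(
                    config, pid, group, s, seed=sub_seed(2, pid, s)
                )
                frames.append(f)
                logger.info(
                    "features %s s%d: %d windows (%.2f s)",
                    pid, s, len(f), time.perf_counter() - t0,
                )
            except Exception as exc:  # participant-level fault isolation
                failures.append(f"{pid} session {s}: {exc}")
                logger.error("skipping %s session %d: %s", pid, s, exc)
    if not frames:
        raise RuntimeError("no participant produced features: " + "; ".join(failures))
    features_raw = pd.concat(frames, ignore_index=True)
    features = normalize_affect(features_raw, config.normalization_scope)
    eio.write_features_tsv(features, out / "features.tsv")

    # ---- per-participant decoding on NM1, both session tags
    cv_results: dict[tuple[str, int, str], CVResult] = {}
    cls = config.classifier
    decode_dir = out / "decoding"
    decode_dir.mkdir(exist_ok=True)
    for (pid, s), sub in features.groupby(["participant_id", "session_index"]):
        nm1 = sub.loc[sub["condition"] == "NM1"]
        seed = sub_seed(3, pid, s)
        for tag, fn in (("ann", train_eval_ann), ("linear_svm", train_eval_linear_svm)):
            try:
                res = fn(nm1, folds=cls.folds, repeats=cls.repeats, seed=seed)
            except ValueError as exc:
                failures.append(f"{pid} session {s} {tag}: {exc}")
                continue
            cv_results[(pid, int(s), tag)] = res
            eio.write_json(
                {**meta, **res.to_dict()},
                decode_dir / f"{pid}_s{s}_{tag}.json",
            )

    # ---- pooled EG centroids for both session tags
    centroid_sets: dict[str, CentroidSet] = {}
    agreement: dict[str, int] = {}
    for tag, s in (("session1", 1), ("post_session4", design.post_session_index)):
        try:
            cs = compute_centroids(features, "NM1", s, group="EG")
        except ValueError as exc:
            failures.append(f"centroids {tag}: {exc}")
            continue
        cs = CentroidSet(cs.coordinates, cs.n_windows, cs.condition, tag)
        centroid_sets[tag] = cs
        agreement[tag] = quadrant_agreement(cs, DEFAULT_LAYOUT).n_matched
        frame = cs.to_frame()
        frame.to_csv(out / f"centroids_{tag}.tsv", sep="\t", index=False)

    summary = {
        **meta,
        "n_feature_windows": len(features),
        "mean_ann_accuracy": float(np.mean([
            r.mean_accuracy for k, r in cv_results.items() if k[2] == "ann"
        ])) if cv_results else float("nan"),
        "quadrant_agreement": agreement,
        "failures": failures,
    }
    eio.write_json(summary, out / "summary.json")

    return ResultBundle(
        config=config,
        features=features,
        cv_results=cv_results,
        centroid_sets=centroid_sets,
        agreement=agreement,
        response_stats={"within_session": within, "across_session": across},
        accuracy=acc,
        failures=failures,
    )
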