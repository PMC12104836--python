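"""Seizure-annotated exam timelines."""

from __future__ import annotations

import numpy as np

from normkit.synth.config import CohortConfig
from normkit.temporal import ExamTimeline, SeizureEvent

EXAM_START = "2024-01-01T08:00:00"


def generate_timeline(config: CohortConfig, subject_index: int) -> ExamTimeline:
    """Alternating wake/sleep intervals plus a Poisson seizure process.

    Wake blocks last 12-16 h, sleep (N2) blocks 6-9 h; seizure count is
    Poisson at ``seizure_rate`` events/day, onsets uniform over the exam,
    types drawn from ``seizure_type_mix`` and durations uniform in
    [30, 120) s.  Deterministic in (config.seed, subject_index).
    """
    rng = np.random.default_rng([config.seed, subject_index, 7])
    duration_s = config.exam_duration * 3600.0
    states: list[tuple[float, float, str]] = []
    t, wake = 0.0, True
    while t < duration_s:
        block = rng.uniform(12, 16) * 3600.0 if wake else rng.uniform(6, 9) * 3600.0
        end = min(t + block, duration_s)
        states.append((t, end, "W" if wake else "N2"))
        t, wake = end, not wake

    days = duration_s / 86400.0
    n_events = rng.poisson(config.seizure_rate * days) if config.seizure_rate > 0 else 0
    seizures = []
    if n_events:
        onsets = np.sort(rng.uniform(0, duration_s, size=n_events))
        types = list(config.seizure_type_mix)
        probs = np.array([config.seizure_type_mix[k] for k in types], dtype=float)
        kinds = rng.choice(types, size=n_events, p=probs)
        durations = rng.uniform(30, 120, size=n_events)
        seizures = [
            SeizureEvent(onset=float(o), duration=float(d), type=str(k))
            for o, d, k in zip(onsets, durations, kinds)
        ]
    return ExamTimeline(
        state_intervals=states,
        seizures=seizures,
        implant_time=0.0,
        fs_intervals=[(0.0, duration_s, config.sampling_rate)],
        exam_start=EXAM_START,
    )
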