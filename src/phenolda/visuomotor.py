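"""Scoring of eye-hand coordination tasks.

Seven tasks are supported: pro/anti/memory saccade, pro/anti/memory tapping
and trajectory prediction.  Gaze streams are sampled at a fixed rate
(typically 120 Hz); a saccade is any run of consecutive samples whose angular
speed exceeds a velocity threshold (default 50 deg/s).  Each trial yields a
correctness flag plus eye latency, hand latency and hand execution time where
defined; task summaries report percentage of correct trials and latency
means, and individual values are expressed as signed deviations from an
age-matched control cohort in SD units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TASKS = (
    "pro_saccade",
    "anti_saccade",
    "memory_saccade",
    "pro_tapping",
    "anti_tapping",
    "memory_tapping",
    "trajectory_prediction",
)
TAPPING_TASKS = frozenset({"pro_tapping", "anti_tapping", "memory_tapping"})
MEMORY_TASKS = frozenset({"memory_saccade", "memory_tapping"})
ANTI_TASKS = frozenset({"anti_saccade", "anti_tapping"})
ANTI_ECCENTRICITIES = frozenset({5.0, 10.0, 15.0, 20.0})

SACCADE_SPEED_THRESHOLD = 50.0  # deg/s; strictly-greater comparison


@dataclass
class VisuomotorTrial:
    """One trial of an eye(-hand) task.

    ``gaze`` is an (n, 3) array of (t_ms, x_deg, y_deg).  ``stimulus_pos``
    is the signed horizontal stimulus position in degrees (paired with a
    vertical component of 0 for the horizontal tasks).  Memory tasks carry
    ``central_dot_offset_ms``, the go signal.  Tapping tasks carry hand
    events: ``key_release_ms`` and ``touch`` = (t_ms, x_deg, y_deg).
    Trajectory trials carry basket indices (1..6) and the decisive-saccade
    time.
    """

    task: str
    stimulus_onset_ms: float
    stimulus_pos: tuple[float, float]
    gaze: np.ndarray
    central_dot_offset_ms: float | None = None
    key_release_ms: float | None = None
    touch: tuple[float, float, float] | None = None
    true_basket: int | None = None
    touched_basket: int | None = None
    decisive_saccade_ms: float | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        self.gaze = np.asarray(self.gaze, dtype=float)
        if self.gaze.ndim != 2 or self.gaze.shape[1] != 3:
            raise ValueError("gaze must be an (n, 3) array of (t, x, y)")
        if len(self.gaze) > 1 and not np.all(np.diff(self.gaze[:, 0]) > 0):
            raise ValueError("gaze timestamps must be strictly increasing")
        if self.task in ANTI_TASKS and abs(self.stimulus_pos[0]) not in ANTI_ECCENTRICITIES:
            raise ValueError(
                "anti-task stimuli lie at +/-5, 10, 15 or 20 deg horizontally"
            )
        if self.task in MEMORY_TASKS and self.central_dot_offset_ms is None:
            raise ValueError("memory trials need a central-dot offset time")
        for basket in (self.true_basket, self.touched_basket):
            if basket is not None and not 1 <= basket <= 6:
                raise ValueError("basket index must be in 1..6")


@dataclass
class TrialOutcome:
    correct: bool
    eye_latency_ms: float | None
    hand_latency_ms: float | None
    hand_execution_ms: float | None


@dataclass
class TaskSummary:
    performance_pct: float
    mean_eye_latency_ms: float | None
    mean_hand_latency_ms: float | None
    mean_execution_ms: float | None
    n_trials: int


@dataclass
class CohortStats:
    """Control-group mean/SD for one outcome measure."""

    measure: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("control SD must be positive")
        if self.n < 2:
            raise ValueError("control cohort needs n >= 2")


def gaze_speed(gaze: np.ndarray) -> np.ndarray:
    """Angular speed (deg/s) between consecutive gaze samples.

    Speed i is assigned to the segment starting at sample i; the returned
    array has length n-1.
    """
    disp = np.hypot(np.diff(gaze[:, 1]), np.diff(gaze[:, 2]))
    return disp / np.diff(gaze[:, 0]) * 1000.0


def detect_primary_saccade(
    gaze: np.ndarray,
    stimulus_onset_ms: float,
    speed_threshold: float = SACCADE_SPEED_THRESHOLD,
) -> tuple[float | None, int | None, int | None]:
    """First saccade after stimulus onset.

    Returns ``(onset_ms, run_start, run_stop)`` where the run is the first
    maximal block of consecutive inter-sample segments with speed strictly
    above ``speed_threshold``; indices are into the gaze array and the run
    covers samples ``run_start..run_stop`` inclusive.  Returns
    ``(None, None, None)`` when no segment exceeds the threshold.
    """
    gaze = np.asarray(gaze, dtype=float)
    after = gaze[gaze[:, 0] >= stimulus_onset_ms]
    if len(after) < 2:
        raise ValueError("need at least 2 gaze samples after stimulus onset")
    speed = gaze_speed(after)
    above = speed > speed_threshold
    if not above.any():
        return None, None, None
    start = int(np.argmax(above))
    stop = start
    while stop + 1 < len(above) and above[stop + 1]:
        stop += 1
    offset = len(gaze) - len(after)
    return float(after[start, 0]), offset + start, offset + stop + 1


def _landing_position(trial: VisuomotorTrial, run_stop: int) -> tuple[float, float]:
    # position once the eye has settled: the sample after the saccade run,
    # or the run's last sample when the stream ends mid-saccade
    idx = min(run_stop + 1, len(trial.gaze) - 1)
    return float(trial.gaze[idx, 1]), float(trial.gaze[idx, 2])


def score_trial(
    trial: VisuomotorTrial,
    landing_tolerance_deg: float = 2.0,
    memory_latency_reference: str = "offset",
    speed_threshold: float = SACCADE_SPEED_THRESHOLD,
) -> TrialOutcome:
    """Correctness and latencies for one trial.

    Correctness rules: *pro* tasks require the primary saccade (and the
    touch, for tapping) to land within ``landing_tolerance_deg`` of the
    stimulus; *anti* tasks require the horizontal sign of the movement to
    oppose the stimulus sign; *memory* tasks require a movement after the
    central-dot offset landing within tolerance of the remembered location;
    *trajectory* requires the touched basket to match the true basket.

    In memory trials latencies are referenced to the central-dot offset (the
    go signal) by default; pass ``memory_latency_reference="stimulus"`` for
    the peripheral-flash reference.
    """
    if memory_latency_reference not in {"offset", "stimulus"}:
        raise ValueError("memory_latency_reference must be 'offset' or 'stimulus'")
    is_memory = trial.task in MEMORY_TASKS
    search_from = (
        trial.central_dot_offset_ms if is_memory else trial.stimulus_onset_ms
    )
    reference = (
        trial.central_dot_offset_ms
        if (is_memory and memory_latency_reference == "offset")
        else trial.stimulus_onset_ms
    )
    onset, _, run_stop = detect_primary_saccade(
        trial.gaze, search_from, speed_threshold
    )
    eye_latency = None if onset is None else max(onset - reference, 0.0)

    hand_latency = None
    execution = None
    if trial.task in TAPPING_TASKS:
        if trial.key_release_ms is None or trial.touch is None:
            raise ValueError("tapping trials require key-release and touch events")
        hand_latency = max(trial.key_release_ms - reference, 0.0)
        execution = trial.touch[0] - trial.key_release_ms

    if trial.task == "trajectory_prediction":
        if trial.true_basket is None or trial.touched_basket is None:
            raise ValueError("trajectory trials require basket indices")
        correct = trial.touched_basket == trial.true_basket
        if trial.decisive_saccade_ms is not None:
            eye_latency = trial.decisive_saccade_ms - trial.stimulus_onset_ms
        if trial.key_release_ms is not None:
            hand_latency = trial.key_release_ms - trial.stimulus_onset_ms
            if trial.touch is not None:
                execution = trial.touch[0] - trial.key_release_ms
        return TrialOutcome(correct, eye_latency, hand_latency, execution)

    if onset is None:
        return TrialOutcome(False, None, hand_latency, execution)

    land = _landing_position(trial, run_stop)
    sx, sy = trial.stimulus_pos
    if trial.task in ANTI_TASKS:
        correct = land[0] * sx < 0
        if trial.task == "anti_tapping":
            correct = correct and trial.touch[1] * sx < 0
    else:  # pro and memory: land on (remembered) stimulus location
        on_target = np.hypot(land[0] - sx, land[1] - sy) <= landing_tolerance_deg
        correct = bool(on_target)
        if is_memory:
            correct = correct and onset >= trial.central_dot_offset_ms
        if trial.task in TAPPING_TASKS:
            touch_ok = (
                np.hypot(trial.touch[1] - sx, trial.touch[2] - sy)
                <= landing_tolerance_deg
            )
            correct = correct and bool(touch_ok)
    return TrialOutcome(correct, eye_latency, hand_latency, execution)


def summarize_task(outcomes: list[TrialOutcome]) -> TaskSummary:
    """Percentage of correct trials and latency means.

    Latency means are over trials where the latency is defined; performance
    is invariant under trial reordering.
    """
    if not outcomes:
        raise ValueError("cannot summarize an empty trial list")
    perf = 100.0 * sum(o.correct for o in outcomes) / len(outcomes)

    def _mean(values: list[float | None]) -> float | None:
        defined = [v for v in values if v is not None]
        return float(np.mean(defined)) if defined else None

    return TaskSummary(
        performance_pct=perf,
        mean_eye_latency_ms=_mean([o.eye_latency_ms for o in outcomes]),
        mean_hand_latency_ms=_mean([o.hand_latency_ms for o in outcomes]),
        mean_execution_ms=_mean([o.hand_execution_ms for o in outcomes]),
        n_trials=len(outcomes),
    )


def deviation_score(value: float, cohort: CohortStats) -> float:
    """Signed deviation of an individual's value from the control cohort.

    ``(value - mean) / SD``; e.g. a patient latency of 463 ms against a
    391 +/- 16 ms control group scores +4.5 SD.
    """
    if cohort.sd <= 0:
        raise ValueError("control SD must be positive")
    return (value - cohort.mean) / cohort.sd
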