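"""Synthetic inputs for every pipeline stage.

The generators emulate the statistical structure of a two-genotype mouse
behavioral battery (15 subjects per class, ~30 variables across eight
assays) and of human eye-hand coordination sessions, so that every
downstream stage is testable without raw recordings: feature matrices with
injected class effects, correlated variable blocks, skewed variables,
outliers and missing sessions; arena tracking series; grooming event logs;
ladder trial records; Y-maze choice records; and 120-Hz gaze streams with
injected saccades.  Each generator returns the raw records plus a
GroundTruth object holding everything injected, so recovery can be checked
by an independent brute-force path.

Determinism: a single integer seed drives a hierarchical
``numpy.random.SeedSequence`` stream with one child per subject or trial,
so enlarging a cohort never perturbs already-generated subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .arena import ArenaLayout, Bout, GroomingLog, TrackingSeries
from .discriminant import FeatureMatrix
from .ladder_ymaze import (
    AIR_DELAY_S,
    N_RUNGS,
    YMAZE_PROTOCOL,
    LadderTrial,
    YMazeTrial,
)
from .visuomotor import MEMORY_TASKS, TAPPING_TASKS, VisuomotorTrial

GAZE_FS_HZ = 120.0


# ---------------------------------------------------------------------------
# cohort feature matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """One behavioral variable of the cohort design.

    ``effect_d`` is the class-mean difference in within-class SD units
    (Cohen's d convention, class2 minus class1); ``skew`` shapes the
    within-class distribution (0 = Gaussian); multi-session variables are
    emitted as ``name::s<k>`` per-session columns tagged for slope
    reduction.
    """

    name: str
    assay: str = "misc"
    multi_session: bool = False
    n_sessions: int = 1
    effect_d: float = 0.0
    sd: float = 1.0
    skew: float = 0.0
    baseline: float = 0.0
    tag: str | None = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"variable {self.name!r}: SD must be positive")
        if self.multi_session and self.n_sessions < 2:
            raise ValueError("multi-session variables need >= 2 sessions")


@dataclass(frozen=True)
class CohortSpec:
    n_per_class: int
    variable_specs: tuple[VariableSpec, ...]
    correlated_blocks: tuple[tuple[tuple[str, ...], float], ...] = ()
    outlier_rate: float = 0.0
    missing_session_rate: float = 0.0
    seed: int = 0
    class_names: tuple[str, str] = ("class1", "class2")

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        names = [v.name for v in self.variable_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        for block, r in self.correlated_blocks:
            if not -1 < r < 1:
                raise ValueError("target correlations must lie in (-1, 1)")
            for name in block:
                if name not in names:
                    raise ValueError(f"unknown variable {name!r} in block")
        for rate in (self.outlier_rate, self.missing_session_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything a generator injected, indexable for recovery tests."""

    effects: dict[str, float] = field(default_factory=dict)
    outliers: list[tuple[str, str]] = field(default_factory=list)
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    saccade_onsets_ms: dict[int, float] = field(default_factory=dict)
    error_trials: list[int] = field(default_factory=list)
    bout_intervals: list[tuple[float, float]] = field(default_factory=list)
    exit_causes: list[str] = field(default_factory=list)
    step_class_counts: dict[str, int] = field(default_factory=dict)
    correct_flags: list[bool] = field(default_factory=list)


def _skew_transform(z: np.ndarray, s: float) -> np.ndarray:
    """Standardized exponentiated Gaussian: skewed, zero mean, unit SD."""
    if s == 0:
        return z
    y = (np.exp(s * z) - 1.0) / s
    mean = (np.exp(s**2 / 2.0) - 1.0) / s
    sd = np.sqrt((np.exp(s**2) - 1.0) * np.exp(s**2)) / abs(s)
    return (y - mean) / sd


def _block_cholesky(
    single_vars: list[VariableSpec],
    blocks: tuple[tuple[tuple[str, ...], float], ...],
) -> np.ndarray:
    p = len(single_vars)
    idx = {v.name: i for i, v in enumerate(single_vars)}
    corr = np.eye(p)
    for names, r in blocks:
        members = [idx[n] for n in names if n in idx]
        for a in members:
            for b in members:
                if a != b:
                    corr[a, b] = r
    return np.linalg.cholesky(corr)


def gen_feature_matrix(spec: CohortSpec) -> tuple[FeatureMatrix, GroundTruth]:
    """Two-class feature matrix with injected effects and structure.

    Within-class noise is Gaussian (correlated blocks via the Cholesky
    factor of the target correlation matrix; skewed variables via a
    standardized exponentiated Gaussian).  Class 2 means sit ``effect_d``
    within-class SDs above class 1; for skewed variables the shift acts on
    the latent Gaussian scale (a multiplicative effect on the raw scale),
    which preserves the distribution's skewness.  Multi-session variables
    carry the class effect on their across-session slope and are emitted as
    per-session columns.  Outliers displace single-session values by
    +/- 8 SD — jointly across the members of a correlated block, the way a
    tracking glitch propagates to every measure derived from the same
    recording; missing sessions blank individual session cells.
    """
    truth = GroundTruth()
    single = [v for v in spec.variable_specs if not v.multi_session]
    multi = [v for v in spec.variable_specs if v.multi_session]
    L = _block_cholesky(single, spec.correlated_blocks)
    for names, r in spec.correlated_blocks:
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                truth.correlations[(a, b)] = r
    n_total = 2 * spec.n_per_class
    labels = pd.Series(
        [spec.class_names[0]] * spec.n_per_class
        + [spec.class_names[1]] * spec.n_per_class,
        index=[f"s{i + 1:03d}" for i in range(n_total)],
    )
    class_streams = np.random.SeedSequence(spec.seed).spawn(2)
    streams = (
        class_streams[0].spawn(spec.n_per_class)
        + class_streams[1].spawn(spec.n_per_class)
    )
    columns: dict[str, list[float]] = {}
    meta_rows: dict[str, dict] = {}
    for v in single:
        columns[v.name] = []
        meta_rows[v.name] = {
            "assay": v.assay,
            "multi_session": False,
            "group": v.name,
            "session": None,
            "tag": v.tag,
        }
        truth.effects[v.name] = v.effect_d
    for v in multi:
        truth.effects[v.name] = v.effect_d
        for k in range(1, v.n_sessions + 1):
            col = f"{v.name}::s{k}"
            columns[col] = []
            meta_rows[col] = {
                "assay": v.assay,
                "multi_session": True,
                "group": v.name,
                "session": k,
                "tag": v.tag,
            }

    block_of: dict[str, int] = {}
    for b, (names, _) in enumerate(spec.correlated_blocks):
        for name in names:
            block_of[name] = b

    for i, subject in enumerate(labels.index):
        rng = np.random.default_rng(streams[i])
        in_class2 = i >= spec.n_per_class
        z = L @ rng.standard_normal(len(single)) if single else np.empty(0)
        # one outlier event per correlated block: a glitch in the raw
        # recording displaces every measure derived from it coherently
        block_shift: dict[int, float] = {}
        for b in range(len(spec.correlated_blocks)):
            if spec.outlier_rate and rng.random() < spec.outlier_rate:
                block_shift[b] = 1.0 if rng.random() < 0.5 else -1.0
        for j, v in enumerate(single):
            shift_d = v.effect_d if in_class2 else 0.0
            if v.skew != 0:
                noise = _skew_transform(np.array([z[j] + shift_d]), v.skew)[0]
                value = v.baseline + v.sd * noise
            else:
                value = v.baseline + v.sd * (shift_d + z[j])
            outlier_sign = None
            if v.name in block_of:
                outlier_sign = block_shift.get(block_of[v.name])
            elif spec.outlier_rate and rng.random() < spec.outlier_rate:
                outlier_sign = 1.0 if rng.random() < 0.5 else -1.0
            if outlier_sign is not None:
                value += 8.0 * v.sd * outlier_sign
                truth.outliers.append((subject, v.name))
            columns[v.name].append(value)
        for v in multi:
            slope_mean = v.effect_d * v.sd if in_class2 else 0.0
            slope = slope_mean + v.sd * rng.standard_normal()
            intercept = v.baseline + v.sd * rng.standard_normal()
            for k in range(1, v.n_sessions + 1):
                value = intercept + slope * (k - 1) + 0.3 * v.sd * rng.standard_normal()
                if (
                    spec.missing_session_rate
                    and rng.random() < spec.missing_session_rate
                ):
                    value = np.nan
                columns[f"{v.name}::s{k}"].append(value)

    data = pd.DataFrame(columns, index=labels.index)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").reindex(data.columns)
    return FeatureMatrix(data, labels, meta), truth


def default_cohort_spec(
    n_per_class: int = 15,
    seed: int = 0,
    outlier_rate: float = 0.005,
    missing_session_rate: float = 0.01,
) -> CohortSpec:
    """The emulated study design: 36 raw variables across eight assays.

    Speed variables duplicate their distance partners (r = 0.99 — mean
    speed is total distance over a fixed session length, so the two are
    nearly deterministically related and the r >= 0.86 correlation filter
    drops them), one learning variable is
    heavily skewed (exercises the skew screen), learning-type measures are
    5-session variables reduced to slopes, and a handful of moderate class
    effects (|d| ~ 0.7-0.8) mirror the reported motor/learning/grooming
    differences.  After the skew exclusion and the four speed drops, 31
    variables enter the discriminant.
    """
    v = VariableSpec
    specs = (
        # open field
        v("OF distance", "OF", tag="distance"),
        v("OF speed", "OF", tag="speed"),
        v("OF time inner", "OF"),
        v("OF time outer", "OF"),
        v("OF time corners", "OF"),
        # elevated-plus maze
        v("EPM distance", "EPM", tag="distance"),
        v("EPM speed", "EPM", tag="speed"),
        v("EPM time open", "EPM"),
        v("EPM time closed", "EPM"),
        v("EPM entries open", "EPM"),
        v("EPM entries closed", "EPM"),
        # grooming
        v("G total time", "G", effect_d=0.4),
        v("G bout count", "G", effect_d=0.5),
        v("G latency", "G"),
        v("G inter-bout interval", "G", effect_d=-0.7),
        v("G short bout pct", "G", effect_d=0.7),
        # marble burying
        v("MB total area", "MB"),
        v("MB buried count", "MB"),
        # social interaction
        v("SI cup ratio", "SI"),
        v("SI cup chamber ratio", "SI", effect_d=-0.7),
        v("SI centre transitions", "SI", effect_d=-0.6),
        v("SI distance", "SI", tag="distance"),
        v("SI speed", "SI", tag="speed"),
        # rotarod (5-day learning)
        v("R total time", "R", multi_session=True, n_sessions=5),
        # Erasmus ladder (5-day learning)
        v("EL time on ladder", "EL", multi_session=True, n_sessions=5,
          effect_d=-0.8),
        v("EL light air ratio", "EL", multi_session=True, n_sessions=5,
          effect_d=0.8),
        v("EL before cue exits", "EL", multi_session=True, n_sessions=5,
          effect_d=0.5),
        v("EL pct missteps", "EL", multi_session=True, n_sessions=5),
        v("EL pct shortsteps", "EL", multi_session=True, n_sessions=5,
          effect_d=0.7),
        v("EL pct jumps", "EL", multi_session=True, n_sessions=5,
          effect_d=-0.8),
        # water Y-maze
        v("YM distance", "YM", tag="distance"),
        v("YM speed", "YM", tag="speed"),
        v("YM acquisition", "YM"),
        v("YM test", "YM"),
        v("YM reversal I", "YM", effect_d=-0.6),
        v("YM reversal II", "YM", effect_d=-0.4, skew=2.5),
    )
    blocks = tuple(
        ((f"{a} distance", f"{a} speed"), 0.99) for a in ("OF", "EPM", "SI", "YM")
    )
    return CohortSpec(
        n_per_class=n_per_class,
        variable_specs=specs,
        correlated_blocks=blocks,
        outlier_rate=outlier_rate,
        missing_session_rate=missing_session_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# arena tracking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackingProfile:
    """Locomotion profile: speed (cm/s), session length (s), frame rate,
    and a thigmotaxis weight in [0, 1] biasing waypoints into the wall
    band (fraction ``band_frac`` of the smaller arena extent)."""

    mean_speed: float = 8.0
    duration: float = 1800.0
    fps: float = 25.0
    thigmotaxis: float = 0.3
    band_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")
        if self.mean_speed < 0:
            raise ValueError("mean speed must be non-negative")
        if not 0 <= self.thigmotaxis <= 1:
            raise ValueError("thigmotaxis weight must lie in [0, 1]")


def _sample_in(polygon, rng: np.random.Generator, n_max: int = 10_000):
    minx, miny, maxx, maxy = polygon.bounds
    for _ in range(n_max):
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if polygon.covers(p):
            return p
    raise RuntimeError("rejection sampling failed (degenerate polygon?)")


def gen_tracking_series(
    layout: ArenaLayout,
    profile: TrackingProfile,
    seed: int = 0,
    subject: str = "m001",
) -> TrackingSeries:
    """Waypoint random walk inside the arena at constant step length.

    Every inter-frame step has length ``mean_speed / fps``, so the empirical
    mean speed equals the profile value by construction.  With probability
    ``thigmotaxis`` the next waypoint is drawn from the wall band within a
    short hop of the current position (wall-hugging); otherwise uniformly
    from the arena.
    """
    arena = layout.arena
    if arena.area <= 0:
        raise ValueError("degenerate arena")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(profile.duration * profile.fps))
    t = np.arange(n) / profile.fps
    start = arena.centroid
    if profile.mean_speed == 0:
        x = np.full(n, start.x)
        y = np.full(n, start.y)
        return TrackingSeries(subject, profile.fps, t, x, y)

    minx, miny, maxx, maxy = arena.bounds
    band_width = profile.band_frac * min(maxx - minx, maxy - miny)
    band = arena.difference(arena.buffer(-band_width))
    step = profile.mean_speed / profile.fps
    max_hop = max(3 * band_width, 10 * step)
    x = np.empty(n)
    y = np.empty(n)
    pos = np.array([start.x, start.y])
    x[0], y[0] = pos
    waypoint = None
    for i in range(1, n):
        if waypoint is None or np.hypot(*(waypoint - pos)) < step:
            if rng.random() < profile.thigmotaxis and band.area > 0:
                local = band.intersection(Point(*pos).buffer(max_hop, quad_segs=16))
                target_poly = local if local.area > 0 else band
                waypoint = _sample_in(target_poly, rng)
            else:
                waypoint = _sample_in(arena, rng)
            waypoint = np.array([waypoint.x, waypoint.y])
        direction = waypoint - pos
        norm = np.hypot(*direction)
        cand = pos + step * direction / norm
        if not arena.covers(Point(*cand)):
            waypoint = None
            cand = pos  # hold one frame; next frame picks a fresh waypoint
        pos = cand
        x[i], y[i] = pos
    return TrackingSeries(subject, profile.fps, t, x, y)


def add_nose_point(
    series: TrackingSeries, offset_cm: float = 2.5, seed: int = 0
) -> TrackingSeries:
    """Attach a nose point ahead of the body along the heading direction."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dx = np.gradient(series.body_x)
    dy = np.gradient(series.body_y)
    norm = np.hypot(dx, dy)
    norm[norm == 0] = 1.0
    jitter = 0.2 * rng.standard_normal((2, series.n_frames))
    return TrackingSeries(
        series.subject,
        series.fps,
        series.t,
        series.body_x,
        series.body_y,
        series.body_x + offset_cm * dx / norm + jitter[0],
        series.body_y + offset_cm * dy / norm + jitter[1],
    )


# ---------------------------------------------------------------------------
# grooming logs
# ---------------------------------------------------------------------------

def gen_grooming_log(
    bout_rate_per_min: float,
    mixture_weights: tuple[float, float] = (0.15, 0.85),
    short_mean_s: float = 4.0,
    long_mean_s: float = 25.0,
    total_duration_s: float = 1800.0,
    seed: int = 0,
    subject: str = "m001",
) -> tuple[GroomingLog, GroundTruth]:
    """Poisson-count grooming bouts with a short/long duration mixture.

    The bout count is Poisson(rate x duration); starts are uniform over the
    session and durations are uniform on [0.5, 1.5] x the component mean
    (so a pure-short mixture stays strictly below a 10-s short/long
    threshold at the default mean).  Overlapping bouts are truncated at the
    next bout's start, which preserves the count.
    """
    if bout_rate_per_min < 0:
        raise ValueError("bout rate must be non-negative")
    if short_mean_s <= 0 or long_mean_s <= 0:
        raise ValueError("durations must be positive")
    w_short, w_long = mixture_weights
    if abs(w_short + w_long - 1.0) > 1e-9 or min(w_short, w_long) < 0:
        raise ValueError("mixture weights must be non-negative and sum to 1")
    mean_dur = w_short * short_mean_s + w_long * long_mean_s
    rate_s = bout_rate_per_min / 60.0
    if rate_s * mean_dur >= 0.9:
        raise ValueError("bout rate too high to pack bouts without overlap")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = rng.poisson(rate_s * total_duration_s)
    starts = np.sort(rng.uniform(0.0, total_duration_s, size=n))
    truth = GroundTruth()
    bouts: list[Bout] = []
    for i, start in enumerate(starts):
        mean = short_mean_s if rng.random() < w_short else long_mean_s
        dur = rng.uniform(0.5 * mean, 1.5 * mean)
        stop = min(start + dur, total_duration_s)
        if i + 1 < n:
            stop = min(stop, starts[i + 1] - 1e-3)
        stop = max(stop, start + 1e-3)
        bouts.append(Bout(start, stop, "grooming"))
        truth.bout_intervals.append((start, stop))
    return GroomingLog(subject, bouts, total_duration_s), truth


# ---------------------------------------------------------------------------
# Erasmus ladder sessions
# ---------------------------------------------------------------------------

def gen_ladder_sessions(
    response_model: list[dict[str, float]],
    step_mix: dict[int, float] | None = None,
    n_sessions: int = 5,
    trials_per_session: int = 42,
    seed: int = 0,
    subject: str = "m001",
) -> tuple[list[LadderTrial], GroundTruth]:
    """Ladder trials with multinomial exit causes and mixed step types.

    ``response_model`` gives per-session probabilities for
    {before_cue, light, air} exits; ``step_mix`` gives probabilities of rung
    displacements (default mostly shortsteps).  Each session holds 42
    trials; the light cue follows a 9-11 s waiting period and the air puff
    comes 3 s later.
    """
    if len(response_model) != n_sessions:
        raise ValueError("response_model must have one entry per session")
    for probs in response_model:
        if set(probs) != {"before_cue", "light", "air"}:
            raise ValueError("exit probabilities need keys before_cue/light/air")
        if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < 0:
            raise ValueError("exit probabilities must be non-negative and sum to 1")
    step_mix = step_mix or {-1: 0.05, 1: 0.75, 2: 0.15, 3: 0.05}
    if abs(sum(step_mix.values()) - 1.0) > 1e-9 or min(step_mix.values()) < 0:
        raise ValueError("step mix must be non-negative and sum to 1")
    displacements = np.array(list(step_mix), dtype=int)
    probs_step = np.array([step_mix[d] for d in displacements])
    streams = np.random.SeedSequence(seed).spawn(n_sessions * trials_per_session)
    truth = GroundTruth(step_class_counts={
        "backstep": 0, "stationary": 0, "shortstep": 0, "longstep": 0, "jump": 0,
    })
    causes = ("before_cue", "light", "air")
    trials: list[LadderTrial] = []
    k = 0
    for session in range(1, n_sessions + 1):
        p = np.array([response_model[session - 1][c] for c in causes])
        for trial_idx in range(1, trials_per_session + 1):
            rng = np.random.default_rng(streams[k])
            k += 1
            light = rng.uniform(9.0, 11.0)
            air = light + AIR_DELAY_S
            cause = causes[rng.choice(3, p=p)]
            if cause == "before_cue":
                exit_t = rng.uniform(0.5, light - 1e-6)
            elif cause == "light":
                exit_t = rng.uniform(light, air - 1e-6)
            else:
                exit_t = air + rng.exponential(1.0)
            truth.exit_causes.append(cause)
            steps: list[tuple[int, int]] = []
            rung = 1
            attempts = 0
            while rung < N_RUNGS:
                attempts += 1
                if attempts > 10_000:
                    raise RuntimeError(
                        "step mix cannot reach the far goal box "
                        "(no positive displacement mass?)"
                    )
                d = int(displacements[rng.choice(len(displacements), p=probs_step)])
                to = rung + d
                if to > N_RUNGS:
                    break
                if to < 1:
                    continue
                steps.append((rung, to))
                cls = {-1: "backstep", 0: "stationary", 1: "shortstep",
                       2: "longstep"}.get(d, "jump")
                if d <= -1:
                    cls = "backstep"
                truth.step_class_counts[cls] += 1
                rung = to
            trials.append(
                LadderTrial(
                    subject=subject,
                    session=session,
                    trial=trial_idx,
                    light_onset_s=light,
                    air_onset_s=air,
                    exit_time_s=exit_t,
                    crossing_time_s=rng.uniform(3.0, 8.0),
                    steps=steps,
                )
            )
    return trials, truth


# ---------------------------------------------------------------------------
# water Y-maze choices
# ---------------------------------------------------------------------------

def gen_ymaze_choices(
    p_correct: dict[str, list[float]],
    seed: int = 0,
    subject: str = "m001",
) -> tuple[list[YMazeTrial], GroundTruth]:
    """Bernoulli correct/incorrect choices over the full Y-maze protocol.

    ``p_correct`` maps each phase to its per-session probabilities of a
    correct choice (acquisition: 4 sessions, test: 1, each reversal: 5, all
    5 trials per session).  Session 5 of each reversal phase is the forced
    session (the incorrect arm blocked).
    """
    truth = GroundTruth()
    trials: list[YMazeTrial] = []
    phases = list(YMAZE_PROTOCOL)
    streams = np.random.SeedSequence(seed).spawn(len(phases))
    for phase, stream in zip(phases, streams):
        n_sessions, n_trials = YMAZE_PROTOCOL[phase]
        probs = p_correct[phase]
        if len(probs) != n_sessions:
            raise ValueError(f"{phase} needs {n_sessions} session probabilities")
        if any(not 0 <= q <= 1 for q in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        rng = np.random.default_rng(stream)
        for session in range(1, n_sessions + 1):
            for trial in range(1, n_trials + 1):
                correct = bool(rng.random() < probs[session - 1])
                forced = phase in {"reversal1", "reversal2"} and session == 5
                trials.append(
                    YMazeTrial(subject, phase, session, trial, correct, forced)
                )
                truth.correct_flags.append(correct)
    return trials, truth


# ---------------------------------------------------------------------------
# visuomotor sessions
# ---------------------------------------------------------------------------

def gen_visuomotor_session(
    task: str,
    n_trials: int = 16,
    eye_latency_ms: tuple[float, float] = (350.0, 40.0),
    hand_latency_ms: tuple[float, float] = (480.0, 50.0),
    execution_ms: tuple[float, float] = (350.0, 60.0),
    error_rate: float = 0.0,
    amplitude_deg: float = 10.0,
    saccade_samples: int = 5,
    fs_hz: float = GAZE_FS_HZ,
    seed: int = 0,
) -> tuple[list[VisuomotorTrial], GroundTruth]:
    """Gaze (and hand) streams with exactly one injected primary saccade.

    Each trial samples gaze at ``fs_hz`` over 1.5 s with a stimulus at
    200 ms (memory tasks: a 50-ms flash, central dot offset at 500 ms).
    The saccade is a linear ramp over ``saccade_samples`` samples whose
    per-sample speed must exceed the 50 deg/s detection threshold (the
    generator refuses kinematics that would be undetectable by design).
    Fixation noise is kept far below threshold, so streams contain no
    spurious saccades.  Injected onset times (the last pre-movement sample)
    land in GroundTruth; error trials move the wrong way (anti: toward the
    stimulus; pro/memory: 4 deg off target; trajectory: wrong basket).
    """
    peak_speed = (amplitude_deg / saccade_samples) * fs_hz
    if peak_speed <= 50.0:
        raise ValueError(
            "saccade kinematics undetectable: per-sample speed "
            f"{peak_speed:.1f} deg/s is not above the 50 deg/s threshold"
        )
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must lie in [0, 1]")
    dt_ms = 1000.0 / fs_hz
    n_samples = int(round(1500.0 / dt_ms))
    t = np.arange(n_samples) * dt_ms
    stim_idx = int(round(200.0 / dt_ms))
    go_idx = int(round(500.0 / dt_ms))
    stim_onset = t[stim_idx]
    is_memory = task in MEMORY_TASKS
    ref_time = t[go_idx] if is_memory else stim_onset
    truth = GroundTruth()
    trials: list[VisuomotorTrial] = []
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    eccentricities = (5.0, 10.0, 15.0, 20.0)
    for i in range(n_trials):
        rng = np.random.default_rng(streams[i])
        is_error = rng.random() < error_rate
        if is_error:
            truth.error_trials.append(i)
        if task == "trajectory_prediction":
            true_basket = int(rng.integers(1, 7))
            if is_error:
                wrong = [b for b in range(1, 7) if b != true_basket]
                touched = int(rng.choice(wrong))
            else:
                touched = true_basket
            basket_x = (true_basket - 3.5) * 5.0
            stim = (basket_x, 0.0)
        else:
            side = 1.0 if rng.random() < 0.5 else -1.0
            ecc = (
                float(rng.choice(eccentricities))
                if task in {"anti_saccade", "anti_tapping"}
                else float(rng.uniform(5.0, 20.0))
            )
            ecc = ecc if task in {"anti_saccade", "anti_tapping"} else round(ecc, 1)
            stim = (side * ecc, 0.0)
            true_basket = touched = None

        lat = max(float(rng.normal(*eye_latency_ms)), 3 * dt_ms)
        onset_idx = int(round((ref_time + lat) / dt_ms))
        onset_idx = min(onset_idx, n_samples - saccade_samples - 2)
        sx = stim[0]
        if task in {"anti_saccade", "anti_tapping"}:
            target_x = sx if is_error else -sx
        elif task == "trajectory_prediction":
            target_x = (touched - 3.5) * 5.0
        else:  # pro / memory tasks aim at the (remembered) stimulus
            target_x = sx + 4.0 if is_error else sx
        gaze = np.zeros((n_samples, 3))
        gaze[:, 0] = t
        noise = 0.02 * rng.standard_normal((n_samples, 2))
        gaze[:, 1:] = noise
        ramp = np.linspace(0.0, target_x, saccade_samples + 1)
        gaze[onset_idx : onset_idx + saccade_samples + 1, 1] = ramp
        gaze[onset_idx + saccade_samples :, 1] = (
            target_x + noise[onset_idx + saccade_samples :, 0]
        )
        gaze[onset_idx : onset_idx + saccade_samples + 1, 2] = 0.0
        truth.saccade_onsets_ms[i] = float(t[onset_idx])

        key_release = touch = None
        if task in TAPPING_TASKS or task == "trajectory_prediction":
            hand_lat = max(float(rng.normal(*hand_latency_ms)), 50.0)
            exec_t = max(float(rng.normal(*execution_ms)), 50.0)
            key_release = ref_time + hand_lat
            touch = (key_release + exec_t, target_x, 0.0)
        trials.append(
            VisuomotorTrial(
                task=task,
                stimulus_onset_ms=stim_onset,
                stimulus_pos=stim,
                gaze=gaze,
                central_dot_offset_ms=t[go_idx] if is_memory else None,
                key_release_ms=key_release,
                touch=touch,
                true_basket=true_basket,
                touched_basket=touched,
                decisive_saccade_ms=(
                    float(t[onset_idx]) if task == "trajectory_prediction" else None
                ),
            )
        )
    return trials, truth


def drift_gaze_stream(
    drift_speed_deg_s: float = 40.0,
    duration_ms: float = 1500.0,
    fs_hz: float = GAZE_FS_HZ,
    seed: int = 0,
) -> np.ndarray:
    """A saccade-free gaze stream drifting below the detection threshold."""
    if drift_speed_deg_s >= 50.0:
        raise ValueError("drift must stay below the 50 deg/s saccade threshold")
    dt_ms = 1000.0 / fs_hz
    n = int(round(duration_ms / dt_ms))
    t = np.arange(n) * dt_ms
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    angle = rng.uniform(0, 2 * np.pi)
    speed = drift_speed_deg_s / 1000.0  # deg per ms
    gaze = np.column_stack(
        (t, t * speed * np.cos(angle), t * speed * np.sin(angle))
    )
    return gaze
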