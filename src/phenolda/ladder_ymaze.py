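"""Erasmus-ladder and water Y-maze scoring.

The ladder assay records, per trial, the goal-box exit time relative to a
light cue (with an air puff 3 s later) and the sequence of rung-to-rung
steps over a 37-rung ladder of alternating high and low rungs.  Steps are
classified by rung displacement (backstep / shortstep / longstep / jump), a
misstep is any step from, to or on a low rung, and exits are classified as
before-cue, light-cue or air-cue.  Session-level learning is summarized by
the light/air exit ratio, and the association between before-cue exits and
that ratio is compared between genotypes with an extra-sum-of-squares F-test
on per-group regression lines.

The water Y-maze records correct/incorrect arm choices across acquisition,
test and two reversal phases; subjects failing an 80% correct-choice
criterion in the test phase are excluded from reversal analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

N_RUNGS = 37
AIR_DELAY_S = 3.0

STEP_CLASSES = ("backstep", "shortstep", "longstep", "jump")
YMAZE_PHASES = ("acquisition", "test", "reversal1", "reversal2")

#: sessions x trials per phase: 4x5 acquisition, 1x5 test, 5x5 per reversal
YMAZE_PROTOCOL = {
    "acquisition": (4, 5),
    "test": (1, 5),
    "reversal1": (5, 5),
    "reversal2": (5, 5),
}


def default_rung_heights(n_rungs: int = N_RUNGS) -> dict[int, str]:
    """Alternating high/low rung map (even index = high)."""
    return {i: ("high" if i % 2 == 0 else "low") for i in range(1, n_rungs + 1)}


@dataclass
class LadderTrial:
    """One goal-box-to-goal-box crossing."""

    subject: str
    session: int
    trial: int
    light_onset_s: float
    air_onset_s: float
    exit_time_s: float
    crossing_time_s: float
    steps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.session <= 5:
            raise ValueError("session must be in 1..5")
        if abs(self.air_onset_s - self.light_onset_s - AIR_DELAY_S) > 1e-6:
            raise ValueError("air onset must be light onset + 3 s")
        for fr, to in self.steps:
            if not (1 <= fr <= N_RUNGS and 1 <= to <= N_RUNGS):
                raise ValueError("rung indices must be in 1..37")


@dataclass
class LadderSessionSummary:
    subject: str
    session: int
    n_trials: int
    exit_counts: dict[str, int]
    light_air_ratio: float | None
    step_pct: dict[str, float]
    misstep_pct: float
    mean_crossing_time_s: float
    long_backstep_warnings: int = 0


@dataclass
class YMazeTrial:
    subject: str
    phase: str
    session: int
    trial: int
    correct: bool
    forced: bool = False

    def __post_init__(self) -> None:
        if self.phase not in YMAZE_PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        n_sessions, n_trials = YMAZE_PROTOCOL[self.phase]
        if not 1 <= self.session <= n_sessions:
            raise ValueError(f"{self.phase} session must be in 1..{n_sessions}")
        if not 1 <= self.trial <= n_trials:
            raise ValueError(f"trial must be in 1..{n_trials}")
        if self.forced and not (
            self.phase in {"reversal1", "reversal2"} and self.session == 5
        ):
            raise ValueError("forced trials occur only in session 5 of reversals")


# ---------------------------------------------------------------------------
# step / exit classification
# ---------------------------------------------------------------------------

def classify_step(from_rung: int, to_rung: int) -> str:
    """Step class from rung displacement.

    d = to - from: d <= -1 backstep, d = 0 stationary, d = 1 shortstep
    (adjacent rung), d = 2 longstep (second-next rung), d >= 3 jump.
    """
    for r in (from_rung, to_rung):
        if not 1 <= r <= N_RUNGS:
            raise ValueError("rung index out of range 1..37")
    d = to_rung - from_rung
    if d <= -1:
        return "backstep"
    if d == 0:
        return "stationary"
    if d == 1:
        return "shortstep"
    if d == 2:
        return "longstep"
    return "jump"


def flag_misstep(
    step: tuple[int, int], rung_heights: dict[int, str] | None = None
) -> bool:
    """True when the step involves a low rung (from, to or onto)."""
    heights = rung_heights if rung_heights is not None else default_rung_heights()
    fr, to = step
    for r in (fr, to):
        if r not in heights:
            raise ValueError(f"rung {r} missing from height map")
    return heights[fr] == "low" or heights[to] == "low"


def classify_exit(
    exit_time_s: float, light_onset_s: float, air_onset_s: float
) -> str:
    """Exit cause by cue interval (closed-left: exit at cue onset = that cue)."""
    if light_onset_s >= air_onset_s:
        raise ValueError("light onset must precede air onset")
    if exit_time_s < light_onset_s:
        return "before_cue"
    if exit_time_s < air_onset_s:
        return "light"
    return "air"


def summarize_ladder_session(
    trials: list[LadderTrial],
    rung_heights: dict[int, str] | None = None,
) -> LadderSessionSummary:
    """Aggregate one subject's session: exit counts, step mix, missteps.

    Step percentages are over the four moving-step classes (stationary
    events excluded); misstep percentage is over all steps.  The light/air
    ratio is light-exit count / air-exit count, reported missing when there
    are no air exits.
    """
    if not trials:
        raise ValueError("empty session")
    subjects = {t.subject for t in trials}
    sessions = {t.session for t in trials}
    if len(subjects) > 1 or len(sessions) > 1:
        raise ValueError("all trials must share subject and session")
    heights = rung_heights if rung_heights is not None else default_rung_heights()
    exit_counts = {"before_cue": 0, "light": 0, "air": 0}
    step_counts = dict.fromkeys(STEP_CLASSES, 0)
    long_backsteps = 0
    n_steps = 0
    n_missteps = 0
    for t in trials:
        exit_counts[classify_exit(t.exit_time_s, t.light_onset_s, t.air_onset_s)] += 1
        for fr, to in t.steps:
            cls = classify_step(fr, to)
            n_steps += 1
            if flag_misstep((fr, to), heights):
                n_missteps += 1
            if cls == "stationary":
                continue
            if cls == "backstep" and to - fr < -1:
                long_backsteps += 1
            step_counts[cls] += 1
    n_classified = sum(step_counts.values())
    step_pct = {
        k: (100.0 * v / n_classified if n_classified else 0.0)
        for k, v in step_counts.items()
    }
    ratio = (
        exit_counts["light"] / exit_counts["air"]
        if exit_counts["air"] > 0
        else None
    )
    return LadderSessionSummary(
        subject=trials[0].subject,
        session=trials[0].session,
        n_trials=len(trials),
        exit_counts=exit_counts,
        light_air_ratio=ratio,
        step_pct=step_pct,
        misstep_pct=100.0 * n_missteps / n_steps if n_steps else 0.0,
        mean_crossing_time_s=float(np.mean([t.crossing_time_s for t in trials])),
        long_backstep_warnings=long_backsteps,
    )


# ---------------------------------------------------------------------------
# before-cue / light-air-ratio association
# ---------------------------------------------------------------------------

@dataclass
class GroupLine:
    rho: float
    rho_p: float
    slope: float
    intercept: float
    n: int


@dataclass
class AssociationFit:
    groups: dict[str, GroupLine]
    f_statistic: float
    df: tuple[int, int]
    p_value: float


def exit_association_fit(
    x: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
) -> AssociationFit:
    """Per-group association between light/air ratio (x) and before-cue exits (y).

    Reports the Spearman rank correlation and ordinary-least-squares line per
    group, plus an extra-sum-of-squares F-test comparing one shared line
    (2 parameters) against separate per-group lines (4 parameters):
    F = ((RSS_shared - RSS_sep)/2) / (RSS_sep/(N-4)), df = (2, N-4).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    names = list(pd.unique(groups))
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    out: dict[str, GroupLine] = {}
    rss_sep = 0.0
    for name in names:
        m = groups == name
        if m.sum() < 3:
            raise ValueError("each group needs >= 3 observations")
        xg, yg = x[m], y[m]
        if np.ptp(xg) == 0:
            raise ValueError(f"constant x in group {name!r}: slope undefined")
        rho, rho_p = stats.spearmanr(xg, yg)
        slope, intercept = np.polyfit(xg, yg, 1)
        resid = yg - (slope * xg + intercept)
        rss_sep += float(resid @ resid)
        out[str(name)] = GroupLine(
            rho=float(rho),
            rho_p=float(rho_p),
            slope=float(slope),
            intercept=float(intercept),
            n=int(m.sum()),
        )
    slope_all, icpt_all = np.polyfit(x, y, 1)
    resid_all = y - (slope_all * x + icpt_all)
    rss_shared = float(resid_all @ resid_all)
    n = len(x)
    df1, df2 = 2, n - 4
    # noiseless fits leave only float dust in the RSS; judge zero on the
    # scale of the response's sum of squares
    scale = float(y @ y) + 1.0
    if rss_sep < 1e-12 * scale:
        shared_zero = rss_shared < 1e-12 * scale
        f = 0.0 if shared_zero else float("inf")
        p = 1.0 if shared_zero else 0.0
    else:
        f = ((rss_shared - rss_sep) / df1) / (rss_sep / df2)
        p = float(stats.f.sf(f, df1, df2))
    return AssociationFit(groups=out, f_statistic=float(f), df=(df1, df2), p_value=p)


# ---------------------------------------------------------------------------
# water Y-maze
# ---------------------------------------------------------------------------

@dataclass
class YMazeReport:
    """Per-subject Y-maze learning scores.

    ``session_correct`` is a tidy frame (subject, phase, session, n_correct,
    n_trials, pct_correct); ``excluded`` maps subject -> True when the test
    phase correct rate fell below 80% (such subjects are dropped from
    reversal analysis); ``cumulative`` holds each subject's running sum of
    correct choices over the ordered acquisition+test trials, with the
    across-subject median and quartile curves.
    """

    session_correct: pd.DataFrame
    excluded: dict[str, bool]
    cumulative: pd.DataFrame
    cumulative_median: np.ndarray
    cumulative_q1: np.ndarray
    cumulative_q3: np.ndarray


def score_ymaze(trials: list[YMazeTrial]) -> YMazeReport:
    """Score correct-choice records against the Y-maze protocol.

    Exclusion rule: a subject is excluded from reversal phases when its test
    correct rate is below 80% (fewer than 4 of 5 correct); exactly 80%
    passes.  The cumulative curve runs over acquisition sessions 1-4 then
    test, 5 trials each (25 trials), summarized across retained-and-excluded
    subjects alike by median and quartiles.
    """
    if not trials:
        raise ValueError("no trials")
    df = pd.DataFrame(
        {
            "subject": [t.subject for t in trials],
            "phase": [t.phase for t in trials],
            "session": [t.session for t in trials],
            "trial": [t.trial for t in trials],
            "correct": [t.correct for t in trials],
        }
    )
    session_correct = (
        df.groupby(["subject", "phase", "session"], sort=True)["correct"]
        .agg(n_correct="sum", n_trials="count")
        .reset_index()
    )
    session_correct["pct_correct"] = (
        100.0 * session_correct["n_correct"] / session_correct["n_trials"]
    )
    excluded: dict[str, bool] = {}
    for subject, sub in df.groupby("subject"):
        test = sub[sub["phase"] == "test"]
        if test.empty:
            raise ValueError(f"subject {subject!r} is missing the test session")
        rate = test["correct"].mean()
        excluded[str(subject)] = bool(rate < 0.8)

    phase_order = {"acquisition": 0, "test": 1}
    acq = df[df["phase"].isin(phase_order)].copy()
    acq["phase_order"] = acq["phase"].map(phase_order)
    acq = acq.sort_values(["subject", "phase_order", "session", "trial"])
    curves = {}
    for subject, sub in acq.groupby("subject"):
        curves[str(subject)] = np.cumsum(sub["correct"].to_numpy().astype(int))
    lengths = {len(v) for v in curves.values()}
    if len(lengths) != 1:
        raise ValueError("subjects have unequal acquisition+test trial counts")
    cumulative = pd.DataFrame(curves).T
    cumulative.columns = np.arange(1, cumulative.shape[1] + 1)
    arr = cumulative.to_numpy()
    return YMazeReport(
        session_correct=session_correct,
        excluded=excluded,
        cumulative=cumulative,
        cumulative_median=np.median(arr, axis=0),
        cumulative_q1=np.percentile(arr, 25, axis=0),
        cumulative_q3=np.percentile(arr, 75, axis=0),
    )
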