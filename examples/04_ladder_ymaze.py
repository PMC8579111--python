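"""Erasmus-ladder session scoring and water Y-maze learning curves.

Simulates a mouse that shifts from air-driven exits to light-cue exits over
five sessions (cue-association learning), then a Y-maze learner that
acquires the platform position but struggles after reversal.
"""

import numpy as np

from phenolda import (
    exit_association_fit,
    gen_ladder_sessions,
    gen_ymaze_choices,
    score_ymaze,
    summarize_ladder_session,
)

response = [
    {"before_cue": 0.05, "light": light, "air": 0.95 - light}
    for light in (0.10, 0.20, 0.30, 0.40, 0.50)
]
trials, _ = gen_ladder_sessions(response, seed=2)
ratios, before = [], []
for session in range(1, 6):
    s = summarize_ladder_session([t for t in trials if t.session == session])
    ratios.append(s.light_air_ratio)
    before.append(s.exit_counts["before_cue"])
    print(
        f"session {session}: exits {s.exit_counts}, light/air ratio "
        f"{s.light_air_ratio:.2f}, shortsteps {s.step_pct['shortstep']:.0f}%, "
        f"missteps {s.misstep_pct:.0f}%"
    )
# the rising light/air ratio is the learning readout: the mouse leaves the
# goal box on the light cue instead of waiting for the air puff.

# association between impulsive (before-cue) exits and the light/air ratio,
# compared between two synthetic genotypes
rng = np.random.default_rng(4)
x = rng.uniform(0, 2.5, 120)
groups = np.repeat(["wt", "mutant"], 60)
y = np.where(groups == "wt", 4.9 * x + 3.8, 2.3 * x + 4.5) + rng.normal(0, 2, 120)
fit = exit_association_fit(x, y, groups)
for g, line in fit.groups.items():
    print(f"{g}: rho={line.rho:.2f}, y = {line.slope:.1f}x + {line.intercept:.1f}")
print(f"shared-vs-separate lines: F{fit.df} = {fit.f_statistic:.2f}, p = {fit.p_value:.3f}")

p_correct = {
    "acquisition": [0.5, 0.7, 0.85, 0.95],
    "test": [0.95],
    "reversal1": [0.3, 0.5, 0.6, 0.7, 0.8],
    "reversal2": [0.4, 0.6, 0.7, 0.8, 0.9],
}
ymaze_trials = []
for m in range(8):
    t, _ = gen_ymaze_choices(p_correct, seed=m, subject=f"m{m:02d}")
    ymaze_trials += t
report = score_ymaze(ymaze_trials)
print(f"excluded after test phase (<80% correct): "
      f"{[s for s, e in report.excluded.items() if e]}")
print(f"cumulative correct-choice median over acquisition+test trials:\n"
      f"{report.cumulative_median}")
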