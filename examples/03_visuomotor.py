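"""Score a 16-trial anti-tapping session and express it against controls.

Anti-tasks require a movement opposite to the stimulus (response
inhibition); the session below injects a 30% error rate and slowed hand
latencies, then expresses the summary against a control cohort in SD units.
"""

from phenolda import (
    CohortStats,
    deviation_score,
    gen_visuomotor_session,
    score_trial,
    summarize_task,
)

trials, truth = gen_visuomotor_session(
    "anti_tapping",
    n_trials=16,
    eye_latency_ms=(360.0, 35.0),
    hand_latency_ms=(520.0, 40.0),
    execution_ms=(380.0, 60.0),
    error_rate=0.3,
    seed=21,
)
outcomes = [score_trial(t) for t in trials]
summary = summarize_task(outcomes)
print(
    f"performance {summary.performance_pct:.0f}% "
    f"({len(truth.error_trials)} injected error trials)"
)
print(f"mean eye latency  {summary.mean_eye_latency_ms:.0f} ms")
print(f"mean hand latency {summary.mean_hand_latency_ms:.0f} ms")

controls = CohortStats("anti-tapping hand latency", mean=462.0, sd=33.0, n=10)
z = deviation_score(summary.mean_hand_latency_ms, controls)
print(f"hand latency vs controls: {z:+.1f} SD")
# a positive score in SD units means this subject's hand responses are
# slower than the age-matched control group by that many control SDs.
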