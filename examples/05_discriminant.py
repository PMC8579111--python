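"""The full multivariate pipeline on a synthetic two-genotype cohort.

Pre-processes the default cohort (slope reduction of 5-session learning
variables, skew screening, per-class scaled-MAD outlier replacement,
z-scoring, correlation filtering), fits the pseudo-inverse Fisher
discriminant and validates the observed contribution ranking against a
label-shuffle null.
"""

from phenolda import (
    default_cohort_spec,
    fit_lda,
    gen_feature_matrix,
    preprocess,
    shuffle_validate,
)

fm, truth = gen_feature_matrix(default_cohort_spec(seed=1))
fm2, report = preprocess(fm, exclude_skewed=True)
print(
    f"pre-processing: {report.initial_variables} columns -> "
    f"{report.final_variables} variables "
    f"(skew-excluded {report.skew_excluded}, "
    f"correlation-dropped {[e[0] for e in report.correlation_excluded]}, "
    f"{len(report.outlier_replacements)} outliers mean-interpolated)"
)

model = fit_lda(fm2)
print(
    f"LD1 explains {model.explained_pct['LD1']:.1f}% and LD2 "
    f"{model.explained_pct['LD2']:.1f}% of data variation"
)
print("top-5 LD1 contributors (% of absolute coefficients):")
for name, pct in model.top_contributors("LD1", 5).items():
    print(f"  {name:24s} {pct:5.1f}%")

shuffles = shuffle_validate(fm2, n_shuffles=20_000, seed=7)
top1 = shuffles.observed_top[0]
print(
    f"under {shuffles.n_shuffles} label shuffles, the observed top variable "
    f"({top1}) holds rank 1 in "
    f"{shuffles.rank_freq_pct.loc[top1, 'rank1']:.2f}% of shuffles"
)
print(
    f"the observed top-2 set jointly holds ranks 1-2 in "
    f"{shuffles.top2_joint_pct:.3f}% of shuffles"
)
# small null frequencies mean the observed ranking is unlikely under random
# labelling - the contribution pattern reflects genuine class structure.
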