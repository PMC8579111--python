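"""Generate a two-genotype behavioral cohort and inspect its structure.

Builds the default 15-vs-15 cohort (36 raw variables across eight assays,
with correlated speed/distance pairs, one heavily skewed learning variable,
occasional outliers and missing sessions) and prints what was injected.
"""

from phenolda import default_cohort_spec, gen_feature_matrix

spec = default_cohort_spec(seed=11)
fm, truth = gen_feature_matrix(spec)

print(f"cohort: {fm.data.shape[0]} subjects x {fm.data.shape[1]} columns")
print(f"classes: {dict(fm.labels.value_counts())}")
nonzero = {k: v for k, v in truth.effects.items() if v != 0}
print(f"injected class effects (Cohen's d): {nonzero}")
print(f"injected outliers at (subject, variable): {truth.outliers}")
print(f"correlated blocks: {truth.correlations}")
# The effects are what the discriminant should later surface; the outliers
# and the skewed 'YM reversal II' variable are what pre-processing must
# neutralise before the discriminant sees the data.
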