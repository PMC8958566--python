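"""Mixed-model repeated-measures ANOVA of the character design.

Fits, per facial segment, a linear mixed model of percent change with
cooperativeness and assertiveness as within-subject factors and a
random intercept per subject; reports type III F tests with
Satterthwaite degrees of freedom and mixed-model R-squared.
"""

from facekin import SimConfig, run_univariate_suite
from facekin.anova import bonferroni_threshold, suite_frame
from facekin.simulate import simulate_normalized_table

# feature-level simulation: the percent-change table a noise-free
# capture of the default 24-subject cohort would yield
table = simulate_normalized_table(SimConfig(seed=3))

suite = run_univariate_suite(table, kind="character")
frame = suite_frame(suite)
print(frame[["response", "effect", "SumSq", "NumDF", "DenDF", "F", "p",
             "sig"]].to_string(index=False, float_format="%.3f"))
print(f"\nBonferroni-corrected threshold: "
      f"alpha = {bonferroni_threshold(0.05, 4):.4f} (four segments)")

brow = suite["brow"]
print(f"\nbrow R2_marg = {brow.r2_marg:.2f}, R2_cond = {brow.r2_cond:.2f}")
print("\nEstimated marginal means, brow x cooperativeness "
      "(monotone expansion with increasing cooperativeness):")
em = brow.emmeans
print(em[em["factor"] == "cooperativeness"].to_string(index=False,
                                                      float_format="%.2f"))
print("\nThe generator injects cooperativeness effects on brow/eyebrow/"
      "lips and an assertiveness effect on the jaw; the significant rows "
      "above recover exactly that dissociation.")
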