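"""Audit a speaker-independent anxiety regressor for demographic bias.

Generates a synthetic 2x3 (gender x race/ethnicity) public-speaking cohort
with the package's default group moments, fits a leave-one-speaker-out
linear regression from four acoustic measures (F0, loudness, jitter,
shimmer) to the self-reported anxiety score, and reports per-group relative
error (RE) and equality of opportunity (EO = 1 - |RE gap|). EO = 1 means
the model errs equally on the sensitive group and its reference group.
"""

import fairspeech as fs

cohort = fs.generate_anxiety_cohort(fs.anxiety_coupled_spec(strength=0.3, seed=1))
print(f"cohort: {len(cohort.rows)} audio files from {cohort.n_participants} speakers\n")

report = fs.audit_anxiety(cohort)

print("per-group anxiety (actual vs estimated):")
print(report.group_stats.round(2).to_string(index=False), "\n")

print("relative error and equality of opportunity:")
print(report.eo_table().round(3).to_string(index=False), "\n")

anova = report.anova["actual"].gender
print(f"gender effect on self-reported anxiety: "
      f"F({anova.df[0]:.0f}, {anova.df[1]:.0f}) = {anova.statistic:.2f}, p = {anova.p_value:.3f}")
print("EO below 1 flags groups whose anxiety the model estimates less accurately "
      "than the reference (White same-gender / White / male) group.")
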