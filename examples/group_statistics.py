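"""Group-difference statistics on acoustic features and outcome labels.

Runs the label-bias analysis on a synthetic anxiety cohort: a two-way
ANOVA (gender x race/ethnicity) per acoustic measure, post-hoc pooled
t-tests between demographic pairs, and the pooled two-proportion Z-test
on depression base rates.
"""

import fairspeech as fs

cohort = fs.generate_anxiety_cohort(fs.AnxietyCohortSpec(seed=2))
rows = cohort.rows

print("two-way ANOVA (gender x race/ethnicity):")
for measure in ("f0_semitone", "sae_score"):
    res = fs.two_way_anova(rows, measure)
    for effect, tr in res.as_dict().items():
        print(f"  {measure:12s} {effect:15s} F({tr.df[0]:.0f}, {tr.df[1]:.0f}) = "
              f"{tr.statistic:8.2f}, p = {tr.p_value:.4f}")

print("\npost-hoc pooled t (African American female vs White female, F0):")
af = rows[(rows.gender == "female") & (rows.race_ethnicity == "african_american")]
wf = rows[(rows.gender == "female") & (rows.race_ethnicity == "white")]
tr = fs.pairwise_t(af["f0_semitone"], wf["f0_semitone"])
print(f"  t({tr.df:.0f}) = {tr.statistic:.2f}, p = {tr.p_value:.3f}")

print("\ntwo-proportion Z-test, male vs female depression base rates (14/63 vs 17/44):")
z = fs.two_proportion_z(14, 63, 17, 44)
print(f"  z = {z.statistic:.3f}, p = {z.p_value:.3f}")
print("  |z| < 1.96: the gender difference in base rates is not significant at the 5% level.")
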