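"""Cohort simulation and age-adjusted group comparison.

Simulates a 56-subject cohort with the six study subgroups (classic and
late-onset Fabry disease and healthy controls, split by sex), prints the
group summary, fits the linear model of mean VTI on group plus age, and
reports the Tukey-adjusted pairwise contrasts.  With these group
parameters the classic-male subgroup has a markedly higher mean VTI, and
its contrasts against the other subgroups are the ones that reach
significance.
"""

from octavti import (
    CohortConfig,
    demographics_tests,
    describe_groups,
    fit_vti_model,
    simulate_cohort,
    tukey_contrasts,
)

table = simulate_cohort(CohortConfig(seed=1))
print(f"simulated cohort: {len(table)} subjects\n")
print(describe_groups(table).round(3), "\n")

# demographic homogeneity across onset cohorts (the six subgroups are
# single-sex by construction, so sex is tested at the cohort level)
demo = demographics_tests(table.assign(group=table["onset"]))
print(f"age homogeneity across cohorts ({demo['age_test']}): p = {demo['age_p']:.3f}")
print(f"sex composition across cohorts ({demo['sex_test']}): p = {demo['sex_p']:.3f}\n")

fit = fit_vti_model(table)
contrasts = tukey_contrasts(fit, alpha=0.05)
print(f"{len(contrasts)} Tukey-adjusted pairwise contrasts (diff of age-adjusted means):")
for c in contrasts:
    star = " *" if c.p_adj < 0.05 else ""
    print(f"  {c.comparison:30s} {c.estimate:+.4f} [{c.lower:+.4f}, {c.upper:+.4f}] "
          f"p_adj={c.p_adj:.4f}{star}")
print("\n'*' marks contrasts significant at alpha = 0.05")
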