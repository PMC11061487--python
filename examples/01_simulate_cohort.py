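"""Simulate a study-sized two-group cohort and summarise its demographics.

The simulator emulates a 30-vs-22 case-control cohort over 78 cortical
regions: vertex-level thickness samples and voxel-level CBF samples per
region, with sex/age marginals matching the study population.
"""

import numpy as np

from brainnetdx import CohortConfig, chi_square_2x2, simulate_cohort, ttest_two_sample

cohort = simulate_cohort(CohortConfig(base_seed=7))
asd = [s for s in cohort if s.group == "ASD"]
td = [s for s in cohort if s.group == "TD"]

print(f"subjects: {len(cohort)} ({len(asd)} ASD, {len(td)} TD)")
for name, group in (("ASD", asd), ("TD", td)):
    ages = [s.age for s in group]
    males = sum(s.sex == "M" for s in group)
    print(f"  {name}: age {np.mean(ages):.2f} +/- {np.std(ages, ddof=1):.2f}, "
          f"male/female {males}/{len(group) - males}")

t, p = ttest_two_sample([s.age for s in asd], [s.age for s in td])
print(f"age difference: t = {t:.3f}, p = {p:.3f}  (no injected effect -> ns)")

a, b = sum(s.sex == "M" for s in asd), sum(s.sex == "F" for s in asd)
c, d = sum(s.sex == "M" for s in td), sum(s.sex == "F" for s in td)
chi2, p = chi_square_2x2(a, b, c, d)
print(f"sex distribution: chi2 = {chi2:.2f}, p = {p:.3f}")
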