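"""Mutation burden and its association with age and menstrual history.

Simulates a cohort with clock-like mutation accrual, pools each subject's
glands into a single burden (high-MAF SNVs per Mbp of callable target),
and correlates burden with age and the cumulative number of menstrual
cycles (CNMC).
"""

from glandevo import covariate_association, mutation_burden
from glandevo.synthetic import SimulationConfig, simulate_cohort

config = SimulationConfig(n_subjects=12, seed=42)
glands, clinical, truth = simulate_cohort(config)

burdens, ages, cnmcs = [], [], []
for subject in clinical:
    mine = [g for g in glands if g.subject_id == subject.subject_id]
    res = mutation_burden(mine)
    burdens.append(res.burden)
    ages.append(subject.age)
    cnmcs.append(subject.cnmc)
    print(f"{subject.subject_id}: age {subject.age:4.0f}  "
          f"burden {res.burden:5.2f} /Mbp  CpG C>T {res.cpg_ct_burden:4.2f}")

for name, cov in (("age", ages), ("CNMC", cnmcs)):
    a = covariate_association(burdens, cov)
    print(f"burden ~ {name}: r = {a.r:.2f}, p = {a.p:.1e}, "
          f"slope = {a.slope:.3g} per unit")
# Burden rises linearly with age (the planted clock rate is
# 0.08 SNVs/Mbp/year), and CNMC tracks age, so both correlations are high.
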