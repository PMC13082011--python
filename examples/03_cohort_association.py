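"""Cohort association analyses on a simulated serology cohort.

Generates a cohort with a built-in protective odds ratio (0.9 per unit of
mean CE1-VP1 binding signal) and a survival benefit for broad responders
(hazard ratio 2.0 for breadth <= 0.5), then recovers both with the
association layer.
"""

import numpy as np

from mimiscan import synthdata
from mimiscan.association import fit_diagnosis_logistic, km_logrank
from mimiscan.catalog import PeptideGroup
from mimiscan.repertoire import compute_arb

spec = synthdata.CohortSpec(
    n_healthy=400, n_cld=400, n_hcc=500,
    n_peptides_per_group=(59, 30, 30),
    ebs_location_shift=0.0,
    diagnosis_or_per_ebs_unit=0.9,
    arb_hazard_ratio=2.0,
    censor_rate=0.2,
    seed=42,
)
cohort = synthdata.generate_serology_cohort(spec)

ce1 = [p for p, g in cohort.assignments.items() if g == "CE1_VP1"]
x = cohort.ebs[ce1].mean(axis=1).to_numpy()
y = (cohort.metadata["diagnosis"] == "HCC").to_numpy(dtype=float)
fit = fit_diagnosis_logistic(x, y)
print(f"diagnosis logistic: OR per unit EBS = {fit.odds_ratio:.3f} "
      f"(encoded 0.9), p = {fit.p_value:.4f}, n = {fit.n_used}")

arb = {r.individual_id: r.arb
       for r in compute_arb(cohort.ebs, cohort.assignments,
                            PeptideGroup.CE1_VP1)}
arbs = cohort.metadata.index.map(arb)
hcc = (cohort.metadata["diagnosis"] == "HCC").to_numpy()
strata = np.where(arbs > 0.5, "ARB>0.5", "ARB<=0.5")
surv = km_logrank(cohort.metadata.loc[hcc, "survival_time"],
                  cohort.metadata.loc[hcc, "event"], strata[hcc])
print(f"log-rank, broad vs narrow breadth among HCC: "
      f"chi2 = {surv.logrank_statistic:.2f}, p = {surv.logrank_p:.2e}, "
      f"arms = {surv.n_per_stratum}")

# The recovered odds ratio sits near the encoded 0.9, and the log-rank test
# flags the encoded survival advantage of broad CE1-VP1 responders.
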