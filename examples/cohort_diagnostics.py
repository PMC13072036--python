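"""Simulate a diagnostic cohort and evaluate the CD98+ EV Index.

Draws 50 healthy and 136 early-HCC subjects with log-normal index
distributions fitted to published group summaries (median/IQR), pushes
every subject through ExoCounter-style well counts, negative-control
subtraction and total-EV-concentration normalization, then evaluates the
index as a classifier: ROC/AUC, Youden-optimal cutoff, sensitivity and
specificity, Welch's t-test for group separation, and stratified 5-fold
cross-validated logistic regression.
"""

import numpy as np

from evquant import CohortSpec, derive_index, evaluate_cohort, simulate_cohort

spec = CohortSpec()
cohort = simulate_cohort(spec, seed=1)
report = evaluate_cohort(cohort, cv_seed=1)

idx = derive_index(cohort)
print(f"subjects: {report['n_healthy']} healthy, {report['n_hcc']} HCC")
print(f"median index  healthy: {report['median_index_healthy']:.3f}   "
      f"HCC: {report['median_index_hcc']:.3f}")
print(f"AUC: {report['auc']:.3f}")
print(f"Youden cutoff: {report['cutoff']:.2f} (J = {report['youden_j']:.3f})")
print(f"sensitivity: {report['sensitivity']:.2f}   specificity: {report['specificity']:.2f}")
print(f"Welch t = {report['welch_t']['statistic']:.2f}, "
      f"p = {report['welch_t']['p_value']:.2e}")
print(f"5-fold CV: mean AUC {report['cv']['mean_auc']:.3f}, "
      f"mean accuracy {report['cv']['mean_accuracy']:.3f}")
print("\nhigher index in HCC reflects more CD98+ vesicles per unit of total EVs;")
print("the cutoff maximizes sensitivity + specificity - 1 on this cohort")
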