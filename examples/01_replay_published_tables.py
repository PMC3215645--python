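"""Re-derive a validation study's headline statistics from its printed counts.

A coded-diagnosis validation reports a 2x2 table per disease: criteria-positive
and criteria-negative patients in the coded and uncoded arms.  Everything else
(sensitivity, specificity, Wilson intervals, kappa, prevalence adjustment,
predictive values) follows from those four numbers, so it can be recomputed
without any patient-level data.
"""

from phenoval import replay_from_counts

# Diabetes: 423 coded patients (421 met the ADA criteria), 392 evaluable
# uncoded patients (2 met the criteria).
dm = replay_from_counts(tp=421, fp=2, fn=2, tn=390,
                        apparent_prevalence=0.0502,
                        prevalence_grid_values=[0.05])

# Hypertension: 423 coded (415 met the JNC 7 criteria), 326 evaluable uncoded
# (72 met the criteria).
htn = replay_from_counts(tp=415, fp=8, fn=72, tn=254,
                         apparent_prevalence=0.1411,
                         prevalence_grid_values=[0.05, 0.50])

for name, out in (("diabetes", dm), ("hypertension", htn)):
    sn, sp, k = out["sensitivity"], out["specificity"], out["kappa"]
    adj = out["prevalence_adjustment"]
    print(f"{name}:")
    print(f"  sensitivity {100*sn.estimate:6.2f}%  ({100*sn.ci_low:.2f}-{100*sn.ci_high:.2f})")
    print(f"  specificity {100*sp.estimate:6.2f}%  ({100*sp.ci_low:.2f}-{100*sp.ci_high:.2f})")
    print(f"  kappa       {k.kappa:6.3f}   ({k.ci_low:.3f}-{k.ci_high:.3f})  -> {k.label}")
    print(f"  Rogan-Gladen prevalence: coded {100*adj.apparent:.2f}% -> "
          f"criteria-based {100*adj.true_prevalence:.2f}%")
    for row in out["prevalence_grid"].itertuples(index=False):
        print(f"  at prevalence {100*row.prevalence:4.1f}%: "
              f"PPV {100*row.ppv:6.2f}%  NPV {100*row.npv:6.2f}%")

# The kappa labels ("almost perfect" vs "substantial") summarise how far the
# coded diagnosis can stand in for the guideline criteria; the PPV rows show
# how strongly a positive code's meaning depends on disease prevalence.
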