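"""Check that the validation design can recover the true coding quality.

The two-arm design samples patients by their code status, so the pooled
TP/(TP+FN) of the arms is a design-dependent quantity, not the population
probability that a true case gets coded.  The design-corrected estimator
reweights each arm back to the population within age strata; over repeated
synthetic cohorts its intervals should cover the coding sensitivity and
specificity that the generator was actually configured with.
"""

from phenoval import SyntheticConfig
from phenoval.pipeline import coding_recovery_study

config = SyntheticConfig(n_patients=20_000)
study = coding_recovery_study(config, n_replicates=10, base_seed=0)

print(f"{'parameter':<10}{'configured':>12}{'mean estimate':>15}{'interval coverage':>19}")
for key, res in study.items():
    print(f"{key:<10}{res['configured']:>12.4f}{res['mean_estimate']:>15.4f}"
          f"{res['coverage']:>19.0%}")

# Coverage near (or above) 95% and mean estimates centred on the configured
# values show the corrected estimator undoes the case-control sampling and the
# age/sex matching; with only 10 replicates the coverage column is coarse.
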