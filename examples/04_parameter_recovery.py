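"""Parameter-recovery experiment: simulate a group at known parameters,
fit every participant, and compare recovered group means to the truth.

This is the package's core validation logic: an estimator is
trustworthy for a manipulation if it recovers the manipulated
parameter from data generated at the published group-mean estimates.
"""

from driftfit import SCENARIOS, recovery_experiment

rep = recovery_experiment(SCENARIOS["exp3-ez-twice"], seed=1)
print(f"scenario {rep.scenario}: {rep.n_used}/{rep.n_participants} "
      f"participants usable ({rep.n_screened} screened out)")
print(rep.table.round(4).to_string(index=False))
# The drift magnitude |v| should come back near its generating value
# 0.13 with only Monte-Carlo scatter; bias is the mean error and rmse
# its spread across simulated participants.
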