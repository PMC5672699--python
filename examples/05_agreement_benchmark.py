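"""The full four-method benchmark with agreement statistics.

Runs the end-to-end experiment on a reduced cohort: simulate, featurize,
split, train, estimate with all four methods, and report test-set CCC/ICC
and Bland-Altman limits against the reference volumes, plus per-case SV/EF
agreement for the network.
"""

from lvvol import BPNetConfig, CohortSpec, RunConfig, run_experiment

report = run_experiment(RunConfig(
    cohort=CohortSpec(n_cases=15),
    bpnet=BPNetConfig(max_epochs=8000),
    seed=2,
))

print("test-set agreement with reference volumes:")
print(report.agreement[["n", "ccc", "icc", "bias", "loa_low", "loa_high"]]
      .round(4).to_string())
print()
print("per-case cardiac-function agreement (network vs truth):")
print(report.function_agreement.round(4).to_string(index=False))
print()
print("CCC/ICC near 1 mean near-identity agreement; the limits of "
      "agreement are in ml. On these solids of revolution Simpson's "
      "method is unbiased by construction, so all four methods sit within "
      "sampling noise of each other — method separation on clinical data "
      "comes from geometry the single plane cannot see.")
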