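"""Demonstrate feature-selection bias in cross-validation on pure-null data.

The cohort below carries NO signal: labels are independent of all
10,000 genotypes.  Nested LOOCV (selection redone inside every fold)
correctly reports chance-level accuracy.  Selecting the 500 "best" SNPs
once on the full data before cross-validating leaks the held-out
subjects into the panel and produces a wildly optimistic estimate.
"""

from gwps import SimulationConfig, biased_loocv, nested_loocv, simulate

ds = simulate(SimulationConfig(n_cases=50, n_controls=50, n_snps=10_000, seed=21))

biased = biased_loocv(ds.genotypes, ds.labels, m=500, seed=5)
nested = nested_loocv(ds.genotypes, ds.labels, m=500, seed=5, record_panels=False)

print(f"apparent accuracy (selection on full data): {biased.accuracy:.1%}")
print(f"true accuracy (nested selection):           {nested.accuracy:.1%}")
print(f"optimism gap:                               {biased.accuracy - nested.accuracy:.1%}")
# On null data any accuracy far from 50% is an artefact; the gap above is
# produced entirely by letting feature selection see the held-out subjects.
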