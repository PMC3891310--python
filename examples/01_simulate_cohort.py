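"""Generate a synthetic case-control SNP cohort with planted structure.

Builds a 200-subject cohort with 20 SNPs whose case allele frequency is
shifted (the "signal"), plus planted QC violations, and writes the
native TSV pair and the ground-truth sidecar.
"""

from pathlib import Path

from gwps import SimulationConfig, simulate
from gwps.io import write_labels, write_native, write_truth

config = SimulationConfig(
    n_cases=100,
    n_controls=100,
    n_snps=1000,
    n_effect_snps=20,
    effect_delta=0.25,      # case allele frequency = control + 0.25 at effect SNPs
    n_hwe_violating=10,
    hwe_inbreeding_f=0.8,
    n_low_maf=10,
    n_missing_snps=10,
    seed=7,
)
ds = simulate(config)

out = Path("scratch/example_cohort")
out.mkdir(parents=True, exist_ok=True)
write_native(ds.genotypes, out / "genotypes.tsv")
write_labels(ds.labels, out / "labels.tsv")
write_truth(ds.truth, out / "truth.json")

print(f"cohort: {ds.genotypes.n_subjects} subjects x {ds.genotypes.n_snps} SNPs")
print(f"planted effect SNPs: {len(ds.effect_snps)} (e.g. {ds.effect_snps[:3]})")
print(f"planted QC violations: {len(ds.hwe_violating_snps)} HWE, "
      f"{len(ds.low_maf_snps)} low-MAF, {len(ds.missing_snps)} missing-call")
print(f"files written under {out}/")
# The truth sidecar lists exactly which SNPs carry signal or violations,
# so downstream stages can be checked against a known answer.
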