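"""Apply the three SNP-level QC filters and compare against planted truth.

A SNP is removed if it has any missing call, deviates from
Hardy-Weinberg equilibrium in controls (chi-square p < 0.001), or has
minor allele frequency below 5%.
"""

from gwps import SimulationConfig, apply_qc, simulate

ds = simulate(
    SimulationConfig(
        n_cases=500, n_controls=500, n_snps=2000,
        maf_range=(0.1, 0.5),
        n_hwe_violating=15, hwe_inbreeding_f=0.8,
        n_low_maf=15, low_maf_value=0.01,
        n_missing_snps=15, missing_rate=0.05,
        seed=11,
    )
)
filtered, report = apply_qc(ds.genotypes, ds.labels, maf_min=0.05, hwe_alpha=0.001)

print(f"input SNPs:     {ds.genotypes.n_snps}")
print(f"surviving SNPs: {report.n_surviving}")
for name, planted in [
    ("missing", ds.missing_snps),
    ("hwe", ds.hwe_violating_snps),
    ("maf", ds.low_maf_snps),
]:
    removed = set(report.failed_by(name))
    caught = len(removed & set(planted))
    print(f"  {name:>7} filter removed {len(removed):3d} SNPs "
          f"({caught}/{len(planted)} of the planted violations)")
# The missing-call filter is absolute (one missing call removes the SNP);
# the HWE and MAF filters are statistical, so their recall depends on power.
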