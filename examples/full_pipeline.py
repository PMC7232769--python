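"""The whole comparison in one call.

Runs the end-to-end pipeline on a synthetic population: pedigree
matrices, SNP filtering and LD pruning, all estimators with scaling,
estimator-selection ranking, pairing tables per approach, and the
Mantel/Pearson/Kruskal-Wallis comparison statistics.
"""

from kincompare import PipelineConfig, SyntheticConfig, run_compare

config = PipelineConfig(
    synthetic=SyntheticConfig(
        n_family_groups=6,
        offspring_per_group=4,
        n_snps=5000,
        n_microsats=8,
        mean_depth=25.0,
    ),
    n_dyads=300,
    seed=1,
)
report = run_compare(config)

print("sites:", report["n_sites"])
print("\nmean +/- SD of R by dyad class and approach:")
for row in report["dyad_class_summary"]:
    print(f"  {row['approach']:<9} {row['dyad_class']:<17} "
          f"{row['mean_r']:.3f} +/- {row['sd_r']:.3f}  (n={row['n_pairs']})")
print("\nmatrix comparisons (off-diagonal):")
for name, c in report["matrix_comparisons"].items():
    print(f"  {name:<22} Mantel r={c['mantel_r']:.2f} p={c['mantel_p']:.4f} "
          f"Pearson r={c['pearson_r']:.2f}")
print("\nestimator ranking on the microsatellite panel:")
for row in report["estimator_ranking"]:
    print(f"  {row['rank']}. {row['estimator']} (r={row['pearson_r']:.2f})")
# The pedigree and SNP matrices correlate far more strongly with each
# other than either does with the 8-locus microsatellite matrix; the
# downstream pairing concordance report in `report['concordance']`
# shows the same ordering.
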