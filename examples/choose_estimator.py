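"""Choosing a relatedness estimator for a marker panel.

Distils a family-group pedigree into its distinct dyad classes (via
exact identity coefficients), rescales them to 1,000 representative
simulated dyads, simulates genotype pairs under the panel's allele
frequencies with genotyping error, and ranks candidate estimators by
Pearson correlation with true relatedness.
"""

import numpy as np

from kincompare import (
    AlleleFrequencies,
    dyad_distribution,
    estimate_dyadic_ml,
    estimate_rxy,
    rank_estimators,
    simulate_dyad_genotypes,
    simulate_family_groups,
)

sb = simulate_family_groups(6, 4, seed=1)
classes = dyad_distribution(sb, n_target=1000)
print("dyad classes (pedigree pairs -> simulated dyads):")
for c in classes.classes:
    print(f"  true r = {c.true_relatedness:.3f}: "
          f"{c.n_pairs:4d} pairs -> {c.weight:4d} dyads")

# a low-diversity 8-locus microsatellite panel
rng = np.random.default_rng(11)
loci, freqs = [], []
for k in range(8):
    n_alleles = int(rng.integers(2, 4))
    w = rng.dirichlet(np.full(n_alleles, 1.0))
    loci.append(f"m{k}")
    freqs.append({a: float(w[a]) for a in range(n_alleles)})
panel = AlleleFrequencies(loci, freqs)

sim = simulate_dyad_genotypes(classes, panel, error_rate=0.01,
                              missing_rate=0.02, seed=12)


def likelihood(gt, freqs=None, pairs=None):
    return estimate_dyadic_ml(gt, freqs, error_rate=0.01, pairs=pairs)


ranking = rank_estimators(
    sim, {"dyadic_ml": likelihood, "rxy": estimate_rxy}, freqs=panel
)
print("\nestimator ranking (Pearson r with true relatedness):")
print(ranking.to_string(index=False))
# On few low-diversity loci the inbreeding-aware likelihood estimator
# typically correlates best with truth, which is why it gets selected
# for microsatellite panels of this kind.
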