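# Methods

This note documents the models behind `kincompare`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical choices a maintainer would want written down.

## Pedigree kinship and relatedness

Kinship is computed by the standard tabular recursion over a
topologically ordered studbook: for x younger than y,
`f(x,y) = ½(f(sire_x, y) + f(dam_x, y))`, and
`f(x,x) = ½(1 + f(sire_x, dam_x))`; a missing parent contributes zero.
Unknown parents are treated as distinct wild founders, mirroring common
studbook practice; they are tracked so that the summary statistic
"% ancestry known" can count them as unknown ancestry (a record with
*both* parents missing is a true wild founder and counts as known).
Topological ties are broken lexicographically, so matrices are
deterministic. The relatedness coefficient uses the inbreeding-aware
normalisation `R = 2f / √((1+Fx)(1+Fy))`; when nobody is inbred this
reduces to R = 2f, giving 0.5 for parent–offspring and full sibs.

Mean kinship of an individual is defined as the mean of its kinship with
the living population *including itself*, and defaults to living
individuals only (exposed as a flag, since studbook software is not
explicit on this point); gene diversity is 1 − grand mean kinship and
founder genome equivalents 1/(2 · grand mean kinship).

## Identity coefficients

The nine condensed identity coefficients of a dyad are obtained exactly
by a recursion on generalized kinship coefficients — the probability
that all alleles in a set of up to four independent draws are IBD, plus
the paired two-sets variant — always expanding the argument with the
highest topological rank, which can never be an ancestor of the others.
Two subtleties are worth recording. First, repeated draws from one
individual collapse onto at most two physical alleles (one random allele
from each parent), shared across *all* slots that chose the same side;
getting this wrong inflates the paired coefficient for inbred self-dyads
and was caught by the Monte-Carlo cross-check. Second, the nine
coefficients are recovered from nine generalized kinships by solving a
fixed 9×9 linear system; the system matrix was derived state-by-state
from the condensed-state definitions and is verified in the tests
against known dyads (parent–offspring Δ₈ = 1; full sibs
(Δ₇,Δ₈,Δ₉) = (¼,½,¼); inbred dyads against Monte-Carlo tallies).

The Monte-Carlo route drops a single locus with unique founder alleles
through the pedigree and classifies the condensed state of the dyad per
drop (default 100,000 drops). It shares no code with the exact recursion
and serves as its oracle.

## Gene dropping and realized relatedness

Meioses draw a Poisson crossover count with mean equal to the
chromosome's genetic length in Morgans and uniform crossover positions —
the Haldane model, i.e. no interference. This is sufficient for the
variance phenomena of interest; interference would narrow the sibling
distribution slightly but does not change any qualitative conclusion.
Founder haplotypes carry globally unique integer labels, so IBD is exact
label equality, with no probabilistic inference anywhere. Realized
additive relatedness of a pair is the map-length-weighted genome
fraction of IBD allele pairs,
`r = mean over the genome of (#IBD cross-pairs)/2`; the diagonal is
1 + realized F. Parent–offspring sharing is exactly 0.5 whenever parent
and co-parent are unrelated and non-inbred, because the offspring
carries one complete (recombinant) mosaic of that parent's two
haplotypes — a useful exactness check that the tests rely on. A
chromosome of zero genetic length is treated as a single segregating
point.

The canned `human_like_map()` has 22 autosomes totalling ~35.4 Morgans;
gene-dropped full sibs on it have SD(realized r) ≈ 0.039, and the
extremes of a few thousand pairs land near 0.36–0.64 — bracketing the
classic ~0.37–0.61 range reported for human siblings.

## Synthetic genotype panels

One genome carries both marker sets (SNPs and microsatellites
interleaved), so both panels segregate through a single gene drop.
Microsatellites: allele per founder haplotype label drawn from 2–4
allele frequencies per locus; genotyping error replaces an allele call
with a uniformly chosen other allele (rate 0.01 by default); missingness
drops whole genotypes (0.02 by default). The real panels' error and
missing rates are not published, so these are explicit configuration,
not reconstructions. SNPs: per-call depth from a negative binomial
(default mean 25, matching deep resequencing; dispersion 8 for the
overdispersion real coverage shows), alternate reads binomial on the
true dosage with per-read miscall 0.001, dosage = 2k/d, depth 0 =
missing. Defaults for pedigree shape (six family groups of four
offspring, 36 individuals) mirror a family-group sampling design of a
few dozen focal individuals.

What the generator does **not** emulate: mutation, selection, sex
chromosomes, overlapping generations, linked-read artefacts, mapping or
calling error beyond the per-read miscall, and population structure
among founders (founders are unrelated and non-inbred by construction).
Passing tests therefore demonstrate correctness of the estimators and
pipeline under clean Mendelian segregation with depth noise — not
robustness to pedigree errors or founder relatedness, which on real data
are the main caveats.

## Estimators

* **Similarity index (r_xy).** Per locus the presence-based similarity S
  (each individual's alleles scored for presence in the other's
  genotype, averaged both ways) is compared with its expectation s̄
  between unrelated individuals computed by exact enumeration of HWE
  genotype pairs from the allele frequencies;
  `r = Σ(S−s̄) / Σ(1−s̄)` over co-typed loci. Hand analysis at a
  biallelic locus with p = 0.5 gives E[S|parent–offspring] = 0.875 and
  s̄ = 0.75, hence E[r] = 0.5 — the estimator is unbiased for
  first-order relatives, which the simulations confirm. The exact
  variant is our documented choice; the method family is named in the
  literature without formulas.
* **KING.** `φ = (N_het,het − 2·N_opposing_hom) / (N_het,i + N_het,j)`,
  r = 2φ, over co-typed loci. Duplicate genotypes give φ = ½ exactly.
* **Dyadic maximum likelihood.** The per-locus likelihood of a genotype
  pair is `Σ_s Δ_s P(G|state s)` with the nine condensed states encoded
  as partitions of the four allele slots; consistency over genotype
  orderings handles the mirror states. Because the likelihood is linear
  in Δ, the log-likelihood is concave on the simplex, and EM on the
  mixture weights converges to the global maximum — this replaces the
  originally sketched softmax quasi-Newton multistart, which solves a
  harder problem for no benefit. Genotyping error enters as a mixture
  with the unrelated-pair genotype probability (a blunt but monotone
  model). A non-inbred submodel (states 7–9 only) is available and is
  what the dense grid-search oracle checks at step 0.02; the full
  nine-state model is checked against a coarser grid. `r = 2f(Δ)`.
  A triadic (reference-individual) extension is out of scope; the dyadic
  form retains the two properties that matter here — likelihood-based
  and inbreeding-aware.
* **Depth-aware GRM.** On dosages x = 2k/d,
  `r_ij = Σ(x_i−2p)(x_j−2p) / (2Σp(1−p))` over co-observed loci; no
  correction is needed off-diagonal because read noise of different
  individuals is independent. The diagonal substitutes
  `x² − x(2−x)/(d−1)` for x² (loci at depth 1 excluded), which makes
  E[x²] = g² exactly under binomial read sampling, hence
  E[r_ii] = 1 + F at any depth; the uncorrected diagonal is inflated by
  ~0.5 at mean depth 2 in the simulations. Allele frequencies default to
  sample estimates but accept external (e.g. founder) frequencies; with
  frequencies estimated from a small related sample the usual downward
  shrinkage of GRM entries applies.
* **Scaling.** `MS = D·MO·D` with `D = diag(MO)^{-1/2}` standardises
  self-relatedness to exactly 1 and is kept as a separate explicit step.
  Negative estimates are never truncated — sign information matters for
  ranking.

## Estimator selection

All unordered pairs of the target individuals are characterised by exact
identity coefficients; vectors equal to 9 decimals are merged into
classes, and class counts are rescaled to exactly 1,000 dyads by
largest-remainder rounding (proportionality within ±1, total conserved).
Genotype pairs are simulated per class by drawing a condensed state from
Δ per locus and assigning alleles to the state's IBD classes from the
panel frequencies; error is applied after IBD assignment, independently
per allele call. Estimators are ranked by Pearson correlation with
`r = 2f(Δ)`. The condensed-state allele-pattern table is the error-prone
core and is tested with a multinomial check on the drawn states.

## Pairing

MSI components follow the standard four-factor definition: deltaGD is
computed by appending one hypothetical offspring of the pair (kinship
row = mean of the parents' rows; self-kinship ½(1+f(m,f))) to the living
population and differencing gene diversity; the offspring's F is the
pair's kinship; unknown ancestry is the parents' mean unknown fraction
(zero in empirical-only analyses). The exact thresholds of proprietary
studbook software are not public, so the category mapping here is an
explicit, config-overridable penalty scheme, monotone in every component
by construction, with category 7 ("very highly detrimental") reserved
for pairs with offspring F ≥ 0.125 that also lose gene diversity. The
concordance statistics are computed on categories, so the mapping is
auditable; comparisons between approaches use the same mapping
throughout and are therefore insensitive to its absolute calibration.

## Comparison statistics

The Mantel test correlates off-diagonal upper triangles and permutes
rows and columns of one matrix simultaneously, with the add-one p-value
`(#{r_perm ≥ r_obs}+1)/(n_perm+1)` (never zero; 1,000 permutations by
default). Pearson correlation on the off-diagonals is reported alongside
because relatedness data contain many ties. Kruskal–Wallis uses the
tie-corrected H with a Bonferroni multiply-and-cap adjustment; a Tukey
HSD step would be redundant with it for the three-group comparisons and
is omitted. Type-I error calibration of the Mantel test is verified by
simulation in the test suite.

## Determinism and problem sizes

Every stochastic operation derives its generator from
`(seed, operation name)` via a seed sequence, so adding a stage never
perturbs another stage's stream, and whole-pipeline runs are
byte-identical given a seed. The test suite and acceptance script run
the simulations at the scales the quantities are defined at — 10,000
sib pairs for the mean, ~4,000 for the extremes, 20,000 SNPs for the
parameter-recovery checks, 1,000 dyads for estimator selection — with
smaller instances used for the brute-force oracle comparisons
(exhaustive Mantel enumeration at n = 4, all-pairs LD pruning at
hundreds of sites, dense simplex grids at 3 loci).

## Known limitations

* Founder allele frequencies are taken as known in the parameter-recovery
  simulations; on real data frequency estimation from small related
  samples biases all frequency-dependent estimators.
* The MSI mapping is ordinal-faithful but not numerically identical to
  any proprietary implementation; absolute category frequencies should
  not be compared across software.
* The dyadic ML estimator ignores linkage between loci (composite
  likelihood), as do all estimators here; with dense SNP panels the
  effective number of independent loci is smaller than the locus count.
* The pipeline's microsatellite matrix uses the similarity-index
  estimator for matrix-level comparisons even when the likelihood
  estimator wins the dyad ranking, because the ML matrix on 8 loci is
  frequently boundary-valued; both are reported.
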