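"""Pedigree kinship, relatedness and identity coefficients.

Builds a five-bird studbook containing a full-sib mating, computes the
kinship matrix by the tabular recursion, converts it to relatedness
coefficients with the inbreeding-aware normalisation, and derives the
nine condensed identity coefficients for two dyads.
"""

from kincompare import (
    Record,
    Studbook,
    identity_coefficients,
    kinship_matrix,
    kinship_to_relatedness,
    pedigree_summary,
)

studbook = Studbook(
    [
        Record("A", None, None, "M", 2000, True, "wild"),
        Record("B", None, None, "F", 2000, True, "wild"),
        Record("C", "A", "B", "M", 2001, True, "captive"),
        Record("D", "A", "B", "F", 2001, True, "captive"),
        Record("E", "C", "D", "M", 2003, True, "captive"),  # inbred chick
    ]
)

K = kinship_matrix(studbook)
R = kinship_to_relatedness(K)

print("kinship f(C,D) full sibs:      ", K.loc("C", "D"))
print("self-kinship f(E,E):           ", K.loc("E", "E"))
print("relatedness R(A,C) parent-off: ", R.loc("A", "C"))
print("relatedness R(C,E):            ", round(R.loc("C", "E"), 4))
# f(C,D) = 0.25 makes E inbred with F = 0.25, so f(E,E) = 0.5(1+F) =
# 0.625 and R(C,E) is 2*0.375 shrunk by sqrt(1.25).

fs = identity_coefficients(studbook, ("C", "D"))
ce = identity_coefficients(studbook, ("C", "E"))
print("full-sib identity (D7,D8,D9):  ", fs.rounded(4)[6:])
print("C-E identity coefficients:     ", ce.rounded(4))
print("  -> kinship recovered from D: ", ce.kinship)
# Full sibs sit at (0.25, 0.5, 0.25) over the two/one/zero-shared-pair
# states; the C-E dyad needs the inbred states because E's alleles can
# themselves be identical by descent.

summary = pedigree_summary(studbook)
print("gene diversity:                ", summary.gene_diversity)
print("founder genome equivalents:    ", round(
    summary.founder_genome_equivalents, 3))
# Gene diversity is 1 minus the grand mean kinship of the living
# population; FGE counts how many unrelated founders would carry the
# same diversity.
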