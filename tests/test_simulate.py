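"""Synthetic pedigrees, gene dropping and genotype emission: structural
checks, Mendelian consistency, and the segregation-variance behaviour
that motivates genome-wide relatedness estimation."""

import numpy as np
import pytest
from scipy import stats as sps

from kincompare.filtering import parentage_check
from kincompare.pedigree import kinship_matrix, kinship_to_relatedness
from kincompare.simulate import (
    Chromosome,
    FounderPool,
    GenomeModel,
    SeqModel,
    dyad_tally,
    emit_depth_genotypes,
    emit_microsat_panel,
    full_sib_realized,
    gene_drop,
    human_like_map,
    random_founder_pool,
    simulate_family_groups,
    simulate_pedigree,
    snp_genome,
)


class TestSimulatePedigree:
    def test_smallest_family(self):
        sb = simulate_pedigree(2, 1, 1, 2, seed=1)
        assert len(sb) == 4
        tally = dyad_tally(sb)
        assert tally["full_sib"] == 1  # one sib pair among the 2 offspring
        assert tally["parent_offspring"] == 4

    def test_structure_multi_generation(self):
        sb = simulate_pedigree(8, 3, 3, (2, 4), seed=3)
        ids = set(sb.ids)
        for r in sb.records:
            for p in (r.sire, r.dam):
                assert p is None or p in ids
            assert r.id not in sb.ancestors(r.id)
        sb.topological_order()  # acyclic

    def test_deterministic_given_seed(self):
        a = simulate_pedigree(6, 2, 2, (1, 4), seed=9)
        b = simulate_pedigree(6, 2, 2, (1, 4), seed=9)
        assert [r for r in a.records] == [r for r in b.records]

    def test_no_opposite_sex_pair_fails(self):
        # a single offspring in generation 1 cannot form a breeding pair
        with pytest.raises(ValueError, match="opposite-sex|no offspring"):
            simulate_pedigree(2, 2, 1, 1, seed=0)

    def test_family_group_tally_matches_brute_force(self):
        sb = simulate_family_groups(8, (2, 5), seed=3)
        tally = dyad_tally(sb)
        # independent brute-force recount over all unordered pairs
        ids = sb.ids
        po = fs = 0
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = sb[ids[i]], sb[ids[j]]
                if a.id in (b.sire, b.dam) or b.id in (a.sire, a.dam):
                    po += 1
                elif (
                    a.sire is not None
                    and (a.sire, a.dam) == (b.sire, b.dam)
                ):
                    fs += 1
        assert tally["parent_offspring"] == po
        assert tally["full_sib"] == fs


class TestGeneDrop:
    def test_parent_offspring_exactly_half(self, trio_studbook):
        drop = gene_drop(trio_studbook, snp_genome(50, seed=1), seed=4)
        assert drop.realized_relatedness.loc("A", "C") == pytest.approx(0.5)
        assert drop.realized_relatedness.loc("B", "C") == pytest.approx(0.5)

    def test_self_relatedness_is_one_plus_inbreeding(self, family_studbook):
        drop = gene_drop(family_studbook, snp_genome(20, seed=1), seed=5)
        for i in ("A", "C", "D"):
            # non-inbred individuals
            assert drop.realized_relatedness.loc(i, i) == pytest.approx(1.0)
        # E is inbred: self-relatedness at least 1
        assert drop.realized_relatedness.loc("E", "E") >= 1.0

    def test_zero_length_chromosome_full_sibs_discrete(self, family_studbook):
        genome = GenomeModel((Chromosome("c0", 0.0, [0.0], ("snp0",)),))
        seen = set()
        for seed in range(30):
            drop = gene_drop(family_studbook, genome, seed=seed)
            r = drop.realized_relatedness.loc("C", "D")
            seen.add(round(r, 6))
        assert seen <= {0.0, 0.5, 1.0}
        assert len(seen) > 1  # actually segregates

    def test_reproducible_bit_for_bit(self, family_studbook):
        g = snp_genome(30, 2, seed=2)
        a = gene_drop(family_studbook, g, seed=11)
        b = gene_drop(family_studbook, g, seed=11)
        assert np.array_equal(a.ibd_labels, b.ibd_labels)
        assert np.array_equal(
            a.realized_relatedness.values, b.realized_relatedness.values
        )

    def test_empty_pedigree_raises(self):
        from kincompare.pedigree import Studbook

        with pytest.raises(ValueError):
            gene_drop(Studbook([]), snp_genome(5, seed=1), seed=0)

    def test_expected_realized_matches_pedigree(self, family_studbook):
        """Mean realized relatedness over replicate drops approaches the
        pedigree expectation for every dyad class."""
        genome = human_like_map()
        R_ped = kinship_to_relatedness(kinship_matrix(family_studbook))
        acc = {}
        n_rep = 60
        for seed in range(n_rep):
            drop = gene_drop(family_studbook, genome, seed=seed)
            for pair in [("A", "C"), ("C", "D"), ("A", "E"), ("C", "E")]:
                acc.setdefault(pair, []).append(
                    drop.realized_relatedness.loc(*pair)
                )
        for pair, vals in acc.items():
            # pedigree R is normalised by inbreeding; realized sharing is
            # additive (2f), so compare against 2 * kinship
            K = kinship_matrix(family_studbook)
            assert np.mean(vals) == pytest.approx(
                2 * K.loc(*pair), abs=0.05
            )


class TestFullSibVariance:
    def test_mean_half_and_positive_variance(self):
        r = full_sib_realized(600, human_like_map(), seed=21)
        assert r.mean() == pytest.approx(0.5, abs=0.01)
        assert r.var() > 0

    def test_variance_decreases_with_map_length(self):
        short = GenomeModel((Chromosome("c1", 1.0),))
        long = human_like_map()
        v_short = full_sib_realized(400, short, seed=1).var()
        v_long = full_sib_realized(400, long, seed=1).var()
        assert v_long < v_short


class TestMicrosatEmission:
    @pytest.fixture
    def drop_and_pool(self, family_studbook):
        genome = snp_genome(10, 8, n_chromosomes=4, seed=1)
        pool = random_founder_pool(genome, seed=2)
        return gene_drop(family_studbook, genome, seed=3), pool

    def test_error_free_is_mendelian(self, drop_and_pool):
        drop, pool = drop_and_pool
        gt = emit_microsat_panel(drop, pool, 0.0, 0.0, seed=4)
        trios = [("C", "A", "B"), ("D", "A", "B"), ("E", "C", "D")]
        verdicts = parentage_check(gt, trios, max_mismatch_loci=0)
        assert verdicts["pass"].all()
        assert (verdicts["n_mismatch_loci"] == 0).all()

    def test_allele_counts_bounded_by_configuration(self, drop_and_pool):
        drop, pool = drop_and_pool
        gt = emit_microsat_panel(drop, pool, 0.0, 0.0, seed=5)
        for l, name in enumerate(gt.loci):
            observed = set(gt.alleles[:, l, :].ravel()) - {-1}
            assert len(observed) <= len(pool.microsat_allele_freqs[name])

    def test_missing_fraction_within_binomial_ci(self, family_studbook):
        genome = snp_genome(0, 100, n_chromosomes=2, seed=6)
        pool = random_founder_pool(genome, seed=7)
        drop = gene_drop(family_studbook, genome, seed=8)
        gt = emit_microsat_panel(drop, pool, 0.0, 0.5, seed=9)
        n_calls = gt.n_individuals * gt.n_loci
        n_miss = int(gt.missing_mask().sum())
        lo, hi = sps.binom.interval(0.99, n_calls, 0.5)
        assert lo <= n_miss <= hi

    def test_rate_validation(self, drop_and_pool):
        drop, pool = drop_and_pool
        with pytest.raises(ValueError):
            emit_microsat_panel(drop, pool, error_rate=1.5)


class TestDepthGenotypes:
    @pytest.fixture
    def drop_and_pool(self, family_studbook):
        genome = snp_genome(400, 0, n_chromosomes=4, seed=11)
        pool = random_founder_pool(genome, seed=12)
        return gene_drop(family_studbook, genome, seed=13), pool

    def test_infinite_depth_recovers_truth(self, drop_and_pool):
        drop, pool = drop_and_pool
        vt = emit_depth_genotypes(
            drop, pool, SeqModel(mean_depth=10_000, dispersion=1e6,
                                 error_rate=0.0), seed=14
        )
        assert np.array_equal(
            vt.called_dosage().astype(int), vt.meta["true_dosage"]
        )

    def test_depth_one_heterozygote_never_called_het(self, drop_and_pool):
        drop, pool = drop_and_pool
        vt = emit_depth_genotypes(
            drop, pool, SeqModel(mean_depth=1.0, dispersion=1e6,
                                 error_rate=0.0), seed=15
        )
        d1_het = (vt.depth == 1) & (vt.meta["true_dosage"] == 1)
        called = vt.called_dosage()[d1_het]
        assert set(np.unique(called)) <= {0.0, 2.0}

    def test_read_dosage_unbiased_for_true_dosage(self, drop_and_pool):
        drop, pool = drop_and_pool
        vt = emit_depth_genotypes(
            drop, pool, SeqModel(mean_depth=4.0, error_rate=0.0), seed=16
        )
        x = vt.read_dosage()
        g = vt.meta["true_dosage"]
        for dosage in (0, 1, 2):
            mask = (g == dosage) & ~np.isnan(x)
            if mask.sum() > 200:
                se = np.nanstd(x[mask]) / np.sqrt(mask.sum())
                assert np.nanmean(x[mask]) == pytest.approx(
                    dosage, abs=max(4 * se, 0.02)
                )

    def test_depth_zero_is_missing(self, drop_and_pool):
        drop, pool = drop_and_pool
        vt = emit_depth_genotypes(
            drop, pool, SeqModel(mean_depth=1.0, dispersion=0.5), seed=17
        )
        assert np.all(vt.missing_mask() == (vt.depth == 0))


class TestModels:
    def test_chromosome_validation(self):
        with pytest.raises(ValueError):
            Chromosome("bad", 1.0, [1.5], ("x",))  # off-map locus
        with pytest.raises(ValueError):
            Chromosome("bad", -1.0)

    def test_founder_pool_validation(self):
        with pytest.raises(ValueError, match="2-4"):
            FounderPool(microsat_allele_freqs={"m": {0: 1.0}})
        with pytest.raises(ValueError, match="sum"):
            FounderPool(microsat_allele_freqs={"m": {0: 0.5, 1: 0.4}})

    def test_seq_model_depth_mean(self):
        rng = np.random.default_rng(1)
        d = SeqModel(mean_depth=25, dispersion=8).draw_depth(20_000, rng)
        assert d.mean() == pytest.approx(25, rel=0.05)
        assert d.var() > d.mean()  # overdispersed
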