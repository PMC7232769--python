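"""SNP retention rules, LD pruning, diversity statistics and
allele-mismatch parentage checks, each validated against brute-force
re-application of the rules in the test."""

import numpy as np
import pytest

from kincompare.filtering import (
    MeanDepthRule,
    SiteDepthRule,
    diversity_stats,
    filter_variants,
    ld_prune,
    microsat_diversity,
    parentage_check,
)
from kincompare.genotypes import GenotypeTable, VariantTable


def make_table(genos, qual=None, depth=None, chrom=None, pos=None):
    """(n, L) dosage codes -> biallelic VariantTable; -1 = missing."""
    g = np.asarray(genos)
    n, L = g.shape
    alleles = np.zeros((n, L, 2), dtype=np.int32)
    alleles[g == 1] = (0, 1)
    alleles[g == 2] = (1, 1)
    alleles[g == -1] = (-1, -1)
    return VariantTable(
        ids=[f"i{k}" for k in range(n)],
        loci=[f"s{k}" for k in range(L)],
        alleles=alleles,
        depth=None if depth is None else np.asarray(depth),
        qual=np.full(L, 99.0) if qual is None else np.asarray(qual, float),
        chrom=np.array(["1"] * L if chrom is None else chrom, dtype=object),
        pos=np.arange(1, L + 1) * 100 if pos is None else np.asarray(pos),
    )


class TestFilterVariants:
    def test_empty_table_passes_through(self):
        vt = make_table(np.zeros((3, 0), dtype=int).reshape(3, 0))
        assert filter_variants(vt).n_loci == 0

    def test_toy_sites_match_hand_applied_rules(self):
        # 6 individuals; columns engineered for MAF / QUAL / missingness
        genos = np.array(
            [
                [0, 1, 1, 1, -1, 1],
                [0, 1, 1, 1, 1, 1],
                [0, 1, 0, 1, 1, 0],
                [0, 1, 0, 0, 1, 0],
                [0, 1, 0, 0, 1, 0],
                [0, 0, 0, 0, 1, 0],
            ]
        )
        qual = [99, 99, 99, 15, 99, 99]
        vt = make_table(genos, qual=qual)
        kept = filter_variants(vt, maf_min=0.05, qual_min=20, max_missing=0.10)
        # brute-force re-application
        expected = []
        for l in range(6):
            col = genos[:, l]
            called = col[col >= 0]
            p = called.sum() / (2 * len(called))
            maf = min(p, 1 - p)
            miss = np.mean(col < 0)
            if maf > 0.05 and qual[l] > 20 and miss <= 0.10:
                expected.append(f"s{l}")
        assert kept.loci == expected
        assert "s0" not in kept.loci  # monomorphic: MAF 0
        assert "s3" not in kept.loci  # low QUAL
        assert "s4" not in kept.loci  # 1/6 missing > 10%

    def test_maf_exactly_at_threshold_removed(self):
        # 10 individuals, one het -> alt frequency exactly 0.05
        genos = np.zeros((10, 1), dtype=int)
        genos[0, 0] = 1
        vt = make_table(genos)
        assert filter_variants(vt, maf_min=0.05).n_loci == 0
        assert filter_variants(vt, maf_min=0.049).n_loci == 1

    def test_mean_depth_rule_strictly_greater(self):
        genos = np.tile([0, 1, 1, 2], (3, 1)).T.reshape(4, 3)
        genos = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0], [2, 1, 1]])
        depth = np.array(
            [[10, 11, 30], [10, 11, 30], [10, 11, 30], [10, 11, 30]]
        )
        vt = make_table(genos, depth=depth)
        kept = filter_variants(vt, depth_rule=MeanDepthRule(10.0))
        assert kept.loci == ["s1", "s2"]  # mean exactly 10 removed

    def test_site_depth_rule_min_max(self):
        genos = np.array([[1, 1, 1], [0, 1, 1], [1, 0, 1], [1, 1, 0]])
        depth = np.array(
            [[5, 4, 10], [9, 50, 10], [7, 50, 10], [5, 50, 201]]
        )
        vt = make_table(genos, depth=depth)
        kept = filter_variants(vt, depth_rule=SiteDepthRule(5, 200))
        assert kept.loci == ["s0"]

    def test_multiallelic_sites_removed(self):
        alleles = np.zeros((2, 2, 2), dtype=np.int32)
        alleles[0, 0] = (0, 2)  # third allele at locus 0
        alleles[0, 1] = (0, 1)
        alleles[1, 1] = (0, 1)
        vt = VariantTable(
            ids=["a", "b"], loci=["x", "y"], alleles=alleles,
            qual=np.array([99.0, 99.0]),
        )
        assert filter_variants(vt, maf_min=0.0).loci == ["y"]

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        genos = rng.integers(0, 3, size=(20, 50))
        genos[rng.random((20, 50)) < 0.05] = -1
        vt = make_table(genos, qual=rng.uniform(10, 60, 50))
        once = filter_variants(vt)
        twice = filter_variants(once)
        assert once.loci == twice.loci
        assert np.array_equal(once.alleles, twice.alleles)


def brute_force_prune(vt, r2_max, window):
    """Reference pruning: per-pair r^2 on complete data."""
    dos = vt.called_dosage()
    keep = []
    for j in range(vt.n_loci):
        drop = False
        for i in keep:
            if vt.chrom[i] != vt.chrom[j] or j - i >= window:
                continue
            x, y = dos[:, i], dos[:, j]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 2 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            if np.corrcoef(x[ok], y[ok])[0, 1] ** 2 > r2_max:
                drop = True
                break
        if not drop:
            keep.append(j)
    return [vt.loci[k] for k in keep]


class TestLdPrune:
    def test_single_site_retained(self):
        vt = make_table([[1], [0], [1]])
        assert ld_prune(vt).loci == ["s0"]

    def test_duplicated_site_keeps_first(self):
        genos = np.array([[0, 0], [1, 1], [2, 2], [1, 1]])
        vt = make_table(genos)
        assert ld_prune(vt, r2_max=0.6).loci == ["s0"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.integers(0, 3, size=(15, 20))
        # make some columns correlated copies of earlier ones
        for j in range(5, 20, 3):
            base[:, j] = base[:, j - 2]
            flip = rng.random(15) < 0.2
            base[flip, j] = rng.integers(0, 3, flip.sum())
        miss = rng.random(base.shape) < 0.05
        base[miss] = -1
        vt = make_table(base, chrom=["1"] * 12 + ["2"] * 8)
        got = ld_prune(vt, r2_max=0.6, window_sites=8).loci
        assert got == brute_force_prune(vt, 0.6, 8)

    def test_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(9)
        genos = rng.integers(0, 3, size=(25, 60))
        for j in range(10, 60, 5):
            genos[:, j] = genos[:, j - 1]
        vt = make_table(genos)
        pruned = ld_prune(vt, r2_max=0.6, window_sites=30)
        dos = pruned.called_dosage()
        for i in range(pruned.n_loci):
            for j in range(i + 1, pruned.n_loci):
                # indices within the window in the *original* table
                oi = int(pruned.loci[i][1:])
                oj = int(pruned.loci[j][1:])
                if oj - oi >= 30:
                    continue
                x, y = dos[:, i], dos[:, j]
                if np.std(x) == 0 or np.std(y) == 0:
                    continue
                assert np.corrcoef(x, y)[0, 1] ** 2 <= 0.6 + 1e-12


class TestDiversity:
    def test_all_het_site(self):
        vt = make_table(np.ones((8, 1), dtype=int))
        ds = diversity_stats(vt)
        assert ds.per_individual["ho"].tolist() == [1.0] * 8
        assert ds.per_site["he"].iloc[0] == pytest.approx(0.5)

    def test_pi_equals_hand_average_pairwise_difference(self):
        # 3 individuals, 1 site: genotypes 0/0, 0/1, 1/1 -> alleles
        # (0,0,0,1,1,1): pairwise diffs among 6 alleles: 9 of 15 pairs
        vt = make_table([[0], [1], [2]])
        ds = diversity_stats(vt)
        assert ds.per_site["pi"].iloc[0] == pytest.approx(9 / 15)

    def test_monomorphic_sites_excluded(self):
        vt = make_table([[0, 1], [0, 1], [0, 0]])
        ds = diversity_stats(vt)
        assert list(ds.per_site["locus"]) == ["s1"]

    def test_he_converges_to_2pq_with_sample_size(self):
        rng = np.random.default_rng(4)
        p = 0.3
        for n, tol in ((50, 0.08), (2000, 0.02)):
            genos = rng.binomial(2, p, size=(n, 1))
            vt = make_table(genos)
            ds = diversity_stats(vt)
            assert ds.per_site["he"].iloc[0] == pytest.approx(
                2 * p * (1 - p), abs=tol
            )


class TestMicrosatDiversity:
    def test_monomorphic_locus_flagged(self):
        alleles = np.zeros((5, 1, 2), dtype=np.int32)
        gt = GenotypeTable([f"i{k}" for k in range(5)], ["m0"], alleles)
        df = microsat_diversity(gt)
        assert df.loc[0, "n_alleles"] == 1
        assert df.loc[0, "he"] == 0.0
        assert bool(df.loc[0, "excluded"])

    def test_hand_computed_ho_he(self):
        # genotypes: (0,0), (0,1), (1,1), (0,1) -> 4 of 8 alleles are 0
        alleles = np.array(
            [[[0, 0]], [[0, 1]], [[1, 1]], [[0, 1]]], dtype=np.int32
        )
        gt = GenotypeTable(list("abcd"), ["m0"], alleles)
        df = microsat_diversity(gt)
        assert df.loc[0, "ho"] == pytest.approx(0.5)
        p0 = 4 / 8
        assert df.loc[0, "he"] == pytest.approx(1 - p0**2 - (1 - p0) ** 2)

    def test_low_amplification_flagged(self):
        alleles = np.full((6, 1, 2), -1, dtype=np.int32)
        alleles[0] = [[0, 1]]
        alleles[1] = [[0, 0]]
        gt = GenotypeTable([f"i{k}" for k in range(6)], ["m0"], alleles)
        df = microsat_diversity(gt)
        assert bool(df.loc[0, "low_amplification"])
        assert bool(df.loc[0, "excluded"])

    def test_zero_call_locus_raises(self):
        alleles = np.full((3, 1, 2), -1, dtype=np.int32)
        gt = GenotypeTable(list("abc"), ["m0"], alleles)
        with pytest.raises(ValueError):
            microsat_diversity(gt)


def ms_table(rows):
    """rows: list of per-individual list of (a, b) tuples."""
    arr = np.array(rows, dtype=np.int32)
    return GenotypeTable(
        [f"i{k}" for k in range(arr.shape[0])],
        [f"m{k}" for k in range(arr.shape[1])],
        arr,
    )


class TestParentage:
    def test_clean_trio_passes_with_zero_mismatches(self):
        gt = ms_table(
            [
                [(1, 2), (3, 3)],  # sire
                [(2, 3), (1, 2)],  # dam
                [(1, 3), (3, 1)],  # offspring: 1 from sire, 3 from... ok
            ]
        )
        df = parentage_check(gt, [("i2", "i0", "i1")])
        assert df.loc[0, "n_mismatch_loci"] == 0
        assert bool(df.loc[0, "pass"])

    def test_one_mismatching_locus_still_passes(self):
        gt = ms_table(
            [
                [(1, 1), (3, 3)],
                [(1, 1), (3, 3)],
                [(2, 2), (3, 3)],  # locus 0 impossible
            ]
        )
        df = parentage_check(gt, [("i2", "i0", "i1")], max_mismatch_loci=1)
        assert df.loc[0, "n_mismatch_loci"] == 1
        assert bool(df.loc[0, "pass"])

    def test_two_mismatching_loci_fail_with_brute_count(self):
        gt = ms_table(
            [
                [(1, 1), (3, 3), (5, 6)],
                [(1, 1), (3, 3), (5, 5)],
                [(2, 2), (4, 4), (5, 5)],
            ]
        )
        df = parentage_check(gt, [("i2", "i0", "i1")], max_mismatch_loci=1)
        # brute force: offspring shares no allele with either parent at
        # loci 0 and 1; locus 2 is compatible
        brute = 0
        for l in range(3):
            off = set(gt.alleles[2, l])
            s = set(gt.alleles[0, l])
            d = set(gt.alleles[1, l])
            if not (off & s) or not (off & d):
                brute += 1
        assert brute == 2
        assert df.loc[0, "n_mismatch_loci"] == 2
        assert not bool(df.loc[0, "pass"])

    def test_joint_assignment_incompatibility(self):
        # offspring 1/1 but sire can only give 1 and dam only 2: the
        # single-parent checks pass for the sire, fail jointly? here dam
        # shares no allele -> mismatch via single-parent rule; also test
        # a genuinely joint case: off (1,2), sire {1}, dam {1}: each
        # parent shares an allele with offspring, but allele 2 is
        # unexplained -> joint assignment impossible
        gt = ms_table([[(1, 1)], [(1, 1)], [(1, 2)]])
        df = parentage_check(gt, [("i2", "i0", "i1")], max_mismatch_loci=0)
        assert df.loc[0, "n_mismatch_loci"] == 1

    def test_missing_calls_skipped_and_all_missing_raises(self):
        gt = ms_table([[(1, 1), (-1, -1)], [(1, 2), (-1, -1)],
                       [(1, 2), (-1, -1)]])
        df = parentage_check(gt, [("i2", "i0", "i1")])
        assert df.loc[0, "n_loci_used"] == 1
        gt2 = ms_table([[(-1, -1)], [(1, 1)], [(1, 1)]])
        with pytest.raises(ValueError, match="no typed loci"):
            parentage_check(gt2, [("i2", "i0", "i1")])
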