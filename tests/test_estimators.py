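"""Relatedness estimators: hand-counted toys, grid-search oracles, and
parameter recovery on gene-dropped genotypes with known truth."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from kincompare.estimators import (
    AlleleFrequencies,
    allele_frequencies,
    estimate_dyadic_ml,
    estimate_king,
    estimate_kgd,
    estimate_kgd_naive_diagonal,
    estimate_rxy,
    ml_loglik,
    pair_state_likelihoods,
    scale_relatedness,
)
from kincompare.genotypes import GenotypeTable, VariantTable
from kincompare.matrices import RelatednessMatrix
from kincompare.simulate import (
    SeqModel,
    emit_depth_genotypes,
    gene_drop,
    random_founder_pool,
    simulate_family_groups,
    snp_genome,
)


def gtable(rows, loci=None):
    arr = np.array(rows, dtype=np.int32)
    return GenotypeTable(
        [f"i{k}" for k in range(arr.shape[0])],
        loci or [f"L{k}" for k in range(arr.shape[1])],
        arr,
    )


class TestAlleleFrequencies:
    def test_hand_counted(self):
        gt = gtable([[(0, 0)], [(0, 1)]])
        fr = allele_frequencies(gt)
        assert fr.freqs[0] == {0: 0.75, 1: 0.25}

    def test_missing_calls_excluded_from_denominator(self):
        gt = gtable([[(0, 0)], [(-1, -1)], [(1, 1)]])
        fr = allele_frequencies(gt)
        assert fr.freqs[0] == {0: 0.5, 1: 0.5}

    def test_estimates_within_binomial_ci_of_truth(self):
        rng = np.random.default_rng(2)
        p = 0.3
        n = 500
        draws = rng.binomial(2, p, size=(n, 1))
        arr = np.zeros((n, 1, 2), dtype=np.int32)
        arr[draws[:, 0] == 1, 0] = (0, 1)
        arr[draws[:, 0] == 2, 0] = (1, 1)
        gt = GenotypeTable([f"i{k}" for k in range(n)], ["x"], arr)
        fr = allele_frequencies(gt)
        lo, hi = sps.binom.interval(0.999, 2 * n, p)
        assert lo / (2 * n) <= fr.freqs[0][1] <= hi / (2 * n)

    def test_fully_missing_locus_raises(self):
        gt = gtable([[(-1, -1)], [(-1, -1)]])
        with pytest.raises(ValueError, match="non-missing"):
            allele_frequencies(gt)


class TestRxy:
    def test_identical_homozygous_genotypes_give_one(self):
        gt = gtable([[(2, 2), (5, 5), (1, 1)], [(2, 2), (5, 5), (1, 1)]])
        fr = AlleleFrequencies(
            list(gt.loci),
            [{2: 0.5, 3: 0.5}, {5: 0.25, 6: 0.75}, {1: 0.6, 0: 0.4}],
        )
        est = estimate_rxy(gt, fr)
        assert est.loc("i0", "i1") == pytest.approx(1.0)

    def test_unrelated_panel_mean_near_zero(self):
        rng = np.random.default_rng(7)
        n, L = 40, 400
        p = rng.uniform(0.2, 0.8, L)
        dos = rng.binomial(2, p, size=(n, L))
        arr = np.zeros((n, L, 2), dtype=np.int32)
        arr[dos == 1] = (0, 1)
        arr[dos == 2] = (1, 1)
        gt = GenotypeTable([f"i{k}" for k in range(n)],
                           [f"L{k}" for k in range(L)], arr)
        fr = AlleleFrequencies.from_alt([f"L{k}" for k in range(L)], p)
        est = estimate_rxy(gt, fr)
        off = est.matrix.offdiag()
        assert abs(np.mean(off)) < 0.02

    def test_symmetry_and_locus_order_invariance(self):
        rng = np.random.default_rng(8)
        arr = rng.integers(0, 2, size=(5, 12, 2)).astype(np.int32)
        gt = GenotypeTable(list("abcde"), [f"L{k}" for k in range(12)], arr)
        est = estimate_rxy(gt)
        assert est.matrix.is_symmetric()
        perm = rng.permutation(12)
        gt2 = gt.subset_loci(perm)
        est2 = estimate_rxy(gt2)
        assert np.allclose(est.values, est2.values, equal_nan=True)

    def test_no_cotyped_loci_is_nan(self):
        gt = gtable([[(0, 0), (-1, -1)], [(-1, -1), (1, 1)]])
        est = estimate_rxy(gt)
        assert np.isnan(est.loc("i0", "i1"))
        assert est.pair_loci[0, 1] == 0


class TestKing:
    def test_duplicated_individual_is_one(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(1, 60))
        arr = np.zeros((2, 60, 2), dtype=np.int32)
        for i in range(2):
            arr[i][dos[0] == 1] = (0, 1)
            arr[i][dos[0] == 2] = (1, 1)
        gt = GenotypeTable(["a", "b"], [f"L{k}" for k in range(60)], arr)
        est = estimate_king(gt)
        assert est.loc("a", "b") == pytest.approx(1.0)

    def test_five_locus_hand_count(self):
        # dosages: i0 = [1,1,0,2,1], i1 = [1,0,2,2,1]
        gt = gtable(
            [
                [(0, 1), (0, 1), (0, 0), (1, 1), (0, 1)],
                [(0, 1), (0, 0), (1, 1), (1, 1), (0, 1)],
            ]
        )
        est = estimate_king(gt)
        # N_het,het = 2 (loci 0, 4); opposing hom = 1 (locus 2);
        # N_het,i = 3, N_het,j = 2 -> phi = (2 - 2) / 5 = 0
        assert est.loc("i0", "i1") == pytest.approx(0.0)

    def test_requires_biallelic(self):
        gt = gtable([[(0, 2)], [(1, 1)]])
        with pytest.raises(ValueError, match="biallelic"):
            estimate_king(gt)

    def test_no_het_pair_is_nan(self):
        gt = gtable([[(0, 0), (1, 1)], [(0, 0), (1, 1)]])
        est = estimate_king(gt)
        assert np.isnan(est.loc("i0", "i1"))


def simplex_grid(step, k=3):
    """All probability vectors of length k on a grid of the given step."""
    n = round(1 / step)
    for cuts in itertools.combinations_with_replacement(range(n + 1), k - 1):
        v = []
        prev = 0
        for c in cuts:
            v.append((c - prev) * step)
            prev = c
        v.append((n - prev) * step)
        yield np.array(v)


class TestDyadicML:
    def test_unrelated_pair_recovers_state_nine(self):
        rng = np.random.default_rng(5)
        L = 300
        p = rng.uniform(0.3, 0.7, L)
        arr = np.zeros((2, L, 2), dtype=np.int32)
        for i in range(2):
            dos = rng.binomial(2, p)
            arr[i][dos == 1] = (0, 1)
            arr[i][dos == 2] = (1, 1)
        loci = [f"L{k}" for k in range(L)]
        gt = GenotypeTable(["a", "b"], loci, arr)
        fr = AlleleFrequencies.from_alt(loci, p)
        est = estimate_dyadic_ml(gt, fr, pairs=[("a", "b")])
        delta = est.extras["delta"][("a", "b")]
        assert delta[8] > 0.9
        assert abs(est.loc("a", "b")) < 0.05

    @pytest.mark.parametrize("seed", [0, 1])
    def test_noninbred_ml_matches_grid_search(self, seed):
        """3-locus toy pair: EM solution vs dense simplex grid (step 0.02)
        over the non-inbred states."""
        rng = np.random.default_rng(seed)
        gt = gtable(
            [
                [(0, 1), (1, 1), (0, 0)],
                [(0, 1), (0, 1), (0, 1)],
            ]
        )
        p = rng.uniform(0.3, 0.7, 3)
        fr = AlleleFrequencies.from_alt(["L0", "L1", "L2"], p)
        est = estimate_dyadic_ml(
            gt, fr, pairs=[("i0", "i1")], allow_inbreeding=False
        )
        delta = est.extras["delta"][("i0", "i1")]
        T = pair_state_likelihoods(gt.alleles[0], gt.alleles[1], fr)
        T3 = T[:, 6:]
        best_ll, best_w = -np.inf, None
        for w in simplex_grid(0.02, k=3):
            ll = ml_loglik(T3, w)
            if ll > best_ll:
                best_ll, best_w = ll, w
        em_ll = ml_loglik(T3, delta[6:])
        assert em_ll >= best_ll - 1e-9  # EM at least as good as the grid
        # and the implied relatedness agrees to grid resolution
        r_grid = 2 * (0.5 * best_w[0] + 0.25 * best_w[1])
        assert est.loc("i0", "i1") == pytest.approx(r_grid, abs=0.03)

    def test_full_simplex_ml_matches_coarse_grid(self):
        gt = gtable([[(0, 0), (0, 1), (1, 1)], [(0, 0), (0, 1), (0, 1)]])
        fr = AlleleFrequencies.from_alt(["L0", "L1", "L2"], [0.4, 0.5, 0.6])
        est = estimate_dyadic_ml(gt, fr, pairs=[("i0", "i1")])
        delta = est.extras["delta"][("i0", "i1")]
        T = pair_state_likelihoods(gt.alleles[0], gt.alleles[1], fr)
        best_ll = max(ml_loglik(T, w) for w in simplex_grid(0.125, k=9))
        # EM converges to the global optimum of this concave objective;
        # allow its stopping-rule precision when comparing with the grid
        assert ml_loglik(T, delta) >= best_ll - 1e-5

    def test_tracks_inbred_relatedness(self, family_studbook):
        genome = snp_genome(600, 0, n_chromosomes=6, seed=1)
        pool = random_founder_pool(genome, seed=2)
        drop = gene_drop(family_studbook, genome, seed=3)
        vt = emit_depth_genotypes(
            drop, pool, SeqModel(mean_depth=1000, dispersion=1e6,
                                 error_rate=0.0), seed=4
        )
        loci = list(vt.loci)
        fr = AlleleFrequencies.from_alt(
            loci, np.array([pool.snp_allele_freqs[l] for l in loci])
        )
        # C-E: parent-offspring with E inbred; realized 2f(C,E) = 0.75
        est = estimate_dyadic_ml(vt, fr, pairs=[("C", "E")])
        truth = drop.realized_relatedness.loc("C", "E")
        assert est.loc("C", "E") == pytest.approx(truth, abs=0.1)


@pytest.fixture(scope="module")
def dropped():
    sb = simulate_family_groups(4, 3, seed=10)
    genome = snp_genome(2000, 0, n_chromosomes=8, seed=11)
    pool = random_founder_pool(genome, seed=12)
    drop = gene_drop(sb, genome, seed=13)
    loci = list(pool.snp_allele_freqs)
    fr = AlleleFrequencies.from_alt(
        loci, np.array(list(pool.snp_allele_freqs.values()))
    )
    return sb, drop, pool, fr


class TestKgd:
    def test_high_depth_unrelated_diag_one_offdiag_zero(self, dropped):
        sb, drop, pool, fr = dropped
        vt = emit_depth_genotypes(
            drop, pool, SeqModel(mean_depth=200, error_rate=0.0), seed=14
        )
        founders = [r.id for r in sb.records if r.sire is None]
        est = estimate_kgd(vt, fr)
        sub = est.matrix.reindex(founders)
        assert np.allclose(np.diag(sub.values), 1.0, atol=0.1)
        off = sub.offdiag()
        assert abs(off.mean()) < 0.05

    def test_diagonal_unbiased_at_low_depth(self, dropped):
        sb, drop, pool, fr = dropped
        founders = [r.id for r in sb.records if r.sire is None]
        diags = {}
        for depth, seed in ((2.0, 15), (100.0, 16)):
            vt = emit_depth_genotypes(
                drop, pool, SeqModel(mean_depth=depth, error_rate=0.0),
                seed=seed,
            )
            est = estimate_kgd(vt, fr)
            diags[depth] = np.mean(
                [est.loc(i, i) for i in founders]
            )
        assert diags[2.0] == pytest.approx(1.0, abs=0.05)
        assert diags[100.0] == pytest.approx(1.0, abs=0.05)

    def test_naive_diagonal_inflated_at_low_depth(self, dropped):
        sb, drop, pool, fr = dropped
        vt = emit_depth_genotypes(
            drop, pool, SeqModel(mean_depth=2.0, error_rate=0.0), seed=17
        )
        naive = estimate_kgd_naive_diagonal(vt, fr)
        assert np.nanmean(naive) > 1.2

    def test_po_scaled_closer_to_half_than_naive_dosage_grm(self, dropped):
        sb, drop, pool, fr = dropped
        vt = emit_depth_genotypes(
            drop, pool, SeqModel(mean_depth=5.0, error_rate=0.0), seed=18
        )
        po = []
        for r in sb.records:
            if r.sire is not None:
                po += [(r.sire, r.id), (r.dam, r.id)]
        est = scale_relatedness(estimate_kgd(vt, fr))
        scaled_mean = np.mean([est.loc(a, b) for a, b in po])
        # naive comparison: same numerator but scaled by the *naive*
        # (depth-inflated) diagonal
        raw = estimate_kgd(vt, fr)
        naive_diag = estimate_kgd_naive_diagonal(vt, fr)
        d = 1 / np.sqrt(naive_diag)
        naive_scaled = raw.values * np.outer(d, d)
        M = RelatednessMatrix(raw.ids, naive_scaled)
        naive_mean = np.mean([M.loc(a, b) for a, b in po])
        assert abs(scaled_mean - 0.5) < abs(naive_mean - 0.5)

    def test_requires_read_counts(self):
        gt = gtable([[(0, 1)], [(1, 1)]])
        with pytest.raises(ValueError, match="depth"):
            estimate_kgd(gt)


class TestScaleRelatedness:
    def test_identity_unchanged(self):
        from kincompare.estimators import EstimatedRelatedness

        est = EstimatedRelatedness(
            RelatednessMatrix(["a", "b"], np.eye(2)), "x", np.ones((2, 2))
        )
        out = scale_relatedness(est)
        assert np.allclose(out.values, np.eye(2))

    def test_hand_evaluated_two_by_two(self):
        from kincompare.estimators import EstimatedRelatedness

        est = EstimatedRelatedness(
            RelatednessMatrix(["a", "b"], np.array([[2.0, 1.0], [1.0, 0.5]])),
            "x",
            np.ones((2, 2)),
        )
        out = scale_relatedness(est)
        assert np.allclose(out.values, np.ones((2, 2)))

    def test_unit_diagonal_for_random_positive_diagonal(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(6, 6))
        M = A @ A.T + 6 * np.eye(6)
        from kincompare.estimators import EstimatedRelatedness

        est = EstimatedRelatedness(
            RelatednessMatrix([f"i{k}" for k in range(6)], M), "x",
            np.ones((6, 6)),
        )
        out = scale_relatedness(est)
        assert np.all(np.diag(out.values) == 1.0)
        assert out.matrix.is_symmetric()

    def test_nonpositive_diagonal_rejected(self):
        from kincompare.estimators import EstimatedRelatedness

        est = EstimatedRelatedness(
            RelatednessMatrix(["a", "b"], np.array([[0.0, 0.1], [0.1, 1.0]])),
            "x",
            np.ones((2, 2)),
        )
        with pytest.raises(ValueError, match="scale"):
            scale_relatedness(est)


class TestCrossEstimatorConcordance:
    def test_estimators_positively_correlated_on_simulated_data(self):
        sb = simulate_family_groups(5, 3, seed=20)
        genome = snp_genome(1500, 0, n_chromosomes=6, seed=21)
        pool = random_founder_pool(genome, seed=22)
        drop = gene_drop(sb, genome, seed=23)
        vt = emit_depth_genotypes(
            drop, pool, SeqModel(mean_depth=25), seed=24
        )
        loci = list(vt.loci)
        fr = AlleleFrequencies.from_alt(
            loci, np.array([pool.snp_allele_freqs[l] for l in loci])
        )
        ests = {
            "kgd": scale_relatedness(estimate_kgd(vt, fr)).matrix.offdiag(),
            "king": estimate_king(vt).matrix.offdiag(),
            "rxy": estimate_rxy(vt, fr).matrix.offdiag(),
        }
        names = list(ests)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = np.corrcoef(ests[names[i]], ests[names[j]])[0, 1]
                assert r > 0.7, (names[i], names[j], r)
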