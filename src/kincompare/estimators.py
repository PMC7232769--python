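"""Marker-based relatedness estimators.

Four estimators spanning the microsatellite and SNP toolkits of
conservation genetics, all returning a symmetric id-labeled matrix:

``estimate_rxy``
    Frequency-corrected allele-sharing similarity (the classic
    similarity-index family): per locus the presence-based similarity
    ``S`` between the two genotypes is compared with its expectation
    ``s_bar`` between unrelated individuals, and
    ``r = sum(S - s_bar) / sum(1 - s_bar)`` over co-typed loci.

``estimate_king``
    The within-family robust kinship estimator built on heterozygote
    concordance and opposing homozygotes:
    ``phi = (N_het,het - 2 N_opp) / (N_het,i + N_het,j)``, ``r = 2 phi``.

``estimate_dyadic_ml``
    Maximum likelihood over the nine condensed identity coefficients
    (the Jacquard simplex), which makes it inbreeding-aware.  The
    per-locus likelihood is linear in the coefficient vector, so the
    log-likelihood is concave over the simplex and is maximised globally
    by an EM iteration on the mixture weights.

``estimate_kgd``
    A genomic relationship matrix on read-count dosages ``x = 2k/d``
    that remains unbiased at low sequencing depth: off-diagonals need no
    correction (reads of different individuals are independent), while
    the diagonal replaces ``x^2`` with the depth-debiased
    ``x^2 - x(2-x)/(d-1)`` so that ``E[r_ii] = 1 + F_i``.

``scale_relatedness`` applies the diagonal standardisation
``MS = D MO D`` with ``D = diag(MO)^{-1/2}``, making self-relatedness
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import GenotypeTable
from .matrices import RelatednessMatrix

__all__ = [
    "AlleleFrequencies",
    "allele_frequencies",
    "EstimatedRelatedness",
    "estimate_rxy",
    "estimate_king",
    "estimate_dyadic_ml",
    "estimate_kgd",
    "scale_relatedness",
]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencies:
    loci: list[str]
    freqs: list[dict[int, float]]  # per locus: allele -> frequency

    def __post_init__(self) -> None:
        for name, fr in zip(self.loci, self.freqs):
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {name} do not sum to 1")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def matrix(self) -> np.ndarray:
        """(L, A) frequency lookup, A = max allele label + 1."""
        amax = max((max(fr) for fr in self.freqs), default=0)
        F = np.zeros((len(self.loci), amax + 1))
        for l, fr in enumerate(self.freqs):
            for a, p in fr.items():
                F[l, a] = p
        return F

    def alt(self) -> np.ndarray:
        """(L,) alternate-allele (label 1) frequency; biallelic tables."""
        return np.array([fr.get(1, 0.0) for fr in self.freqs])

    @classmethod
    def from_alt(cls, loci: Sequence[str], p: np.ndarray) -> "AlleleFrequencies":
        return cls(
            list(loci),
            [{0: float(1.0 - x), 1: float(x)} for x in np.asarray(p)],
        )


def allele_frequencies(genotypes: GenotypeTable) -> AlleleFrequencies:
    """Empirical allele frequencies over non-missing calls, per locus."""
    if genotypes.n_loci == 0:
        raise ValueError("empty genotype table")
    freqs: list[dict[int, float]] = []
    for l, name in enumerate(genotypes.loci):
        calls = genotypes.alleles[:, l, :].ravel()
        calls = calls[calls >= 0]
        if calls.size == 0:
            raise ValueError(f"locus {name} has no non-missing calls")
        vals, counts = np.unique(calls, return_counts=True)
        tot = counts.sum()
        freqs.append({int(a): c / tot for a, c in zip(vals, counts)})
    return AlleleFrequencies(list(genotypes.loci), freqs)


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class EstimatedRelatedness:
    matrix: RelatednessMatrix
    estimator: str
    pair_loci: np.ndarray  # (n, n) co-typed locus counts
    extras: dict = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return self.matrix.ids

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values

    def loc(self, a: str, b: str) -> float:
        return self.matrix.loc(a, b)


def _pair_indices(
    n: int, ids: list[str], pairs: Sequence[tuple[str, str]] | None
) -> list[tuple[int, int]]:
    if pairs is None:
        return [(i, j) for i in range(n) for j in range(i, n)]
    pos = {x: k for k, x in enumerate(ids)}
    return [(pos[str(a)], pos[str(b)]) for a, b in pairs]


# ---------------------------------------------------------------------------
# similarity-index estimator (r_xy)
# ---------------------------------------------------------------------------

def _presence_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(L,) Lynch presence similarity between genotype arrays (L, 2)."""
    a_in_b = (a[:, :, None] == b[:, None, :]).any(axis=2)  # (L, 2)
    b_in_a = (b[:, :, None] == a[:, None, :]).any(axis=2)
    return 0.5 * (a_in_b.mean(axis=1) + b_in_a.mean(axis=1))


def _expected_similarity(freqs: AlleleFrequencies) -> np.ndarray:
    """(L,) expected presence similarity of two unrelated individuals."""
    out = np.empty(freqs.n_loci)
    for l, fr in enumerate(freqs.freqs):
        alleles = sorted(fr)
        p = np.array([fr[a] for a in alleles])
        k = len(alleles)
        # enumerate unordered genotypes with HWE probabilities
        gts = []
        probs = []
        for i in range(k):
            for j in range(i, k):
                gts.append((alleles[i], alleles[j]))
                probs.append(p[i] ** 2 if i == j else 2 * p[i] * p[j])
        gts_arr = np.array(gts)
        probs_arr = np.array(probs)
        G = len(gts)
        s = 0.0
        for gi in range(G):
            a = gts_arr[gi][None, :].repeat(G, axis=0)
            b = gts_arr
            sim = _presence_similarity(a, b)
            s += probs_arr[gi] * float(np.sum(probs_arr * sim))
        out[l] = s
    return out


def estimate_rxy(
    genotypes: GenotypeTable,
    freqs: AlleleFrequencies | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> EstimatedRelatedness:
    """Frequency-corrected similarity-index relatedness.

    ``r = sum_l (S_l - s_bar_l) / sum_l (1 - s_bar_l)`` over co-typed
    loci; a pair with no co-typed loci is reported as NaN.
    """
    freqs = freqs or allele_frequencies(genotypes)
    sbar = _expected_similarity(freqs)
    n = genotypes.n_individuals
    miss = genotypes.missing_mask()
    R = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=np.int64)
    for i, j in _pair_indices(n, genotypes.ids, pairs):
        ok = ~(miss[i] | miss[j])
        counts[i, j] = counts[j, i] = int(ok.sum())
        if not ok.any():
            continue
        S = _presence_similarity(
            genotypes.alleles[i][ok], genotypes.alleles[j][ok]
        )
        denom = float(np.sum(1.0 - sbar[ok]))
        if denom <= 0:
            continue
        r = float(np.sum(S - sbar[ok])) / denom
        R[i, j] = R[j, i] = r
    return EstimatedRelatedness(
        RelatednessMatrix(genotypes.ids, R, {"estimator": "rxy"}),
        "rxy",
        counts,
    )


# ---------------------------------------------------------------------------
# KING
# ---------------------------------------------------------------------------

def estimate_king(
    genotypes: GenotypeTable,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> EstimatedRelatedness:
    """Robust kinship from heterozygote concordance and opposing homozygotes.

    Requires a biallelic table.  A pair with no heterozygous sites in
    either member is reported as NaN.
    """
    if not genotypes.is_biallelic():
        raise ValueError("KING requires a biallelic genotype table")
    d = genotypes.called_dosage()  # NaN at missing
    n = genotypes.n_individuals
    R = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=np.int64)
    for i, j in _pair_indices(n, genotypes.ids, pairs):
        ok = ~(np.isnan(d[i]) | np.isnan(d[j]))
        counts[i, j] = counts[j, i] = int(ok.sum())
        di, dj = d[i][ok], d[j][ok]
        het_i = di == 1
        het_j = dj == 1
        denom = het_i.sum() + het_j.sum()
        if denom == 0:
            continue
        n_hh = int(np.sum(het_i & het_j))
        n_opp = int(np.sum(np.abs(di - dj) == 2))
        phi = (n_hh - 2.0 * n_opp) / denom
        R[i, j] = R[j, i] = 2.0 * phi
    return EstimatedRelatedness(
        RelatednessMatrix(genotypes.ids, R, {"estimator": "king"}),
        "king",
        counts,
    )


# ---------------------------------------------------------------------------
# dyadic maximum likelihood on the Jacquard simplex
# ---------------------------------------------------------------------------

# the nine condensed identity states as partitions of the four allele
# slots (a1, a2, b1, b2); orderings of each unordered genotype are summed
# over, which covers the mirror configurations of states 3, 5 and 8
_PARTITIONS: list[tuple[tuple[int, ...], ...]] = [
    ((0, 1, 2, 3),),
    ((0, 1), (2, 3)),
    ((0, 1, 2), (3,)),
    ((0, 1), (2,), (3,)),
    ((0, 2, 3), (1,)),
    ((2, 3), (0,), (1,)),
    ((0, 2), (1, 3)),
    ((0, 2), (1,), (3,)),
    ((0,), (1,), (2,), (3,)),
]


def pair_state_likelihoods(
    ga: np.ndarray, gb: np.ndarray, freqs: AlleleFrequencies
) -> np.ndarray:
    """(L, 9) P(observed genotype pair | condensed state) per locus.

    ``ga``/``gb`` are (L, 2) allele arrays (no missing entries).
    """
    F = freqs.matrix()  # (L, A)
    L = ga.shape[0]
    T = np.zeros((L, 9))
    a_orders = [(0, 1), (1, 0)]
    het_a = ga[:, 0] != ga[:, 1]
    het_b = gb[:, 0] != gb[:, 1]
    for oa in a_orders:
        for ob in a_orders:
            # skip duplicate orderings of homozygotes via weighting below
            slots = [
                ga[:, oa[0]], ga[:, oa[1]], gb[:, ob[0]], gb[:, ob[1]]
            ]
            w = np.ones(L)
            if oa == (1, 0):
                w = w * het_a
            if ob == (1, 0):
                w = w * het_b
            lidx = np.arange(L)
            for s, part in enumerate(_PARTITIONS):
                consistent = np.ones(L, dtype=bool)
                prob = np.ones(L)
                for cls in part:
                    first = slots[cls[0]]
                    for other in cls[1:]:
                        consistent &= slots[other] == first
                    prob = prob * F[lidx, first]
                T[:, s] += w * np.where(consistent, prob, 0.0)
    return T


def _hwe_pair_prob(T: np.ndarray) -> np.ndarray:
    """(L,) P(genotype pair) for unrelated non-inbred pair = state-9 column."""
    return T[:, 8]


def estimate_dyadic_ml(
    genotypes: GenotypeTable,
    freqs: AlleleFrequencies | None = None,
    error_rate: float = 0.0,
    pairs: Sequence[tuple[str, str]] | None = None,
    allow_inbreeding: bool = True,
    max_iter: int = 5000,
    tol: float = 1e-12,
) -> EstimatedRelatedness:
    """Likelihood-based relatedness over the nine-state identity simplex.

    Maximises ``prod_l sum_s Delta_s P(G_pair | state s)`` by EM (the
    objective is concave in Delta, so EM attains the global maximum).
    With ``allow_inbreeding=False`` the search is restricted to states
    7-9, the non-inbred submodel.  ``error_rate`` mixes each per-locus
    likelihood with the unrelated-pair genotype probability, a blunt but
    monotone model of genotyping error.  Per-pair Delta vectors are
    returned in ``extras["delta"]``.
    """
    freqs = freqs or allele_frequencies(genotypes)
    n = genotypes.n_individuals
    miss = genotypes.missing_mask()
    R = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=np.int64)
    deltas: dict[tuple[str, str], np.ndarray] = {}
    active = (
        np.arange(9) if allow_inbreeding else np.array([6, 7, 8])
    )
    for i, j in _pair_indices(n, genotypes.ids, pairs):
        ok = ~(miss[i] | miss[j])
        counts[i, j] = counts[j, i] = int(ok.sum())
        if not ok.any():
            continue
        sub = freqs_subset(freqs, ok)
        T = pair_state_likelihoods(
            genotypes.alleles[i][ok], genotypes.alleles[j][ok], sub
        )
        if error_rate > 0:
            U = _hwe_pair_prob(T)
            T = (1.0 - error_rate) * T + error_rate * U[:, None]
        Ta = T[:, active]
        delta_a = _em_simplex(Ta, max_iter=max_iter, tol=tol)
        delta = np.zeros(9)
        delta[active] = delta_a
        deltas[(genotypes.ids[i], genotypes.ids[j])] = delta
        f = delta[0] + 0.5 * (delta[2] + delta[4] + delta[6]) + 0.25 * delta[7]
        R[i, j] = R[j, i] = 2.0 * f
    return EstimatedRelatedness(
        RelatednessMatrix(genotypes.ids, R, {"estimator": "dyadic_ml"}),
        "dyadic_ml",
        counts,
        {"delta": deltas},
    )


def freqs_subset(freqs: AlleleFrequencies, mask: np.ndarray) -> AlleleFrequencies:
    idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
    return AlleleFrequencies(
        [freqs.loci[k] for k in idx], [freqs.freqs[k] for k in idx]
    )


def _em_simplex(T: np.ndarray, max_iter: int = 5000, tol: float = 1e-12) -> np.ndarray:
    """Maximise sum_l log(T_l . w) over the probability simplex by EM."""
    L, S = T.shape
    w = np.full(S, 1.0 / S)
    prev = -np.inf
    for _ in range(max_iter):
        lik = T @ w  # (L,)
        lik = np.maximum(lik, 1e-300)
        ll = float(np.sum(np.log(lik)))
        resp = (T * w[None, :]) / lik[:, None]
        w = resp.mean(axis=0)
        w = np.maximum(w, 0.0)
        w /= w.sum()
        if ll - prev < tol and ll >= prev:
            break
        prev = ll
    return w


def ml_loglik(T: np.ndarray, delta: np.ndarray) -> float:
    """Log-likelihood of a condensed-coefficient vector for a state table."""
    lik = np.maximum(T @ delta, 1e-300)
    return float(np.sum(np.log(lik)))


# ---------------------------------------------------------------------------
# depth-aware GRM (KGD)
# ---------------------------------------------------------------------------

def estimate_kgd(
    depth_genotypes: GenotypeTable,
    freqs: AlleleFrequencies | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> EstimatedRelatedness:
    """Depth-aware genomic relationship matrix on dosages ``x = 2k/d``.

    Off-diagonal: ``r_ij = sum_l (x_il - 2p_l)(x_jl - 2p_l) /
    (2 sum_l p_l(1-p_l))`` over co-observed loci -- unbiased without any
    depth correction because the read-sampling noise of different
    individuals is independent.  Diagonal: ``x^2`` is replaced by
    ``x^2 - x(2-x)/(d-1)`` (loci at depth 1 are excluded) so the expected
    self-relatedness is ``1 + F`` at any depth.
    """
    x = depth_genotypes.read_dosage()  # (n, L), NaN at depth 0
    d = depth_genotypes.depth
    if freqs is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(x, axis=0) / 2.0
    else:
        p = freqs.alt()
    n, L = x.shape
    obs = ~np.isnan(x)
    z = np.where(obs, x - 2.0 * p[None, :], 0.0)
    pq = p * (1.0 - p)
    num = z @ z.T
    denom = 2.0 * (obs.astype(float) * pq[None, :]) @ obs.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(denom > 0, num / denom, np.nan)
    # diagonal with depth-debiased squared dosage
    for i in range(n):
        ok = obs[i] & (d[i] >= 2)
        if not ok.any():
            R[i, i] = np.nan
            continue
        xi = x[i][ok]
        di = d[i][ok].astype(float)
        x2 = xi**2 - xi * (2.0 - xi) / (di - 1.0)
        pi = p[ok]
        sq = x2 - 4.0 * pi * xi + 4.0 * pi**2
        dd = 2.0 * float(np.sum(pi * (1.0 - pi)))
        R[i, i] = float(np.sum(sq)) / dd if dd > 0 else np.nan
    counts = (obs.astype(np.int64)) @ obs.T.astype(np.int64)
    return EstimatedRelatedness(
        RelatednessMatrix(depth_genotypes.ids, R, {"estimator": "kgd"}),
        "kgd",
        counts,
    )


def estimate_kgd_naive_diagonal(
    depth_genotypes: GenotypeTable,
    freqs: AlleleFrequencies | None = None,
) -> np.ndarray:
    """Self-relatedness without the depth correction (for comparison).

    Uses raw ``(x - 2p)^2`` on the diagonal; upwardly biased at low depth.
    """
    x = depth_genotypes.read_dosage()
    if freqs is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(x, axis=0) / 2.0
    else:
        p = freqs.alt()
    obs = ~np.isnan(x)
    out = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        ok = obs[i]
        zi = x[i][ok] - 2.0 * p[ok]
        dd = 2.0 * float(np.sum(p[ok] * (1.0 - p[ok])))
        out[i] = float(np.sum(zi**2)) / dd if dd > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# diagonal standardisation
# ---------------------------------------------------------------------------

def scale_relatedness(MO: EstimatedRelatedness) -> EstimatedRelatedness:
    """``MS = D MO D`` with ``D = diag(MO)^{-1/2}``: unit self-relatedness.

    Raises on a non-positive diagonal entry.
    """
    diag = MO.matrix.diagonal()
    if np.any(~np.isfinite(diag)) or np.any(diag <= 0):
        bad = MO.ids[int(np.argmin(np.nan_to_num(diag, nan=-np.inf)))]
        raise ValueError(
            f"non-positive self-relatedness for {bad!r}; cannot scale"
        )
    d = 1.0 / np.sqrt(diag)
    MS = MO.values * np.outer(d, d)
    np.fill_diagonal(MS, 1.0)
    meta = dict(MO.matrix.meta)
    meta["scaled"] = True
    return EstimatedRelatedness(
        RelatednessMatrix(MO.ids, MS, meta),
        MO.estimator + "_scaled",
        MO.pair_loci.copy(),
        dict(MO.extras),
    )
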