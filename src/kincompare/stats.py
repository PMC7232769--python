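"""Matrix-comparison statistics.

Mantel permutation tests and off-diagonal Pearson correlations compare
relatedness matrices from different data sources; a Kruskal-Wallis test
with Bonferroni correction compares distributions of mate-suitability
scores between approaches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._rng import child_rng
from .matrices import LabeledMatrix

__all__ = [
    "MantelResult",
    "mantel",
    "mantel_exact",
    "pearson_offdiag",
    "kruskal_bonferroni",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int


def _as_array(m) -> np.ndarray:
    if isinstance(m, LabeledMatrix):
        return m.values
    return np.asarray(m, dtype=float)


def _check_pair(A: np.ndarray, B: np.ndarray) -> None:
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")


def mantel(
    matA, matB, n_perm: int = 1000, seed: int = 0
) -> MantelResult:
    """One-sided Mantel test of matrix association.

    The statistic is the Pearson correlation of the off-diagonal upper
    triangles; the null distribution permutes the rows and columns of the
    second matrix simultaneously.  The p-value uses the add-one rule
    ``p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)`` and so is never 0.
    """
    A, B = _as_array(matA), _as_array(matB)
    _check_pair(A, B)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    va = A[iu]
    if np.std(va) == 0 or np.std(B[iu]) == 0:
        raise ValueError("constant off-diagonal entries: r undefined")
    r_obs = float(np.corrcoef(va, B[iu])[0, 1])
    rng = child_rng(seed, "mantel")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vb = B[np.ix_(perm, perm)][iu]
        if np.std(vb) == 0:
            continue
        if np.corrcoef(va, vb)[0, 1] >= r_obs:
            count += 1
    return MantelResult(
        r=r_obs,
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
    )


def mantel_exact(matA, matB) -> MantelResult:
    """Exhaustive-permutation Mantel p-value (small matrices only)."""
    from itertools import permutations

    A, B = _as_array(matA), _as_array(matB)
    _check_pair(A, B)
    n = A.shape[0]
    if n > 8:
        raise ValueError("exhaustive enumeration is limited to n <= 8")
    iu = np.triu_indices(n, k=1)
    va = A[iu]
    r_obs = float(np.corrcoef(va, B[iu])[0, 1])
    count = 0
    total = 0
    for perm in permutations(range(n)):
        vb = B[np.ix_(perm, perm)][iu]
        total += 1
        if np.corrcoef(va, vb)[0, 1] >= r_obs - 1e-12:
            count += 1
    return MantelResult(r=r_obs, p_value=count / total, n_permutations=total, seed=0)


def pearson_offdiag(matA, matB) -> tuple[float, float]:
    """Pearson r and two-sided t-test p on the off-diagonal triangles."""
    A, B = _as_array(matA), _as_array(matB)
    _check_pair(A, B)
    iu = np.triu_indices(A.shape[0], k=1)
    va, vb = A[iu], B[iu]
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 off-diagonal pairs")
    res = sps.pearsonr(va[ok], vb[ok])
    return float(res.statistic), float(res.pvalue)


def kruskal_bonferroni(
    groups: list[np.ndarray], n_comparisons: int = 1
) -> dict:
    """Kruskal-Wallis H (tie-corrected) with Bonferroni-adjusted p.

    ``n_comparisons`` is the number of tests in the family; the adjusted
    p is ``min(1, p * n_comparisons)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 1:
            raise ValueError("every group needs at least one observation")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0  # all observations tied: no evidence of any shift
    else:
        H, p = sps.kruskal(*groups)
    return {
        "H": float(H),
        "p_value": float(p),
        "p_adjusted": float(min(1.0, p * n_comparisons)),
        "n_comparisons": int(n_comparisons),
    }
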