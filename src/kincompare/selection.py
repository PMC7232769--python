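"""Estimator selection by pedigree-representative dyad simulation.

To choose a relatedness estimator for a given marker panel, the observed
pedigree is distilled into its distinct dyad classes (each characterised
by the nine condensed identity coefficients), the class frequencies are
rescaled to a fixed number of simulated dyads (largest-remainder
rounding, conserving the exact total), genotype pairs are simulated per
class from the panel's allele frequencies with genotyping error and
missingness, and the candidate estimators are ranked by Pearson
correlation between their estimates and the true relatedness
``r = 2 f(Delta)`` of each simulated dyad.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .estimators import AlleleFrequencies, EstimatedRelatedness
from .genotypes import GenotypeTable
from .pedigree import IdentityCalculator, IdentityCoefficients, Studbook

__all__ = [
    "DyadClass",
    "DyadClassDistribution",
    "dyad_distribution",
    "DyadSimulation",
    "simulate_dyad_genotypes",
    "rank_estimators",
]

# allele-slot partitions of the nine condensed states, slots (a1,a2,b1,b2);
# mirror-symmetric states use the canonical representative, which is
# indistinguishable at unordered-genotype level
_STATE_PARTITIONS: list[tuple[tuple[int, ...], ...]] = [
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


@dataclass(frozen=True)
class DyadClass:
    coefficients: IdentityCoefficients
    n_pairs: int  # observed pedigree pairs in this class
    weight: int = 0  # simulated dyads allotted after rescaling

    @property
    def true_relatedness(self) -> float:
        return self.coefficients.relatedness


@dataclass
class DyadClassDistribution:
    classes: list[DyadClass]
    n_target: int

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.classes)
        if total != self.n_target:
            raise ValueError(
                f"class weights sum to {total}, expected {self.n_target}"
            )


def dyad_distribution(
    studbook: Studbook,
    ids: Sequence[str] | None = None,
    n_target: int = 1000,
) -> DyadClassDistribution:
    """Distinct dyad classes among all unordered pairs, rescaled to
    ``n_target`` simulated dyads by largest-remainder rounding."""
    if ids is None:
        ids = studbook.ids
    ids = [str(i) for i in ids]
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals")
    calc = IdentityCalculator(studbook)
    buckets: dict[tuple, list] = {}
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            ic = calc.coefficients(ids[a_i], ids[b_i])
            buckets.setdefault(ic.rounded(9), []).append(ic)
    keys = sorted(buckets)
    counts = np.array([len(buckets[k]) for k in keys], dtype=float)
    if n_target < len(keys):
        raise ValueError(
            f"n_target={n_target} is below the {len(keys)} distinct classes"
        )
    weights = _largest_remainder(counts, n_target)
    classes = [
        DyadClass(buckets[k][0], int(c), int(w))
        for k, c, w in zip(keys, counts, weights)
    ]
    return DyadClassDistribution(classes, n_target)


def _largest_remainder(counts: np.ndarray, total: int) -> np.ndarray:
    quota = counts * total / counts.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    out = base.copy()
    out[order[:rem]] += 1
    return out


@dataclass
class DyadSimulation:
    genotypes: GenotypeTable  # 2 * n_dyads individuals
    pairs: list[tuple[str, str]]
    true_r: np.ndarray  # (n_dyads,)
    states: np.ndarray | None = None  # (n_dyads, L) drawn condensed states


def simulate_dyad_genotypes(
    classes: DyadClassDistribution,
    freqs: AlleleFrequencies,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    n_loci: int | None = None,
    seed: int = 0,
) -> DyadSimulation:
    """Genotype pairs drawn under each dyad class's identity coefficients.

    Per dyad and locus: a condensed state is drawn from Delta, the allele
    of each IBD class is drawn from the locus frequencies, a genotyping
    error replaces an allele call with a random other allele of the
    locus, and a missing call drops the genotype.  ``n_loci`` defaults to
    the size of the panel whose frequencies are supplied.
    """
    if not 0.0 <= error_rate <= 1.0 or not 0.0 <= missing_rate <= 1.0:
        raise ValueError("error_rate and missing_rate must lie in [0, 1]")
    rng = child_rng(seed, "simulate_dyad_genotypes")
    L = freqs.n_loci if n_loci is None else int(n_loci)
    locus_pool = list(range(freqs.n_loci))
    loci_idx = (
        locus_pool
        if L == freqs.n_loci
        else [locus_pool[k % freqs.n_loci] for k in range(L)]
    )
    per_locus = []
    for k in loci_idx:
        fr = freqs.freqs[k]
        alleles = np.array(sorted(fr))
        p = np.array([fr[a] for a in alleles])
        per_locus.append((alleles, p / p.sum()))

    n_dyads = sum(c.weight for c in classes.classes)
    geno = np.zeros((2 * n_dyads, L, 2), dtype=np.int32)
    all_states = np.zeros((n_dyads, L), dtype=np.int64)
    true_r = np.empty(n_dyads)
    pairs: list[tuple[str, str]] = []
    ids: list[str] = []
    d = 0
    for cls in classes.classes:
        delta = np.array(cls.coefficients.delta)
        delta = np.maximum(delta, 0.0)
        delta = delta / delta.sum()
        for _ in range(cls.weight):
            states = rng.choice(9, size=L, p=delta)
            all_states[d] = states + 1  # 1-based condensed state labels
            for l in range(L):
                alleles, p = per_locus[l]
                part = _STATE_PARTITIONS[states[l]]
                slot = np.empty(4, dtype=np.int64)
                for cls_slots in part:
                    a = alleles[rng.choice(len(alleles), p=p)]
                    for s in cls_slots:
                        slot[s] = a
                geno[2 * d, l] = slot[:2]
                geno[2 * d + 1, l] = slot[2:]
            true_r[d] = cls.true_relatedness
            ida, idb = f"dy{d:05d}a", f"dy{d:05d}b"
            ids += [ida, idb]
            pairs.append((ida, idb))
            d += 1
    if error_rate > 0:
        for l in range(L):
            alleles, _ = per_locus[l]
            if len(alleles) < 2:
                continue
            err = rng.random((geno.shape[0], 2)) < error_rate
            for (i, j) in zip(*np.nonzero(err)):
                others = alleles[alleles != geno[i, l, j]]
                geno[i, l, j] = others[rng.integers(len(others))]
    if missing_rate > 0:
        miss = rng.random(geno.shape[:2]) < missing_rate
        geno[miss] = -1
    table = GenotypeTable(ids, list(freqs.loci) if n_loci is None else
                          [f"{freqs.loci[k]}" if L == freqs.n_loci else
                           f"L{i:05d}" for i, k in enumerate(loci_idx)],
                          geno, meta={"panel": "dyad_simulation"})
    return DyadSimulation(table, pairs, true_r, all_states)


EstimatorFn = Callable[..., EstimatedRelatedness]


def rank_estimators(
    simulation: DyadSimulation,
    estimators: dict[str, EstimatorFn],
    freqs: AlleleFrequencies | None = None,
) -> pd.DataFrame:
    """Rank estimators by Pearson correlation with true dyad relatedness.

    Each estimator is called as ``fn(genotypes, pairs=...)`` (frequencies
    passed through when given); NaN estimates are dropped pairwise.
    Returns a DataFrame sorted by descending correlation, ties broken by
    estimator name.
    """
    truth = simulation.true_r
    if np.all(truth == truth[0]):
        raise ValueError(
            "constant true relatedness across dyads: correlation undefined"
        )
    rows = []
    for name in sorted(estimators):
        fn = estimators[name]
        kwargs = {"pairs": simulation.pairs}
        if freqs is not None:
            try:
                est = fn(simulation.genotypes, freqs, **kwargs)
            except TypeError:
                est = fn(simulation.genotypes, **kwargs)
        else:
            est = fn(simulation.genotypes, **kwargs)
        vals = np.array([est.loc(a, b) for a, b in simulation.pairs])
        ok = np.isfinite(vals)
        if ok.sum() >= 3 and np.std(vals[ok]) > 0:
            r = float(np.corrcoef(vals[ok], truth[ok])[0, 1])
        else:
            r = float("nan")
        rows.append({"estimator": name, "pearson_r": r, "n_dyads": int(ok.sum())})
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["pearson_r", "estimator"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
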