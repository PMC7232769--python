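"""Pairing recommendations from kinship or relatedness matrices.

Two complementary tools of captive-breeding management:

* **Mean kinship (MK) rank** -- each individual's mean kinship with the
  living population (including itself), ranked from lowest (most
  genetically valuable) to highest within each sex.
* **Mate suitability index (MSI)** -- an ordinal 1-7 score per candidate
  male x female pair combining four components: the change in gene
  diversity if the pair bred once (deltaGD), the difference in the
  parents' mean kinships, the inbreeding coefficient of the hypothetical
  offspring (the pair's kinship), and the offspring's unknown-ancestry
  fraction.  1 is "very beneficial", 6 "very detrimental", and 7 "very
  highly detrimental" (reserved for inbred, diversity-losing pairings).

Empirical relatedness matrices enter through ``empirical_kinship`` (R/2).
The exact MSI thresholds of studbook software are not public; the
mapping here is an explicit, overridable configuration that is monotone
in each component, which is what the downstream concordance statistics
rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrices import KinshipMatrix, LabeledMatrix, RelatednessMatrix

__all__ = [
    "empirical_kinship",
    "mean_kinship_table",
    "MsiThresholds",
    "MateScoreTable",
    "msi_scores",
    "compare_recommendations",
]


def empirical_kinship(R: RelatednessMatrix) -> KinshipMatrix:
    """Empirical kinship K = R / 2 (weights empirical data fully)."""
    meta = dict(R.meta)
    meta["kind"] = "empirical_kinship"
    return KinshipMatrix(R.ids, R.values / 2.0, meta)


def mean_kinship_table(
    K: KinshipMatrix,
    sexes: Mapping[str, str],
    living_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean kinship and within-sex MK rank (1 = lowest MK).

    ``MK_i`` is the mean of individual i's kinship with every living
    individual including itself.  Ties are broken by id, making ranks a
    permutation of 1..n within each sex.
    """
    living = list(K.ids) if living_ids is None else [str(i) for i in living_ids]
    Kp = K.reindex(living)
    mk = Kp.values.mean(axis=1)
    rows = []
    for i, ind in enumerate(living):
        sex = sexes.get(ind)
        if sex is None:
            raise KeyError(f"no sex recorded for {ind!r}")
        rows.append({"id": ind, "sex": sex, "mk": float(mk[i])})
    df = pd.DataFrame(rows)
    order = df.sort_values(["mk", "id"]).index
    ranks = np.empty(len(df), dtype=int)
    for sex in df["sex"].unique():
        sex_sorted = [k for k in order if df.loc[k, "sex"] == sex]
        for r, k in enumerate(sex_sorted, start=1):
            ranks[k] = r
    df["rank"] = ranks
    return df


@dataclass(frozen=True)
class MsiThresholds:
    """Monotone component-to-penalty mapping behind the MSI categories.

    Each component maps to a small integer penalty; the category is
    ``1 + total penalty`` capped at 6, overridden to 7 when the offspring
    would be substantially inbred (F >= ``severe_f``) while the pairing
    also loses gene diversity.  All breakpoints are ascending.
    """

    delta_gd_bands: tuple[float, ...] = (-0.03, -0.01)  # below first: 2, ...
    mk_diff_bands: tuple[float, ...] = (0.01, 0.05)
    offspring_f_bands: tuple[float, ...] = (1e-9, 0.0625, 0.125)
    unknown_bands: tuple[float, ...] = (0.25,)
    severe_f: float = 0.125

    def category(
        self,
        delta_gd: float,
        mk_diff: float,
        offspring_f: float,
        unknown_fraction: float,
    ) -> int:
        if offspring_f >= self.severe_f and delta_gd < 0:
            return 7
        penalty = 0
        # deltaGD: larger is better, so count bands *below*
        penalty += sum(delta_gd < b for b in self.delta_gd_bands)
        penalty += sum(mk_diff >= b for b in self.mk_diff_bands)
        penalty += sum(offspring_f >= b for b in self.offspring_f_bands)
        penalty += sum(unknown_fraction >= b for b in self.unknown_bands)
        return min(1 + penalty, 6)


@dataclass
class MateScoreTable:
    males: list[str]
    females: list[str]
    category: np.ndarray  # (n_males, n_females) int 1..7
    delta_gd: np.ndarray
    mk_difference: np.ndarray
    offspring_f: np.ndarray
    unknown_ancestry: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.males):
            for j, f in enumerate(self.females):
                rows.append(
                    {
                        "male": m,
                        "female": f,
                        "msi": int(self.category[i, j]),
                        "delta_gd": float(self.delta_gd[i, j]),
                        "mk_difference": float(self.mk_difference[i, j]),
                        "offspring_f": float(self.offspring_f[i, j]),
                        "unknown_ancestry": float(self.unknown_ancestry[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def msi_scores(
    K: KinshipMatrix,
    sexes: Mapping[str, str],
    living_ids: Sequence[str] | None = None,
    unknown_ancestry: Mapping[str, float] | None = None,
    thresholds: MsiThresholds | None = None,
) -> MateScoreTable:
    """Mate suitability categories for every candidate male x female pair.

    deltaGD is computed by appending one hypothetical offspring of the
    pair to the living population (its kinship row is the mean of its
    parents' rows; its self-kinship ``0.5 (1 + K(m, f))``) and taking the
    change in gene diversity ``1 - grand mean kinship``.  The offspring's
    inbreeding coefficient is the pair's kinship, and its unknown
    ancestry the mean of the parents' unknown fractions (zero for
    empirical-only analyses).
    """
    thresholds = thresholds or MsiThresholds()
    living = list(K.ids) if living_ids is None else [str(i) for i in living_ids]
    Kp = K.reindex(living).values
    n = len(living)
    males = [i for i in living if sexes.get(i) == "M"]
    females = [i for i in living if sexes.get(i) == "F"]
    if not males or not females:
        raise ValueError("need at least one living male and one female")
    unknown = unknown_ancestry or {}
    pos = {i: k for k, i in enumerate(living)}
    mk = Kp.mean(axis=1)
    gd_old = 1.0 - float(mk.mean())
    grand_sum = float(Kp.sum())

    nm, nf = len(males), len(females)
    cat = np.zeros((nm, nf), dtype=int)
    dgd = np.zeros((nm, nf))
    mkd = np.zeros((nm, nf))
    off_f = np.zeros((nm, nf))
    unk = np.zeros((nm, nf))
    for a, m in enumerate(males):
        im = pos[m]
        for b, f in enumerate(females):
            jf = pos[f]
            f_off = Kp[im, jf]
            row = 0.5 * (Kp[im] + Kp[jf])  # offspring kinship with living
            self_k = 0.5 * (1.0 + f_off)
            new_sum = grand_sum + 2.0 * row.sum() + self_k
            gd_new = 1.0 - new_sum / (n + 1) ** 2
            dgd[a, b] = gd_new - gd_old
            mkd[a, b] = abs(mk[im] - mk[jf])
            off_f[a, b] = f_off
            unk[a, b] = 0.5 * (
                unknown.get(m, 0.0) + unknown.get(f, 0.0)
            )
            cat[a, b] = thresholds.category(
                dgd[a, b], mkd[a, b], off_f[a, b], unk[a, b]
            )
    return MateScoreTable(males, females, cat, dgd, mkd, off_f, unk)


def compare_recommendations(
    mk_a: pd.DataFrame,
    mk_b: pd.DataFrame,
    msi_a: MateScoreTable | None = None,
    msi_b: MateScoreTable | None = None,
) -> dict:
    """Concordance between two sets of pairing recommendations.

    Reports the MK rank-shift histogram (bins 0-3, 4-7, >=8) and, when
    MSI tables are supplied, the percentage of pairs with identical
    category, with a >=3-category change, crossing 1 <-> 7, and the
    Pearson correlation of the category matrices.
    """
    a = mk_a.set_index("id")
    b = mk_b.set_index("id")
    if set(a.index) != set(b.index):
        raise ValueError("MK tables cover different individuals")
    shifts = (a["rank"] - b.loc[a.index, "rank"]).abs().to_numpy()
    report: dict = {
        "n_individuals": len(shifts),
        "rank_shift_0_3": float(np.mean(shifts <= 3) * 100),
        "rank_shift_4_7": float(np.mean((shifts >= 4) & (shifts <= 7)) * 100),
        "rank_shift_8_plus": float(np.mean(shifts >= 8) * 100),
        "mk_pearson_r": float(
            np.corrcoef(a["mk"], b.loc[a.index, "mk"])[0, 1]
        ),
    }
    if msi_a is not None and msi_b is not None:
        if msi_a.males != msi_b.males or msi_a.females != msi_b.females:
            raise ValueError("MSI tables cover different pairs")
        ca = msi_a.category.ravel().astype(float)
        cb = msi_b.category.ravel().astype(float)
        diff = np.abs(ca - cb)
        report.update(
            {
                "n_pairs": ca.size,
                "msi_identical_pct": float(np.mean(diff == 0) * 100),
                "msi_change_3plus_pct": float(np.mean(diff >= 3) * 100),
                "msi_1_to_7_pct": float(
                    np.mean(((ca == 1) & (cb == 7)) | ((ca == 7) & (cb == 1)))
                    * 100
                ),
                "msi_pearson_r": float(np.corrcoef(ca, cb)[0, 1])
                if np.std(ca) > 0 and np.std(cb) > 0
                else float("nan"),
            }
        )
    return report
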