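"""Pedigree computations on studbook data.

The studbook is the registry of a managed breeding programme: one record
per individual with sire, dam, sex, hatch/birth year, alive status and
origin.  From it this module computes

* pairwise kinship ``f`` by the recursive tabular method, with
  ``f(x,x) = 0.5 (1 + F_x)`` on the diagonal,
* the relatedness coefficient ``R(x,y) = 2 f(x,y) / sqrt((1+F_x)(1+F_y))``
  (Crow & Kimura normalisation), so that non-inbred first-order relatives
  have R = 0.5,
* the nine condensed (Jacquard) identity coefficients of any dyad, either
  exactly by a generalized-kinship recursion or by Monte-Carlo single-locus
  gene dropping,
* studbook summary statistics (gene diversity, founder genome equivalents,
  mean kinship, generation time, percent known ancestry).

Unknown parents are treated as distinct wild founders: a missing parent
contributes nothing to kinship and is counted as unknown ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from ._rng import child_rng
from .matrices import KinshipMatrix, LabeledMatrix, RelatednessMatrix

__all__ = [
    "Record",
    "Studbook",
    "ValidationIssue",
    "validate_studbook",
    "kinship_matrix",
    "kinship_to_relatedness",
    "IdentityCoefficients",
    "identity_coefficients",
    "IdentityCalculator",
    "PedigreeSummary",
    "pedigree_summary",
]

Sex = Literal["M", "F", "U"]


@dataclass(frozen=True)
class Record:
    id: str
    sire: str | None = None
    dam: str | None = None
    sex: Sex = "U"
    birth_year: int | None = None
    alive: bool = True
    origin: str = "captive"


class Studbook:
    """An ordered collection of pedigree records indexed by id."""

    def __init__(self, records: Iterable[Record]):
        self.records: list[Record] = list(records)
        self._by_id: dict[str, Record] = {}
        for r in self.records:
            if r.id in self._by_id:
                raise ValueError(f"duplicate studbook id: {r.id!r}")
            self._by_id[r.id] = r

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, ind: str) -> bool:
        return str(ind) in self._by_id

    def __getitem__(self, ind: str) -> Record:
        return self._by_id[str(ind)]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def living_ids(self) -> list[str]:
        return [r.id for r in self.records if r.alive]

    def founders(self) -> list[str]:
        """Individuals with both parents unknown."""
        return [r.id for r in self.records if r.sire is None and r.dam is None]

    def sexes(self) -> dict[str, Sex]:
        return {r.id: r.sex for r in self.records}

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        r = self[ind]
        return r.sire, r.dam

    def topological_order(self) -> list[str]:
        """Ids with parents before children; ties broken lexicographically.

        Raises ``ValueError`` on a parentage cycle.
        """
        children: dict[str, list[str]] = {i: [] for i in self._by_id}
        indeg = {i: 0 for i in self._by_id}
        for r in self.records:
            for p in (r.sire, r.dam):
                if p is not None and p in self._by_id:
                    children[p].append(r.id)
                    indeg[r.id] += 1
        import heapq

        ready = [i for i, d in indeg.items() if d == 0]
        heapq.heapify(ready)
        order: list[str] = []
        while ready:
            i = heapq.heappop(ready)
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(ready, c)
        if len(order) != len(self.records):
            raise ValueError("pedigree contains a parentage cycle")
        return order

    def ancestors(self, ind: str) -> set[str]:
        seen: set[str] = set()
        stack = [str(ind)]
        while stack:
            x = stack.pop()
            for p in self.parents(x):
                if p is not None and p in self._by_id and p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # cycle | missing_parent | sex_conflict | birth_order
    individual: str
    detail: str


def validate_studbook(studbook: Studbook) -> list[ValidationIssue]:
    """Report pedigree inconsistencies; an empty report means a valid book.

    Checks: parentage cycles (including self-parenthood), parent ids without
    records, sires recorded as female / dams as male, and children born no
    later than a parent.
    """
    issues: list[ValidationIssue] = []
    for r in studbook.records:
        for role, p in (("sire", r.sire), ("dam", r.dam)):
            if p is None:
                continue
            if p == r.id:
                issues.append(
                    ValidationIssue("cycle", r.id, f"individual is its own {role}")
                )
                continue
            if p not in studbook:
                issues.append(
                    ValidationIssue(
                        "missing_parent", r.id, f"{role} {p!r} has no record"
                    )
                )
                continue
            pr = studbook[p]
            want = "M" if role == "sire" else "F"
            if pr.sex != "U" and pr.sex != want:
                issues.append(
                    ValidationIssue(
                        "sex_conflict",
                        r.id,
                        f"{role} {p!r} is recorded with sex {pr.sex}",
                    )
                )
            if (
                r.birth_year is not None
                and pr.birth_year is not None
                and r.birth_year < pr.birth_year
            ):
                issues.append(
                    ValidationIssue(
                        "birth_order",
                        r.id,
                        f"born {r.birth_year}, before {role} {p!r} ({pr.birth_year})",
                    )
                )
    # cycle detection over the full graph (self-loops caught above)
    try:
        studbook.topological_order()
    except ValueError:
        on_cycle = _individuals_on_cycles(studbook)
        for i in sorted(on_cycle):
            issues.append(ValidationIssue("cycle", i, "on a parentage cycle"))
    return issues


def _individuals_on_cycles(studbook: Studbook) -> set[str]:
    ids = set(studbook.ids)
    # iteratively strip individuals with no in-book parents / children
    parents = {
        i: {p for p in studbook.parents(i) if p in ids and p != i}
        for i in ids
    }
    changed = True
    alive = set(ids)
    while changed:
        changed = False
        for i in list(alive):
            if not (parents[i] & alive):
                alive.discard(i)
                changed = True
    return alive


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def kinship_matrix(studbook: Studbook) -> KinshipMatrix:
    """Pairwise kinship by the recursive tabular method.

    ``f(x,x) = 0.5 (1 + f(sire_x, dam_x))`` and, for x younger than y,
    ``f(x,y) = 0.5 (f(sire_x, y) + f(dam_x, y))``; a missing parent
    contributes 0 (unknown parents are unrelated wild founders).  Rows and
    columns are ordered as in the studbook.
    """
    order = studbook.topological_order()  # raises on cycles
    pos = {i: k for k, i in enumerate(order)}
    n = len(order)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for k, i in enumerate(order):
        s, d = studbook.parents(i)
        if s is not None and s in studbook:
            sire[k] = pos[s]
        if d is not None and d in studbook:
            dam[k] = pos[d]
    f = np.zeros((n, n))
    for k in range(n):
        s, d = sire[k], dam[k]
        fs = f[s, :k] if s >= 0 else 0.0
        fd = f[d, :k] if d >= 0 else 0.0
        row = 0.5 * (fs + fd)
        if np.isscalar(row):  # founder: unrelated to everyone older
            row = np.zeros(k)
        f[k, :k] = row
        f[:k, k] = row
        f_sd = f[s, d] if (s >= 0 and d >= 0) else 0.0
        f[k, k] = 0.5 * (1.0 + f_sd)
    # back to studbook order
    take = [pos[i] for i in studbook.ids]
    return KinshipMatrix(
        studbook.ids, f[np.ix_(take, take)], {"kind": "pedigree_kinship"}
    )


def kinship_to_relatedness(K: KinshipMatrix) -> RelatednessMatrix:
    """Crow & Kimura conversion ``R = 2 f / sqrt((1+Fx)(1+Fy))``.

    ``F`` is read off the kinship diagonal (``f(x,x) = 0.5 (1 + F)``).
    """
    diag = K.diagonal()
    if np.any(diag < 0.5 - 1e-12):
        bad = K.ids[int(np.argmin(diag))]
        raise ValueError(
            f"kinship diagonal below 0.5 for {bad!r}: implies negative "
            "inbreeding, not a valid pedigree kinship matrix"
        )
    one_plus_F = 2.0 * diag
    denom = np.sqrt(np.outer(one_plus_F, one_plus_F))
    R = 2.0 * K.values / denom
    meta = dict(K.meta)
    meta["kind"] = "pedigree_relatedness"
    return RelatednessMatrix(K.ids, R, meta)


def inbreeding_coefficients(K: KinshipMatrix) -> dict[str, float]:
    """Per-individual F from the kinship diagonal."""
    return {i: 2.0 * v - 1.0 for i, v in zip(K.ids, K.diagonal())}


# ---------------------------------------------------------------------------
# identity coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentityCoefficients:
    """The nine condensed identity-state probabilities of a dyad.

    State numbering follows Jacquard: 1 = all four alleles IBD ...
    9 = no IBD at all.  Kinship is recoverable as
    ``f = D1 + (D3 + D5 + D7)/2 + D8/4``.
    """

    delta: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.delta) != 9:
            raise ValueError("nine condensed states required")
        if any(d < -1e-9 for d in self.delta):
            raise ValueError("negative identity coefficient")
        if abs(sum(self.delta) - 1.0) > 1e-6:
            raise ValueError("identity coefficients must sum to 1")

    def __getitem__(self, k: int) -> float:
        """1-based state access: ic[1] is Delta_1."""
        return self.delta[k - 1]

    @property
    def kinship(self) -> float:
        d = self.delta
        return d[0] + 0.5 * (d[2] + d[4] + d[6]) + 0.25 * d[7]

    @property
    def relatedness(self) -> float:
        """Additive relatedness 2f implied by the coefficients."""
        return 2.0 * self.kinship

    def rounded(self, decimals: int = 9) -> tuple[float, ...]:
        return tuple(round(max(d, 0.0), decimals) for d in self.delta)


class IdentityCalculator:
    """Exact condensed identity coefficients via generalized kinships.

    Implements the classical recursion on generalized kinship coefficients
    (the probability that all alleles in a set of independent draws are
    IBD, and the paired two-sets variant), always expanding the individual
    with the highest topological rank, which is never an ancestor of the
    other arguments.  The nine condensed coefficients are then obtained by
    solving the linear system relating them to the generalized kinships.
    Memoization is shared across dyads of the same studbook.
    """

    def __init__(self, studbook: Studbook):
        order = studbook.topological_order()
        self._rank = {i: k for k, i in enumerate(order)}
        self._sire: dict[str, str | None] = {}
        self._dam: dict[str, str | None] = {}
        n_ph = 0
        for i in order:
            s, d = studbook.parents(i)
            # a parent id without a record acts as an unknown -> placeholder
            s = s if (s is not None and s in studbook) else None
            d = d if (d is not None and d in studbook) else None
            if (s is None) != (d is None):
                # synthesize a distinct placeholder founder for the gap
                ph = f"\x00ph{n_ph}"
                n_ph += 1
                self._rank[ph] = -1 - n_ph  # below every real individual
                self._sire[ph] = None
                self._dam[ph] = None
                if s is None:
                    s = ph
                else:
                    d = ph
            self._sire[i] = s
            self._dam[i] = d
        self._phi: dict[tuple, float] = {}
        self._phi22: dict[tuple, float] = {}

    # -- generalized kinships -------------------------------------------
    def phi(self, *args: str) -> float:
        """P(one random allele drawn from each argument are all IBD)."""
        if len(args) == 1:
            return 1.0
        key = tuple(sorted(args, key=lambda a: (self._rank[a], a)))
        hit = self._phi.get(key)
        if hit is not None:
            return hit
        a = key[-1]  # max rank: not an ancestor of the others
        rest = list(key)
        t = rest.count(a)
        rest = [x for x in rest if x != a]
        s, d = self._sire[a], self._dam[a]
        if s is None:  # founder
            val = 0.0 if rest else 0.5 ** (len(key) - 1)
        else:
            val = 0.0
            half_t = 0.5 ** t
            for j in range(t + 1):
                comb = _binom(t, j) * half_t
                if j == 0:
                    sub = rest + [d]
                elif j == t:
                    sub = rest + [s]
                else:
                    sub = rest + [s, d]
                val += comb * self.phi(*sub)
        self._phi[key] = val
        return val

    def phi22(self, pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
        """P(the two draws of pair1 are IBD and the two of pair2 are IBD)."""
        p1 = tuple(sorted(pair1, key=lambda a: (self._rank[a], a)))
        p2 = tuple(sorted(pair2, key=lambda a: (self._rank[a], a)))
        key = tuple(sorted((p1, p2), key=lambda p: (self._rank[p[0]], p)))
        hit = self._phi22.get(key)
        if hit is not None:
            return hit
        (w, x), (y, z) = key
        a = max((w, x, y, z), key=lambda i: (self._rank[i], i))
        s, d = self._sire[a], self._dam[a]
        if s is None:
            # all arguments are founders: the two events are independent
            val = (0.5 if w == x else 0.0) * (0.5 if y == z else 0.0)
        else:
            in1 = (w == a) + (x == a)
            in2 = (y == a) + (z == a)
            if in2 > in1:
                (w, x), (y, z) = (y, z), (w, x)
                in1, in2 = in2, in1
            b = w if x == a else x  # the non-a member of pair1 (if any)
            if in1 == 2 and in2 == 2:
                # all four draws come from a's two physical alleles (one
                # draw from each parent, shared across the slots): unless
                # both pairs picked the same allele, the event collapses
                # to those two alleles being IBD
                val = 0.25 + 0.75 * self.phi(s, d)
            elif in1 == 2 and in2 == 1:
                c = y if z == a else z
                val = 0.25 * (self.phi(s, c) + self.phi(d, c)) + 0.5 * self.phi(
                    s, d, c
                )
            elif in1 == 2:
                val = 0.5 * self.phi(y, z) + 0.5 * self.phi22((s, d), (y, z))
            elif in2 == 1:  # a once in each pair
                c = y if z == a else z
                val = 0.25 * (
                    self.phi(s, b, c)
                    + self.phi(d, b, c)
                    + self.phi22((s, b), (d, c))
                    + self.phi22((d, b), (s, c))
                )
            else:  # a only in pair1, once
                val = 0.5 * (
                    self.phi22((s, b), (y, z)) + self.phi22((d, b), (y, z))
                )
        self._phi22[key] = val
        return val

    # -- condensed coefficients ------------------------------------------
    _M = np.array(
        [
            # D1   D2   D3    D4   D5    D6   D7     D8      D9
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],  # total
            [1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # F_a
            [1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0],  # F_b
            [1.0, 0.0, 0.5, 0.0, 0.5, 0.0, 0.5, 0.25, 0.0],  # phi(ab)
            [1.0, 0.0, 0.5, 0.0, 0.25, 0.0, 0.25, 0.125, 0.0],  # phi(aab)
            [1.0, 0.0, 0.25, 0.0, 0.5, 0.0, 0.25, 0.125, 0.0],  # phi(abb)
            [1.0, 0.0, 0.25, 0.0, 0.25, 0.0, 0.125, 0.0625, 0.0],  # phi(aabb)
            [1.0, 1.0, 0.5, 0.5, 0.5, 0.5, 0.25, 0.25, 0.25],  # phi22(aa;bb)
            [1.0, 0.0, 0.25, 0.0, 0.25, 0.0, 0.25, 0.0625, 0.0],  # phi22(ab;ab)
        ]
    )
    _Minv = np.linalg.inv(_M)

    def coefficients(self, a: str, b: str) -> IdentityCoefficients:
        rhs = np.array(
            [
                1.0,
                2.0 * self.phi(a, a) - 1.0,
                2.0 * self.phi(b, b) - 1.0,
                self.phi(a, b),
                self.phi(a, a, b),
                self.phi(a, b, b),
                self.phi(a, a, b, b),
                self.phi22((a, a), (b, b)),
                self.phi22((a, b), (a, b)),
            ]
        )
        delta = self._Minv @ rhs
        delta = np.where(np.abs(delta) < 1e-12, 0.0, delta)
        return IdentityCoefficients(tuple(float(x) for x in delta))


def _binom(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def _montecarlo_identity(
    studbook: Studbook, a: str, b: str, n_drops: int, rng: np.random.Generator
) -> IdentityCoefficients:
    """Single-locus gene dropping with unique founder alleles.

    Tallies the nine condensed states of the dyad over ``n_drops``
    independent drops of one locus through the pedigree.
    """
    order = studbook.topological_order()
    pos = {i: k for k, i in enumerate(order)}
    n = len(order)
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for k, i in enumerate(order):
        s, d = studbook.parents(i)
        sire[k] = pos[s] if (s is not None and s in studbook) else -1
        dam[k] = pos[d] if (d is not None and d in studbook) else -1
    pat = np.zeros((n, n_drops), dtype=np.int64)
    mat = np.zeros((n, n_drops), dtype=np.int64)
    next_label = 1
    for k in range(n):
        for arr, p in ((pat, sire[k]), (mat, dam[k])):
            if p < 0:
                arr[k] = next_label  # fresh founder haplotype (per slot)
                next_label += 1
                # unique per drop is unnecessary: labels never collide
                # across slots, and a founder slot is a single haplotype
            else:
                pick = rng.integers(0, 2, size=n_drops, dtype=np.int64)
                arr[k] = np.where(pick == 0, pat[p], mat[p])
    ia, ib = pos[str(a)], pos[str(b)]
    a1, a2, b1, b2 = pat[ia], mat[ia], pat[ib], mat[ib]
    state = _condensed_state(a1, a2, b1, b2)
    counts = np.bincount(state, minlength=10)[1:]
    return IdentityCoefficients(tuple(counts / n_drops))


def _condensed_state(a1, a2, b1, b2) -> np.ndarray:
    """Vectorized condensed-state classification from four IBD labels."""
    a1, a2, b1, b2 = (np.asarray(x) for x in (a1, a2, b1, b2))
    wa = a1 == a2
    wb = b1 == b2
    x11 = a1 == b1
    x12 = a1 == b2
    x21 = a2 == b1
    x22 = a2 == b2
    any_cross = x11 | x12 | x21 | x22
    both_cross = (x11 & x22) | (x12 & x21)
    one_cross = (
        x11.astype(int) + x12.astype(int) + x21.astype(int) + x22.astype(int)
    ) == 1
    state = np.full(a1.shape, 9, dtype=np.int64)
    state[wa & wb & any_cross] = 1
    state[wa & wb & ~any_cross] = 2
    state[wa & ~wb & any_cross] = 3
    state[wa & ~wb & ~any_cross] = 4
    state[~wa & wb & any_cross] = 5
    state[~wa & wb & ~any_cross] = 6
    state[~wa & ~wb & both_cross] = 7
    state[~wa & ~wb & one_cross] = 8
    return state


def identity_coefficients(
    studbook: Studbook,
    pair: tuple[str, str],
    method: Literal["exact", "montecarlo"] = "exact",
    n_drops: int = 100_000,
    seed: int = 0,
) -> IdentityCoefficients:
    """Condensed identity coefficients for a dyad.

    ``exact`` uses the generalized-kinship recursion; ``montecarlo`` tallies
    states over ``n_drops`` single-locus gene drops (the independent
    cross-check of the exact path).
    """
    a, b = (str(pair[0]), str(pair[1]))
    for i in (a, b):
        if i not in studbook:
            raise KeyError(f"unknown individual {i!r}")
    if method == "exact":
        return IdentityCalculator(studbook).coefficients(a, b)
    if method == "montecarlo":
        rng = child_rng(seed, f"identity_mc:{a}:{b}")
        return _montecarlo_identity(studbook, a, b, n_drops, rng)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeSummary:
    n_individuals: int
    sex_ratio: float  # proportion of males among known-sex individuals
    gene_diversity: float
    n_founders: int
    founder_genome_equivalents: float
    mean_inbreeding: float
    mean_mean_kinship: float
    mean_generation_time: float | None
    pct_ancestry_known: float


def pedigree_summary(
    studbook: Studbook,
    selected_ids: Sequence[str] | None = None,
    living_only: bool = True,
) -> PedigreeSummary:
    """Studbook descriptive statistics for a selection of individuals.

    Mean kinship of an individual is the mean of its kinship with every
    (living, if ``living_only``) selected individual *including itself*;
    gene diversity is 1 minus the grand mean kinship and founder genome
    equivalents 1 / (2 * grand mean kinship).
    """
    if selected_ids is None:
        selected_ids = studbook.ids
    selected_ids = [str(i) for i in selected_ids]
    if not selected_ids:
        raise ValueError("empty selection")
    for i in selected_ids:
        if i not in studbook:
            raise KeyError(f"unknown individual {i!r}")
    K = kinship_matrix(studbook)
    pool = [
        i for i in selected_ids if (studbook[i].alive or not living_only)
    ]
    if not pool:
        raise ValueError("no living individuals in selection")
    Kp = K.reindex(pool)
    mk = Kp.values.mean(axis=1)  # row mean including self
    grand = float(mk.mean())
    F = inbreeding_coefficients(K)

    # founders among the ancestors of the selection (inclusive)
    relevant: set[str] = set(selected_ids)
    for i in selected_ids:
        relevant |= studbook.ancestors(i)
    founders = [
        i
        for i in relevant
        if all(
            p is None or p not in studbook for p in studbook.parents(i)
        )
    ]

    sexes = [studbook[i].sex for i in selected_ids]
    known_sex = [s for s in sexes if s != "U"]
    sex_ratio = (
        sum(1 for s in known_sex if s == "M") / len(known_sex)
        if known_sex
        else float("nan")
    )

    # generation time: mean parent age at offspring birth over all
    # (child, parent) links with both birth years recorded
    ages: list[float] = []
    for r in studbook.records:
        if r.birth_year is None:
            continue
        for p in (r.sire, r.dam):
            if p is not None and p in studbook:
                py = studbook[p].birth_year
                if py is not None:
                    ages.append(r.birth_year - py)
    gen_time = float(np.mean(ages)) if ages else None

    known = _known_ancestry_fractions(studbook)
    return PedigreeSummary(
        n_individuals=len(selected_ids),
        sex_ratio=sex_ratio,
        gene_diversity=1.0 - grand,
        n_founders=len(founders),
        founder_genome_equivalents=(
            1.0 / (2.0 * grand) if grand > 0 else float("inf")
        ),
        mean_inbreeding=float(np.mean([F[i] for i in selected_ids])),
        mean_mean_kinship=grand,
        mean_generation_time=gen_time,
        pct_ancestry_known=100.0
        * float(np.mean([known[i] for i in selected_ids])),
    )


def _known_ancestry_fractions(studbook: Studbook) -> dict[str, float]:
    """Fraction of each individual's ancestry tracing to real founders.

    A record with both parents unknown is a wild founder (fully known
    ancestry); a single missing parent is a placeholder founder and counts
    as unknown ancestry.
    """
    order = studbook.topological_order()
    known: dict[str, float] = {}
    for i in order:
        s, d = studbook.parents(i)
        s_ok = s is not None and s in studbook
        d_ok = d is not None and d in studbook
        if not s_ok and not d_ok:
            known[i] = 1.0
        else:
            ks = known[s] if s_ok else 0.0
            kd = known[d] if d_ok else 0.0
            known[i] = 0.5 * (ks + kd)
    return known
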