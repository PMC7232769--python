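"""Synthetic pedigrees, gene-dropped genotypes and sequencing noise.

Because the study system's real data (critically endangered birds whose
genomic data are culturally protected) cannot ship with the package, this
module generates every input the downstream analyses need, with exact
ground truth:

* multi-generation captive pedigrees descending from wild founders,
* recombination-aware gene dropping of founder haplotypes (Poisson
  crossover counts, uniform positions -- the Haldane no-interference map
  function), tracking identity-by-descent as globally unique founder
  haplotype labels, so realized genome sharing is known exactly,
* microsatellite panels (few loci, 2-4 alleles each) with genotyping error
  and missingness,
* biallelic SNP panels with per-call read depth (negative-binomial by
  default), binomial allele sampling and per-read error -- the raw
  material of the depth-aware relatedness estimator.

Realized additive relatedness of a pair is the genetic-map-length-weighted
fraction of allele pairs IBD:  0.5 exactly for parent and offspring (one
gamete is a full mosaic of that parent's two haplotypes), but dispersed
around 0.5 for full siblings, with variance set by the recombination map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._rng import child_rng
from .genotypes import GenotypeTable, VariantTable
from .matrices import RelatednessMatrix
from .pedigree import Record, Studbook

__all__ = [
    "Chromosome",
    "GenomeModel",
    "FounderPool",
    "SeqModel",
    "DropResult",
    "simulate_pedigree",
    "simulate_family_groups",
    "dyad_tally",
    "gene_drop",
    "full_sib_realized",
    "emit_microsat_panel",
    "emit_depth_genotypes",
    "human_like_map",
    "snp_genome",
    "random_founder_pool",
]


# ---------------------------------------------------------------------------
# genome / founder / sequencing models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    name: str
    length: float  # genetic length in Morgans
    positions: np.ndarray = field(default_factory=lambda: np.empty(0))  # Morgans
    locus_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positions", np.asarray(self.positions, dtype=float)
        )
        if self.length < 0:
            raise ValueError(f"negative genetic length on {self.name}")
        if len(self.positions) != len(self.locus_names):
            raise ValueError("positions and locus_names differ in length")
        if len(self.positions) and (
            self.positions.min() < 0 or self.positions.max() > self.length
        ):
            raise ValueError(f"locus position off the map on {self.name}")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError(f"locus positions not sorted on {self.name}")


@dataclass(frozen=True)
class GenomeModel:
    chromosomes: tuple[Chromosome, ...]

    @property
    def total_length(self) -> float:
        return float(sum(c.length for c in self.chromosomes))

    @property
    def locus_names(self) -> list[str]:
        out: list[str] = []
        for c in self.chromosomes:
            out.extend(c.locus_names)
        return out


@dataclass(frozen=True)
class FounderPool:
    """Founder allele-frequency model for the marker panels.

    ``snp_allele_freqs`` maps SNP locus name -> alternate-allele frequency;
    ``microsat_allele_freqs`` maps microsatellite locus name -> {allele
    label: frequency} with 2-4 alleles per locus.
    """

    snp_allele_freqs: dict[str, float] = field(default_factory=dict)
    microsat_allele_freqs: dict[str, dict[int, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for name, p in self.snp_allele_freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"SNP frequency out of range at {name}")
        for name, fr in self.microsat_allele_freqs.items():
            if not 2 <= len(fr) <= 4:
                raise ValueError(
                    f"microsatellite locus {name} must have 2-4 alleles"
                )
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {name} do not sum to 1")


@dataclass(frozen=True)
class SeqModel:
    """Short-read sequencing model for SNP genotype emission.

    Depth is drawn per call from a negative-binomial with the given mean
    and dispersion (Poisson in the limit ``dispersion -> inf``); the
    alternate-read count is binomial on the true allele dosage with
    per-read miscall probability ``error_rate``; calls at depth 0 are
    missing, and an extra ``missing_rate`` drops calls outright.
    """

    mean_depth: float = 25.0
    dispersion: float = 8.0  # NB size parameter; larger = closer to Poisson
    error_rate: float = 0.001
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean depth must be >= 0")
        for r in (self.error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def draw_depth(self, shape, rng: np.random.Generator) -> np.ndarray:
        if self.mean_depth == 0:
            return np.zeros(shape, dtype=np.int64)
        k = self.dispersion
        p = k / (k + self.mean_depth)
        return rng.negative_binomial(k, p, size=shape)


# ---------------------------------------------------------------------------
# pedigree generation
# ---------------------------------------------------------------------------

def _offspring_count(dist, rng: np.random.Generator) -> int:
    if isinstance(dist, int):
        return dist
    if isinstance(dist, tuple) and len(dist) == 2:
        return int(rng.integers(dist[0], dist[1] + 1))
    if callable(dist):
        return int(dist(rng))
    raise TypeError("offspring_distribution must be int, (lo, hi) or callable")


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    pairs_per_generation: int,
    offspring_distribution: int | tuple[int, int] | Callable = 2,
    seed: int = 0,
) -> Studbook:
    """A discrete-generation captive pedigree descending from wild founders.

    Founders (generation 0, half of each sex) are unrelated wild birds;
    each later generation forms ``pairs_per_generation`` disjoint
    male-female pairs from the previous generation and draws a brood size
    per pair from ``offspring_distribution``.  Offspring sex is random.
    Raises if any generation lacks an opposite-sex pair.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = child_rng(seed, "simulate_pedigree")
    records: list[Record] = []
    sex_of: dict[str, str] = {}
    year0 = 2000
    gen_ids: list[str] = []
    for k in range(n_founders):
        sex = "M" if k % 2 == 0 else "F"
        i = f"F{k:03d}"
        records.append(Record(i, None, None, sex, year0, True, "wild"))
        sex_of[i] = sex
        gen_ids.append(i)
    counter = 0
    for g in range(1, n_generations + 1):
        by_sex = {"M": [], "F": []}
        for i in gen_ids:
            by_sex[sex_of[i]].append(i)
        if not by_sex["M"] or not by_sex["F"]:
            raise ValueError(
                f"no valid opposite-sex pair available at generation {g}"
            )
        males = list(by_sex["M"])
        females = list(by_sex["F"])
        rng.shuffle(males)
        rng.shuffle(females)
        n_pairs = min(pairs_per_generation, len(males), len(females))
        next_gen: list[str] = []
        for p in range(n_pairs):
            sire, dam = males[p], females[p]
            n_off = _offspring_count(offspring_distribution, rng)
            for _ in range(n_off):
                i = f"G{g}I{counter:04d}"
                counter += 1
                sex = "M" if rng.random() < 0.5 else "F"
                records.append(
                    Record(i, sire, dam, sex, year0 + g, True, "captive")
                )
                sex_of[i] = sex
                next_gen.append(i)
        if not next_gen and g < n_generations:
            raise ValueError(f"generation {g} produced no offspring")
        gen_ids = next_gen
    return Studbook(records)


def simulate_family_groups(
    n_groups: int,
    offspring_per_group: int | tuple[int, int] | Callable = 3,
    seed: int = 0,
) -> Studbook:
    """Unrelated captive family groups: a wild founder pair plus offspring.

    Emulates a family-group sampling strategy in which each sampled group
    contributes its two parents and their brood.
    """
    rng = child_rng(seed, "simulate_family_groups")
    records: list[Record] = []
    for g in range(n_groups):
        sire = f"S{g:03d}"
        dam = f"D{g:03d}"
        records.append(Record(sire, None, None, "M", 2000, True, "wild"))
        records.append(Record(dam, None, None, "F", 2000, True, "wild"))
        for k in range(_offspring_count(offspring_per_group, rng)):
            sex = "M" if rng.random() < 0.5 else "F"
            records.append(
                Record(f"C{g:03d}_{k}", sire, dam, sex, 2001, True, "captive")
            )
    return Studbook(records)


def dyad_tally(studbook: Studbook, ids: Sequence[str] | None = None) -> dict:
    """Count parent-offspring and full-sibling dyads among ``ids``.

    Returns ``{"parent_offspring": n, "full_sib": m, "n_individuals": k}``.
    """
    if ids is None:
        ids = studbook.ids
    ids = [str(i) for i in ids]
    idset = set(ids)
    po = 0
    fs = 0
    for k, a in enumerate(ids):
        ra = studbook[a]
        for b in ids[k + 1:]:
            rb = studbook[b]
            if b in (ra.sire, ra.dam) or a in (rb.sire, rb.dam):
                po += 1
            elif (
                ra.sire is not None
                and ra.dam is not None
                and ra.sire == rb.sire
                and ra.dam == rb.dam
            ):
                fs += 1
    return {"parent_offspring": po, "full_sib": fs, "n_individuals": len(ids)}


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------
# A haplotype on one chromosome is a piecewise-constant mosaic of founder
# haplotype labels: (breaks, labels) with len(labels) == len(breaks) + 1.

Haplotype = tuple[np.ndarray, np.ndarray]

_EMPTY = np.empty(0)


def _founder_haplotype(label: int) -> Haplotype:
    return (_EMPTY, np.array([label], dtype=np.int64))


def _recombine(
    hap_a: Haplotype, hap_b: Haplotype, length: float, rng: np.random.Generator
) -> Haplotype:
    """One meiosis: crossover count ~ Poisson(length), uniform positions."""
    n_x = rng.poisson(length) if length > 0 else 0
    start = int(rng.integers(0, 2))
    if n_x == 0:
        return hap_a if start == 0 else hap_b
    cuts = np.sort(rng.uniform(0.0, length, size=n_x))
    return _normalise_mosaic(hap_a, hap_b, cuts, start, length)


def _normalise_mosaic(
    hap_a: Haplotype,
    hap_b: Haplotype,
    cuts: np.ndarray,
    start: int,
    length: float,
) -> Haplotype:
    haps = (hap_a, hap_b)
    seg_bounds = np.concatenate(([0.0], cuts, [length]))
    breaks: list[float] = []
    labels: list[int] = []
    src = start
    for s in range(len(seg_bounds) - 1):
        lo, hi = float(seg_bounds[s]), float(seg_bounds[s + 1])
        if hi <= lo:
            src = 1 - src
            continue
        b, l = haps[src]
        i0 = int(np.searchsorted(b, lo, side="right"))
        i1 = int(np.searchsorted(b, hi, side="left"))
        pos = lo
        for j in range(i0, i1 + 1):
            lab = int(l[j])
            if labels and labels[-1] == lab:
                pass
            else:
                if labels:
                    breaks.append(pos)
                labels.append(lab)
            if j < i1:
                pos = float(b[j])
        src = 1 - src
    return (np.asarray(breaks, dtype=float), np.asarray(labels, dtype=np.int64))


def _label_at(hap: Haplotype, positions: np.ndarray) -> np.ndarray:
    breaks, labels = hap
    idx = np.searchsorted(breaks, positions, side="right")
    return labels[idx]


def _shared_length(hap1: Haplotype, hap2: Haplotype, length: float) -> float:
    """Total map length on which the two mosaics carry the same label."""
    b1, l1 = hap1
    b2, l2 = hap2
    if len(b1) == 0 and len(b2) == 0:
        return length if l1[0] == l2[0] else 0.0
    edges = np.concatenate(([0.0], np.union1d(b1, b2), [length]))
    mids = 0.5 * (edges[:-1] + edges[1:])
    same = l1[np.searchsorted(b1, mids)] == l2[np.searchsorted(b2, mids)]
    return float(np.sum(np.diff(edges)[same]))


def _pair_shared_fraction(
    hapsA: list[tuple[Haplotype, Haplotype]],
    hapsB: list[tuple[Haplotype, Haplotype]],
    genome: GenomeModel,
) -> float:
    """Additive relatedness: mean over the genome of (#IBD allele pairs)/2.

    Chromosomes are weighted by genetic length; if the whole map has zero
    length every chromosome is a single segregating point with equal
    weight.
    """
    total = genome.total_length
    num = 0.0
    for c, (pa, pb) in enumerate(zip(hapsA, hapsB)):
        L = genome.chromosomes[c].length
        w = L if total > 0 else 1.0
        if total > 0 and L == 0:
            continue
        a1, a2 = pa
        b1, b2 = pb
        if total > 0:
            shared = (
                _shared_length(a1, b1, L)
                + _shared_length(a1, b2, L)
                + _shared_length(a2, b1, L)
                + _shared_length(a2, b2, L)
            ) / L
        else:
            shared = float(
                (a1[1][0] == b1[1][0])
                + (a1[1][0] == b2[1][0])
                + (a2[1][0] == b1[1][0])
                + (a2[1][0] == b2[1][0])
            )
        num += w * shared / 2.0
    denom = total if total > 0 else len(genome.chromosomes)
    return num / denom


@dataclass
class DropResult:
    """Outcome of a gene drop: IBD labels, realized relatedness, haplotypes."""

    studbook: Studbook
    genome: GenomeModel
    ibd_labels: np.ndarray  # (n, total_loci, 2) founder haplotype labels
    realized_relatedness: RelatednessMatrix
    haplotypes: dict[str, list[tuple[Haplotype, Haplotype]]]
    founder_labels: dict[str, tuple[int, int]]

    @property
    def ids(self) -> list[str]:
        return self.studbook.ids


def gene_drop(
    studbook: Studbook,
    genome: GenomeModel,
    seed: int = 0,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> DropResult:
    """Drop founder haplotypes down the pedigree with recombination.

    Every founder receives two globally unique haplotype labels; each
    transmission is one recombinant gamete per parent (Poisson crossovers,
    Haldane).  ``realized_relatedness`` holds, for every pair (or only
    ``pairs`` if given), the map-length-weighted fraction of allele pairs
    IBD; its diagonal is ``1 + realized F``.
    """
    if len(studbook) == 0:
        raise ValueError("empty pedigree")
    rng = child_rng(seed, "gene_drop")
    order = studbook.topological_order()
    n_chrom = len(genome.chromosomes)
    haps: dict[str, list[tuple[Haplotype, Haplotype]]] = {}
    founder_labels: dict[str, tuple[int, int]] = {}
    next_label = 0
    for i in order:
        s, d = studbook.parents(i)
        s = s if (s is not None and s in studbook) else None
        d = d if (d is not None and d in studbook) else None
        chroms: list[tuple[Haplotype, Haplotype]] = []
        if s is None and d is None:
            lab = (next_label, next_label + 1)
            next_label += 2
            founder_labels[i] = lab
            for c in range(n_chrom):
                chroms.append(
                    (_founder_haplotype(lab[0]), _founder_haplotype(lab[1]))
                )
        else:
            # an unknown single parent contributes fresh founder haplotypes
            gametes_s: list[Haplotype] = []
            gametes_d: list[Haplotype] = []
            if s is None or d is None:
                lab = (next_label, next_label + 1)
                next_label += 2
            for c, chrom in enumerate(genome.chromosomes):
                if s is not None:
                    gametes_s.append(
                        _recombine(*haps[s][c], chrom.length, rng)
                    )
                else:
                    gametes_s.append(
                        _recombine(
                            _founder_haplotype(lab[0]),
                            _founder_haplotype(lab[1]),
                            chrom.length,
                            rng,
                        )
                    )
                if d is not None:
                    gametes_d.append(
                        _recombine(*haps[d][c], chrom.length, rng)
                    )
                else:
                    gametes_d.append(
                        _recombine(
                            _founder_haplotype(lab[0]),
                            _founder_haplotype(lab[1]),
                            chrom.length,
                            rng,
                        )
                    )
            chroms = list(zip(gametes_s, gametes_d))
        haps[i] = chroms

    ids = studbook.ids
    total_loci = sum(len(c.positions) for c in genome.chromosomes)
    labels = np.zeros((len(ids), total_loci, 2), dtype=np.int64)
    for k, i in enumerate(ids):
        off = 0
        for c, chrom in enumerate(genome.chromosomes):
            m = len(chrom.positions)
            if m:
                h1, h2 = haps[i][c]
                labels[k, off:off + m, 0] = _label_at(h1, chrom.positions)
                labels[k, off:off + m, 1] = _label_at(h2, chrom.positions)
            off += m

    n = len(ids)
    R = np.full((n, n), np.nan)
    if pairs is None:
        wanted = [(a, b) for a in range(n) for b in range(a, n)]
    else:
        pos = {i: k for k, i in enumerate(ids)}
        wanted = [(pos[str(a)], pos[str(b)]) for a, b in pairs]
        wanted += [(k, k) for k in range(n)]
    for a, b in wanted:
        r = _pair_shared_fraction(haps[ids[a]], haps[ids[b]], genome)
        R[a, b] = r
        R[b, a] = r
    return DropResult(
        studbook=studbook,
        genome=genome,
        ibd_labels=labels,
        realized_relatedness=RelatednessMatrix(
            ids, R, {"kind": "realized_relatedness"}
        ),
        haplotypes=haps,
        founder_labels=founder_labels,
    )


def full_sib_realized(
    n_pairs: int, genome: GenomeModel, seed: int = 0
) -> np.ndarray:
    """Realized additive relatedness of independent full-sib pairs.

    A fast path over :func:`gene_drop`: each pair descends from its own
    unrelated founder couple, and only the sib-sib sharing is computed.
    """
    rng = child_rng(seed, "full_sib_realized")
    total = genome.total_length
    if total <= 0:
        raise ValueError("genome must have positive total map length")
    out = np.empty(n_pairs)
    hapP = (_founder_haplotype(0), _founder_haplotype(1))
    hapM = (_founder_haplotype(2), _founder_haplotype(3))
    for k in range(n_pairs):
        acc = 0.0
        for chrom in genome.chromosomes:
            L = chrom.length
            if L == 0:
                continue
            g1p = _recombine(*hapP, L, rng)
            g2p = _recombine(*hapP, L, rng)
            g1m = _recombine(*hapM, L, rng)
            g2m = _recombine(*hapM, L, rng)
            # parental gametes carry disjoint label sets, so only the
            # paternal-paternal and maternal-maternal comparisons count;
            # IBD allele pairs per point = [pat same] + [mat same] in {0,1,2}
            acc += _shared_length(g1p, g2p, L) + _shared_length(g1m, g2m, L)
        out[k] = acc / (2.0 * total)
    return out


# ---------------------------------------------------------------------------
# genotype emission
# ---------------------------------------------------------------------------

def _label_to_allele_map(
    n_labels: int,
    freqs: dict[int, float] | float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign an allelic state to every founder haplotype label."""
    if isinstance(freqs, dict):
        alleles = np.array(sorted(freqs))
        p = np.array([freqs[a] for a in alleles])
        return alleles[rng.choice(len(alleles), size=n_labels, p=p / p.sum())]
    return (rng.random(n_labels) < freqs).astype(np.int64)


def _locus_indices(genome: GenomeModel, names: Sequence[str]) -> np.ndarray:
    all_names = genome.locus_names
    index = {n: k for k, n in enumerate(all_names)}
    try:
        return np.array([index[n] for n in names], dtype=np.int64)
    except KeyError as e:
        raise KeyError(f"locus {e.args[0]!r} is not placed on the genome")


def emit_microsat_panel(
    drop: DropResult,
    founders: FounderPool,
    error_rate: float = 0.01,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> GenotypeTable:
    """Multiallelic microsatellite genotypes from the gene-drop IBD labels.

    Each founder haplotype label is assigned an allele from the locus
    frequencies; a genotyping error replaces an allele call with a
    uniformly chosen *other* allele of the locus; a missing call drops the
    whole genotype.
    """
    if not 0.0 <= error_rate <= 1.0 or not 0.0 <= missing_rate <= 1.0:
        raise ValueError("error_rate and missing_rate must lie in [0, 1]")
    if not founders.microsat_allele_freqs:
        raise ValueError("founder pool defines no microsatellite loci")
    rng = child_rng(seed, "emit_microsat_panel")
    loci = list(founders.microsat_allele_freqs)
    idx = _locus_indices(drop.genome, loci)
    labels = drop.ibd_labels[:, idx, :]  # (n, L, 2)
    n_labels = int(drop.ibd_labels.max()) + 1
    n, L, _ = labels.shape
    geno = np.zeros((n, L, 2), dtype=np.int32)
    for l, name in enumerate(loci):
        fr = founders.microsat_allele_freqs[name]
        amap = _label_to_allele_map(n_labels, fr, rng)
        geno[:, l, :] = amap[labels[:, l, :]]
        if error_rate > 0:
            alleles = np.array(sorted(fr))
            err = rng.random((n, 2)) < error_rate
            if err.any() and len(alleles) > 1:
                for (i, j) in zip(*np.nonzero(err)):
                    others = alleles[alleles != geno[i, l, j]]
                    geno[i, l, j] = rng.choice(others)
    if missing_rate > 0:
        miss = rng.random((n, L)) < missing_rate
        geno[miss] = -1
    return GenotypeTable(
        drop.ids, loci, geno, meta={"panel": "microsatellite"}
    )


def emit_depth_genotypes(
    drop: DropResult,
    founders: FounderPool,
    seq: SeqModel | None = None,
    seed: int = 0,
) -> VariantTable:
    """Biallelic SNP calls with read depth and allele counts.

    Per call: depth ``d`` from the sequencing model, alternate reads
    ``k ~ Binomial(d, pi)`` with ``pi = (g/2)(1-e) + (1-g/2)e`` for true
    dosage ``g`` and per-read error ``e``.  The hard call is 0/0, 0/1 or
    1/1 as k is 0, intermediate, or d; depth-0 calls are missing.
    """
    seq = seq or SeqModel()
    if not founders.snp_allele_freqs:
        raise ValueError("founder pool defines no SNP loci")
    rng = child_rng(seed, "emit_depth_genotypes")
    loci = list(founders.snp_allele_freqs)
    idx = _locus_indices(drop.genome, loci)
    labels = drop.ibd_labels[:, idx, :]
    n_labels = int(drop.ibd_labels.max()) + 1
    n, L, _ = labels.shape
    p_alt = np.array([founders.snp_allele_freqs[x] for x in loci])
    # one allelic state per (locus, founder haplotype label)
    amap = (rng.random((L, n_labels)) < p_alt[:, None]).astype(np.int8)
    true_g = (
        amap[np.arange(L)[None, :], labels[:, :, 0]]
        + amap[np.arange(L)[None, :], labels[:, :, 1]]
    ).astype(np.int64)  # (n, L) true dosage
    depth = seq.draw_depth((n, L), rng)
    if seq.missing_rate > 0:
        depth[rng.random((n, L)) < seq.missing_rate] = 0
    e = seq.error_rate
    pi = (true_g / 2.0) * (1 - e) + (1 - true_g / 2.0) * e
    alt = rng.binomial(depth, pi)
    # hard calls: 0/0 if no alt reads, 1/1 if all alt, 0/1 otherwise
    g1 = np.where(alt == 0, 0, np.where(alt == depth, 1, 0))
    g2 = np.where(alt == 0, 0, np.where(alt == depth, 1, 1))
    geno = np.stack([g1, g2], axis=2).astype(np.int32)
    geno[depth == 0] = -1
    # positions: map Morgan coordinates to 1-based bp at 1 cM ~ 1 Mb
    chrom_names: list[str] = []
    pos: list[int] = []
    for c in drop.genome.chromosomes:
        for name, x in zip(c.locus_names, c.positions):
            if name in founders.snp_allele_freqs:
                chrom_names.append(c.name)
                pos.append(int(round(x * 1e8)) + 1)
    true_table = VariantTable(
        ids=drop.ids,
        loci=loci,
        alleles=geno,
        depth=depth,
        alt_counts=alt,
        meta={"panel": "snp", "mean_depth": seq.mean_depth},
        chrom=np.array(chrom_names, dtype=object),
        pos=np.array(pos),
        ref=np.array(["A"] * L, dtype=object),
        alt=np.array(["T"] * L, dtype=object),
        qual=np.full(L, 99.0),
    )
    true_table.meta["true_dosage"] = true_g
    return true_table


# ---------------------------------------------------------------------------
# canned models
# ---------------------------------------------------------------------------

#: Sex-averaged genetic lengths (Morgans) of a 22-autosome human-like map,
#: totalling ~35.4 Morgans.
_HUMAN_LIKE_MORGANS = (
    2.84, 2.69, 2.24, 2.14, 2.04, 1.92, 1.87, 1.70, 1.68, 1.81,
    1.58, 1.75, 1.26, 1.19, 1.41, 1.34, 1.29, 1.17, 1.08, 1.08,
    0.62, 0.74,
)


def human_like_map() -> GenomeModel:
    """A 22-autosome genome with human-like genetic lengths (no loci)."""
    return GenomeModel(
        tuple(
            Chromosome(f"chr{k + 1}", L)
            for k, L in enumerate(_HUMAN_LIKE_MORGANS)
        )
    )


def snp_genome(
    n_snps: int,
    n_microsats: int = 0,
    n_chromosomes: int = 10,
    chrom_length: float = 1.0,
    seed: int = 0,
) -> GenomeModel:
    """Evenly sized chromosomes carrying uniformly placed named loci.

    SNP loci are named ``snp000...``; microsatellite loci ``ms00...`` and
    are interleaved on the same map so both panels segregate through one
    gene drop.
    """
    rng = child_rng(seed, "snp_genome")
    names = [f"snp{k:06d}" for k in range(n_snps)] + [
        f"ms{k:03d}" for k in range(n_microsats)
    ]
    chrom_of = rng.integers(0, n_chromosomes, size=len(names))
    pos = rng.uniform(0, chrom_length, size=len(names))
    chroms = []
    for c in range(n_chromosomes):
        mask = chrom_of == c
        order = np.argsort(pos[mask], kind="stable")
        cnames = tuple(np.array(names, dtype=object)[mask][order])
        chroms.append(
            Chromosome(
                f"chr{c + 1}", chrom_length, pos[mask][order], cnames
            )
        )
    return GenomeModel(tuple(chroms))


def random_founder_pool(
    genome: GenomeModel,
    maf_range: tuple[float, float] = (0.05, 0.5),
    microsat_allele_range: tuple[int, int] = (2, 4),
    seed: int = 0,
) -> FounderPool:
    """Founder frequencies for every locus named on the genome."""
    rng = child_rng(seed, "random_founder_pool")
    snp: dict[str, float] = {}
    ms: dict[int, dict[int, float]] = {}
    for name in genome.locus_names:
        if name.startswith("ms"):
            k = int(rng.integers(microsat_allele_range[0],
                                 microsat_allele_range[1] + 1))
            w = rng.dirichlet(np.full(k, 2.0))
            ms[name] = {a: float(w[a]) for a in range(k)}
        else:
            maf = float(rng.uniform(*maf_range))
            p = maf if rng.random() < 0.5 else 1.0 - maf
            snp[name] = p
    return FounderPool(snp_allele_freqs=snp, microsat_allele_freqs=ms)
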