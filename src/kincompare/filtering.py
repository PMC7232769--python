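"""SNP retention rules, LD pruning, diversity statistics and parentage
verification.

The SNP filter retains biallelic sites with minor allele frequency
strictly above 0.05, quality strictly above 20 and at most 10% missing
calls, plus one of two depth rules: a mean-depth rule (site mean across
individuals strictly above a threshold) or a per-site min/max rule
(every individual's depth within the closed interval).  No
Hardy-Weinberg filter is applied: family-structured data violate random
mating by design.

LD pruning is greedy in position order within a sliding window counted
in sites: a later site whose genotype correlation r^2 with an already
retained site in the window exceeds the threshold is dropped.  r^2 is
computed on dosages (composite LD), appropriate for unphased genotypes.

Parentage verification is allele-mismatch exclusion: a locus mismatches
when the offspring shares no allele with a claimed parent or when no
joint assignment of one allele from each parent can produce the
offspring genotype; a trio passes with at most the allowed number of
mismatching loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, VariantTable

__all__ = [
    "MeanDepthRule",
    "SiteDepthRule",
    "filter_variants",
    "ld_prune",
    "DiversityStats",
    "diversity_stats",
    "microsat_diversity",
    "parentage_check",
]


@dataclass(frozen=True)
class MeanDepthRule:
    """Retain sites whose mean depth across individuals is > ``min_mean``."""

    min_mean: float = 10.0


@dataclass(frozen=True)
class SiteDepthRule:
    """Retain sites where every individual's depth is in [min, max]."""

    min_depth: int = 5
    max_depth: int = 200


DepthRule = MeanDepthRule | SiteDepthRule


def filter_variants(
    variants: VariantTable,
    maf_min: float = 0.05,
    qual_min: float = 20.0,
    max_missing: float = 0.10,
    depth_rule: DepthRule | None = None,
) -> VariantTable:
    """Apply the SNP retention rules; inequalities are strict as stated.

    A site is kept iff it is biallelic, MAF > ``maf_min``,
    QUAL > ``qual_min``, missing fraction <= ``max_missing`` and the
    depth rule (if any) passes.  Idempotent: the rules are functions of
    per-site statistics that filtering does not change.
    """
    if variants.n_loci == 0:
        return variants
    keep = np.ones(variants.n_loci, dtype=bool)
    # biallelic: at most alleles {0, 1} among called genotypes
    keep &= ~np.any(variants.alleles > 1, axis=(0, 2))
    maf = variants.maf()
    with np.errstate(invalid="ignore"):
        keep &= np.where(np.isnan(maf), False, maf > maf_min)
    keep &= variants.qual > qual_min
    miss_frac = variants.missing_mask().mean(axis=0)
    keep &= miss_frac <= max_missing
    if depth_rule is not None:
        if variants.depth is None:
            raise ValueError("depth rule requested but table has no depth")
        d = variants.depth
        if isinstance(depth_rule, MeanDepthRule):
            keep &= d.mean(axis=0) > depth_rule.min_mean
        elif isinstance(depth_rule, SiteDepthRule):
            keep &= (d.min(axis=0) >= depth_rule.min_depth) & (
                d.max(axis=0) <= depth_rule.max_depth
            )
        else:
            raise ValueError(f"unknown depth rule {depth_rule!r}")
    return variants.subset_loci(keep)


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over co-typed."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return 0.0
    return float(np.corrcoef(xs, ys)[0, 1] ** 2)


def ld_prune(
    variants: VariantTable, r2_max: float = 0.6, window_sites: int = 1000
) -> VariantTable:
    """Greedy keep-first LD pruning within a site-count window.

    Sites are scanned in position order per chromosome; a site is dropped
    if its dosage r^2 with any *retained* site fewer than
    ``window_sites`` sites before it (original site index) exceeds
    ``r2_max``.  r^2 is pairwise-complete over co-typed individuals.
    """
    if variants.n_loci <= 1:
        return variants
    dos = variants.called_dosage()  # (n, L) with NaN at missing
    mask = (~np.isnan(dos)).astype(float)
    x0 = np.nan_to_num(dos, nan=0.0)
    x0sq = x0**2
    keep: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    lo_by_chrom: dict[str, int] = {}
    for j in range(variants.n_loci):
        c = variants.chrom[j]
        prior = kept_by_chrom.setdefault(c, [])
        lo = lo_by_chrom.get(c, 0)
        while lo < len(prior) and j - prior[lo] >= window_sites:
            lo += 1
        lo_by_chrom[c] = lo
        window = prior[lo:]
        drop = False
        if window:
            I = np.array(window, dtype=np.int64)
            mj, xj, xj2 = mask[:, j], x0[:, j], x0sq[:, j]
            MY, Y, Y2 = mask[:, I], x0[:, I], x0sq[:, I]
            n_co = MY.T @ mj
            sx = Y.T @ mj
            sy = MY.T @ xj
            sxy = Y.T @ xj
            sxx = Y2.T @ mj
            syy = MY.T @ xj2
            with np.errstate(invalid="ignore", divide="ignore"):
                num = n_co * sxy - sx * sy
                den = (n_co * sxx - sx**2) * (n_co * syy - sy**2)
                r2 = np.where(den > 0, num**2 / den, 0.0)
            drop = bool(np.any(r2[n_co >= 2] > r2_max))
        if not drop:
            prior.append(j)
            keep.append(j)
    return variants.subset_loci(np.array(keep, dtype=np.int64))


@dataclass
class DiversityStats:
    per_site: pd.DataFrame  # missingness, mean depth, he, pi
    per_individual: pd.DataFrame  # ho, n_calls
    mean_pi: float
    mean_ho: float
    sd_ho: float
    mean_he: float
    snp_density_per_kb: float


def diversity_stats(variants: VariantTable) -> DiversityStats:
    """Missingness, depth, heterozygosity, nucleotide diversity, density.

    Computed over polymorphic sites only.  Per-site expected
    heterozygosity is ``2p(1-p)`` from sample frequencies; per-site
    nucleotide diversity uses the sample-size correction
    ``pi = n/(n-1) * 2p(1-p)`` with ``n`` called alleles; per-individual
    observed heterozygosity is the fraction of heterozygous calls among
    its non-missing calls; density is sites per kb of spanned sequence.
    """
    if variants.n_loci == 0:
        raise ValueError("empty variant table")
    p = variants.alt_frequency()
    poly = (p > 0) & (p < 1)
    vt = variants.subset_loci(poly)
    p = p[poly]
    miss = vt.missing_mask()
    n_alleles = 2 * (~miss).sum(axis=0)
    he = 2.0 * p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n_alleles > 1, he * n_alleles / (n_alleles - 1), np.nan)
    per_site = pd.DataFrame(
        {
            "locus": vt.loci,
            "chrom": vt.chrom,
            "pos": vt.pos,
            "missingness": miss.mean(axis=0),
            "mean_depth": (
                vt.depth.mean(axis=0) if vt.depth is not None else np.nan
            ),
            "he": he,
            "pi": pi,
        }
    )
    dos = vt.called_dosage()
    het = dos == 1
    n_calls = (~np.isnan(dos)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ho = het.sum(axis=1) / n_calls
    per_ind = pd.DataFrame({"id": vt.ids, "ho": ho, "n_calls": n_calls})
    span_kb = 0.0
    for c in pd.unique(vt.chrom):
        pc = vt.pos[vt.chrom == c]
        span_kb += (pc.max() - pc.min() + 1) / 1000.0
    return DiversityStats(
        per_site=per_site,
        per_individual=per_ind,
        mean_pi=float(np.nanmean(pi)),
        mean_ho=float(np.nanmean(ho)),
        sd_ho=float(np.nanstd(ho)),
        mean_he=float(np.mean(he)),
        snp_density_per_kb=float(vt.n_loci / span_kb) if span_kb > 0 else 0.0,
    )


def microsat_diversity(genotypes: GenotypeTable) -> pd.DataFrame:
    """Per-locus allele count, observed/expected heterozygosity and flags.

    Monomorphic loci and loci amplifying in at most half the individuals
    are flagged for exclusion.
    """
    rows = []
    for l, name in enumerate(genotypes.loci):
        g = genotypes.alleles[:, l, :]
        called = ~np.any(g < 0, axis=1)
        if called.sum() == 0:
            raise ValueError(f"locus {name} has zero calls")
        gc = g[called]
        alleles, counts = np.unique(gc.ravel(), return_counts=True)
        pfreq = counts / counts.sum()
        ho = float(np.mean(gc[:, 0] != gc[:, 1]))
        he = float(1.0 - np.sum(pfreq**2))
        call_rate = called.mean()
        rows.append(
            {
                "locus": name,
                "n_alleles": len(alleles),
                "ho": ho,
                "he": he,
                "call_rate": float(call_rate),
                "monomorphic": len(alleles) == 1,
                "low_amplification": call_rate < 0.5,
                "excluded": len(alleles) == 1 or call_rate < 0.5,
            }
        )
    return pd.DataFrame(rows)


def _locus_mismatch(
    off: np.ndarray, sire: np.ndarray | None, dam: np.ndarray | None
) -> bool:
    """True if the offspring genotype is incompatible at this locus."""

    def shares(child, parent):
        return bool(np.isin(child, parent).any())

    if sire is not None and not shares(off, sire):
        return True
    if dam is not None and not shares(off, dam):
        return True
    if sire is not None and dam is not None:
        o1, o2 = int(off[0]), int(off[1])
        for a, b in ((o1, o2), (o2, o1)):
            if np.isin(a, sire).any() and np.isin(b, dam).any():
                return False
        return True
    return False


def parentage_check(
    genotypes: GenotypeTable,
    trios: Sequence[tuple[str, str | None, str | None]],
    max_mismatch_loci: int = 1,
) -> pd.DataFrame:
    """Allele-mismatch exclusion over claimed (offspring, sire, dam) trios.

    Loci with a missing call in any claimed member are skipped; a trio
    passes when at most ``max_mismatch_loci`` loci mismatch.
    """
    rows = []
    for off_id, sire_id, dam_id in trios:
        io = genotypes.index_of(off_id)
        is_ = genotypes.index_of(sire_id) if sire_id is not None else None
        id_ = genotypes.index_of(dam_id) if dam_id is not None else None
        mismatches = 0
        n_used = 0
        for l in range(genotypes.n_loci):
            off = genotypes.alleles[io, l]
            if np.any(off < 0):
                continue
            sire = None
            if is_ is not None:
                sire = genotypes.alleles[is_, l]
                if np.any(sire < 0):
                    continue
            dam = None
            if id_ is not None:
                dam = genotypes.alleles[id_, l]
                if np.any(dam < 0):
                    continue
            n_used += 1
            if _locus_mismatch(off, sire, dam):
                mismatches += 1
        if n_used == 0:
            raise ValueError(
                f"trio ({off_id}, {sire_id}, {dam_id}) shares no typed loci"
            )
        rows.append(
            {
                "offspring": off_id,
                "sire": sire_id,
                "dam": dam_id,
                "n_loci_used": n_used,
                "n_mismatch_loci": mismatches,
                "pass": mismatches <= max_mismatch_loci,
            }
        )
    return pd.DataFrame(rows)
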