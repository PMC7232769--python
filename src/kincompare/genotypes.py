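"""In-memory genotype containers.

:class:`GenotypeTable` holds individuals x loci allele calls.  Alleles are
small non-negative integers (for SNPs: 0 = reference, 1 = alternate; for
microsatellites: arbitrary allele labels); ``-1`` encodes a missing call.
Sequencing-aware tables additionally carry per-call read depth and
alternate-allele read counts, from which continuous dosages ``2k/d`` are
derived for the depth-aware relatedness estimator.

:class:`VariantTable` is the VCF-shaped specialisation with per-site
chromosome, position, alleles and quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["GenotypeTable", "VariantTable"]

MISSING = -1


@dataclass
class GenotypeTable:
    ids: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n, L, 2) int; -1 = missing
    depth: np.ndarray | None = None  # (n, L) int read depth
    alt_counts: np.ndarray | None = None  # (n, L) int alt-allele reads (biallelic)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        n, L = len(self.ids), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        for name, arr in (("depth", self.depth), ("alt_counts", self.alt_counts)):
            if arr is not None and np.asarray(arr).shape != (n, L):
                raise ValueError(f"{name} shape {np.asarray(arr).shape} != ({n}, {L})")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.alt_counts is not None:
            self.alt_counts = np.asarray(self.alt_counts, dtype=np.int32)
        self._index = {i: k for k, i in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate individual ids")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def index_of(self, ind: str) -> int:
        return self._index[str(ind)]

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean: True where the call is missing."""
        return np.any(self.alleles < 0, axis=2)

    def is_biallelic(self) -> bool:
        return bool(np.all(self.alleles <= 1))

    def called_dosage(self) -> np.ndarray:
        """(n, L) float alt-allele count of the hard calls; NaN where missing."""
        d = self.alleles.sum(axis=2).astype(float)
        d[self.missing_mask()] = np.nan
        return d

    def read_dosage(self) -> np.ndarray:
        """(n, L) continuous dosage 2k/d from read counts; NaN at depth 0.

        Requires per-call depth and alt counts.
        """
        if self.depth is None or self.alt_counts is None:
            raise ValueError(
                "read_dosage requires per-call depth and alt-allele counts "
                "(AD); this table has none"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            x = 2.0 * self.alt_counts / self.depth
        x = np.asarray(x, dtype=float)
        x[self.depth == 0] = np.nan
        return x

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeTable":
        idx = [self._index[str(i)] for i in ids]
        return GenotypeTable(
            list(ids),
            list(self.loci),
            self.alleles[idx],
            None if self.depth is None else self.depth[idx],
            None if self.alt_counts is None else self.alt_counts[idx],
            dict(self.meta),
        )

    def subset_loci(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeTable(
            list(self.ids),
            [self.loci[k] for k in keep],
            self.alleles[:, keep],
            None if self.depth is None else self.depth[:, keep],
            None if self.alt_counts is None else self.alt_counts[:, keep],
            dict(self.meta),
        )


@dataclass
class VariantTable(GenotypeTable):
    """Biallelic-or-multiallelic variant sites with VCF-style metadata.

    Positions are 1-based, sorted within each chromosome.
    """

    chrom: np.ndarray = None  # (L,) str
    pos: np.ndarray = None  # (L,) int, 1-based
    ref: np.ndarray = None  # (L,) str
    alt: np.ndarray = None  # (L,) str (comma-joined if multiallelic)
    qual: np.ndarray = None  # (L,) float

    def __post_init__(self) -> None:
        super().__post_init__()
        L = self.n_loci
        if self.chrom is None:
            self.chrom = np.array(["1"] * L)
        if self.pos is None:
            self.pos = np.arange(1, L + 1)
        if self.ref is None:
            self.ref = np.array(["A"] * L)
        if self.alt is None:
            self.alt = np.array(["T"] * L)
        if self.qual is None:
            self.qual = np.full(L, 99.0)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.qual = np.asarray(self.qual, dtype=float)
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt"), (self.qual, "qual")):
            if len(arr) != L:
                raise ValueError(f"{name} has length {len(arr)} != {L} loci")

    def subset_loci(self, keep: np.ndarray) -> "VariantTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return VariantTable(
            ids=list(self.ids),
            loci=[self.loci[k] for k in keep],
            alleles=self.alleles[:, keep],
            depth=None if self.depth is None else self.depth[:, keep],
            alt_counts=None if self.alt_counts is None else self.alt_counts[:, keep],
            meta=dict(self.meta),
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ref=self.ref[keep],
            alt=self.alt[keep],
            qual=self.qual[keep],
        )

    def alt_frequency(self) -> np.ndarray:
        """(L,) sample alternate-allele frequency over non-missing calls."""
        valid = ~self.missing_mask()
        alt = np.where(valid[:, :, None], self.alleles, 0).sum(axis=(0, 2))
        n = 2 * valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)
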