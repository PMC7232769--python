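"""Readers and writers for the package's on-disk formats.

* Studbook CSV: ``id,sire,dam,sex,birth_year,alive,origin`` with empty
  parent fields meaning unknown.
* VCF 4.2 with GT, DP and AD per call (uncompressed text on write; any
  cyvcf2-readable file on read).  Multiallelic records are excluded on
  read with a logged count.  Positions are 1-based.
* Microsatellite CSV: ``id`` then two columns per locus
  (``<locus>_1``, ``<locus>_2``); empty cells are missing calls.
* Square matrices: see :meth:`kincompare.matrices.LabeledMatrix.to_csv`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, VariantTable
from .pedigree import Record, Studbook

__all__ = [
    "read_studbook",
    "write_studbook",
    "read_variants",
    "write_vcf",
    "read_microsats",
    "write_microsats",
]

log = logging.getLogger("kincompare")


# ---------------------------------------------------------------------------
# studbook
# ---------------------------------------------------------------------------

_STUDBOOK_COLUMNS = ["id", "sire", "dam", "sex", "birth_year", "alive", "origin"]


def read_studbook(path) -> Studbook:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _STUDBOOK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"studbook file lacks columns: {missing}")
    seen: set[str] = set()
    records = []
    for _, row in df.iterrows():
        i = row["id"].strip()
        if not i:
            raise ValueError("studbook contains a record with empty id")
        if i in seen:
            raise ValueError(f"duplicate studbook id: {i!r}")
        seen.add(i)
        records.append(
            Record(
                id=i,
                sire=row["sire"].strip() or None,
                dam=row["dam"].strip() or None,
                sex=(row["sex"].strip().upper() or "U"),
                birth_year=(
                    int(row["birth_year"]) if row["birth_year"].strip() else None
                ),
                alive=row["alive"].strip().lower() in ("1", "true", "yes", "y"),
                origin=row["origin"].strip() or "captive",
            )
        )
    return Studbook(records)


def write_studbook(studbook: Studbook, path) -> None:
    rows = []
    for r in studbook.records:
        rows.append(
            {
                "id": r.id,
                "sire": r.sire or "",
                "dam": r.dam or "",
                "sex": r.sex,
                "birth_year": "" if r.birth_year is None else r.birth_year,
                "alive": "true" if r.alive else "false",
                "origin": r.origin,
            }
        )
    pd.DataFrame(rows, columns=_STUDBOOK_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(variants: VariantTable, path) -> None:
    """Uncompressed VCF 4.2 with GT:DP:AD per call."""
    has_depth = variants.depth is not None and variants.alt_counts is not None
    fmt = "GT:DP:AD" if has_depth else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_depth:
            fh.write(
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            )
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths">\n'
            )
        for c in pd.unique(variants.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(variants.ids)
            + "\n"
        )
        for l in range(variants.n_loci):
            cells = []
            for i in range(variants.n_individuals):
                a, b = variants.alleles[i, l]
                gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
                if has_depth:
                    d = int(variants.depth[i, l])
                    alt = int(variants.alt_counts[i, l])
                    cells.append(f"{gt}:{d}:{d - alt},{alt}")
                else:
                    cells.append(gt)
            fh.write(
                "\t".join(
                    [
                        str(variants.chrom[l]),
                        str(int(variants.pos[l])),
                        str(variants.loci[l]),
                        str(variants.ref[l]),
                        str(variants.alt[l]),
                        f"{variants.qual[l]:g}",
                        "PASS",
                        ".",
                        fmt,
                    ]
                    + cells
                )
                + "\n"
            )


def read_variants(path) -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    Multiallelic records are excluded (their count is logged); GT, DP and
    AD are preserved when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    n = len(ids)
    chrom, pos, ref, alt, qual, names = [], [], [], [], [], []
    gts, dps, ads = [], [], []
    n_multi = 0
    has_depth = False
    for k, v in enumerate(vcf):
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        names.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        g = np.array(v.genotypes, dtype=object)
        row = np.full((n, 2), -1, dtype=np.int32)
        for i in range(n):
            a, b = g[i][0], g[i][1]
            if a >= 0 and b >= 0:
                row[i] = (a, b)
        gts.append(row)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if dp is not None and ad is not None:
            has_depth = True
            dpc = dp.reshape(n).astype(np.int64)
            dpc = np.where(dpc < 0, 0, dpc)
            adc = ad.reshape(n, -1)[:, 1].astype(np.int64)
            adc = np.where(adc < 0, 0, adc)
            dps.append(dpc)
            ads.append(adc)
        else:
            dps.append(np.zeros(n, dtype=np.int64))
            ads.append(np.zeros(n, dtype=np.int64))
    if n_multi:
        log.info("excluded %d multiallelic records", n_multi)
    L = len(pos)
    alleles = (
        np.stack(gts, axis=1) if L else np.zeros((n, 0, 2), dtype=np.int32)
    )
    return VariantTable(
        ids=ids,
        loci=names,
        alleles=alleles,
        depth=np.stack(dps, axis=1) if (L and has_depth) else None,
        alt_counts=np.stack(ads, axis=1) if (L and has_depth) else None,
        meta={"source": str(path), "n_multiallelic_excluded": n_multi},
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qual=np.array(qual, dtype=float),
    )


# ---------------------------------------------------------------------------
# microsatellites
# ---------------------------------------------------------------------------

def write_microsats(genotypes: GenotypeTable, path) -> None:
    cols = {"id": genotypes.ids}
    for l, name in enumerate(genotypes.loci):
        for k in (0, 1):
            vals = genotypes.alleles[:, l, k]
            cols[f"{name}_{k + 1}"] = [
                "" if v < 0 else str(int(v)) for v in vals
            ]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_microsats(path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError("microsatellite CSV needs an 'id' column")
    loci: list[str] = []
    for c in df.columns:
        if c.endswith("_1"):
            base = c[:-2]
            if f"{base}_2" not in df.columns:
                raise ValueError(f"locus {base} lacks its second allele column")
            loci.append(base)
    ids = [s.strip() for s in df["id"]]
    if len(set(ids)) != len(ids):
        dup = [i for i in ids if ids.count(i) > 1][0]
        raise ValueError(f"duplicate individual id: {dup!r}")
    n, L = len(ids), len(loci)
    alleles = np.full((n, L, 2), -1, dtype=np.int32)
    for l, base in enumerate(loci):
        for k in (0, 1):
            col = df[f"{base}_{k + 1}"]
            for i, v in enumerate(col):
                v = v.strip()
                if v:
                    alleles[i, l, k] = int(v)
    # a call with one missing allele is treated as fully missing
    half = (alleles < 0).any(axis=2)
    alleles[half] = -1
    return GenotypeTable(ids, loci, alleles, meta={"source": str(path)})
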