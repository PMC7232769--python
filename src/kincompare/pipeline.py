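"""End-to-end comparison pipeline.

``run_compare`` reproduces, on synthetic or user data, the full
comparison of pedigree-, microsatellite- and SNP-based relatedness and
its downstream pairing recommendations: pedigree matrices, SNP
filtering, all estimators (with diagonal scaling), estimator-selection
ranking, mean-kinship and mate-suitability tables per approach, and the
Mantel / Pearson / Kruskal-Wallis comparison statistics, plus a
dyad-class summary (mean +/- SD of R for parent-offspring and full-sib
pairs under each approach) and a rank/score concordance report.

Every stochastic step derives its stream from the single config seed, so
two runs of the same config are numerically identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as kio
from .estimators import (
    AlleleFrequencies,
    allele_frequencies,
    estimate_dyadic_ml,
    estimate_king,
    estimate_kgd,
    estimate_rxy,
    scale_relatedness,
)
from .filtering import (
    MeanDepthRule,
    SiteDepthRule,
    diversity_stats,
    filter_variants,
    ld_prune,
    microsat_diversity,
    parentage_check,
)
from .matrices import LabeledMatrix
from .pairing import (
    compare_recommendations,
    empirical_kinship,
    mean_kinship_table,
    msi_scores,
)
from .pedigree import (
    Studbook,
    kinship_matrix,
    kinship_to_relatedness,
    pedigree_summary,
    validate_studbook,
    _known_ancestry_fractions,
)
from .selection import dyad_distribution, rank_estimators, simulate_dyad_genotypes
from .simulate import (
    FounderPool,
    SeqModel,
    emit_depth_genotypes,
    emit_microsat_panel,
    gene_drop,
    random_founder_pool,
    simulate_family_groups,
    snp_genome,
)
from .stats import kruskal_bonferroni, mantel, pearson_offdiag

log = logging.getLogger("kincompare")

__all__ = ["SyntheticConfig", "PipelineConfig", "run_compare"]


@dataclass
class SyntheticConfig:
    n_family_groups: int = 6
    offspring_per_group: int = 4
    n_snps: int = 20_000
    n_microsats: int = 8
    n_chromosomes: int = 10
    chrom_length_morgans: float = 1.0
    mean_depth: float = 25.0
    snp_error_rate: float = 0.001
    microsat_error_rate: float = 0.01
    microsat_missing_rate: float = 0.02


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    studbook_path: str | None = None
    vcf_path: str | None = None
    microsat_path: str | None = None
    maf_min: float = 0.05
    qual_min: float = 20.0
    max_missing: float = 0.10
    depth_rule: str = "mean"  # "mean" | "minmax" | "none"
    mean_depth_min: float = 10.0
    site_depth_min: int = 5
    site_depth_max: int = 200
    ld_r2: float = 0.6
    ld_window: int = 1000
    n_dyads: int = 1000
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        real = self.studbook_path is not None
        if real == (self.synthetic is not None):
            raise ValueError(
                "exactly one of synthetic generation or real input paths "
                "must be configured"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(
            synthetic=SyntheticConfig(**syn) if isinstance(syn, dict) else None,
            **raw,
        )
        return cfg


def _depth_rule(config: PipelineConfig):
    if config.depth_rule == "mean":
        return MeanDepthRule(config.mean_depth_min)
    if config.depth_rule == "minmax":
        return SiteDepthRule(config.site_depth_min, config.site_depth_max)
    if config.depth_rule == "none":
        return None
    raise ValueError(f"unknown depth rule {config.depth_rule!r}")


def _dyad_classes(studbook: Studbook) -> dict[str, list[tuple[str, str]]]:
    """Parent-offspring and full-sib id pairs recorded in the studbook."""
    po: list[tuple[str, str]] = []
    fs: list[tuple[str, str]] = []
    ids = studbook.ids
    for k, a in enumerate(ids):
        ra = studbook[a]
        for b in ids[k + 1:]:
            rb = studbook[b]
            if b in (ra.sire, ra.dam) or a in (rb.sire, rb.dam):
                po.append((a, b))
            elif (
                ra.sire is not None
                and ra.dam is not None
                and (ra.sire, ra.dam) == (rb.sire, rb.dam)
            ):
                fs.append((a, b))
    return {"parent_offspring": po, "full_sib": fs}


def _class_summary(
    matrices: dict[str, LabeledMatrix], classes: dict[str, list[tuple[str, str]]]
) -> pd.DataFrame:
    rows = []
    for approach, M in matrices.items():
        for cls, pairs in classes.items():
            vals = np.array([M.loc(a, b) for a, b in pairs])
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "approach": approach,
                    "dyad_class": cls,
                    "n_pairs": len(vals),
                    "mean_r": float(vals.mean()) if len(vals) else np.nan,
                    "sd_r": float(vals.std()) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_compare(config: PipelineConfig) -> dict:
    """Run the full comparison; returns a report bundle (dict).

    When ``config.outdir`` is set, matrices and tables are also written
    there as CSV/TSV.
    """
    seed = config.seed
    report: dict = {"seed": seed}

    # -- stage 1: inputs -------------------------------------------------
    if config.synthetic is not None:
        syn = config.synthetic
        log.info("generating synthetic inputs (seed %d)", seed)
        studbook = simulate_family_groups(
            syn.n_family_groups, syn.offspring_per_group, seed=seed
        )
        genome = snp_genome(
            syn.n_snps,
            syn.n_microsats,
            syn.n_chromosomes,
            syn.chrom_length_morgans,
            seed=seed,
        )
        pool = random_founder_pool(genome, seed=seed)
        drop = gene_drop(studbook, genome, seed=seed)
        microsats = emit_microsat_panel(
            drop,
            pool,
            syn.microsat_error_rate,
            syn.microsat_missing_rate,
            seed=seed,
        )
        variants = emit_depth_genotypes(
            drop,
            pool,
            SeqModel(mean_depth=syn.mean_depth, error_rate=syn.snp_error_rate),
            seed=seed,
        )
        snp_freqs = AlleleFrequencies.from_alt(
            list(pool.snp_allele_freqs),
            np.array(list(pool.snp_allele_freqs.values())),
        )
    else:
        log.info("loading real inputs")
        studbook = kio.read_studbook(config.studbook_path)
        variants = kio.read_variants(config.vcf_path)
        microsats = (
            kio.read_microsats(config.microsat_path)
            if config.microsat_path
            else None
        )
        drop = None
        snp_freqs = None

    issues = validate_studbook(studbook)
    report["validation_issues"] = [dataclasses.asdict(i) for i in issues]
    if issues:
        log.warning("studbook validation reported %d issues", len(issues))

    # -- stage 2: pedigree matrices --------------------------------------
    K_ped = kinship_matrix(studbook)
    R_ped = kinship_to_relatedness(K_ped)
    report["pedigree_summary"] = dataclasses.asdict(pedigree_summary(studbook))

    # -- stage 3: filtering ----------------------------------------------
    rule = _depth_rule(config)
    log.info(
        "filtering: maf>%.3g qual>%.3g missing<=%.3g depth_rule=%s",
        config.maf_min, config.qual_min, config.max_missing, rule,
    )
    filtered = filter_variants(
        variants, config.maf_min, config.qual_min, config.max_missing, rule
    )
    pruned = ld_prune(filtered, config.ld_r2, config.ld_window)
    log.info(
        "sites: %d raw -> %d filtered -> %d after LD pruning",
        variants.n_loci, filtered.n_loci, pruned.n_loci,
    )
    report["n_sites"] = {
        "raw": variants.n_loci,
        "filtered": filtered.n_loci,
        "ld_pruned": pruned.n_loci,
    }
    div = diversity_stats(pruned)
    report["snp_diversity"] = {
        "mean_pi": div.mean_pi,
        "mean_ho": div.mean_ho,
        "sd_ho": div.sd_ho,
        "mean_he": div.mean_he,
        "snp_density_per_kb": div.snp_density_per_kb,
    }
    if microsats is not None:
        ms_div = microsat_diversity(microsats)
        report["microsat_diversity"] = ms_div.to_dict("records")
        kept = ~ms_div["excluded"].to_numpy()
        microsats = microsats.subset_loci(kept)
        trios = [
            (r.id, r.sire, r.dam)
            for r in studbook.records
            if r.sire is not None and r.dam is not None
        ]
        if trios:
            pc = parentage_check(microsats, trios)
            report["parentage"] = {
                "n_trios": len(pc),
                "n_pass": int(pc["pass"].sum()),
            }

    # -- stage 4: estimators ---------------------------------------------
    matrices: dict[str, LabeledMatrix] = {"pedigree": R_ped}
    if microsats is not None:
        ms_freqs = allele_frequencies(microsats)
        rxy = estimate_rxy(microsats, ms_freqs)
        ml = estimate_dyadic_ml(microsats, ms_freqs, error_rate=0.01)
        matrices["microsat"] = rxy.matrix
        report["microsat_estimators"] = ["rxy", "dyadic_ml"]
    if snp_freqs is not None:
        # restrict the founder frequencies to the loci surviving filtering
        by_name = dict(zip(snp_freqs.loci, snp_freqs.alt()))
        snp_freqs = AlleleFrequencies.from_alt(
            list(pruned.loci), np.array([by_name[l] for l in pruned.loci])
        )
    kgd = estimate_kgd(pruned, snp_freqs)
    kgd_scaled = scale_relatedness(kgd)
    king = estimate_king(pruned)
    matrices["snp"] = kgd_scaled.matrix
    report["snp_estimators"] = ["kgd_scaled", "king"]

    # -- stage 5: estimator selection ------------------------------------
    if microsats is not None and len(studbook.ids) >= 2:
        classes = dyad_distribution(studbook, n_target=config.n_dyads)
        sim = simulate_dyad_genotypes(
            classes,
            ms_freqs,
            error_rate=config.synthetic.microsat_error_rate
            if config.synthetic
            else 0.01,
            missing_rate=config.synthetic.microsat_missing_rate
            if config.synthetic
            else 0.02,
            seed=seed,
        )
        ranking = rank_estimators(
            sim,
            {"rxy": estimate_rxy, "dyadic_ml": estimate_dyadic_ml},
            freqs=ms_freqs,
        )
        report["estimator_ranking"] = ranking.to_dict("records")

    # -- stage 6: pairing ------------------------------------------------
    sexes = studbook.sexes()
    living = studbook.living_ids()
    unknown = {
        i: 1.0 - f for i, f in _known_ancestry_fractions(studbook).items()
    }
    pairing_tables = {}
    for approach, M in matrices.items():
        if approach == "pedigree":
            K = K_ped
            unk = unknown
        else:
            K = empirical_kinship(M)
            unk = None  # empirical-only analyses assume known ancestry
        mk = mean_kinship_table(K, sexes, living)
        msi = msi_scores(K, sexes, living, unk)
        pairing_tables[approach] = {"mk": mk, "msi": msi}
    report["mean_msi"] = {
        a: float(t["msi"].category.mean()) for a, t in pairing_tables.items()
    }

    # -- stage 7: comparison statistics ----------------------------------
    names = list(matrices)
    comparisons = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            A = matrices[a].reindex(living)
            B = matrices[b].reindex(living)
            m = mantel(A, B, n_perm=1000, seed=seed)
            pr, pp = pearson_offdiag(A, B)
            comparisons[f"{a}_vs_{b}"] = {
                "mantel_r": m.r,
                "mantel_p": m.p_value,
                "pearson_r": pr,
                "pearson_p": pp,
            }
    report["matrix_comparisons"] = comparisons
    msi_groups = [
        pairing_tables[a]["msi"].category.ravel().astype(float) for a in names
    ]
    if len(msi_groups) >= 2:
        report["msi_kruskal"] = kruskal_bonferroni(
            msi_groups, n_comparisons=max(1, len(names) - 1)
        )

    concordance = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            concordance[f"{a}_vs_{b}"] = compare_recommendations(
                pairing_tables[a]["mk"],
                pairing_tables[b]["mk"],
                pairing_tables[a]["msi"],
                pairing_tables[b]["msi"],
            )
    report["concordance"] = concordance

    # -- stage 8: dyad-class summary (the headline precision figure) -----
    classes_obs = _dyad_classes(studbook)
    summary = _class_summary(matrices, classes_obs)
    report["dyad_class_summary"] = summary.to_dict("records")

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        kio.write_studbook(studbook, out / "studbook.csv")
        for name, M in matrices.items():
            M.to_csv(out / f"relatedness_{name}.csv")
        summary.to_csv(out / "dyad_class_summary.tsv", sep="\t", index=False)
        for approach, t in pairing_tables.items():
            t["mk"].to_csv(out / f"mk_{approach}.tsv", sep="\t", index=False)
            t["msi"].to_frame().to_csv(
                out / f"msi_{approach}.tsv", sep="\t", index=False
            )
        pd.DataFrame(
            [
                {"comparison": k, **v}
                for k, v in report["matrix_comparisons"].items()
            ]
        ).to_csv(out / "matrix_comparisons.tsv", sep="\t", index=False)
        log.info("wrote outputs to %s", out)

    return report
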