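"""End-to-end orchestration: rarefy → cores → seawater overlap → statistics.

:func:`run_all` executes the full analysis on a count table + metadata pair
and returns a :class:`RunResult`; :func:`write_results` exports every
product as TSV/Newick/JSON into an output directory together with a
manifest (parameters, seeds, dropped samples) sufficient to reproduce the
run exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import community_stats, multivariate, sw_overlap
from .core_analysis import (CoreSet, SpeciesSpecificResult, core_size_vs_replicates,
                            core_summary, extract_core, species_specific)
from .io_tables import (CountTable, SampleMetadata, TaxonomyTable, SEAWATER_GROUP,
                        validate_pair)
from .preprocess import DEFAULT_RAREFACTION_DEPTH, rarefy, to_relative_abundance, aggregate_taxa

__all__ = ["RunConfig", "RunResult", "run_all", "write_results"]


@dataclass
class RunConfig:
    """Every numeric setting of the workflow, with the reference defaults."""

    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    seed: int = 0
    occurrence_threshold: float = 1.0
    sw_abundance_cutoff_pct: float = 0.01
    rare_cutoff_pct: float = 0.01
    highly_abundant_cutoff_pct: float = 1.0
    heatmap_floor_pct: float = 1.0
    n_permutations: int = 999
    alpha: float = 0.05
    indval_alpha: float = 0.01
    indval_threshold: float = 0.6
    linkage: str = "average"

    def validate(self) -> None:
        if not 0 < self.occurrence_threshold <= 1:
            raise ValueError("occurrence_threshold must be in (0, 1]")
        if self.rarefaction_depth < 1 or self.n_permutations < 1:
            raise ValueError("depth and permutation number must be positive")
        for name in ("sw_abundance_cutoff_pct", "rare_cutoff_pct",
                     "highly_abundant_cutoff_pct", "heatmap_floor_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cannot be negative")
        if not (0 < self.alpha < 1 and 0 < self.indval_alpha < 1):
            raise ValueError("alpha levels must be in (0, 1)")
        if not 0 <= self.indval_threshold <= 1:
            raise ValueError("indval_threshold must be in [0, 1]")


@dataclass
class RunResult:
    config: RunConfig
    rarefied: CountTable
    dropped_samples: list[str]
    cores: dict[str, CoreSet]
    sw_core_ref: "sw_overlap.SWReference"
    abundant_ref: "sw_overlap.SWReference"
    specific: dict[str, SpeciesSpecificResult]
    overlap_core: dict[str, "sw_overlap.OverlapReport"]
    overlap_abundant: dict[str, "sw_overlap.OverlapReport"]
    method_difference: pd.Series
    enrichment: dict[str, "sw_overlap.EnrichmentFlag"]
    contaminants: pd.DataFrame
    summary: pd.DataFrame
    correlations: tuple
    core_shannon: pd.DataFrame
    shannon_kruskal: tuple | None
    sample_dendrogram: "community_stats.Dendrogram"
    permanova_species: "multivariate.PermanovaResult"
    permanova_habitat: "multivariate.PermanovaResult"
    permdisp_species: "multivariate.DispersionResult"
    permdisp_habitat: "multivariate.DispersionResult"
    indval: list
    heatmap: "community_stats.HeatmapExport"
    stage_log: list[str] = field(default_factory=list)


def run_all(
    table: CountTable,
    meta: SampleMetadata,
    taxonomy: TaxonomyTable | None = None,
    config: RunConfig | None = None,
    permissive: bool = False,
) -> RunResult:
    """Run the whole analysis; any stage error aborts with the stage named."""
    config = config or RunConfig()
    config.validate()
    log: list[str] = []
    stage = "validate"
    try:
        report = validate_pair(table, meta)
        if not report.consistent:
            if not permissive:
                raise ValueError(
                    f"sample sets differ (table-only {report.only_in_table}, "
                    f"metadata-only {report.only_in_metadata}); pass permissive=True "
                    "to proceed on the intersection")
            table = table.subset_samples(report.shared)
        log.append(f"validate: {len(report.shared)} shared samples")

        stage = "rarefy"
        rarefied, rlog = rarefy(table, depth=config.rarefaction_depth,
                                seed=config.seed, drop_below=True)
        meta_kept = SampleMetadata(meta.data.loc[rarefied.sample_ids].copy())
        log.append(f"rarefy: depth={rlog.depth} seed={rlog.seed} "
                   f"dropped={rlog.dropped_samples}")

        stage = "core extraction"
        groups = meta_kept.sponge_groups
        cores = {g: extract_core(rarefied, meta_kept, g, config.occurrence_threshold)
                 for g in groups}
        log.append(f"core: {len(cores)} sponge cores")

        stage = "species-specific"
        specific = species_specific(list(cores.values()))

        stage = "seawater references"
        sw_core_ref = sw_overlap.sw_core(rarefied, meta_kept)
        abundant_ref = sw_overlap.abundant_sw(rarefied, meta_kept,
                                              cutoff_pct=config.sw_abundance_cutoff_pct)
        log.append(f"swref: core={len(sw_core_ref.taxa)} abundant={len(abundant_ref.taxa)}")

        stage = "overlap"
        overlap_core = {g: sw_overlap.overlap(cores[g], sw_core_ref) for g in groups}
        overlap_abundant = {g: sw_overlap.overlap(cores[g], abundant_ref) for g in groups}
        method_diff = pd.Series({
            g: sw_overlap.method_difference(overlap_core[g], overlap_abundant[g])
            for g in groups})
        enrichment = sw_overlap.enrichment_flags(overlap_core,
                                                 rare_cutoff_pct=config.rare_cutoff_pct)
        contaminants = sw_overlap.potential_contaminants(
            overlap_core, sw_abundant_cutoff_pct=config.highly_abundant_cutoff_pct,
            core_rare_cutoff_pct=config.rare_cutoff_pct)

        stage = "summary"
        summary = core_summary(rarefied, meta_kept, list(cores.values()),
                               specific=specific, overlap_reports=overlap_core)
        correlations = (core_size_vs_replicates(summary)
                        if len(summary) >= 4 else None)

        stage = "diversity"
        shannon_rows = []
        for g in groups:
            core_cols = sorted(cores[g].taxa)
            for s in meta_kept.samples_of(g):
                shannon_rows.append({
                    "group": g, "sample": s,
                    "habitat_class": meta_kept.habitat_of(g),
                    "core_shannon": community_stats.shannon(
                        rarefied.data.loc[s, core_cols].to_numpy()),
                })
        core_shannon = pd.DataFrame(shannon_rows)
        by_species = core_shannon.groupby(["group", "habitat_class"], sort=False)[
            "core_shannon"].mean().reset_index()
        hma = by_species.loc[by_species["habitat_class"] == "HMA", "core_shannon"]
        lma = by_species.loc[by_species["habitat_class"] == "LMA", "core_shannon"]
        shannon_kw = (community_stats.kruskal_wallis([hma, lma])
                      if len(hma) and len(lma) and len(hma) + len(lma) >= 5 else None)

        stage = "distances"
        rel = to_relative_abundance(rarefied)
        dm = community_stats.bray_curtis(rel)
        dendro = community_stats.hcluster(dm, method=config.linkage)

        stage = "permanova"
        grouping_species = meta_kept.grouping(dm.ids, "group")
        sponge_ids = [s for s in dm.ids
                      if grouping_species[s] != SEAWATER_GROUP]
        dm_sponge = dm.filter(sponge_ids)
        permanova_species = multivariate.permanova(
            dm_sponge, meta_kept.grouping(sponge_ids, "group"),
            n_permutations=config.n_permutations, seed=config.seed, factor="species")
        permanova_habitat = multivariate.permanova(
            dm_sponge, meta_kept.grouping(sponge_ids, "habitat_class"),
            n_permutations=config.n_permutations, seed=config.seed, factor="habitat")

        stage = "permdisp"
        permdisp_species = multivariate.permdisp(
            dm_sponge, meta_kept.grouping(sponge_ids, "group"),
            n_permutations=config.n_permutations, seed=config.seed, factor="species")
        permdisp_habitat = multivariate.permdisp(
            dm_sponge, meta_kept.grouping(sponge_ids, "habitat_class"),
            n_permutations=config.n_permutations, seed=config.seed, factor="habitat")

        stage = "indval"
        if taxonomy is not None:
            agg = aggregate_taxa(rarefied, taxonomy, rank="phylum",
                                 proteobacteria_to_class=True)
            rel_agg = agg.div(agg.sum(axis=1), axis=0)
            rel_sponge = rel_agg.loc[sponge_ids]
            indval_res = multivariate.indval(
                rel_sponge, meta_kept.grouping(sponge_ids, "habitat_class"),
                threshold=config.indval_threshold, alpha=config.indval_alpha,
                n_permutations=config.n_permutations, seed=config.seed)
        else:
            warnings.warn("no taxonomy supplied; IndVal stage skipped", stacklevel=2)
            indval_res = []

        stage = "heatmap"
        long_rows = []
        for g in groups:
            pt = overlap_core[g].per_taxon.reset_index()
            pt["group"] = g
            long_rows.append(pt[["group", "taxon", "sponge_core_pct"]])
        per_taxon_long = pd.concat(long_rows, ignore_index=True)
        heatmap = community_stats.heatmap_export(per_taxon_long,
                                                 abundance_floor=config.heatmap_floor_pct)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return RunResult(
        config=config, rarefied=rarefied, dropped_samples=rlog.dropped_samples,
        cores=cores, sw_core_ref=sw_core_ref, abundant_ref=abundant_ref,
        specific=specific, overlap_core=overlap_core, overlap_abundant=overlap_abundant,
        method_difference=method_diff, enrichment=enrichment, contaminants=contaminants,
        summary=summary, correlations=correlations, core_shannon=core_shannon,
        shannon_kruskal=shannon_kw, sample_dendrogram=dendro,
        permanova_species=permanova_species, permanova_habitat=permanova_habitat,
        permdisp_species=permdisp_species, permdisp_habitat=permdisp_habitat,
        indval=indval_res, heatmap=heatmap, stage_log=log,
    )


def write_results(result: RunResult, outdir: str | Path) -> None:
    """Export all run products as plain-text files plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary.round(4).to_csv(out / "species_summary.tsv", sep="\t")

    overlap_rows = []
    for method, reports in (("core", result.overlap_core),
                            ("abundant", result.overlap_abundant)):
        for g, rep in reports.items():
            overlap_rows.append({
                "group": g, "method": method, "n_shared": len(rep.shared_taxa),
                "pct_of_sponge_core": rep.pct_of_sponge_core,
                "pct_of_sw_reference": rep.pct_of_sw_reference,
            })
    pd.DataFrame(overlap_rows).round(6).to_csv(out / "sw_overlap.tsv", sep="\t", index=False)
    result.method_difference.round(6).rename("method_difference_pct").to_csv(
        out / "method_difference.tsv", sep="\t")

    per_taxon = []
    for g, rep in result.overlap_core.items():
        pt = rep.per_taxon.reset_index()
        pt.insert(0, "group", g)
        per_taxon.append(pt)
    pd.concat(per_taxon, ignore_index=True).round(8).to_csv(
        out / "sw_overlap_per_taxon.tsv", sep="\t", index=False)

    for g, core in result.cores.items():
        safe = g.replace(" ", "_").replace("/", "_")
        (out / f"core_taxa_{safe}.txt").write_text(
            "\n".join(sorted(core.taxa)) + "\n")

    stats_rows = []
    for res in (result.permanova_species, result.permanova_habitat):
        stats_rows.append({"test": "permanova", "factor": res.factor, "stat": res.pseudo_f,
                           "r2": res.r2, "p": res.p, "n_perm": res.n_permutations})
    for res in (result.permdisp_species, result.permdisp_habitat):
        stats_rows.append({"test": "permdisp", "factor": res.factor, "stat": res.f,
                           "r2": float("nan"), "p": res.p, "n_perm": res.n_permutations})
    if result.shannon_kruskal is not None:
        h, p = result.shannon_kruskal
        stats_rows.append({"test": "kruskal_wallis_core_shannon", "factor": "habitat",
                           "stat": h, "r2": float("nan"), "p": p, "n_perm": 0})
    pd.DataFrame(stats_rows).to_csv(out / "multivariate_stats.tsv", sep="\t", index=False)

    if result.indval:
        pd.DataFrame([vars(r) for r in result.indval]).round(6).to_csv(
            out / "indval.tsv", sep="\t", index=False)
    result.core_shannon.round(6).to_csv(out / "core_shannon.tsv", sep="\t", index=False)
    (out / "samples_dendrogram.nwk").write_text(result.sample_dendrogram.to_newick() + "\n")
    if not result.heatmap.matrix.empty:
        result.heatmap.matrix.round(6).to_csv(out / "heatmap_matrix.tsv", sep="\t")
        if result.heatmap.row_dendrogram is not None:
            (out / "heatmap_rows.nwk").write_text(
                result.heatmap.row_dendrogram.to_newick() + "\n")
        if result.heatmap.col_dendrogram is not None:
            (out / "heatmap_cols.nwk").write_text(
                result.heatmap.col_dendrogram.to_newick() + "\n")
    if result.correlations is not None:
        r_size, r_frac = result.correlations
        corr = pd.DataFrame([
            {"pair": "n_replicates_vs_core_size", "rho": r_size.rho, "p": r_size.p},
            {"pair": "n_replicates_vs_core_fraction", "rho": r_frac.rho, "p": r_frac.p},
        ])
        corr.to_csv(out / "replicate_correlations.tsv", sep="\t", index=False)

    manifest = {
        "config": asdict(result.config),
        "dropped_samples": result.dropped_samples,
        "n_samples": len(result.rarefied.sample_ids),
        "n_taxa": len(result.rarefied.taxon_ids),
        "stages": result.stage_log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
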