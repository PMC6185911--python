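"""Per-species core communities, species-specific taxa and summary tables.

The core microbiome of a group is defined by an occurrence rule: a taxon
belongs to the core if it has a nonzero count in at least
``ceil(threshold * n)`` of the group's replicate samples.  The default
threshold of 1.0 (presence in *all* replicates) is the restrictive
definition appropriate when the goal is to separate persistent symbionts
from transient environmental bacteria.  Everything a group's replicates
contain beyond its core is the *variable* community; core + variable shares
sum to one in every replicate.

A taxon is *species-specific* when it belongs to exactly one species' core
among all cores analysed — membership is tested against the other cores
only, not against the species' full (variable) communities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_stats import spearman, SpearmanResult
from .io_tables import CountTable, SampleMetadata, SEAWATER_GROUP
from .preprocess import to_relative_abundance

__all__ = [
    "CoreSet",
    "SpeciesSpecificResult",
    "SpeciesSummary",
    "extract_core",
    "species_specific",
    "core_summary",
    "core_size_vs_replicates",
]


@dataclass
class CoreSet:
    """Core community of one group at a given occurrence threshold."""

    group: str
    occurrence_threshold: float
    taxa: frozenset[str]
    #: taxa observed in the group but failing the occurrence rule
    variable_taxa: frozenset[str]
    #: share of each replicate's reads belonging to core taxa
    per_replicate_core_fraction: pd.Series
    #: per-core-taxon mean relative abundance across the group's replicates
    mean_rel_abundance: pd.Series

    @property
    def size(self) -> int:
        return len(self.taxa)

    @property
    def mean_core_fraction(self) -> float:
        return float(self.per_replicate_core_fraction.mean())

    @property
    def sd_core_fraction(self) -> float:
        return float(self.per_replicate_core_fraction.std(ddof=1)) if len(
            self.per_replicate_core_fraction) > 1 else 0.0

    @property
    def total_core_abundance(self) -> float:
        """Summed mean relative abundance of the core taxa (denominator for
        the species-specific and seawater-shared percentages)."""
        return float(self.mean_rel_abundance.sum())


@dataclass
class SpeciesSpecificResult:
    group: str
    taxa: frozenset[str]
    #: summed mean relative abundance of the specific taxa, as % of the
    #: group's core-community abundance
    pct_of_core_abundance: float


@dataclass
class SpeciesSummary:
    """One row of the per-species summary report (nine columns)."""

    group: str
    n_replicates: int
    mean_richness: float
    sd_richness: float
    core_size: int
    core_fraction_pct: float
    core_fraction_sd: float
    n_species_specific: int | None = None
    species_specific_pct_of_core: float | None = None
    n_sw_shared: int | None = None
    sw_shared_pct_of_core: float | None = None


def extract_core(
    table: CountTable,
    meta: SampleMetadata,
    group: str,
    threshold: float = 1.0,
) -> CoreSet:
    """Occurrence-based core extraction for one group.

    ``threshold`` is the required occurrence fraction in (0, 1]; a taxon
    passes with a nonzero count in at least ``ceil(threshold * n)``
    replicates (all replicates at the default 1.0).
    """
    if not 0 < threshold <= 1:
        raise ValueError("occurrence threshold must be in (0, 1]")
    samples = meta.samples_of(group)
    samples = [s for s in samples if s in set(table.sample_ids)]
    if not samples:
        raise KeyError(f"group {group!r} has no samples in the count table")
    if len(samples) < 2:
        warnings.warn(
            f"group {group!r} has a single replicate; its 'core' is simply "
            "the sample's observed taxa", stacklevel=2)
    sub = table.data.loc[samples]
    presence = (sub > 0).sum(axis=0)
    needed = math.ceil(threshold * len(samples))
    core_mask = presence >= needed
    observed = presence > 0
    core_taxa = frozenset(sub.columns[core_mask & observed])
    variable = frozenset(sub.columns[observed & ~core_mask])

    core_cols = sorted(core_taxa)
    totals = sub.sum(axis=1)
    core_reads = sub[core_cols].sum(axis=1)
    rel = sub[core_cols].div(totals, axis=0)
    return CoreSet(
        group=group,
        occurrence_threshold=threshold,
        taxa=core_taxa,
        variable_taxa=variable,
        per_replicate_core_fraction=core_reads / totals,
        mean_rel_abundance=rel.mean(axis=0),
    )


def species_specific(cores: list[CoreSet]) -> dict[str, SpeciesSpecificResult]:
    """Taxa belonging to exactly one core among ``cores``.

    Returns, per group, the specific taxon set and its summed mean relative
    abundance as a percentage of that group's core-community abundance.
    """
    if len(cores) < 2:
        raise ValueError("species-specific taxa need at least two cores to compare")
    results: dict[str, SpeciesSpecificResult] = {}
    for core in cores:
        others: set[str] = set()
        for other in cores:
            if other.group != core.group:
                others |= other.taxa
        specific = frozenset(core.taxa - others)
        denom = core.total_core_abundance
        num = float(core.mean_rel_abundance.loc[sorted(specific)].sum()) if specific else 0.0
        results[core.group] = SpeciesSpecificResult(
            group=core.group,
            taxa=specific,
            pct_of_core_abundance=100.0 * num / denom if denom > 0 else 0.0,
        )
    return results


def core_summary(
    table: CountTable,
    meta: SampleMetadata,
    cores: list[CoreSet],
    specific: dict[str, SpeciesSpecificResult] | None = None,
    overlap_reports: dict[str, "OverlapReport"] | None = None,  # noqa: F821
) -> pd.DataFrame:
    """Per-species summary (richness, core size/share, specific and
    seawater-shared columns), one row per sponge group.

    Percentages for the species-specific and seawater-shared columns use the
    core community's abundance as denominator; the core-fraction percentage
    uses each replicate's total reads.  Without ``overlap_reports`` the
    seawater columns are omitted with a warning.
    """
    if overlap_reports is None:
        warnings.warn("no seawater overlap report supplied; SW columns omitted",
                      stacklevel=2)
    rows = []
    rel = to_relative_abundance(table)
    for core in cores:
        if core.group == SEAWATER_GROUP:
            continue
        samples = [s for s in meta.samples_of(core.group) if s in set(table.sample_ids)]
        richness = (table.data.loc[samples] > 0).sum(axis=1)
        row = SpeciesSummary(
            group=core.group,
            n_replicates=len(samples),
            mean_richness=float(richness.mean()),
            sd_richness=float(richness.std(ddof=1)) if len(samples) > 1 else 0.0,
            core_size=core.size,
            core_fraction_pct=100.0 * core.mean_core_fraction,
            core_fraction_sd=100.0 * core.sd_core_fraction,
        )
        if specific is not None and core.group in specific:
            row.n_species_specific = len(specific[core.group].taxa)
            row.species_specific_pct_of_core = specific[core.group].pct_of_core_abundance
        if overlap_reports is not None and core.group in overlap_reports:
            rep = overlap_reports[core.group]
            row.n_sw_shared = len(rep.shared_taxa)
            row.sw_shared_pct_of_core = rep.pct_of_sponge_core
        rows.append(vars(row))
    del rel
    return pd.DataFrame(rows).set_index("group")


def core_size_vs_replicates(
    summaries: pd.DataFrame,
) -> tuple[SpearmanResult, SpearmanResult]:
    """Spearman correlations of replicate number against core size and
    against mean core share.

    A strong negative size correlation is the signature of occurrence-based
    cores: every added replicate can only remove taxa.  The abundance share
    of the core is typically uncorrelated with replicate number, because
    the taxa lost with extra replicates are low-abundance ones.
    """
    if len(summaries) < 4:
        raise ValueError("need at least 4 species for a meaningful rank correlation")
    n = summaries["n_replicates"].to_numpy(dtype=float)
    r_size = spearman(n, summaries["core_size"].to_numpy(dtype=float))
    r_frac = spearman(n, summaries["core_fraction_pct"].to_numpy(dtype=float))
    return r_size, r_frac
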