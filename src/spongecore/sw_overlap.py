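"""Seawater contribution to sponge core microbiomes, by two reference sets.

Two complementary seawater (SW) references are supported:

* the **SW core** — taxa present in *all* water replicates (cosmopolitan
  bacteria; same occurrence rule as sponge cores), and
* the **abundant SW** community — taxa whose mean relative abundance across
  all water samples exceeds a cutoff (0.01 % by default).

For every sponge species the overlap of its core with either reference is
expressed two ways: the shared taxa's summed mean relative abundance as a
percentage of the sponge core's abundance, and as a percentage of the SW
reference's abundance.  The signed difference between the two methods'
sponge-side percentages flags species whose cores are built from seawater
bacteria that are *rare* in the water column — the seed-bank signature of
host enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_analysis import CoreSet, extract_core
from .io_tables import CountTable, SampleMetadata, SEAWATER_GROUP
from .preprocess import to_relative_abundance

__all__ = [
    "SWReference",
    "OverlapReport",
    "EnrichmentFlag",
    "sw_core",
    "abundant_sw",
    "overlap",
    "rarity_class",
    "method_difference",
    "enrichment_flags",
    "potential_contaminants",
]

#: rarity cutoffs in percent mean relative abundance across water samples
RARE_CUTOFF_PCT = 0.01
HIGHLY_ABUNDANT_CUTOFF_PCT = 1.0


@dataclass
class SWReference:
    """A seawater reference community (method 'core' or 'abundant')."""

    method: str
    taxa: frozenset[str]
    #: mean relative abundance across all water samples, *all* observed SW
    #: taxa (not just the reference members), as fractions in [0, 1]
    sw_mean_abundance: pd.Series

    @property
    def total_reference_abundance(self) -> float:
        return float(self.sw_mean_abundance.loc[sorted(self.taxa)].sum())


@dataclass
class OverlapReport:
    group: str
    method: str
    shared_taxa: frozenset[str]
    #: shared taxa's abundance as % of the sponge core community's abundance
    pct_of_sponge_core: float
    #: shared taxa's abundance as % of the SW reference's abundance
    pct_of_sw_reference: float
    #: per-shared-taxon detail: sponge-core mean abundance (% of core),
    #: SW mean abundance (%), rarity class, enrichment ratio
    per_taxon: pd.DataFrame


def _water_samples(table: CountTable, meta: SampleMetadata) -> list[str]:
    try:
        samples = meta.samples_of(SEAWATER_GROUP)
    except KeyError:
        raise ValueError("metadata contains no seawater samples") from None
    samples = [s for s in samples if s in set(table.sample_ids)]
    if not samples:
        raise ValueError("no seawater samples present in the count table")
    return samples


def _sw_mean_abundance(table: CountTable, meta: SampleMetadata) -> pd.Series:
    samples = _water_samples(table, meta)
    rel = to_relative_abundance(table.subset_samples(samples))
    return rel.mean(axis=0)


def sw_core(table: CountTable, meta: SampleMetadata) -> SWReference:
    """Cosmopolitan seawater reference: taxa present in all water replicates."""
    samples = _water_samples(table, meta)
    if len(samples) < 2:
        raise ValueError("the seawater core needs at least 2 water replicates")
    core = extract_core(table, meta, SEAWATER_GROUP, threshold=1.0)
    return SWReference(
        method="core",
        taxa=core.taxa,
        sw_mean_abundance=_sw_mean_abundance(table, meta),
    )


def abundant_sw(table: CountTable, meta: SampleMetadata, cutoff_pct: float = RARE_CUTOFF_PCT) -> SWReference:
    """Abundant seawater reference: mean SW abundance strictly above
    ``cutoff_pct`` percent (0.01 % default)."""
    mean_ab = _sw_mean_abundance(table, meta)
    taxa = frozenset(mean_ab.index[mean_ab * 100.0 > cutoff_pct])
    return SWReference(method="abundant", taxa=taxa, sw_mean_abundance=mean_ab)


def rarity_class(sw_abundance_pct: float) -> str:
    """'rare' below 0.01 %, 'abundant' above 1 %, otherwise 'intermediate'."""
    if sw_abundance_pct < 0:
        raise ValueError("abundance cannot be negative")
    if sw_abundance_pct < RARE_CUTOFF_PCT:
        return "rare"
    if sw_abundance_pct > HIGHLY_ABUNDANT_CUTOFF_PCT:
        return "abundant"
    return "intermediate"


def overlap(core: CoreSet, ref: SWReference) -> OverlapReport:
    """Quantify the seawater contribution to one sponge core.

    Per-taxon means are computed first and then summed over the shared set,
    which keeps the percentages decomposable per taxon (as needed for
    heatmap exports).
    """
    if not core.taxa:
        raise ValueError(f"group {core.group!r} has an empty core")
    shared = sorted(core.taxa & ref.taxa)
    core_denom = core.total_core_abundance
    sw_denom = ref.total_reference_abundance
    sponge_num = float(core.mean_rel_abundance.loc[shared].sum())
    sw_num = float(ref.sw_mean_abundance.loc[shared].sum())

    sponge_pct = core.mean_rel_abundance.loc[shared] / core_denom * 100.0
    sw_pct = ref.sw_mean_abundance.reindex(shared).fillna(0.0) * 100.0
    per_taxon = pd.DataFrame(
        {
            "sponge_core_pct": sponge_pct,
            "sw_mean_pct": sw_pct,
            "rarity": [rarity_class(v) for v in sw_pct],
            "enrichment_ratio": (core.mean_rel_abundance.loc[shared] /
                                 ref.sw_mean_abundance.reindex(shared)).astype(float),
        }
    )
    per_taxon.index.name = "taxon"
    return OverlapReport(
        group=core.group,
        method=ref.method,
        shared_taxa=frozenset(shared),
        pct_of_sponge_core=100.0 * sponge_num / core_denom if core_denom else 0.0,
        pct_of_sw_reference=100.0 * sw_num / sw_denom if sw_denom else 0.0,
        per_taxon=per_taxon,
    )


def method_difference(report_core: OverlapReport, report_abundant: OverlapReport) -> float:
    """Signed difference (percentage points) between the SW-core-method and
    abundant-SW-method sponge-side overlaps.

    Large positive values mean the sponge core relies on seawater bacteria
    that are individually rare in the water column.
    """
    if report_core.group != report_abundant.group:
        raise ValueError(
            f"reports compare different groups: {report_core.group!r} vs "
            f"{report_abundant.group!r}")
    if {report_core.method, report_abundant.method} != {"core", "abundant"}:
        raise ValueError("expected one 'core'-method and one 'abundant'-method report")
    return report_core.pct_of_sponge_core - report_abundant.pct_of_sponge_core


@dataclass
class EnrichmentFlag:
    group: str
    #: summed sponge-core share (% of core) of shared taxa that are rare in SW
    rare_sw_score: float
    enriched: bool


def enrichment_flags(
    reports: dict[str, OverlapReport],
    rare_cutoff_pct: float = RARE_CUTOFF_PCT,
    dominance_cutoff_pct: float = 50.0,
) -> dict[str, EnrichmentFlag]:
    """Flag species whose cores are dominated by SW-rare cosmopolitan taxa.

    ``reports`` must be SW-core-method overlap reports.  The score is the
    summed sponge-core share of shared taxa whose SW mean abundance is below
    ``rare_cutoff_pct``; a species is flagged when the score exceeds
    ``dominance_cutoff_pct`` percent of its core.
    """
    flags: dict[str, EnrichmentFlag] = {}
    for group, rep in reports.items():
        if rep.method != "core":
            raise ValueError("enrichment flags are defined on SW-core-method reports")
        pt = rep.per_taxon
        score = float(pt.loc[pt["sw_mean_pct"] < rare_cutoff_pct, "sponge_core_pct"].sum())
        flags[group] = EnrichmentFlag(group=group, rare_sw_score=score,
                                      enriched=score > dominance_cutoff_pct)
    return flags


def potential_contaminants(
    reports: dict[str, OverlapReport],
    sw_abundant_cutoff_pct: float = HIGHLY_ABUNDANT_CUTOFF_PCT,
    core_rare_cutoff_pct: float = RARE_CUTOFF_PCT,
) -> pd.DataFrame:
    """List shared taxa that are highly abundant in seawater yet nearly
    absent from a sponge core.

    Such cases are candidate environmental carry-over (especially with few
    replicates); they are reported, never removed automatically.
    """
    rows = []
    for group, rep in reports.items():
        pt = rep.per_taxon
        sus = pt[(pt["sw_mean_pct"] > sw_abundant_cutoff_pct)
                 & (pt["sponge_core_pct"] < core_rare_cutoff_pct)]
        for taxon, row in sus.iterrows():
            rows.append({"group": group, "taxon": taxon,
                         "sponge_core_pct": row["sponge_core_pct"],
                         "sw_mean_pct": row["sw_mean_pct"]})
    return pd.DataFrame(rows, columns=["group", "taxon", "sponge_core_pct", "sw_mean_pct"])
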