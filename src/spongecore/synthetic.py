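"""Synthetic paired sponge/seawater communities with known ground truth.

The generator emulates the structure of a multi-species sponge microbiome
survey so that every pipeline stage has a recoverable target:

* a **seawater pool** with a cosmopolitan core (a handful of abundant taxa
  carrying most of the water-column reads, a band of mid-abundance
  cosmopolitans, and a set of *rare* cosmopolitans present in every water
  replicate yet individually below the 0.01 % abundance cutoff) plus a
  rare tail;
* per-species **planted cores** mixing four member categories:
  (a) abundant/mid seawater-core taxa, (r) rare-cosmopolitan seawater taxa
  (only in species flagged as enriching rare seawater bacteria — the
  seed-bank signature), (b) sponge-enriched taxa shared between at least
  two host species but effectively absent from the water column, and
  (c) species-specific taxa that do not occur in the seawater pool at all;
* a **transient fraction**: each sponge replicate draws a fixed share of
  its reads directly from the seawater pool, proportional to seawater
  abundances;
* multinomial read sampling at a configurable depth, seeded.

Design notes.  Shared (b) and seawater-derived members are assigned
round-robin so that every one of them belongs to at least two species'
cores, keeping the planted species-specific sets exactly recoverable by
set algebra over cores.  The seawater abundance spectrum is deliberately
block-structured: taxa whose per-replicate detection probability would sit
in the ambiguous mid range are always planted members of ≥ 2 cores, so
occurrence-based membership of the references is decidable.  Every planted
core member receives at least ``min_core_weight`` of its species' core
profile, i.e. an expected per-replicate count ≈ 16 reads at the default
depth — planted cores model *consistently present* symbionts, while the
transient fraction supplies the stochastic variable community.

The ground truth records, per species, the exact expected values of the
pipeline's estimands (core read fraction, seawater-overlap percentages by
both methods, method difference) under the planted mixture, including the
expected contribution of transient taxa likely to appear in all replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import CountTable, SampleMetadata, TaxonomyTable, SEAWATER_GROUP

__all__ = [
    "SpeciesSpec",
    "SWPoolSpec",
    "SimulationParams",
    "SyntheticTruth",
    "generate",
    "recovery_report",
    "RecoveryReport",
]


# ---------------------------------------------------------------------------
# parameters

@dataclass
class SpeciesSpec:
    """Planted structure of one sponge species.

    ``core_size`` decomposes as |seawater-derived| (= ``n_sw_shared``) +
    |shared sponge-enriched| + |species-specific| (= ``n_specific``).
    ``rare_sw_core_share``, ``abundant_sw_core_share`` and
    ``specific_share`` are target shares of the core's read mass for the
    rare-cosmopolitan, abundant/mid-cosmopolitan and species-specific
    member categories; the shared sponge-enriched category receives the
    remainder.
    """

    name: str
    n_replicates: int
    hma: bool
    core_size: int
    n_specific: int
    n_sw_shared: int
    rare_sw_core_share: float = 0.0
    abundant_sw_core_share: float = 0.2
    specific_share: float = 0.0

    @property
    def rare_planted(self) -> bool:
        return self.rare_sw_core_share > 0


@dataclass
class SWPoolSpec:
    """Block structure of the regional seawater pool (abundances are
    fractions of the water community; the abundant block absorbs whatever
    mass the other blocks leave)."""

    n_abundant: int = 12
    n_mid: int = 160
    mid_abundance: tuple[float, float] = (2e-4, 3e-4)
    n_rare_cosmo: int = 25
    rare_cosmo_abundance: tuple[float, float] = (4e-5, 6e-5)
    n_shared_hma: int = 110
    n_shared_lma: int = 600
    shared_abundance: float = 3e-7
    n_tail: int = 500
    tail_abundance: tuple[float, float] = (1e-7, 1e-6)

    @property
    def n_rare_members_per_species(self) -> int:
        # rare-cosmopolitan members drawn by each rare-planted species
        return max(2, self.n_rare_cosmo - 1)


@dataclass
class SimulationParams:
    species: list[SpeciesSpec]
    sw_pool: SWPoolSpec = field(default_factory=SWPoolSpec)
    n_sw_samples: int = 9
    n_locations: int = 3
    depth: int = 41_000
    transient_fraction: float = 0.2
    min_core_weight: float = 5e-4
    hma_evenness_sigma: float = 0.7
    lma_evenness_sigma: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.transient_fraction < 1:
            raise ValueError("transient_fraction must be in [0, 1)")
        if self.depth < 1 or self.n_sw_samples < 2:
            raise ValueError("need a positive depth and at least 2 water samples")
        for sp in self.species:
            n_rare = self._n_rare(sp)
            n_shared = sp.core_size - sp.n_sw_shared - sp.n_specific
            if sp.n_sw_shared < self.sw_pool.n_abundant + n_rare:
                raise ValueError(
                    f"{sp.name}: n_sw_shared must cover the abundant block "
                    f"({self.sw_pool.n_abundant}) plus rare members ({n_rare})")
            if n_shared < 0:
                raise ValueError(f"{sp.name}: core_size < n_sw_shared + n_specific")
            if sp.core_size * self.min_core_weight > 0.95:
                raise ValueError(f"{sp.name}: core too large for the per-member floor")

    def _n_rare(self, sp: SpeciesSpec) -> int:
        if not sp.rare_planted:
            return 0
        return min(self.sw_pool.n_rare_members_per_species,
                   sp.n_sw_shared - self.sw_pool.n_abundant)

    @classmethod
    def default_study(cls, seed: int = 0) -> "SimulationParams":
        """Default parameters mirroring the structure of the 19-species
        survey shipped with the package (replicate numbers, core sizes,
        species-specific and seawater-shared counts, HMA flags)."""
        from .datasets import survey_summary

        survey = survey_summary()
        rare_share = {
            "Aaptos suberitoides": 0.30,
            "Neofibularia hartmani": 0.50,
            "Suberea cf. laboutei": 0.20,
            "Clathria reinwardti": 0.80,
            "Gellioides sp.": 0.55,
            "Mycale sp.": 0.60,
        }
        am_share = {
            "Aaptos suberitoides": 0.30, "Neofibularia hartmani": 0.18,
            "Suberea cf. laboutei": 0.06, "Amphimedon paraviridis": 0.97,
            "Antho sp.": 0.02, "Callyspongia sp.": 0.25,
            "Clathria reinwardti": 0.08, "Clathria sp.": 0.15,
            "Dendroxea sp.": 0.15, "Dysidea sp.": 0.12,
            "Gellioides cf. gracilis": 0.35, "Gellioides sp.": 0.10,
            "Haliclona sp.": 0.05, "Haliclona (Gellius) toxotes": 0.40,
            "Monanchora unguiculata": 0.38, "Mycale sp.": 0.12,
            "Phorbas sp.": 0.32, "Pseudosuberites sp.": 0.03,
            "Thrinacophora rhaphidophora": 0.05,
        }
        species = []
        for name, row in survey.iterrows():
            species.append(SpeciesSpec(
                name=name,
                n_replicates=int(row["n_replicates"]),
                hma=row["habitat_class"] == "HMA",
                core_size=int(row["core_size"]),
                n_specific=int(row["n_species_specific"]),
                n_sw_shared=int(row["n_sw_shared"]),
                rare_sw_core_share=rare_share.get(name, 0.0),
                abundant_sw_core_share=am_share[name],
                specific_share=float(row["species_specific_pct_of_core"]) / 100.0,
            ))
        return cls(species=species, seed=seed)


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class SyntheticTruth:
    """Planted parameters of a simulated dataset."""

    core_taxa: dict[str, frozenset[str]]
    specific_taxa: dict[str, frozenset[str]]
    sw_derived_taxa: dict[str, frozenset[str]]  # (a) + (r) members per species
    rare_sw_taxa: dict[str, frozenset[str]]  # (r) members per species
    sw_core_taxa: frozenset[str]
    abundant_sw_taxa: frozenset[str]
    sw_abundance: pd.Series  # pool relative abundances (0 outside pool)
    enrichment_factor: dict[str, dict[str, float]]  # per species, per (a∪r) taxon
    #: exact expected values of the pipeline estimands, one row per species:
    #: core_fraction_pct, overlap_core_pct, overlap_abundant_pct,
    #: method_difference_pct, rare_planted
    expected: pd.DataFrame
    params: SimulationParams

    def to_json(self, path: str | Path) -> None:
        doc = {
            "core_taxa": {g: sorted(t) for g, t in self.core_taxa.items()},
            "specific_taxa": {g: sorted(t) for g, t in self.specific_taxa.items()},
            "sw_derived_taxa": {g: sorted(t) for g, t in self.sw_derived_taxa.items()},
            "rare_sw_taxa": {g: sorted(t) for g, t in self.rare_sw_taxa.items()},
            "sw_core_taxa": sorted(self.sw_core_taxa),
            "abundant_sw_taxa": sorted(self.abundant_sw_taxa),
            "enrichment_factor": self.enrichment_factor,
            "expected": self.expected.to_dict(orient="index"),
            "params": {
                "depth": self.params.depth,
                "transient_fraction": self.params.transient_fraction,
                "seed": self.params.seed,
                "n_sw_samples": self.params.n_sw_samples,
                "species": [asdict(s) for s in self.params.species],
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# generation

def _floor_normalise(weights: np.ndarray, floor: float) -> np.ndarray:
    """Rescale ``weights`` to sum to 1 with every entry ≥ ``floor``."""
    w = weights / weights.sum()
    for _ in range(200):
        low = w < floor
        if not low.any():
            break
        w[low] = floor
        high = ~low
        spare = 1.0 - floor * low.sum()
        w[high] *= spare / w[high].sum()
    return w / w.sum()


class _RoundRobin:
    """Cyclic distinct-pick assignment guaranteeing even pool coverage."""

    def __init__(self, pool: list[str]):
        self.pool = pool
        self.offset = 0

    def take(self, k: int) -> list[str]:
        if k > len(self.pool):
            raise ValueError(f"cannot pick {k} distinct items from a pool of {len(self.pool)}")
        picks = [self.pool[(self.offset + i) % len(self.pool)] for i in range(k)]
        self.offset = (self.offset + k) % len(self.pool)
        return picks


_PHYLA_COSMO = [("Proteobacteria", "Alphaproteobacteria"),
                ("Proteobacteria", "Gammaproteobacteria"),
                ("Cyanobacteria", "Cyanobacteriia"),
                ("Bacteroidetes", "Bacteroidia")]
_PHYLA_HMA = [("Chloroflexi", "Anaerolineae"), ("Acidobacteria", "Acidobacteriia"),
              ("Actinobacteria", "Acidimicrobiia"), ("Nitrospinae", "Nitrospinia"),
              ("PAUC34f", "PAUC34f")]
_PHYLA_LMA = [("Proteobacteria", "Alphaproteobacteria"),
              ("Proteobacteria", "Betaproteobacteria"),
              ("Proteobacteria", "Gammaproteobacteria"),
              ("Bacteroidetes", "Bacteroidia"), ("Firmicutes", "Bacilli")]


def _build_pool(params: SimulationParams, rng: np.random.Generator):
    """Seawater pool abundances and the taxon id blocks."""
    sw = params.sw_pool
    ids: list[str] = []
    blocks: dict[str, list[str]] = {}

    def block(prefix: str, n: int) -> list[str]:
        names = [f"{prefix}{i + 1:04d}" for i in range(n)]
        ids.extend(names)
        return names

    blocks["abundant"] = block("ZOTU_A", sw.n_abundant)
    blocks["mid"] = block("ZOTU_M", sw.n_mid)
    blocks["rare_cosmo"] = block("ZOTU_R", sw.n_rare_cosmo)
    blocks["shared_hma"] = block("ZOTU_H", sw.n_shared_hma)
    blocks["shared_lma"] = block("ZOTU_L", sw.n_shared_lma)
    blocks["tail"] = block("ZOTU_T", sw.n_tail)

    p = pd.Series(0.0, index=ids)
    p[blocks["mid"]] = np.linspace(*sw.mid_abundance, sw.n_mid)
    p[blocks["rare_cosmo"]] = np.linspace(*sw.rare_cosmo_abundance, sw.n_rare_cosmo)
    p[blocks["shared_hma"]] = sw.shared_abundance
    p[blocks["shared_lma"]] = sw.shared_abundance
    lo, hi = sw.tail_abundance
    tail = np.exp(rng.uniform(np.log(lo), np.log(hi), sw.n_tail))
    p[blocks["tail"]] = tail
    remaining = 1.0 - p.sum()
    if remaining <= 0:
        raise ValueError("seawater pool blocks leave no mass for the abundant block")
    # top-heavy abundant block, geometric-ish decay
    prof = np.array([0.30, 0.15, 0.12, 0.09, 0.07, 0.06, 0.05,
                     0.04, 0.03, 0.02, 0.02, 0.01][:sw.n_abundant], dtype=float)
    if len(prof) < sw.n_abundant:
        prof = np.concatenate([prof, np.full(sw.n_abundant - len(prof), prof[-1])])
    p[blocks["abundant"]] = remaining * prof / prof.sum()
    return p, blocks


def generate(params: SimulationParams):
    """Generate (CountTable, SampleMetadata, TaxonomyTable, SyntheticTruth)."""
    rng = np.random.default_rng(params.seed)
    sw = params.sw_pool
    t = params.transient_fraction
    depth = params.depth

    p_sw, blocks = _build_pool(params, rng)
    pool_ids = list(p_sw.index)

    # species-specific taxa live outside the seawater pool entirely
    n_spec_total = sum(sp.n_specific for sp in params.species)
    specific_ids = [f"ZOTU_S{i + 1:04d}" for i in range(n_spec_total)]
    all_ids = pool_ids + specific_ids
    index = pd.Index(all_ids)

    # Pre-compute per-pool demands so each pool can be clamped to at most
    # half the total demand: round-robin assignment then uses every drawn
    # taxon in at least two species' cores, which keeps chance-core
    # transients from ever being mistaken for species-specific taxa.
    demands: dict[str, list[int]] = {k: [] for k in
                                     ("mid_hma", "mid_lma", "rare",
                                      "shared_hma", "shared_lma")}
    for sp in params.species:
        n_rare = params._n_rare(sp)
        n_mid = sp.n_sw_shared - sw.n_abundant - n_rare
        n_shared = sp.core_size - sp.n_sw_shared - sp.n_specific
        demands["rare"].append(n_rare)
        demands["mid_hma" if sp.hma else "mid_lma"].append(n_mid)
        demands["shared_hma" if sp.hma else "shared_lma"].append(n_shared)

    def clamp(pool: list[str], demand: list[int]) -> list[str]:
        if not any(demand):
            return pool
        size = min(len(pool), max(max(demand), sum(demand) // 2, 1))
        return pool[:size]

    mid_hma_pool = clamp(blocks["mid"][: max(1, min(60, sw.n_mid))],
                         demands["mid_hma"])
    pickers = {
        "mid_hma": _RoundRobin(mid_hma_pool),
        "mid_lma": _RoundRobin(clamp(blocks["mid"], demands["mid_lma"])),
        "rare": _RoundRobin(clamp(blocks["rare_cosmo"], demands["rare"])),
        "shared_hma": _RoundRobin(clamp(blocks["shared_hma"], demands["shared_hma"])),
        "shared_lma": _RoundRobin(clamp(blocks["shared_lma"], demands["shared_lma"])),
    }
    spec_cursor = 0

    core_taxa: dict[str, frozenset[str]] = {}
    specific_taxa: dict[str, frozenset[str]] = {}
    sw_derived: dict[str, frozenset[str]] = {}
    rare_members: dict[str, frozenset[str]] = {}
    enrichment: dict[str, dict[str, float]] = {}
    pi_rows: dict[str, np.ndarray] = {}
    p_vec = p_sw.reindex(index).fillna(0.0).to_numpy()

    for sp in params.species:
        n_rare = params._n_rare(sp)
        a_members = list(blocks["abundant"])
        n_mid = sp.n_sw_shared - sw.n_abundant - n_rare
        a_members += pickers["mid_hma" if sp.hma else "mid_lma"].take(n_mid)
        r_members = pickers["rare"].take(n_rare)
        n_shared = sp.core_size - sp.n_sw_shared - sp.n_specific
        b_members = pickers["shared_hma" if sp.hma else "shared_lma"].take(n_shared)
        c_members = specific_ids[spec_cursor:spec_cursor + sp.n_specific]
        spec_cursor += sp.n_specific

        sigma = params.hma_evenness_sigma if sp.hma else params.lma_evenness_sigma

        def category_weights(members: list[str], share: float) -> np.ndarray:
            if not members:
                return np.array([])
            raw = np.exp(rng.normal(0.0, sigma, len(members)))
            return share * raw / raw.sum()

        w_c = max(sp.specific_share, sp.n_specific * params.min_core_weight)
        w_r = sp.rare_sw_core_share
        w_am = max(sp.abundant_sw_core_share,
                   len(a_members) * params.min_core_weight)
        w_b = 1.0 - w_c - w_r - w_am
        if w_b < n_shared * params.min_core_weight:
            raise ValueError(f"{sp.name}: core shares leave too little mass for "
                             "the shared sponge-enriched members")
        members = a_members + r_members + b_members + c_members
        weights = np.concatenate([
            category_weights(a_members, w_am),
            category_weights(r_members, w_r),
            category_weights(b_members, w_b),
            category_weights(c_members, w_c),
        ])
        weights = _floor_normalise(weights, params.min_core_weight)

        pi = t * p_vec.copy()
        member_pos = index.get_indexer(members)
        pi[member_pos] += (1.0 - t) * weights
        pi_rows[sp.name] = pi

        core_taxa[sp.name] = frozenset(members)
        specific_taxa[sp.name] = frozenset(c_members)
        sw_derived[sp.name] = frozenset(a_members) | frozenset(r_members)
        rare_members[sp.name] = frozenset(r_members)
        enrichment[sp.name] = {
            taxon: float(pi[index.get_loc(taxon)] / p_sw[taxon])
            for taxon in list(a_members) + list(r_members)
        }

    shared_use: dict[str, int] = {}
    for sp in params.species:
        for taxon in core_taxa[sp.name] - specific_taxa[sp.name]:
            shared_use[taxon] = shared_use.get(taxon, 0) + 1
    lonely = [t for t, k in shared_use.items() if k < 2]
    if lonely:
        import warnings

        warnings.warn(
            f"{len(lonely)} shared core member(s) are planted in a single "
            "species (pool demand too low for round-robin sharing); "
            "species-specific sets are not exactly recoverable", stacklevel=2)

    # --- sampling -----------------------------------------------------------
    counts = {}
    meta_rows = []
    locations = [f"site{i + 1}" for i in range(params.n_locations)]
    for si, sp in enumerate(params.species):
        for r in range(sp.n_replicates):
            sample = f"S{si + 1:02d}_{r + 1:02d}"
            counts[sample] = rng.multinomial(depth, pi_rows[sp.name])
            meta_rows.append({
                "sample_id": sample, "group": sp.name,
                "habitat_class": "HMA" if sp.hma else "LMA",
                "location": locations[r % len(locations)], "replicate": r + 1,
            })
    designated_sw_core = blocks["abundant"] + blocks["mid"] + blocks["rare_cosmo"]
    sw_core_pos = index.get_indexer(designated_sw_core)
    for r in range(params.n_sw_samples):
        sample = f"SW_{r + 1:02d}"
        draw = rng.multinomial(depth, p_vec)
        # cosmopolitan taxa are, by definition, present in every water
        # replicate; guarantee this by moving single reads from the most
        # abundant taxon (row sum preserved)
        missing = sw_core_pos[draw[sw_core_pos] == 0]
        for pos in missing:
            draw[np.argmax(draw)] -= 1
            draw[pos] = 1
        counts[sample] = draw
        meta_rows.append({
            "sample_id": sample, "group": SEAWATER_GROUP, "habitat_class": "SW",
            "location": locations[r % len(locations)],
            "replicate": r + 1,
        })

    table = CountTable(pd.DataFrame.from_dict(counts, orient="index", columns=index))
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))

    # --- taxonomy -----------------------------------------------------------
    tax_rows = {}
    for name in pool_ids:
        if name in set(blocks["shared_hma"]):
            choices = _PHYLA_HMA
        elif name in set(blocks["shared_lma"]):
            choices = _PHYLA_LMA
        else:
            choices = _PHYLA_COSMO
        phylum, klass = choices[rng.integers(len(choices))]
        tax_rows[name] = {"domain": "Bacteria", "phylum": phylum, "class": klass}
    for si, sp in enumerate(params.species):
        choices = _PHYLA_HMA if sp.hma else _PHYLA_LMA
        for taxon in sorted(specific_taxa[sp.name]):
            phylum, klass = choices[rng.integers(len(choices))]
            tax_rows[taxon] = {"domain": "Bacteria", "phylum": phylum, "class": klass}
    taxonomy = TaxonomyTable(pd.DataFrame.from_dict(tax_rows, orient="index"))

    # --- expectations -------------------------------------------------------
    expected = _expected_estimands(params, index, p_vec, pi_rows, core_taxa,
                                   sw_derived, rare_members,
                                   frozenset(designated_sw_core),
                                   frozenset(blocks["abundant"] + blocks["mid"]))
    truth = SyntheticTruth(
        core_taxa=core_taxa,
        specific_taxa=specific_taxa,
        sw_derived_taxa=sw_derived,
        rare_sw_taxa=rare_members,
        sw_core_taxa=frozenset(designated_sw_core),
        abundant_sw_taxa=frozenset(blocks["abundant"] + blocks["mid"]),
        sw_abundance=p_sw,
        enrichment_factor=enrichment,
        expected=expected,
        params=params,
    )
    return table, meta, taxonomy, truth


def _expected_estimands(params, index, p_vec, pi_rows, core_taxa, sw_derived,
                        rare_members, sw_core, abundant_sw) -> pd.DataFrame:
    """Exact expected values of the measured estimands per species.

    The expectation of a measured share sums π over planted members plus a
    chance-inclusion term over non-members — transient taxa abundant enough
    to occur in every replicate predictably join the detected core.  For the
    abundance-weighted terms the inclusion factor of a non-member is
    p_rep^(n−1), not p_rep^n: E[X·1{X≥1}] = E[X] for the replicate whose
    reads are being counted, so only the other n−1 replicates discount the
    expectation.
    """
    rows = {}
    sw_core_mask = index.isin(sw_core)
    abundant_mask = index.isin(abundant_sw)
    for sp in params.species:
        pi = pi_rows[sp.name]
        member_mask = index.isin(core_taxa[sp.name])
        with np.errstate(over="ignore"):
            p_rep = -np.expm1(params.depth * np.log1p(-np.minimum(pi, 1 - 1e-12)))
        p_incl = np.where(member_mask, 1.0, p_rep ** max(sp.n_replicates - 1, 1))
        incl = pi * p_incl  # expected abundance share captured by the detected core
        denom = incl.sum()
        core_frac = denom
        num_core = incl[sw_core_mask].sum()
        num_abundant = incl[abundant_mask & sw_core_mask].sum()
        # sampling variance of the measured core fraction: multinomial read
        # noise plus the Bernoulli variance of borderline transient taxa
        # being included in the detected core at all
        with np.errstate(divide="ignore", invalid="ignore"):
            cond_share = np.where(p_rep > 0, pi / np.maximum(p_rep, 1e-12), 0.0)
        q = p_incl
        var_incl = np.where(member_mask, 0.0, (cond_share * q) ** 2 / np.maximum(q, 1e-12)
                            * (1.0 - q)).sum()
        var_reads = max(core_frac * (1 - core_frac), 0.0) / (sp.n_replicates * params.depth)
        rows[sp.name] = {
            "core_fraction_se_pct": 100.0 * float(np.sqrt(var_reads + var_incl)),
            "core_fraction_pct": 100.0 * core_frac,
            "overlap_core_pct": 100.0 * num_core / denom,
            "overlap_abundant_pct": 100.0 * num_abundant / denom,
            "method_difference_pct": 100.0 * (num_core - num_abundant) / denom,
            "rare_planted": sp.rare_planted,
            "n_replicates": sp.n_replicates,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "group"
    return df


# ---------------------------------------------------------------------------
# recovery scoring

@dataclass
class RecoveryReport:
    """Pipeline-output vs planted-truth comparison, one row per species.

    Deviation columns (``*_z``) are measured-minus-expected in units of one
    multinomial standard error of the species-level estimate.
    """

    per_species: pd.DataFrame
    #: smallest zero band (percentage points) below which a measured method
    #: difference is considered indistinguishable from zero
    noise_floor_pct: float

    @property
    def min_weighted_core_recall(self) -> float:
        return float(self.per_species["core_recall_weighted"].min())

    @property
    def all_specific_exact(self) -> bool:
        return bool(self.per_species["specific_exact"].all())

    @property
    def max_abs_overlap_z(self) -> float:
        return float(self.per_species["overlap_core_z"].abs().max())

    @property
    def max_abs_core_fraction_z(self) -> float:
        return float(self.per_species["core_fraction_z"].abs().max())

    def method_difference_sign_consistent(self) -> bool:
        """True when the measured method difference is positive (beyond the
        noise floor) exactly for the species planted with rare-seawater
        cores."""
        df = self.per_species
        positive = df["method_difference_pct"] > self.noise_floor_pct
        return bool((positive == df["rare_planted"]).all())


def recovery_report(
    truth: SyntheticTruth,
    cores: dict[str, "CoreSet"],  # noqa: F821
    specific: dict[str, "SpeciesSpecificResult"],  # noqa: F821
    overlap_core: dict[str, "OverlapReport"],  # noqa: F821
    overlap_abundant: dict[str, "OverlapReport"] | None = None,  # noqa: F821
) -> RecoveryReport:
    """Score pipeline outputs against the planted truth."""
    depth = truth.params.depth
    rows = {}
    for sp in truth.params.species:
        g = sp.name
        if g not in cores:
            raise KeyError(f"no pipeline core supplied for planted group {g!r}")
        det = set(cores[g].taxa)
        planted = set(truth.core_taxa[g])
        inter = det & planted
        # abundance weights = planted core-profile shares (π restricted to core)
        exp = truth.expected.loc[g]
        rows[g] = {
            "core_precision": len(inter) / len(det) if det else 0.0,
            "core_recall": len(inter) / len(planted),
            "n_detected_core": len(det),
            "n_planted_core": len(planted),
        }
        # weighted recall via the species' mean core member abundances as
        # measured on the detected table restricted to planted members
        mra = cores[g].mean_rel_abundance
        planted_weight = mra.reindex(sorted(inter)).fillna(0.0).sum()
        # weight of missed planted members is unobservable from the pipeline
        # output; bound it by the per-member floor
        missed = len(planted) - len(inter)
        missed_weight = missed * truth.params.min_core_weight
        rows[g]["core_recall_weighted"] = float(
            planted_weight / (planted_weight + missed_weight)) if planted_weight else 0.0

        det_specific = set(specific[g].taxa) if g in specific else set()
        planted_specific = set(truth.specific_taxa[g])
        rows[g]["specific_exact"] = det_specific == planted_specific
        sp_inter = det_specific & planted_specific
        rows[g]["specific_precision"] = (len(sp_inter) / len(det_specific)
                                         if det_specific else float(not planted_specific))
        rows[g]["specific_recall"] = (len(sp_inter) / len(planted_specific)
                                      if planted_specific else 1.0)

        n_eff = sp.n_replicates * depth
        f = exp["core_fraction_pct"] / 100.0
        se_f = float(exp["core_fraction_se_pct"])
        meas_f = 100.0 * cores[g].mean_core_fraction
        rows[g]["core_fraction_pct"] = meas_f
        rows[g]["core_fraction_expected_pct"] = exp["core_fraction_pct"]
        rows[g]["core_fraction_z"] = (meas_f - exp["core_fraction_pct"]) / max(se_f, 1e-9)

        # overlap deviations: binomial SE on the core's read budget, with a
        # 0.05-point floor absorbing the chance-inclusion approximation of
        # the expectation
        for method, reports, key in (
            ("core", overlap_core, "overlap_core"),
            ("abundant", overlap_abundant, "overlap_abundant"),
        ):
            if reports is None or g not in reports:
                continue
            gexp = exp[f"{key}_pct"] / 100.0
            se = 100.0 * np.sqrt(max(gexp * (1 - gexp), 0.0) / (f * n_eff))
            se = float(np.hypot(se, 0.05))
            meas = reports[g].pct_of_sponge_core
            rows[g][f"{key}_pct"] = meas
            rows[g][f"{key}_expected_pct"] = exp[f"{key}_pct"]
            rows[g][f"{key}_z"] = (meas - exp[f"{key}_pct"]) / se
        if overlap_abundant is not None and g in overlap_abundant and g in overlap_core:
            rows[g]["method_difference_pct"] = (overlap_core[g].pct_of_sponge_core
                                                - overlap_abundant[g].pct_of_sponge_core)
            rows[g]["method_difference_expected_pct"] = exp["method_difference_pct"]
        rows[g]["rare_planted"] = bool(exp["rare_planted"])
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "group"
    return RecoveryReport(per_species=df, noise_floor_pct=0.1)
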