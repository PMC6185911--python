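"""Seawater reference communities, overlap percentages and enrichment logic."""

import numpy as np
import pandas as pd
import pytest

from spongecore.core_analysis import CoreSet, extract_core
from spongecore.io_tables import CountTable, SampleMetadata
from spongecore.sw_overlap import (SWReference, abundant_sw, enrichment_flags,
                                   method_difference, overlap, potential_contaminants,
                                   rarity_class, sw_core)


def _sw_table(counts_by_sample: dict, taxa: list[str], n_sponge=2):
    rows = dict(counts_by_sample)
    meta_rows = {}
    for s in counts_by_sample:
        meta_rows[s] = {"group": "seawater", "habitat_class": "SW"}
    for i in range(n_sponge):
        rows[f"P{i}"] = [1] * len(taxa)
        meta_rows[f"P{i}"] = {"group": "sponge", "habitat_class": "LMA"}
    table = CountTable(pd.DataFrame.from_dict(rows, orient="index", columns=taxa))
    meta = SampleMetadata(pd.DataFrame.from_dict(meta_rows, orient="index"))
    return table, meta


class TestSWReferences:
    def test_taxon_missing_from_one_of_nine_replicates_excluded(self):
        taxa = ["a", "b"]
        counts = {f"W{i}": [1, 1] for i in range(9)}
        counts["W8"] = [0, 2]  # taxon a misses the 9th replicate
        table, meta = _sw_table(counts, taxa)
        ref = sw_core(table, meta)
        assert ref.taxa == frozenset({"b"})

    def test_ten_shared_taxa_enumerated(self):
        rng = np.random.default_rng(0)
        taxa = [f"z{i}" for i in range(25)]
        counts = {}
        for i in range(4):
            row = rng.integers(0, 3, 25)
            row[:10] = 1 + rng.integers(0, 5, 10)  # first ten always present
            counts[f"W{i}"] = list(row)
        table, meta = _sw_table(counts, taxa)
        ref = sw_core(table, meta)
        shared_by_hand = {t for j, t in enumerate(taxa)
                          if all(counts[f"W{i}"][j] > 0 for i in range(4))}
        assert ref.taxa == frozenset(shared_by_hand)
        assert frozenset(taxa[:10]) <= ref.taxa

    def test_sw_core_subset_of_observed_water_taxa(self, toy_table, toy_meta):
        ref = sw_core(toy_table, toy_meta)
        water = toy_table.data.loc[["W1", "W2", "W3"]]
        observed = set(water.columns[(water > 0).any()])
        assert set(ref.taxa) <= observed
        assert ref.taxa == frozenset({"t8"})

    def test_abundant_cutoff_is_strict(self):
        # taxon 'a' at exactly 0.01% mean, 'b' just above
        taxa = ["a", "b", "c"]
        depth = 10_000
        counts = {f"W{i}": [1, 2, depth - 3] for i in range(3)}
        table, meta = _sw_table(counts, taxa)
        ref = abundant_sw(table, meta, cutoff_pct=0.01)
        assert "a" not in ref.taxa  # 1/10000 = 0.01 % exactly → excluded
        assert {"b", "c"} <= ref.taxa

    def test_cutoff_zero_keeps_all_observed(self):
        taxa = ["a", "b", "c"]
        counts = {"W0": [5, 0, 5], "W1": [0, 5, 5]}
        table, meta = _sw_table(counts, taxa)
        ref = abundant_sw(table, meta, cutoff_pct=0.0)
        assert ref.taxa == frozenset(taxa)

    def test_reference_shrinks_as_cutoff_grows(self, toy_table, toy_meta):
        sizes = [len(abundant_sw(toy_table, toy_meta, cutoff_pct=c).taxa)
                 for c in (0.0, 0.01, 1.0, 10.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_no_water_samples_rejected(self, toy_table, toy_meta):
        sponge_only = toy_meta.data.loc[[s for s in toy_meta.sample_ids
                                         if not s.startswith("W")]]
        with pytest.raises(ValueError, match="seawater"):
            sw_core(toy_table, SampleMetadata(sponge_only.copy()))


class TestRarityClass:
    @pytest.mark.parametrize("value,expected", [
        (0.005, "rare"), (0.0099, "rare"), (0.01, "intermediate"),
        (0.5, "intermediate"), (1.0, "intermediate"), (1.01, "abundant"),
        (2.0, "abundant"), (0.0, "rare"),
    ])
    def test_boundaries(self, value, expected):
        assert rarity_class(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rarity_class(-0.1)


def _core(group, taxa_abund: dict[str, float]) -> CoreSet:
    ser = pd.Series(taxa_abund)
    return CoreSet(group=group, occurrence_threshold=1.0, taxa=frozenset(taxa_abund),
                   variable_taxa=frozenset(),
                   per_replicate_core_fraction=pd.Series([ser.sum()]),
                   mean_rel_abundance=ser)


def _ref(method, taxa, sw_abund: dict[str, float]) -> SWReference:
    return SWReference(method=method, taxa=frozenset(taxa),
                       sw_mean_abundance=pd.Series(sw_abund))


class TestOverlap:
    def test_disjoint_core_and_reference_zero(self):
        core = _core("g", {"a": 0.5, "b": 0.3})
        ref = _ref("core", {"x", "y"}, {"x": 0.6, "y": 0.4, "a": 0.0, "b": 0.0})
        rep = overlap(core, ref)
        assert rep.pct_of_sponge_core == 0.0 and rep.pct_of_sw_reference == 0.0

    def test_identical_sets_hundred_percent(self):
        core = _core("g", {"a": 0.6, "b": 0.2})
        ref = _ref("core", {"a", "b"}, {"a": 0.5, "b": 0.5})
        rep = overlap(core, ref)
        assert rep.pct_of_sponge_core == pytest.approx(100.0)
        assert rep.pct_of_sw_reference == pytest.approx(100.0)

    def test_rare_enriched_pattern(self):
        """Taxa at 5 % of the seawater core carrying 90 % of the sponge core:
        the 'rare cosmopolitan enrichment' pattern."""
        core = _core("g", {"rare1": 0.5, "rare2": 0.4, "other": 0.1})
        ref = _ref("core", {"rare1", "rare2", "big"},
                   {"rare1": 0.03, "rare2": 0.02, "big": 0.95})
        rep = overlap(core, ref)
        assert rep.pct_of_sponge_core == pytest.approx(90.0)
        assert rep.pct_of_sw_reference == pytest.approx(5.0)

    def test_empty_core_rejected(self):
        core = CoreSet("g", 1.0, frozenset(), frozenset(),
                       pd.Series(dtype=float), pd.Series(dtype=float))
        ref = _ref("core", {"a"}, {"a": 1.0})
        with pytest.raises(ValueError, match="empty core"):
            overlap(core, ref)

    def test_invariant_to_taxon_relabelling_and_sample_order(self, toy_table, toy_meta):
        core = extract_core(toy_table, toy_meta, "sponge A")
        ref = sw_core(toy_table, toy_meta)
        base = overlap(core, ref)
        # permute samples
        perm = toy_table.data.sample(frac=1, random_state=0)
        table2 = CountTable(perm)
        core2 = extract_core(table2, toy_meta, "sponge A")
        ref2 = sw_core(table2, toy_meta)
        rep2 = overlap(core2, ref2)
        assert rep2.pct_of_sponge_core == pytest.approx(base.pct_of_sponge_core)
        # relabel taxa
        mapping = {t: f"renamed_{t}" for t in toy_table.taxon_ids}
        table3 = CountTable(toy_table.data.rename(columns=mapping))
        core3 = extract_core(table3, toy_meta, "sponge A")
        ref3 = sw_core(table3, toy_meta)
        rep3 = overlap(core3, ref3)
        assert rep3.pct_of_sponge_core == pytest.approx(base.pct_of_sponge_core)


class TestMethodDifference:
    def test_identical_references_zero(self):
        core = _core("g", {"a": 0.7, "b": 0.3})
        ref1 = _ref("core", {"a"}, {"a": 0.5, "b": 0.5})
        ref2 = _ref("abundant", {"a"}, {"a": 0.5, "b": 0.5})
        assert method_difference(overlap(core, ref1), overlap(core, ref2)) == 0.0

    def test_group_mismatch_rejected(self):
        c1 = _core("g1", {"a": 1.0})
        c2 = _core("g2", {"a": 1.0})
        ref1 = _ref("core", {"a"}, {"a": 1.0})
        ref2 = _ref("abundant", {"a"}, {"a": 1.0})
        with pytest.raises(ValueError, match="different groups"):
            method_difference(overlap(c1, ref1), overlap(c2, ref2))


class TestEnrichmentFlags:
    def test_all_shared_abundant_scores_zero(self):
        core = _core("g", {"a": 0.9, "b": 0.1})
        ref = _ref("core", {"a", "b"}, {"a": 0.5, "b": 0.5})
        flags = enrichment_flags({"g": overlap(core, ref)})
        assert flags["g"].rare_sw_score == 0.0 and not flags["g"].enriched

    def test_rare_sw_core_at_ninety_percent_flagged(self):
        # shared taxa rare in seawater (<0.01 %) but 90 % of the sponge core
        core = _core("g", {"r1": 0.5, "r2": 0.4, "other": 0.1})
        ref = _ref("core", {"r1", "r2"}, {"r1": 5e-5, "r2": 4e-5, "big": 0.9})
        flags = enrichment_flags({"g": overlap(core, ref)})
        assert flags["g"].rare_sw_score == pytest.approx(90.0)
        assert flags["g"].enriched

    def test_dominance_cutoff_hundred_flags_nothing(self):
        core = _core("g", {"r1": 0.99, "other": 0.01})
        ref = _ref("core", {"r1"}, {"r1": 1e-5, "big": 0.9})
        flags = enrichment_flags({"g": overlap(core, ref)}, dominance_cutoff_pct=100.0)
        assert not flags["g"].enriched

    def test_wrong_method_rejected(self):
        core = _core("g", {"a": 1.0})
        ref = _ref("abundant", {"a"}, {"a": 1.0})
        with pytest.raises(ValueError, match="core-method"):
            enrichment_flags({"g": overlap(core, ref)})


class TestPotentialContaminants:
    def test_sw_abundant_core_rare_taxon_listed(self):
        core = _core("g", {"sus": 5e-5, "main": 0.9})
        ref = _ref("core", {"sus", "main"}, {"sus": 0.05, "main": 0.01})
        out = potential_contaminants({"g": overlap(core, ref)})
        assert list(out["taxon"]) == ["sus"]

    def test_nothing_suspicious_empty(self):
        core = _core("g", {"a": 0.9})
        ref = _ref("core", {"a"}, {"a": 0.02})
        assert potential_contaminants({"g": overlap(core, ref)}).empty
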