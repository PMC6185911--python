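"""PERMANOVA, PERMDISP and IndVal on a simulated host/seawater dataset.

Tests whether host species structures the communities (PERMANOVA), whether
HMA and LMA hosts differ in within-group dispersion (PERMDISP with the
small-sample bias adjustment), and which phyla/classes indicate each habitat
class (Dufrêne–Legendre IndVal).
"""

from spongecore import (aggregate_taxa, bray_curtis, generate, indval, permanova,
                        permdisp, to_relative_abundance)
from spongecore.synthetic import SimulationParams

params = SimulationParams.default_study(seed=0)
table, meta, taxonomy, _ = generate(params)

rel = to_relative_abundance(table)
sponges = [s for s in table.sample_ids if meta.data.loc[s, "group"] != "seawater"]
dm = bray_curtis(rel.loc[sponges])

res = permanova(dm, meta.grouping(sponges, "group"), n_permutations=199, seed=1,
                factor="species")
print(f"PERMANOVA (species factor): pseudo-F = {res.pseudo_f:.1f}, "
      f"R² = {res.r2:.3f}, p = {res.p:.4f}")
res_h = permanova(dm, meta.grouping(sponges, "habitat_class"), n_permutations=199,
                  seed=1, factor="habitat")
print(f"PERMANOVA (HMA/LMA factor): pseudo-F = {res_h.pseudo_f:.1f}, "
      f"R² = {res_h.r2:.3f}, p = {res_h.p:.4f}")

disp = permdisp(dm, meta.grouping(sponges, "habitat_class"), bias_adjust=True,
                n_permutations=199, seed=1, factor="habitat")
print(f"PERMDISP  (HMA/LMA):        F = {disp.f:.1f}, p = {disp.p:.4f}; "
      f"mean distance to centroid: "
      + ", ".join(f"{g}={d:.3f}" for g, d in disp.group_mean_distance.items()))

agg = aggregate_taxa(table, taxonomy, rank="phylum", proteobacteria_to_class=True)
rel_agg = agg.div(agg.sum(axis=1), axis=0).loc[sponges]
results = indval(rel_agg, meta.grouping(sponges, "habitat_class"),
                 threshold=0.6, alpha=0.01, n_permutations=199, seed=1)
print("\nIndVal indicators (value ≥ 0.6, p < 0.01):")
for r in sorted(results, key=lambda r: -r.indval):
    if r.is_indicator:
        print(f"  {r.taxon:<24} → {r.group}  IndVal = {r.indval:.2f}, p = {r.p:.4f}")
# Host species explains most of the community variance; HMA hosts cluster
# tightly (low dispersion) and carry their own indicator phyla/classes.
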