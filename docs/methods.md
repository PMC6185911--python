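# Methods

## The analysis model

The pipeline operates on a samples × taxa table of non-negative integer
read counts (ZOTUs — exact sequence variants at 100 % identity — or OTUs;
the pipeline is agnostic) with per-sample metadata assigning a host-species
group or `seawater`, and an HMA/LMA/SW habitat class.

**Rarefaction.** All analyses run on a table rarefied to even depth by a
seeded multivariate-hypergeometric draw per sample (subsampling without
replacement). Default depth 41 000 reads; samples below depth are dropped
and logged. One seeded draw is taken (no rarefaction averaging): the goal is
a reproducible, even-effort table for occurrence rules, not a variance
estimate of the rarefaction itself.

**Core communities.** The core of a group with *n* replicates at occurrence
threshold *t* is the set of taxa with a nonzero count in at least ⌈t·n⌉
replicates; the default t = 1 (presence in *all* replicates) is the
restrictive definition appropriate for isolating persistent symbionts from
transient environmental bacteria. Presence means count ≥ 1 in the rarefied
table; no abundance floor is applied. Everything a group's replicates
contain beyond its core is the *variable* community, so core + variable read
shares sum to one in every replicate. A taxon is *species-specific* when it
belongs to exactly one core among all cores analysed; membership is tested
against cores only, never against full communities (a taxon may therefore be
species-specific *and* shared with seawater).

**Denominators.** The core fraction is relative to each replicate's total
reads (mean ± sd across replicates). Species-specific and seawater-shared
percentages are relative to the *core community's* summed mean relative
abundance — the only convention consistent with a species whose seawater
overlap (99.5 %) exceeds its core-of-total share (61.9 %). Per-taxon means
across replicates are computed first and then summed over sets, which keeps
every percentage decomposable per taxon for heatmap export.

**Seawater references.** Two references: the seawater *core* (taxa present
in all water replicates — cosmopolitans) and the *abundant* seawater
community (mean relative abundance across water samples strictly greater
than 0.01 %). Rarity classes use <0.01 % (rare) and >1 % (highly abundant).
The method difference (core-method overlap minus abundant-method overlap, in
percentage points of the sponge core) is positive when the core relies on
cosmopolitan taxa individually below the abundance cutoff: the seed-bank
enrichment signature. The enrichment flag scores the summed core share of
shared taxa rarer than 0.01 % in seawater and flags a species above a
dominance cutoff (default 50 % — a documented package choice, not an
established threshold). Seawater-abundant taxa nearly absent from a core are
*reported* as potential contamination, never removed: blanket removal of
abundant seawater taxa would delete genuine symbionts.

## Permutation statistics

All three tests are first-principles implementations with free
(unstratified) label permutations, seeded, and add-one p-values
p = (1 + #{stat* ≥ stat}) / (B + 1), which can never reach zero. Default
B = 999, α = 0.05 (0.01 for IndVal).

* **PERMANOVA** (one-way): SS_total = N⁻¹ Σ_{i<j} d²ᵢⱼ,
  SS_within = Σ_g n_g⁻¹ Σ_{i<j∈g} d²ᵢⱼ, pseudo-F =
  (SS_between/(a−1))/(SS_within/(N−a)), R² = SS_between/SS_total. Verified
  against scikit-bio's implementation and, on Euclidean 1-D toys, against
  the classical one-way ANOVA F.
* **PERMDISP**: samples are embedded by principal-coordinates analysis of
  the Gower-centred matrix; squared distances to group *centroids* subtract
  the contribution of negative-eigenvalue axes and are clamped at zero
  (the standard convention for semi-metric dissimilarities such as
  Bray-Curtis). The optional bias adjustment multiplies each group's
  distances by √(n_g/(n_g−1)), which matters for strongly unequal group
  sizes (e.g. 3 HMA vs 16 LMA species). F is the classical one-way ANOVA F
  on the (adjusted) distances; the permutation fully recomputes centroids,
  distances and F for every relabelling. Verified against frozen reference
  values from R vegan's `betadisper(type = "centroid")` in both
  bias-adjustment settings. Centroids, not spatial medians, are used — a
  deliberate, documented choice.
* **IndVal** (Dufrêne–Legendre): specificity A_ij = mean abundance of taxon
  i in group j divided by the sum of its group means; fidelity B_ij =
  fraction of group j's samples containing the taxon; IndVal_i =
  max_j A_ij·B_ij, permutation p on that max. Computed on (possibly
  rank-aggregated) relative abundances as given — the statistic is not
  renormalised internally. Indicator status requires IndVal ≥ 0.6 and
  p < 0.01.

Because each test is an exact permutation test under exchangeability, the
type-I error at rejection rule p ≤ α equals ⌊α(B+1)⌋/(B+1) regardless of the
statistic; the calibration module verifies 0.05 empirically over 500 null
simulations with B = 199.

Community statistics that have canonical library implementations (Shannon
entropy, Bray-Curtis, Spearman with average ranks, tie-corrected
Kruskal-Wallis, average/complete/single linkage) are thin wrappers over
scipy/scikit-bio; clustering sorts ids lexicographically first so
equal-distance merges resolve deterministically.

## The synthetic generator

The generator emulates a multi-species host/seawater survey so every
pipeline stage has a planted, recoverable target.

**Seawater pool.** A block-structured community: ~12 abundant cosmopolitans
carrying most of the water-column reads (top taxon ~30 % of the remaining
mass, geometric-ish decay), a band of mid-abundance cosmopolitans
(2–3 × 10⁻⁴ each), a set of *rare cosmopolitans* (4–6 × 10⁻⁵ — present in
every water replicate yet below the 0.01 % abundance cutoff; these drive the
method difference), a pool of sponge-enriched taxa effectively absent from
the water (3 × 10⁻⁷), and a lognormal rare tail (10⁻⁷–10⁻⁶). All designated
cosmopolitans are guaranteed present in every water sample (single-read
swaps from the most abundant taxon, preserving row sums) — the definition of
a cosmopolitan, made literal.

The block structure is deliberate: taxa whose per-replicate detection
probability sits in the ambiguous middle are always *planted* members of at
least two species' cores (round-robin assignment over demand-clamped pools),
so occurrence-based reference and core membership is decidable and planted
species-specific sets are exactly recoverable by set algebra. A real
seawater community has a continuous abundance spectrum; the cost of the
simplification is that the simulated variable fraction is small (see
Limitations).

**Sponge samples.** Each species has a planted core mixing four member
categories: (a) abundant/mid cosmopolitans, (r) rare cosmopolitans (only in
species flagged as rare-seawater enrichers), (b) shared sponge-enriched
taxa, (c) species-specific taxa absent from the pool entirely, with target
read shares per category and within-category lognormal weight profiles
(σ = 0.7 for HMA species, 2.4 for LMA — producing the higher, more even
core diversity of HMA hosts). Every planted member receives at least
`min_core_weight` (5 × 10⁻⁴) of the core profile, i.e. ≥ ~16 expected reads
per replicate at depth 41 000: planted cores model *consistently present*
symbionts, and detection misses are vanishingly rare. Each replicate is one
multinomial draw of `depth` reads from
(1 − t)·(core profile) + t·(seawater pool), with transient fraction
t = 0.2: the variable community is seawater carried in proportionally to
water-column abundance.

**Defaults.** The default parameter set mirrors the bundled 19-species
survey: its replicate numbers (2–15, 98 sponge samples), per-species core
sizes (54–600), species-specific counts (0–195), seawater-shared counts,
HMA flags, 9 water samples, depth 41 000. Six species are flagged as
rare-seawater enrichers with rare-category shares of 0.2–0.8 of their core
(the strongest, 0.8, reproduces the pattern of a core that is ~90 % rare
cosmopolitans representing only a few percent of the seawater core's
abundance). Per-species abundant-cosmopolitan shares span 0.02–0.97 so the
seawater overlap ranges from ~20 % to ~98 % across species.

**Ground truth and expectations.** The truth object records the planted
sets and the *exact expected values* of the pipeline estimands under the
mixture. Expectations include the predictable contribution of non-planted
transient taxa: a taxon with per-replicate detection probability p_rep joins
the measured core share with inclusion factor p_rep^(n−1) (the counted
replicate contributes E[X·1{X≥1}] = E[X]). The reported standard error of
the core fraction combines multinomial read noise with the Bernoulli
variance of those borderline inclusions; overlap-percentage SEs use binomial
noise on the core's read budget plus a 0.05-point floor absorbing the
chance-inclusion approximation. Recovery scoring treats a method difference
as "positive" only beyond a 0.1-point noise floor (≈ 40 reads at default
depth): unflagged species sit at ±0.01 points of read noise with arbitrary
sign, flagged species at > 10 points.

**What passing recovery does and does not show.** Exact recovery of cores
and species-specific sets, overlap percentages within 3 SE of expectation,
and the method-difference sign pattern show that every pipeline stage
implements its definition correctly at realistic depth and replication. They
do not show robustness to features the generator omits: biological
overdispersion between replicates (simulated replicates are exchangeable
multinomials, so the species-factor PERMANOVA R² is ~0.999 where a real
survey reported 0.56), compositional correlation among taxa, patchy
high-abundance symbionts (the simulated variable fraction is < 1 % of reads
where real sponges show 10–50 %), or sequencing error (denoising is out of
scope). With a continuous seawater abundance spectrum there is also a small
residual chance (~2 % per run at default size) that an ultra-rare transient
lands single reads in both replicates of a 2-replicate species and is
mis-called species-specific — visible as an exact-fraction of 18/19 at some
seeds.

## Numerical and design choices

* Shannon diversity is in natural log; core-community diversity is computed
  per replicate on core members' counts, then averaged per species.
* Bray-Curtis is computed on relative abundances of the rarefied table;
  Fig-style heatmap clustering uses species-mean shared-taxon profiles,
  average linkage.
* The abundant-seawater cutoff is a strict inequality (> 0.01 %), so a taxon
  at exactly the cutoff is excluded.
* Occurrence thresholds use ⌈t·n⌉ with presence = count ≥ 1; a
  single-replicate group warns and returns its observed taxa.
* Identifier matching is exact and case-sensitive for taxon ids
  (machine-generated), case-insensitive for habitat classes (hand-edited).
* All stochastic stages take explicit integer seeds; identical
  configuration + seed reproduces every exported file byte-identically.
* One-way designs only: host species and HMA/LMA identity are tested as
  separate factors, matching the analysis the pipeline reimplements;
  multi-factor or nested permutation schemes are out of scope.

## Problem sizes

Default analyses run on 107 samples × ~2 000 taxa at depth 41 000 with 199
permutations in tests (999 by default in the CLI); the calibration study
uses 500 null simulations of 16 samples × 200 taxa at depth 2 000 with 199
permutations. These sizes were chosen so the full suite and the acceptance
script each complete in well under a minute on one CPU while leaving all
statistical margins (3 SE bands, calibration bands) intact.
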