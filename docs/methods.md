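# Methods

This note records the models implemented in `cladediv`, the conventions and
defaults chosen where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Tree-based metrics

All per-plot metrics are abundance weighted by relative cover: a plot's raw
covers are normalized to proportions inside the metric functions, never at
read time (field percentage covers need not sum to 100, and keeping raw
values preserves the user's data). All three metrics are therefore invariant
to rescaling a plot's covers, and a zero-cover species changes nothing.

**Weighted Faith's PD.** For the subtree spanning the plot's species (stem
above the plot MRCA excluded), with branch lengths `λ_i` and `Ā_i` the mean
relative cover of the plot species descending from branch `i`,

    PD_w = B · Σ_i λ_i Ā_i / Σ_i Ā_i,   B = number of branches.

This Barker-style branch weighting is pinned by its limit: at equal covers
`Ā_i` is constant and `PD_w` reduces exactly to the unweighted branch-length
sum. The implementation never prunes per plot; it counts plot species below
every edge of the pool tree (a sparse ancestor-incidence product), marks the
edges below the plot MRCA, and exploits the fact that every edge of a merged
(unary) path has the same descendant plot-species set. Equality with
explicit prune-then-sum is asserted in the test suite to 1e-9.

**MPD / VPD.** Pair weights are `w_jk = f_j f_k` over unordered pairs
`j < k`. MPD is the weighted mean of patristic distances; VPD is the
weighted *population* variance (`Σw d²/Σw − MPD²`, no n−1 correction —
nothing in the definition of "variation of pairwise distances" asks for
one). Negative variances of numerical size (≲1e-12, from catastrophic
cancellation at near-constant distances) are clamped to zero. Plots with a
single species get missing PD/MPD/VPD and are excluded listwise from fits,
with counts recorded: pairwise quantities are undefined at S = 1.

**Patristic distances** are computed as `depth_j + depth_k − 2·(shared
root-path length)`, with the shared lengths obtained from a sparse
tips × edges incidence matrix carrying `√(edge length)` (so the Gram matrix
is exactly the shared path length). Zero-length edges are permitted
throughout; they are the standard encoding of soft polytomies in supertrees,
and the pure-birth simulator also emits one zero-length terminal pair (its
stopping rule ends at the birth of the n-th tip).

## Clade indices

With `S` the plot richness, `p_i` the relative cover of clade `i`, `CR_i`
the clade's species richness in the pool, `CR_SP` the number of pool clades
and `S_SP` the pool richness:

    CRI = ln(S) + 3 · Σ_i p_i / CR_i
    CDI = 1 − Σ_i (p_i − 1/CR_SP)²
    CRG = 1 − Σ_i (p_i − CR_i/S_SP)²

Conventions, each the package's own resolution of an open point:

* Sums run over **all pool clades**; a clade absent from the plot
  contributes `(0 − optimum)²`. This is forced by the optimum semantics —
  CDI can only reach 1 when every pool clade is present — but a
  `include_absent=False` switch allows present-clades-only sums for
  sensitivity checks.
* The logarithm is natural. The base only shifts the intercept of the
  downstream linear fits, never R².
* The multiplier 3 in CRI is fixed, not a tuning knob.
* CDI is provably in (0, 1]: `Σ(p_i − 1/k)² = Σp_i² − 1/k ≤ 1 − 1/k < 1`.
  CRG has no such lower bound and **can be negative** for extreme
  proportions (e.g. all cover on a small clade of a lopsided pool gives
  −0.62 in the tests), although it is often described as scaling from 0
  to 1. Values are returned unclipped; any threshold rule (such as
  restricting attention to plots with CRG > 0.2) should operate on raw
  values.
* The default species pool is every species appearing in the community
  matrix; an explicit pool can be passed. Computing indices at a different
  clade resolution is done by swapping the clade map only — there is no
  other code path.

## Synthetic generators

The simulation module reproduces a factorial community-simulation workflow
without any external tree:

* **Yule trees** (pure birth, rate 1) via dendropy, seeded and
  deterministic; ultrametric by construction.
* **Phylogenetic scales.** Two realizations are provided. *Nested
  subclades*: successively smaller monophyletic clades along the
  largest-child chain of one simulated megaphylogeny (mirroring
  vascular plants ⊃ angiosperms ⊃ superasterids, where each smaller scale
  drops basal structure). *Depth rescaling*: independent trees rescaled to
  prescribed crown depths. Rescaling on its own cannot change any fit —
  R² is invariant under linear rescaling of distances — so depth acts only
  relative to the fixed clade-cut height, exactly as a fixed-age taxonomic
  rank sits at different relative depths in young and old clades.
* **Clade maps** by cutting an ultrametric tree at a fixed height above the
  tips; clades are the tip sets of the lineages crossing the cut, a
  monophyletic partition. The default cut of 1.5 (in units of the unit
  birth rate) gives a mean clade size of ≈ e^1.5 ≈ 4.5–5 species per clade
  across tree sizes, matching family-level granularity in herbaceous
  vegetation datasets (≈ 5 species per family). Cuts are applied to the
  *scale* tree and restricted to the sampled pool, so a pool whose MRCA
  happens to sit below the cut still gets a well-defined map.
* **Species pools** are uniform draws without replacement from a scale
  tree's tips.
* **Communities**: per site, richness S is drawn uniformly over the
  inclusive integer range, S species are drawn uniformly, and proportions
  come from a flat Dirichlet (uniform on the simplex — the maximally
  uninformative way to make random proportions sum to one). A
  `proportion_model="uniform"` switch normalizes iid U(0,1) draws instead,
  for sensitivity analysis.
* **Seed discipline**: a master seed is combined with each design-cell
  label (scale / pool size / richness range / replicate) through SHA-256,
  so every cell is independently reproducible and no two cells share a
  stream. Uniqueness across the full 2,700-cell design is tested.

The default factorial (`SimulationConfig.paper_design()`) is 3 scales ×
pool sizes {2000, 500, 250} × richness ranges {10–160, 10–80, 10–40, 10–20,
5–10, 2–5} × 50 replicate matrices of 240 sites. `run_factorial` has a
`compute="generate"` mode that samples pools and matrices without computing
metrics or fits, for design-level checks at full scale.

## Evaluation

* **Fit accuracy** is the OLS R² of `√PD ~ CRI`, `MPD ~ CDI` and
  `log VPD ~ CRG` (natural log; nonpositive responses dropped and counted).
  A quadratic term can be added; its p-value is reported and R² can only
  increase.
* **Heteroscedastic fits** use GLS with an exponential variance function,
  `Var(ε_i) = σ²·exp(2δ·v_i)`, the variance covariate `v` defaulting to the
  predictor. (β, δ, σ²) are maximum-likelihood estimates with the
  likelihood profiled over δ by a bounded 1-D optimizer; δ = 0 reduces
  exactly to OLS, and the GLS log-likelihood can never fall below the OLS
  one. The R² reported for GLS is the squared correlation of fitted and
  observed values and is labeled pseudo-R² — it is not interchangeable
  with the OLS coefficient of determination.
* **Variance components** of R² across the design use the balanced nested
  layout scale / pool size / richness range / replicate and
  expected-mean-squares method-of-moments estimators; negative estimates
  are truncated at zero before normalizing to percentages (which then sum
  to 100 exactly). The design generated here is balanced by construction;
  REML would be preferable on unbalanced data and may differ slightly
  there, which is why unbalanced input is rejected rather than silently
  mishandled.
* The generative recovery tests standardize each simulated batch of random
  effects to its nominal standard deviation, so the *realized* variance
  components equal the targets exactly and the generator is an exact
  oracle. Without this conditioning, a three-level top factor (2 degrees of
  freedom) makes any single recovery run a high-variance draw. Similarly,
  the GLS recovery uses a variance covariate spanning [0, 2] — about a
  five-fold error-SD ratio at δ = 0.8, a realistic degree of
  heteroscedasticity.

## Scaled-down experiment sizes

The trend experiments run at sizes chosen once as a desk-scale rendition of
the full design:

* *Richness-range sweep*: one 360-tip Yule megaphylogeny, nested scales of
  360/180/90 tips, pool 80, ranges (2–5), (5–10), (10–20), (10–40), 20
  replicate matrices of 120 sites per cell, clade cut 1.5.
* *Depth sweep*: independent 250-tip Yule trees rescaled to crown depths
  9/6/3, pools {120, 60}, the same four ranges, 15 replicates of 120
  sites, cut 1.5.

On these, the median richness-fit R² increases monotonically with the
richness-range midpoint, and the divergence and regularity fits are worse on
deeper trees than on shallow ones — the ordinal behavior expected of the
surrogates.

## What the synthetic experiments do not show

Communities here are **completely random**: species are drawn uniformly and
proportions are exchangeable. Real vegetation is assembled non-randomly
(filtering, competition, dispersal), which *strengthens* the
clade-composition signal; surrogate fits on real data are typically far
higher than on random matrices, so the synthetic R² levels are a stress
test, not a forecast. Conversely:

* On homogeneous Yule trees the **regularity** surrogate carries little
  linear signal (median R² of a few percent): VPD there is driven by the
  balance of within- vs between-clade pair weight, which is a non-monotone
  function of clade evenness, and the richness-proportional optimum of CRG
  does not coincide with the VPD minimum the way it does on strongly
  imbalanced real phylogenies with a dominant clade. The depth *ordering*
  still holds, but regularity variance components on Yule trees attribute
  almost nothing to scale, unlike on a real megaphylogeny.
* At large phylogenetic scales the divergence/regularity relationships can
  flip sign entirely — the quantitative reason these surrogates are
  inadvisable in assemblages spanning many distantly related lineages.
* The clade indices need abundance data; they are undefined for
  presence/absence records.
* Full-scale quantitative reproduction (real case-study R², megaphylogeny
  variance components) requires the user to supply the corresponding tree
  and plot data; nothing external is bundled or downloaded.
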