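# Methods

This note documents the statistical models implemented in `guildlink`, the
defaults and why they were chosen, what the synthetic-cohort generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Study design assumed

All analyses target a two-group (case vs control) cross-sectional design
with three omic layers measured on the same subjects: an untargeted serum
metabolite intensity table with pooled-QC injections, a species-level
relative-abundance table from shotgun metagenomics, and a KEGG-ortholog
(KO) relative-abundance table. Clinical metadata carry the group label, an
optional subgroup, binary clinical indices (e.g. cardiac involvement) and
continuous covariates. Default sample sizes are 13 cases vs 22 controls,
the scale at which the pipeline's small-sample behaviour (exact rank tests,
permutation validation) matters.

## Quality control and normalization

Metabolite features are retained when their coefficient of variation across
the pooled-QC injections is below 0.30 (sd/mean, n−1 denominator); features
with zero QC mean have no defined CV and are dropped with a warning. QC
columns are then removed. Before multivariate modelling and t-tests,
intensities are auto-scaled (per-feature centring and unit-variance
scaling, n−1 denominator); zero-variance features become all-zero rows
rather than NaNs. t-test p-values are location-scale invariant per feature,
so testing on the scaled table is equivalent to testing raw intensities;
the scaled table is used so that a single matrix feeds both the univariate
and multivariate steps.

Missing abundance values are a hard error for species/KO tables. For
metabolite intensity tables an explicit opt-in imputation (per-feature
minimum / 2) is available; it is off by default because missingness policy
is a dataset-level decision, not something to silently guess.

## Univariate tests and multiplicity

- Student's t (equal-variance, two-sided) for metabolites; a Welch variant
  is available. Degenerate zero-variance input returns p = 1 when means
  agree and p = 0 (with a warning) when they do not.
- Wilcoxon rank-sum (two-sided) for species and KOs. The exact null
  distribution is used when the pooled sample size is ≤ 25 and there are no
  ties — at 13 + 22 = 35 the normal approximation applies, with average
  ranks, tie-corrected variance and a 0.5 continuity correction. An
  all-tied comparison returns p = 1 (the tie-corrected variance is zero).
- Benjamini–Hochberg step-up q-values everywhere an adjusted value is
  reported (delegated to statsmodels).

Selection rules: metabolites need t-test p < 0.05 AND OPLS-DA VIP > 1;
species need Wilcoxon p < 0.05 AND overall mean relative abundance > 10⁻⁶
(species absent everywhere are excluded before testing); KOs need Wilcoxon
p < 0.05. Direction ("case_enriched"/"case_depleted") is the sign of the
case-minus-control mean difference; no fold-change criterion is applied.

## PLS-DA and OPLS-DA

Both models are PLS1 fits by NIPALS on the centred {0,1} class vector.
For each component: w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt,
then deflation X ← X − tpᵀ, y ← y − qt. PLS-DA adds components while the
cross-validated Q² improves by more than 0.01 (configurable), up to a cap
(default 5); at least one component is always fitted.

OPLS-DA follows Trygg–Wold orthogonal signal correction: from the current
w and p, the orthogonal weight w_orth ∝ p − (wᵀp)w is extracted, its score
removed from X, and the step repeated for each orthogonal component; a
single predictive component is then fitted on the filtered X. With zero
orthogonal components this reduces exactly to one-component PLS-DA (a
tested identity). `n_orth="auto"` adds orthogonal components under the
same ΔQ² > 0.01 rule.

VIP is computed over predictive components only:
VIP_j = √( p · Σₐ SSₐ w²ⱼₐ / Σₐ SSₐ ) with SSₐ = qₐ² tₐᵀtₐ. Since each wₐ
has unit norm, mean(VIP²) = 1 identically — used as a self-check. A flag to
include orthogonal components exists but is off: VIP thresholding at 1 is
conventionally read off the predictive part.

Q² = 1 − PRESS/SS with SS about the centred response. Folds are
"venetian blinds": a seeded shuffle of the sample order followed by
interleaved assignment to 7 folds (the de facto default of the commercial
chemometrics tools this replaces; fold count configurable). The fold seed
is fixed (default 0) so fits are deterministic. Fold assignments are
re-drawn (with a warning) until every held-out fold contains both classes;
when fold sizes make that impossible (e.g. singleton folds at small n) the
requirement is relaxed to both classes in every *training* set, which is
what the refit actually needs.

Permutation validation refits the model under n_perm (default 99) random
label permutations, recording R²Y, Q² and the Pearson correlation between
permuted and original labels. The empirical p for Q² uses the add-one
estimator (#{Q²_perm ≥ Q²} + 1)/(n_perm + 1), which cannot be zero. The
model is flagged valid when every permuted Q² falls below the original and
the regression of Q² on |label correlation| (original point included)
intercepts at ≤ 0.05.

Sign convention: within every component the loading entry of largest
magnitude is made positive, so scores/loadings/weights are bit-identical
across repeated runs.

## Guild detection

Pairwise Spearman correlations use average ranks; two-sided p-values come
from the exact permutation null for tie-free pairs with ≤ 9 samples (the
null distribution of Σd² is enumerated once per n and cached) and from the
t approximation otherwise. Constant features get ρ = 0, p = 1 with a
warning.

Guilds are flat clusters of the average-linkage dendrogram on distance
d = 1 − ρ, cut at a fixed height: 0.4 for metabolite modules, 0.5 for
species co-abundance groups (CAGs). The distance is deliberately 1 − ρ and
not 1 − |ρ|: guild abundances are member *sums*, and summing strongly
anti-correlated features would cancel signal; a `1-|rho|` option exists for
exploratory use. Singletons remain as their own guilds. Labels (M1…, CAG1…)
are assigned by decreasing guild size, ties broken by the lexicographically
first member id — any fixed rule works, this one is stable under feature
reordering. Module clustering operates on the differential features across
all samples (case and control pooled).

The co-occurrence network BH-adjusts the upper-triangle p-values (each
unordered pair once) and keeps edges with q < 0.05 and |ρ| strictly
greater than 0.46, signed by correlation direction.

## Enrichment

Over-representation is the exact hypergeometric upper tail
P(X ≥ k) for k hits of n in a set of K within a universe of N, with the
enrichment ratio k/(nK/N). Set members are intersected with the universe;
sets with fewer than 2 surviving members are dropped. The universe defaults
to the measured features surviving QC (metabolites) or all profiled KOs — a
reference-metabolome universe is not reconstructable offline, so the
measured universe is the honest default, overridable by the caller. Hit
lists are split by direction (case-enriched vs case-depleted) and tested
separately.

## Integration

Cross-block Spearman correlations (guild × guild, guild × clinical) share
the sample set, rank binary indices as 0/1, and drop missing values
pairwise; pairs with fewer than 3 overlapping samples are reported missing.
Heatmap annotations use RAW p thresholds (* p < 0.05, ** p < 0.01) while
the co-occurrence network uses BH q — the two conventions are intentional
and kept distinct; an `adjust` flag adds q matrices to any block. Sankey
link sets chain two blocks (e.g. CAG → module → clinical), keeping links
with the required sign and raw p < 0.05 and only middle nodes present in
both surviving legs.

ROC AUC uses the Mann–Whitney identity U/(n₁n₂) with ties counted 0.5,
computed on guild cumulative abundances or single-feature intensities. The
reported value is apparent (no cross-validation) and orientation-preserving
by default, with an oriented max(AUC, 1−AUC) option. Sample ordering for
abundance heatmaps is the leaf order of average-linkage clustering on
Bray–Curtis distance.

## Synthetic cohort generator

Each guild (metabolite module or CAG) has a single latent factor
f ~ N(0,1) per sample; a member's log-scale value is
√ρ·f + √(1−ρ)·ε, giving any two members latent-scale Pearson (and, after
the monotone exp transform, Spearman ≈ (6/π)·arcsin(ρ/2)) correlation
controlled by one number. Defaults: within-module ρ = 0.7, 10 modules of
5–15 members among 200 metabolites, 12 CAGs of 4–10 members among 150
species, 300 KOs. Designated differential guilds (half of them, alternating
sign) receive a standardized group shift on the log scale
(default 1.5 SD) — the source study reports no effect sizes, so this is a
calibration choice giving realistic partial power at n = 13 vs 22. Species
get heterogeneous log-normal baselines, per-entry Bernoulli zero-inflation
(default rate 0.3) and are then closed to column sum 1, so correlations are
induced on the compositional scale the analysis actually sees. KO tables
mix null features with a 10% planted differential fraction and are closed
likewise.

One binary clinical flag ("cardiac") is drawn Bernoulli(logistic(slope·f))
from a designated driver module's latent factor (default slope 2). The
driver is the first *non-differential* module: if the driver also carried
the group shift, that shift would dominate the members' sample ranks and
decouple the module's observed abundance from the flag — the flag is
defined on the latent, so a driver orthogonal to the group effect is the
construction that makes the planted link recoverable. Pooled-QC columns are
the grand-mean feature profile with 5% multiplicative noise, so genuine
features pass the CV filter.

The generator is deterministic given its seed and writes the full ground
truth (memberships, differential features with signed effects, flag
drivers) next to the tables.

What it does **not** emulate: realistic taxon names and phylogenetic
structure, sequencing depth and count noise, batch/injection-order drift in
the metabolome, correlated clinical covariates, longitudinal sampling, or
any mechanistic microbe–metabolite coupling (cross-omics correlations arise
only through the group effect and the flag driver). Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
stated model, not performance on real data.

## Problem sizes in the test suite

Recovery and calibration suites run at sizes chosen for statistical
resolution rather than realism: guild recovery uses 50 seeds of a
120-metabolite, 10-module cohort at n = 40 (within-module ρ = 0.8);
permutation validity uses 20 seeds each of planted-effect (2 SD, n = 30,
p = 50) and pure-noise data with 99 permutations; null calibration uses
2000 independent features at 13 vs 22; large-n generator checks use up to
10⁴ samples. The brute-force oracles (rank-test enumeration, BH step-up,
average-linkage agglomeration, hypergeometric tails, AUC pair counts) are
written independently inside the tests.

## Known limitations

- PLS1 only (two classes); no multi-class PLS2, no kernel variants.
- The component-entry rule (ΔQ² > 0.01) and 7-fold venetian blinds are one
  reasonable convention among several used by commercial tools; absolute
  R²Y/Q² values depend on the CV scheme.
- Wilcoxon exact mode requires tie-free data; heavily tied small samples
  fall back to the corrected normal approximation.
- Spearman p-values for n > 9 use the t approximation, which is slightly
  anti-conservative at very small n with strong ties.
- Compositional closure induces spurious negative correlation among
  high-abundance species; the network threshold |ρ| > 0.46 was adopted as a
  fixed rule, not re-derived.
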