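# Methods

This note documents the models, algorithms and numerical choices behind
`guildnet`, and what the synthetic-cohort validation does and does not
demonstrate.

## Synthetic cohort generator

The generator (`guildnet.simulate`) emulates a small two-arm inflammatory
bowel disease diet cohort: by default 29 participants, 13 whose fecal
calprotectin (FCP) rises between baseline and week 8 and 16 whose FCP
falls, with 551 features across seven blocks (331 taxa, 84 serum
metabolites, 6 SCFAs, 9 bile acids, 121 diet variables split into total
nutrients, energy-adjusted nutrients and food-group frequencies). The
per-block counts are a documented invention: only the total and its
composition by data type are anchored to the emulated study design.

**Module structure.** K = 10 latent factors are drawn per sample
(standard normal). A module feature is

    x = loading * F_k + sqrt(1 - loading^2) * eps + noise_sd * eta

with independent standard-normal `eps`, `eta`, so two same-module features
correlate at `loading^2 / (1 + noise_sd^2)` and the correlation tends to
`loading^2` as the extra noise vanishes. Defaults `loading = 0.8`,
`noise_sd = 0.5` give a within-module Spearman correlation of ≈ 0.51 —
strong but realistically noisy co-abundance. About one third of features
are unstructured noise, mirroring the proportion of unclassifiable
features expected at this scale. Module membership is striped across
blocks so every module is genuinely multi-omic.

**Compositional taxa.** Taxa are logistic-normal: the Gaussian matrix is
sparsified (10 % random absences), exponentiated and closed to relative
abundances per sample. This is a stand-in for relative-abundance
structure, not a sequencing model: there is no read-depth/count noise, no
phylogenetic correlation, and zeros are structural rather than sampling
zeros. Consequences: Spearman correlations among taxa are mildly
attenuated relative to Gaussian blocks (shared log-total noise plus
zero-ties), which the recovery tests absorb.

**Enterotypes.** Each sample belongs to one of three enterotypes
(stratified by trajectory arm so cluster–FCP contrasts are not confounded
by the arm split). Each enterotype has eight signature taxa with a +2.5
log-abundance shift in their own cluster and only 5 % presence elsewhere.
One designated cluster carries a +1.5 log-scale elevation of baseline FCP,
planting a clearly orderable high-risk cluster. Because signature taxa
co-vary, they are real planted co-abundance structure and the ground-truth
labels mark them as `cag_0..2` (and chain mediators as `chain_<id>`)
rather than noise.

**Traits and mediation chains.** MDS is Binomial(13, ½) — the 14-item
Mediterranean-diet screener with the alcohol point removed. log1p(FCP at
week 8) follows a linear structural equation: a trajectory-arm mean (4.0
for the decrease arm, +2.87 for the increase arm, matching the emulated
arms' medians of ≈ 54 and ≈ 960 mcg/g), a small direct MDS path (−0.05 per
point), the planted chain contributions, and Gaussian noise (sd 0.6); the
result is mapped through expm1 and floored at zero. The default planted
chain is a "guild" of three taxa (a = 0.5, b = −0.4) and four metabolites
(a = 0.4, b = −0.25) whose joint indirect effect is Σ a_j·b_j = −1.0.
Chain contributions are computed from the *observed* mediation-scale
feature values (log relative abundance for taxa) after compositional
closure, so the planted effect refers to features an analyst can see; an
earlier latent-scale formulation biased recovery by ≈ 7 % through
closure-induced measurement error. Baseline FCP is drawn per arm
(log-normal) and, for the rare sample whose week-8 draw crosses its
baseline in the wrong direction, the *baseline* is repaired — baseline is
exogenous to the chains, so the planted X → M → Y model is untouched
(redrawing week-8 noise instead would censor the outcome selectively and
bias the indirect effect).

## Network construction

Features are rank-transformed (Spearman convention) before everything
else. The correlation matrix is Pearson on ranks (mid-ranks for ties);
constant features are rejected by name. Unsigned adjacency is
|ρ|^β (signed: ((1+ρ)/2)^β). The soft-threshold scan covers β = 1..20;
the scale-free fit splits connectivities into 10 equal-width bins and
regresses log10(bin frequency) on log10(bin mean connectivity). The
default power is β = 10; the emulated analysis quotes both 10 and 11, so
the choice is configurable and logged.

**Module detection.** The dendrogram is average linkage on Euclidean
distances between standardized feature profiles (a literal reading of the
reference procedure); topological-overlap dissimilarity is available by
configuration as the more conventional alternative. The cut is a
variable-height rule of this package's own design: among all merge
heights, pick the one maximising the number of *qualifying* clusters —
size ≥ `min_module_size` (default 11) and mean within-cluster |ρ| at or
above a null-scale cohesion floor of 2/√n — breaking ties toward the
higher height so each qualifying cluster is maximal. A fixed-height cut is
available as a fallback. After eigengene merging (average-linkage on
1 − cor(ME), threshold 0.25, iterated to a fixed point), a two-pass
*completion* stage re-admits unassigned features whose best signed kME is
≥ 0.40 — the analogue of the assignment stage of hybrid tree cutting; the
floor is deliberately stricter than the retention floor so chance-level
membership (null kME sd ≈ 1/√n) essentially never joins. Finally the
membership refinement removes features with own-module kME < 0.30
(inclusive at the boundary). Membership refinement runs after merging;
the order is logged.

**Eigengenes.** First principal component of the z-scored module
sub-matrix (SVD), scaled to unit variance (ddof = 1) and sign-oriented so
its correlation with the module's mean standardized profile is
non-negative. Module colors are assigned by descending size from the
conventional palette; unassigned features always carry the distinct label
`unclassified`, and `grey` is an ordinary color, never a synonym for
unclassified.

**What recovery means here.** Module-recovery ARI is computed against the
module ground truth — planted-module features plus unstructured noise.
The planted enterotype-signature groups (8 taxa each) and the guild (7
features) sit below the minimum module size by design; they are assessed
by the enterotyping and mediation checks respectively, not by the module
ARI. At the default conditions the pipeline reaches ARI ≈ 0.85 at n = 60
and ≈ 0.5–0.6 at the study's n = 29 — the small-sample floor is real and
is why the acceptance bar halves at n = 29.

## Trait association and screening

Module eigengenes and features are associated with traits by Spearman ρ
with a two-sided p from the t approximation (exact permutation enumeration
for n ≤ 9 without ties). Tiers: `*` p < 0.05, `@` 0.05 ≤ p < 0.10, else
`N`. The candidate screen for the mediation cascade applies
Benjamini–Hochberg FDR separately within the MDS family and the FCP
family and admits features at q ≤ 0.20 (inclusive) for at least one trait
(`any`, default) or both (`both`) — both readings are implemented because
the underlying procedure is ambiguous.

## Enterotyping and risk CAGs

PAM is implemented directly (greedy BUILD, best-improvement SWAP to
convergence, index-order tie-breaks — fully deterministic); no
partitioning-around-medoids implementation exists in the installed
scientific stack. The default community distance is the Jensen–Shannon
distance (square root of the divergence, the enterotyping-literature
convention); Bray–Curtis is available. k is chosen by average silhouette
over 2..6 unless fixed. Dominant taxa: prevalence (fraction of subjects
with non-zero abundance) ≥ 10 %, Kruskal–Wallis across clusters at
BH-FDR ≤ 0.1, assigned to the cluster with the highest median abundance.
Risk labels order clusters by median baseline FCP (highest → high,
lowest → low, ties → neutral with a warning); the overall Kruskal–Wallis
is reported alongside. Module enrichment for risk-CAG taxa is a one-sided
hypergeometric over-representation test on the universe of classified
taxa, BH-corrected across module × risk-set pairs, flagged at q ≤ 0.1.

## Mediation

Point estimates are the classical product of coefficients from two OLS
fits; in this linear, no-interaction setting ACME + ADE = total exactly
(asserted to 1e-8). Uncertainty is quasi-Bayesian: coefficient vectors
are drawn from each model's asymptotic distribution and the ACME is
recomputed per draw; the draws use a multivariate t with the model's
residual degrees of freedom rather than a plain normal because at the
cohort sizes this package targets (n ≈ 30) normal-theory intervals are
visibly anti-conservative (observed 95 % coverage ≈ 0.88 vs ≈ 0.93–0.95
with t draws; at n = 500 the two are indistinguishable and measured
coverage is ≈ 0.94). CIs are percentile intervals, widened if necessary
to bracket the point estimate; p = 2·min(fraction of draws ≤ 0, ≥ 0),
floored at 1/n_sims. A nonparametric case-resampling bootstrap is
available as an alternative. Guards: n ≥ 10; n_sims ≥ 100; condition
number of the centered [X, M] design ≤ 1e8; mediator count < n/2.
Proportion mediated is ACME/total, reported as NaN when |total| < 1e-12
or the two disagree in sign.

FCP enters mediation models as log1p(FCP) by default (FCP is non-negative
and right-skewed; the raw scale is available by flag). Covariates default
to none; the cohort validation conditions on the trajectory arm, which is
an exogenous design stratum in the generator and removes designed outcome
variance without biasing the planted paths. Taxa enter mediation on the
log relative-abundance scale (pseudocount 1e-6), SCFAs/bile acids on the
log concentration scale (`cascade.mediation_view`).

The mediation graphs: candidate (source, sink) pairs — MDS → FCP and all
ordered module-eigengene pairs — pass a marginal Spearman pre-filter at
p < 0.10; each remaining pair is tested against every other module as
mediator, and edges whose ACME interval excludes zero are kept, with the
edge sign taken from the ACME (positive/negative association semantics).
Acyclicity is enforced: an edge set that would close a cycle is skipped
with a warning. No multiplicity correction is applied across mediation
edges beyond the per-edge intervals — raw p-values are reported, matching
the practice the pipeline emulates — so the graph should be read as
hypothesis-generating.

## Statistical battery

Scalar tests wrap the installed stack (scipy for Fisher's exact — the
probability-mass two-sided convention — Mann–Whitney with exact small-n
mode, Wilcoxon signed-rank with zeros dropped, Kruskal–Wallis;
statsmodels RLM for Huber M-estimation at c = 1.345). PERMANOVA, PCoA and
BH-FDR are implemented in-package: PERMANOVA needs seeded, vectorised
label permutations (Anderson's partition, pseudo-F, p with the +1
correction; 999 permutations by default); PCoA is Gower double-centering
with negative eigenvalues reported and excluded from coordinates; BH is
the step-up q-value mapped back to input order. Each has an independent
oracle in the test suite (scikit-bio PERMANOVA, distance reconstruction,
exhaustive enumeration, statsmodels multipletests).

## Validation scope and limitations

The acceptance checks are property-based on synthetic cohorts: the
emulated study's own headline numbers are functions of its deposited
dataset and are not reproducible from synthetic data. Passing tests
therefore demonstrate that the pipeline recovers *planted* structure
under a plausible generative model at the study's scale — not that the
generative model matches real gut-microbiome data. Known gaps: no count /
sequencing-depth noise, no phylogenetic or cross-feature correlation
beyond the module factors, two time points only, and Gaussian diet/
metabolite blocks. Problem sizes in the test suite and acceptance script
(n = 29 and 60; 100–500 replicates for calibration checks; 499–999
permutations) were chosen as the smallest sizes at which the measured
quantities are stable to well within the asserted tolerances.
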