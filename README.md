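# guildnet

Weighted co-abundance networks, enterotype risk groups and causal mediation
cascades for small multi-omics microbiome cohorts.

## The problem

In diet-intervention studies of ulcerative colitis, the interesting question
is rarely whether a single taxon correlates with inflammation — it is how a
*web* of diet variables, microbial taxa, serum metabolites, short-chain
fatty acids (SCFAs) and bile acids jointly transmits the effect of diet
quality onto mucosal inflammation. `guildnet` implements that analysis as a
reusable, tested pipeline:

1. **Co-abundance modules.** Heterogeneous features (taxa, metabolites,
   SCFAs, bile acids, diet variables) are rank-transformed and correlated
   (Spearman ρ), soft-thresholded into a weighted network
   (a<sub>ij</sub> = |ρ<sub>ij</sub>|<sup>β</sup>, default β = 10, scanned
   over 1–20 with a scale-free-topology fit), and clustered into modules.
   Each module is summarised by its **eigengene** (first principal component
   of the standardized member profiles); per-feature membership is the
   signed **kME** (correlation with the eigengene). Modules closer than an
   eigengene dissimilarity of 0.25 are merged, and features with own-module
   kME < 0.30 are returned to an explicit *unclassified* pool.
2. **Module–trait association.** Eigengenes are tested against the
   Mediterranean diet score (MDS, the 14-item screener with the alcohol
   point removed, range 0–13) and fecal calprotectin (FCP, mcg/g) with
   tiered significance (`*` p < 0.05, `@` p < 0.10, `N` otherwise).
3. **Risk CAGs.** Baseline microbiomes are enterotyped by PAM
   (partitioning around medoids) on the Jensen–Shannon distance, k chosen
   by silhouette; clusters are labelled high/low risk by baseline FCP;
   cluster-dominant taxa (prevalence ≥ 10 %, Kruskal–Wallis FDR ≤ 0.1)
   define risk co-abundant groups, whose over-representation in network
   modules is scored by a hypergeometric test.
4. **Mediation cascade.** For exposure X, mediator M and outcome Y the
   package fits the linear mediator and outcome models M ~ X and
   Y ~ X + M and reports the average causal mediation effect
   **ACME = â·b̂**, the direct effect (ADE), the total effect
   (= ACME + ADE exactly in this linear no-interaction case) and the
   proportion mediated, with quasi-Bayesian (multivariate-t coefficient
   draw) intervals. Joint mediator sets (ACME = Σ<sub>j</sub> â<sub>j</sub>b̂<sub>j</sub>),
   multi-step chains and the screened feature-level mediation graph
   (FDR ≤ 0.20 candidate screen) build the full diet → microbiome →
   inflammation cascade.

Because cohorts like this are small (tens of participants), every stage is
validated against a **synthetic cohort generator** with planted ground
truth: latent co-abundance modules across all omics blocks, logistic-normal
compositional taxa, three enterotypes with signature taxa, and planted
MDS → guild → FCP mediation chains with known indirect effects.

## Worked example

Generate the default 29-participant cohort (13 FCP-increase / 16
FCP-decrease, 551 features) and measure the planted seven-feature guild
(three taxa + four serum metabolites, true joint indirect effect −1.0 on
the log1p-FCP scale):

```python
import numpy as np
import guildnet as gn
from guildnet.cascade import mediation_view
from guildnet.mediation import mediate_joint

cohort = gn.generate_cohort(seed=7)
features = mediation_view(cohort.features)      # log-abundance scale for taxa
guild = cohort.truth["chain_features"]["guild"]
strata = (cohort.traits.data["trajectory"] == "increase").astype(float).to_numpy()

res = mediate_joint(cohort.traits["MDS"].astype(float), features[guild],
                    np.log1p(cohort.traits["FCP_week8"]),
                    covariates=strata, n_sims=1000, seed=11)
print(res.summary())
```

```
Causal mediation: X -> [taxon:guild_taxon_1 + ... + serum_metabolite:guild_metabolite_4] -> Y
============================================================
ACME               -1.1697   95% CI [-1.6547, -0.7218]   p = 0.001
ADE                 0.1033
Total effect       -1.0664
Prop. mediated      1.0969
(n = 29, 1000 quasi-bayesian draws, seed 11)
```

The combined ACME of −1.17 (CI excluding zero) recovers the planted −1.0:
higher diet quality lowers week-8 inflammation *through* the guild, with
essentially no direct effect left over. Enterotyping the same cohort:

```python
from guildnet.enterotypes import Enterotyper, classify_risk, dominant_taxa

part = Enterotyper(cohort.features.taxa(), seed=7).fit()
part.dominant = dominant_taxa(cohort.features.taxa(), part.assignments)
part.risk, part.fcp_kw = classify_risk(part.assignments, cohort.traits["FCP_baseline"])
print(part.summary())
```

```
Enterotype partition
========================================
k = 3 (jsd distance), avg silhouette = 0.178
  cluster 0: n=11  risk=high     dominant taxa=8
  cluster 1: n=9   risk=low      dominant taxa=8
  cluster 2: n=9   risk=neutral  dominant taxa=8
baseline FCP Kruskal-Wallis: H=4.11 p=0.128
```

All three planted enterotypes are recovered exactly, each with its eight
signature taxa, and the planted high-FCP cluster is labelled high risk.

The same stages are available from the shell:

```bash
guildnet simulate --seed 7 --out cohort/
guildnet network  --data cohort/ --power 10 --min-module-size 11 --out net/
guildnet cags     --data cohort/ --k auto --distance jsd --out cags/
guildnet mediate  --data cohort/ --x MDS --m taxon:guild_taxon_1 --y FCP_week8
guildnet run      --seed 7 --out full_run/        # entire pipeline + manifest
```

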