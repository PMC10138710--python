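"""Synthetic multi-omics cohort generator with planted ground truth.

Emulates a small ulcerative-colitis diet-intervention cohort: 29
participants split into fecal-calprotectin (FCP) "increase" (n=13) and
"decrease" (n=16) trajectories, ~551 features across seven omics blocks,
latent co-abundance modules shared across blocks, three planted
enterotypes with cluster-specific signature taxa, and diet-score ->
mediator -> inflammation mediation chains with known indirect effects.

Generative model
----------------
* K latent module factors per sample, standard normal.
* A module feature is ``loading * factor + sqrt(1 - loading^2) * eps +
  noise_sd * eta`` with independent standard-normal eps, eta, so the
  correlation between two same-module features is
  ``loading^2 / (1 + noise_sd^2)`` (-> loading^2 as noise_sd -> 0).
* Taxa are synthesised on a logistic-normal scale: Gaussian values,
  sparsified by random absences, exponentiated and closed to relative
  abundances per sample.  Enterotype signature taxa get a mean shift in
  their own cluster and are rarely present elsewhere.
* SCFA and bile-acid blocks are exponentiated (concentrations are
  positive); serum metabolites and diet variables stay on a Gaussian
  (intensity z-score) scale.
* MDS is Binomial(13, 1/2) — the 14-item Mediterranean diet screener with
  the alcohol point removed.
* log1p(FCP week 8) follows a linear structural model: a trajectory mean
  shift, a small direct MDS effect, the planted mediation-chain
  contributions and Gaussian noise; FCP is mapped back through expm1 and
  floored at zero.  The true indirect effect of a chain is the sum of its
  per-mediator path products a_j * b_j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .datatypes import BLOCK_LABELS, OmicsFeatureTable, TraitTable

__all__ = ["ChainMediator", "MediationChain", "CohortConfig", "SyntheticCohort",
           "generate_cohort", "planted_acme"]

_BLOCK_PREFIX = {
    "taxon": "sp",
    "serum_metabolite": "met",
    "scfa": "scfa",
    "bile_acid": "ba",
    "diet_total": "nutr",
    "diet_adjusted": "adjnutr",
    "food_group_freq": "food",
}

#: blocks stored on a positive (exponentiated) concentration scale
_POSITIVE_BLOCKS = ("scfa", "bile_acid")

_MDS_CENTER = 6.5  # theoretical mean of Binomial(13, 1/2)


@dataclass(frozen=True)
class ChainMediator:
    """One mediator of a planted chain: X -> (a) -> M -> (b) -> Y."""

    name: str
    block: str
    a: float
    b: float

    def __post_init__(self):
        if self.block not in BLOCK_LABELS:
            raise ValueError(f"mediation_chains: unknown block {self.block!r}")
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("mediation_chains: path coefficients must be finite")


@dataclass(frozen=True)
class MediationChain:
    """A planted X -> mediators -> Y mediation structure.

    ``source`` is "MDS" or the full id of a previously planted mediator
    feature; ``sink`` is "FCP_week8" (contributions enter the log1p-FCP
    structural equation) or the name of a later mediator.
    """

    chain_id: str
    mediators: tuple[ChainMediator, ...]
    source: str = "MDS"
    sink: str = "FCP_week8"

    def __post_init__(self):
        if not self.mediators:
            raise ValueError(f"mediation_chains[{self.chain_id!r}]: empty mediator list")

    @property
    def acme(self) -> float:
        """True indirect effect: sum of per-mediator path products."""
        return float(sum(m.a * m.b for m in self.mediators))


def _default_chains() -> tuple[MediationChain, ...]:
    """A health-associated guild of 3 taxa + 4 metabolites jointly carrying
    a diet -> inflammation indirect effect of -1.0 on the log1p(FCP) scale."""
    meds = tuple(
        ChainMediator(f"guild_taxon_{i}", "taxon", 0.5, -0.4) for i in range(1, 4)
    ) + tuple(
        ChainMediator(f"guild_metabolite_{i}", "serum_metabolite", 0.4, -0.25)
        for i in range(1, 5)
    )
    return (MediationChain("guild", meds),)


def _default_blocks() -> dict[str, int]:
    return {
        "taxon": 331,
        "serum_metabolite": 84,
        "scfa": 6,
        "bile_acid": 9,
        "diet_total": 60,
        "diet_adjusted": 46,
        "food_group_freq": 15,
    }


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 29 participants (13 FCP-increase,
    16 FCP-decrease), 551 features, 10 latent modules with about a third of
    the features left as unstructured noise, three enterotypes and a
    planted mediating guild.
    """

    n_samples: int = 29
    n_increase: int = 13
    n_decrease: int = 16
    block_sizes: dict = field(default_factory=_default_blocks)
    n_modules: int = 10
    loading: float = 0.8
    noise_sd: float = 0.5
    unassigned_frac: float = 1.0 / 3.0
    mediation_chains: tuple = field(default_factory=_default_chains)
    # enterotype structure
    n_enterotypes: int = 3
    signature_taxa_per_cluster: int = 8
    signature_shift: float = 2.5
    signature_other_presence: float = 0.05
    taxa_sparsity: float = 0.10
    # trait model (log1p mcg/g scale)
    fcp_baseline_mu_increase: float = 4.05   # median ~ 57 mcg/g
    fcp_baseline_mu_decrease: float = 7.00   # median ~ 1100 mcg/g
    fcp_baseline_sd: float = 0.8
    fcp_week8_mu_decrease: float = 4.00      # median ~ 54 mcg/g
    trajectory_effect: float = 2.87          # log1p separation increase vs decrease
    fcp_cluster_shift: float = 1.5           # baseline elevation of the high-risk enterotype
    direct_effect: float = -0.05             # direct MDS -> log1p FCP path
    fcp_noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_increase + self.n_decrease != self.n_samples:
            raise ValueError("n_increase + n_decrease must equal n_samples")
        if self.n_increase < 0 or self.n_decrease < 0:
            raise ValueError("trajectory group sizes must be non-negative")
        for block, size in self.block_sizes.items():
            if block not in BLOCK_LABELS:
                raise ValueError(f"block_sizes: unknown block {block!r}")
            if size <= 0:
                raise ValueError(f"block_sizes[{block!r}] must be positive")
        if not (0 < self.loading <= 1):
            raise ValueError("loading must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_modules < 1:
            raise ValueError("n_modules must be at least 1")
        if not (0 <= self.unassigned_frac < 1):
            raise ValueError("unassigned_frac must lie in [0, 1)")
        self.mediation_chains = tuple(self.mediation_chains)
        seen: set[str] = set()
        for chain in self.mediation_chains:
            for m in chain.mediators:
                if m.block not in self.block_sizes:
                    raise ValueError(
                        f"mediation_chains[{chain.chain_id!r}]: mediator block "
                        f"{m.block!r} absent from block_sizes")
                fid = f"{m.block}:{m.name}"
                if fid in seen:
                    raise ValueError(f"duplicate mediator feature {fid!r}")
                seen.add(fid)
            if chain.source != "MDS" and chain.source not in seen:
                raise ValueError(
                    f"mediation_chains[{chain.chain_id!r}]: unknown source "
                    f"{chain.source!r}")

    def chain(self, chain_id: str) -> MediationChain:
        for chain in self.mediation_chains:
            if chain.chain_id == chain_id:
                return chain
        raise KeyError(f"unknown mediation chain {chain_id!r}")


@dataclass
class SyntheticCohort:
    """Generated cohort plus the ground truth used by recovery tests."""

    features: OmicsFeatureTable
    traits: TraitTable
    truth: dict
    config: CohortConfig


def planted_acme(config: CohortConfig, chain_id: str) -> float:
    """True indirect effect sum(a_j * b_j) for one planted chain."""
    return config.chain(chain_id).acme


def _allocate_features(config: CohortConfig) -> tuple[pd.Index, pd.Series, pd.Series]:
    """Feature ids, block labels and truth module labels.

    Mediator features are carved out of their block's budget; the remaining
    budget is split into module features (round-robin across modules, so
    every module spans blocks) and unstructured noise features.
    """
    mediator_count: dict[str, int] = {}
    mediator_ids: dict[str, list[str]] = {b: [] for b in config.block_sizes}
    for chain in config.mediation_chains:
        for m in chain.mediators:
            mediator_count[m.block] = mediator_count.get(m.block, 0) + 1
            mediator_ids[m.block].append(f"{m.block}:{m.name}")

    ids: list[str] = []
    blocks: list[str] = []
    modules: list[str] = []
    module_cursor = 0
    for block, size in config.block_sizes.items():
        n_med = mediator_count.get(block, 0)
        n_free = size - n_med
        if n_free < 0:
            raise ValueError(f"block_sizes[{block!r}] smaller than its mediator count")
        n_mod = int(round(n_free * (1 - config.unassigned_frac)))
        prefix = _BLOCK_PREFIX[block]
        for i in range(n_free):
            ids.append(f"{block}:{prefix}{i + 1:04d}")
            blocks.append(block)
            if i < n_mod:
                modules.append(f"module_{module_cursor % config.n_modules + 1}")
                module_cursor += 1
            else:
                modules.append("none")
        for fid in mediator_ids[block]:
            ids.append(fid)
            blocks.append(block)
            modules.append("none")
    index = pd.Index(ids, name="feature")
    return index, pd.Series(blocks, index=index), pd.Series(modules, index=index)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a cohort; identical config + seed gives identical output.

    ``seed`` overrides ``config.seed`` when given.
    """
    config = config if config is not None else CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.n_modules
    samples = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample")

    trajectory = np.array(["increase"] * config.n_increase + ["decrease"] * config.n_decrease)

    # enterotypes stratified by trajectory so cluster FCP contrasts are not
    # confounded by the trajectory split
    enterotype = np.empty(n, dtype=int)
    for label in ("increase", "decrease"):
        idx = np.flatnonzero(trajectory == label)
        enterotype[idx] = rng.permutation(np.arange(len(idx)) % config.n_enterotypes)

    factors = rng.standard_normal((n, k))
    feature_ids, blocks, module_truth = _allocate_features(config)

    # latent Gaussian matrix for every feature
    gauss = pd.DataFrame(0.0, index=samples, columns=feature_ids)
    resid_sd = math.sqrt(max(0.0, 1 - config.loading**2))
    for j, fid in enumerate(feature_ids):
        lab = module_truth.iloc[j]
        if lab.startswith("module_"):
            m = int(lab.split("_")[1]) - 1
            gauss[fid] = (config.loading * factors[:, m]
                          + resid_sd * rng.standard_normal(n)
                          + config.noise_sd * rng.standard_normal(n))
        else:
            gauss[fid] = rng.standard_normal(n)

    # MDS and planted chains.  Mediator values are generated here (latent
    # scale); their contributions to week-8 FCP are computed AFTER the
    # compositional closure from the *observed* mediation-scale values
    # (log relative abundance for taxa), so the planted indirect effect is
    # carried by the features an analyst can actually see.
    mds = rng.binomial(13, 0.5, size=n).astype(float)
    planted_values: dict[str, np.ndarray] = {}
    chain_feature_ids: dict[str, list[str]] = {}
    for chain in config.mediation_chains:
        if chain.source == "MDS":
            src = mds - _MDS_CENTER
        else:
            src = planted_values[chain.source] - planted_values[chain.source].mean()
        contribution = np.zeros(n)
        ids = []
        for m in chain.mediators:
            fid = f"{m.block}:{m.name}"
            value = m.a * src + rng.standard_normal(n)
            planted_values[fid] = value
            gauss[fid] = value
            contribution += m.b * (value - value.mean())
            ids.append(fid)
        chain_feature_ids[chain.chain_id] = ids
        if chain.sink != "FCP_week8":
            if chain.sink not in planted_values:
                raise ValueError(f"chain {chain.chain_id!r}: unknown sink {chain.sink!r}")
            if chain.sink.startswith("taxon:"):
                raise ValueError(f"chain {chain.chain_id!r}: taxa cannot be "
                                 "chain sinks (compositional closure)")
            planted_values[chain.sink] = planted_values[chain.sink] + contribution
            gauss[chain.sink] = planted_values[chain.sink]

    # assemble observed feature matrix block by block
    data = gauss.copy()
    taxa_cols = blocks.index[blocks == "taxon"]
    signature: dict[int, list[str]] = {c: [] for c in range(config.n_enterotypes)}
    mediator_taxa = {fid for ids in chain_feature_ids.values() for fid in ids
                     if fid.startswith("taxon:")}
    noise_taxa = [c for c in taxa_cols
                  if module_truth[c] == "none" and c not in mediator_taxa]
    need = config.n_enterotypes * config.signature_taxa_per_cluster
    if len(noise_taxa) < need:
        raise ValueError("not enough unstructured taxa for enterotype signatures")
    for c_idx in range(config.n_enterotypes):
        start = c_idx * config.signature_taxa_per_cluster
        signature[c_idx] = noise_taxa[start:start + config.signature_taxa_per_cluster]
        # signature taxa co-vary (shared cluster shift): real planted
        # co-abundance structure, so the truth labels must say so
        module_truth.loc[signature[c_idx]] = f"cag_{c_idx}"
    for chain_id, ids in chain_feature_ids.items():
        # chain mediators share the exposure-driven component
        module_truth.loc[ids] = f"chain_{chain_id}"

    if len(taxa_cols):
        g_taxa = data[taxa_cols].to_numpy().copy()
        present = rng.random(g_taxa.shape) >= config.taxa_sparsity
        col_of = {c: i for i, c in enumerate(taxa_cols)}
        for c_idx, cols in signature.items():
            own = enterotype == c_idx
            for c in cols:
                j = col_of[c]
                g_taxa[own, j] += config.signature_shift
                present[own, j] = True
                present[~own, j] = rng.random((~own).sum()) < config.signature_other_presence
        for fid in mediator_taxa:
            j = col_of[fid]
            g_taxa[:, j] += 1.0  # keep guild taxa common
            present[:, j] = True
        weights = np.where(present, np.exp(g_taxa), 0.0)
        rowsum = weights.sum(axis=1, keepdims=True)
        if (rowsum == 0).any():
            raise ValueError("a sample lost every taxon; lower taxa_sparsity")
        data[taxa_cols] = weights / rowsum

    for block in _POSITIVE_BLOCKS:
        cols = blocks.index[blocks == block]
        data[cols] = np.exp(data[cols].to_numpy())

    # planted chain contributions to week-8 FCP, taken from the observed
    # mediation-scale feature values (matching cascade.mediation_view)
    def _mediation_scale(fid: str) -> np.ndarray:
        if fid.startswith("taxon:"):
            return np.log(data[fid].to_numpy(dtype=float) + 1e-6)
        if fid.split(":", 1)[0] in _POSITIVE_BLOCKS:
            return np.log(data[fid].to_numpy(dtype=float))
        return data[fid].to_numpy(dtype=float)

    fcp_chain_term = np.zeros(n)
    for chain in config.mediation_chains:
        if chain.sink != "FCP_week8":
            continue
        for m in chain.mediators:
            obs = _mediation_scale(f"{m.block}:{m.name}")
            fcp_chain_term += m.b * (obs - obs.mean())

    # traits: baseline FCP per trajectory (+ enterotype elevation), week-8
    # FCP from the log1p-scale structural model
    high_cluster = 0
    log_base = np.where(trajectory == "increase",
                        config.fcp_baseline_mu_increase,
                        config.fcp_baseline_mu_decrease).astype(float)
    log_base = log_base + config.fcp_baseline_sd * rng.standard_normal(n)
    log_base[enterotype == high_cluster] += config.fcp_cluster_shift
    fcp_baseline = np.expm1(np.clip(log_base, 0.0, None))

    mu_w8 = np.where(trajectory == "increase",
                     config.fcp_week8_mu_decrease + config.trajectory_effect,
                     config.fcp_week8_mu_decrease).astype(float)
    mean_w8 = mu_w8 + config.direct_effect * (mds - _MDS_CENTER) + fcp_chain_term
    log_w8 = mean_w8 + config.fcp_noise_sd * rng.standard_normal(n)
    fcp_week8 = np.expm1(np.clip(log_w8, 0.0, None))

    # enforce trajectory consistency by repairing the *baseline* of any
    # sample whose draw crosses its week-8 value: baseline is exogenous to
    # the planted mediation chains, so the X -> M -> Y linear model is
    # untouched (redrawing week-8 noise instead would censor the outcome
    # selectively and bias the planted indirect effects)
    for i in range(n):
        want_up = trajectory[i] == "increase"
        consistent = (fcp_week8[i] > fcp_baseline[i]) == want_up and \
            fcp_week8[i] != fcp_baseline[i]
        if not consistent:
            if want_up:
                if fcp_week8[i] <= 0:  # already censored by the zero floor
                    fcp_week8[i] = 0.5
                fcp_baseline[i] = fcp_week8[i] * rng.uniform(0.3, 0.9)
            else:
                fcp_baseline[i] = max(fcp_week8[i], 1.0) * rng.uniform(1.5, 4.0)

    traits = pd.DataFrame(
        {
            "MDS": mds.astype(int),
            "FCP_baseline": fcp_baseline,
            "FCP_week8": fcp_week8,
            "trajectory": trajectory,
            "med_corticosteroid": rng.random(n) < 0.25,
            "med_5asa": rng.random(n) < 0.6,
            "med_biologic": rng.random(n) < 0.3,
        },
        index=samples,
    )

    truth = {
        "module_labels": module_truth,
        "factors": pd.DataFrame(factors, index=samples,
                                columns=[f"module_{i + 1}" for i in range(k)]),
        "acme": {c.chain_id: c.acme for c in config.mediation_chains},
        "chain_features": chain_feature_ids,
        "chain_latent": pd.DataFrame(planted_values, index=samples),
        "enterotype": pd.Series(enterotype, index=samples, name="enterotype"),
        "signature_taxa": signature,
        "high_fcp_cluster": high_cluster,
    }
    features = OmicsFeatureTable(data, blocks)
    trait_table = TraitTable(
        traits, medication_cols=("med_corticosteroid", "med_5asa", "med_biologic")
    )
    return SyntheticCohort(features=features, traits=trait_table, truth=truth,
                           config=config)
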