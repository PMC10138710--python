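"""Weighted co-abundance network construction and module detection.

The workflow mirrors weighted correlation network analysis (WGCNA) adapted
to mixed multi-omics features: Spearman correlation over rank-transformed
profiles, soft-thresholded adjacency, scale-free topology scan, hierarchical
module detection, module eigengenes, signed module membership (kME),
eigengene-similarity merging and a final kME refinement that moves weak
members to an explicit "unclassified" pool.

Organised statsmodels-style: :class:`CoAbundanceNetwork` is the model,
``fit()`` returns a :class:`ModuleSolution` results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats as sps

from .datatypes import OmicsFeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "CoAbundanceNetwork",
    "ModuleSolution",
    "correlation_matrix",
    "adjacency",
    "soft_threshold_scan",
    "detect_modules",
    "module_eigengene",
    "signed_kme",
    "merge_modules",
    "complete_membership",
    "refine_membership",
    "MODULE_COLORS",
]

# WGCNA-style color palette, assigned by descending module size.  "grey" is
# deliberately usable as an ordinary module color: unassigned features carry
# the distinct label "unclassified" and are never conflated with a module.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

UNCLASSIFIED = "unclassified"


@dataclass
class NetworkConfig:
    """Tunable parameters of the network stage.

    Defaults follow the emulated analysis: soft-threshold scan over powers
    1..20 with chosen power 10, minimum module size 11, eigengene
    dissimilarity merge threshold 0.25 and module-membership floor 0.30.
    (The source analysis quotes both 10 and 11 for the chosen power; 10 is
    the methods-section value and is logged when used.)
    """

    power_range: Sequence[int] = tuple(range(1, 21))
    power: int = 10
    min_module_size: int = 11
    me_diss_threshold: float = 0.25
    kme_min: float = 0.30
    network_sign: str = "unsigned"  # or "signed"
    linkage: str = "average"  # or "complete", "ward"
    clustering_input: str = "standardized_profiles"  # or "tom_dissimilarity"
    cut_method: str = "dynamic"  # or "fixed_height"
    cut_height: float | None = None  # required for fixed_height
    kme_join: float = 0.40  # membership floor for re-admitting unassigned features

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if any(p < 1 for p in self.power_range):
            raise ValueError("powers must be >= 1")
        if not (0 < self.me_diss_threshold < 1):
            raise ValueError("me_diss_threshold must lie in (0, 1)")
        if not (0 < self.kme_min < 1):
            raise ValueError("kme_min must lie in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValueError("network_sign must be 'unsigned' or 'signed'")
        if self.clustering_input not in ("standardized_profiles", "tom_dissimilarity"):
            raise ValueError("unknown clustering_input")
        if self.cut_method not in ("dynamic", "fixed_height"):
            raise ValueError("unknown cut_method")


# ---------------------------------------------------------------------------
# correlation / adjacency / soft threshold


def correlation_matrix(table, method: str = "spearman") -> pd.DataFrame:
    """Feature-by-feature correlation matrix (Spearman by default).

    Ties get mid-ranks.  Constant features are rejected by name because
    their correlation is undefined.
    """
    df = table.data if isinstance(table, OmicsFeatureTable) else table
    if df.shape[0] < 3:
        raise ValueError("need at least three samples")
    sd = df.std(axis=0, ddof=0)
    constant = list(sd.index[sd == 0])
    if constant:
        raise ValueError(f"constant features: {constant[:5]}")
    if method == "spearman":
        ranked = df.rank(axis=0, method="average")
        rho = np.corrcoef(ranked.to_numpy(), rowvar=False)
    elif method == "pearson":
        rho = np.corrcoef(df.to_numpy(), rowvar=False)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def adjacency(rho: pd.DataFrame, beta: int, network_sign: str = "unsigned") -> pd.DataFrame:
    """Soft-thresholded adjacency: |rho|^beta (unsigned) or ((1+rho)/2)^beta."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r = np.asarray(rho, dtype=float)
    if network_sign == "unsigned":
        a = np.abs(r) ** beta
    elif network_sign == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ValueError("network_sign must be 'unsigned' or 'signed'")
    return pd.DataFrame(a, index=rho.index, columns=rho.columns)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) ~ log10 k fit over equal-width degree bins.

    Connectivities are split into ``n_bins`` equal-width intervals; p(k) is
    the fraction of features per non-empty bin and k-bar the bin's mean
    connectivity.  Returns NaN when the connectivities are degenerate (all
    equal) or fewer than three usable bins remain.
    """
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]):
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        members = k[which == b]
        if len(members) == 0:
            continue
        mean_k.append(members.mean())
        freq.append(len(members) / len(k))
    mean_k, freq = np.asarray(mean_k), np.asarray(freq)
    ok = mean_k > 0
    if ok.sum() < 3:
        return float("nan")
    x, y = np.log10(mean_k[ok]), np.log10(freq[ok])
    if np.allclose(x, x[0]):
        return float("nan")
    slope, intercept, r, _, _ = sps.linregress(x, y)
    return float(r**2)


def soft_threshold_scan(rho: pd.DataFrame, power_range: Sequence[int] | None = None,
                        network_sign: str = "unsigned") -> pd.DataFrame:
    """Scale-free topology fit and mean connectivity per candidate power.

    Connectivity of a feature is its adjacency row sum (self-edge
    excluded).  Features are split into 10 equal-width connectivity bins
    and R^2 is taken from the log10-log10 regression of bin frequency on
    bin mean connectivity.
    """
    if rho.shape[0] < 20:
        raise ValueError("need at least 20 features for a meaningful degree histogram")
    power_range = tuple(power_range) if power_range is not None else tuple(range(1, 21))
    rows = []
    for beta in power_range:
        a = adjacency(rho, beta, network_sign).to_numpy().copy()
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append({"power": beta, "scale_free_r2": _scale_free_r2(k),
                     "mean_connectivity": float(k.mean()),
                     "median_connectivity": float(np.median(k)),
                     "max_connectivity": float(k.max())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# module detection


def _tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap dissimilarity 1 - TOM from an adjacency matrix."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return 1.0 - tom


def _cluster_tree(df: pd.DataFrame, rho: pd.DataFrame, config: NetworkConfig) -> np.ndarray:
    if config.clustering_input == "standardized_profiles":
        z = (df - df.mean(axis=0)) / df.std(axis=0, ddof=0)
        dist = ssd.pdist(z.to_numpy().T, metric="euclidean")
    else:
        adj = adjacency(rho, config.power, config.network_sign).to_numpy()
        dist = ssd.squareform(_tom_dissimilarity(adj), checks=False)
    return sch.linkage(dist, method=config.linkage)


def _mean_abs_offdiag(rho: np.ndarray, idx: np.ndarray) -> float:
    sub = np.abs(rho[np.ix_(idx, idx)])
    m = len(idx)
    return float((sub.sum() - m) / (m * (m - 1)))


def detect_modules(table, rho: pd.DataFrame, config: NetworkConfig | None = None) -> pd.Series:
    """Initial module labels from hierarchical clustering of the features.

    The dendrogram (average linkage on Euclidean distances between
    standardized feature profiles by default; topological-overlap
    dissimilarity as an alternative) is cut at a data-chosen height: among
    all merge heights, the one maximising the number of *qualifying*
    clusters — size >= ``min_module_size`` and mean within-cluster |rho|
    above a null-scale cohesion floor 2/sqrt(n_samples) — with ties broken
    toward the higher height, keeping each qualifying cluster maximal.
    Features outside qualifying clusters are
    labelled 0 (unassigned pool).  Returned labels are positive integers
    ordered by descending module size.
    """
    config = config or NetworkConfig()
    df = table.data if isinstance(table, OmicsFeatureTable) else table
    n_feat = df.shape[1]
    if n_feat < config.min_module_size:
        return pd.Series(0, index=df.columns, name="module")
    rho_arr = np.asarray(rho, dtype=float)
    tree = _cluster_tree(df, rho, config)
    cohesion_floor = 2.0 / np.sqrt(df.shape[0])

    def qualifying(labels: np.ndarray) -> list[np.ndarray]:
        out = []
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if len(idx) >= config.min_module_size and \
                    _mean_abs_offdiag(rho_arr, idx) >= cohesion_floor:
                out.append(idx)
        return out

    if config.cut_method == "fixed_height":
        if config.cut_height is None:
            raise ValueError("cut_height required for fixed_height cutting")
        best_labels = sch.fcluster(tree, t=config.cut_height, criterion="distance")
        best_clusters = qualifying(best_labels)
    else:
        heights = np.unique(tree[:, 2])
        # probe between successive merge heights (coarse grid keeps this fast)
        if len(heights) > 120:
            sel = np.linspace(0, len(heights) - 1, 120).astype(int)
            heights = heights[sel]
        best_clusters: list[np.ndarray] = []
        best_key = (-1, -np.inf)
        for h in heights:
            labels = sch.fcluster(tree, t=h + 1e-9, criterion="distance")
            clusters = qualifying(labels)
            if len(clusters) > best_key[0] or \
                    (len(clusters) == best_key[0] and h > best_key[1]):
                best_key = (len(clusters), h)
                best_clusters = clusters
    out = np.zeros(n_feat, dtype=int)
    for rank, idx in enumerate(
            sorted(best_clusters, key=lambda i: (-len(i), i[0])), start=1):
        out[idx] = rank
    logger.info("detected %d initial modules (%d features unassigned)",
                len(best_clusters), int((out == 0).sum()))
    return pd.Series(out, index=df.columns, name="module")


# ---------------------------------------------------------------------------
# eigengenes / kME


def module_eigengene(table, features: Sequence[str]) -> pd.Series:
    """First principal component of the z-scored module sub-matrix.

    Scaled to unit variance and sign-oriented so that its correlation with
    the module's mean standardized profile is non-negative.
    """
    df = table.data if isinstance(table, OmicsFeatureTable) else table
    features = list(features)
    if not features:
        raise ValueError("empty module")
    sub = df[features]
    if sub.shape[0] < 2:
        raise ValueError("need at least two samples for an eigengene")
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=0)
    u, s, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
    scores = u[:, 0] * s[0]
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate module: zero-variance eigengene")
    scores = scores / sd
    mean_profile = z.mean(axis=1).to_numpy()
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    return pd.Series(scores, index=df.index, name="ME")


def signed_kme(table, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Signed module membership: Pearson r of each feature with each ME."""
    df = table.data if isinstance(table, OmicsFeatureTable) else table
    x = df.to_numpy(dtype=float)
    e = eigengenes.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    ec = e - e.mean(axis=0)
    xs = xc.std(axis=0, ddof=0)
    es = ec.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        kme = (xc.T @ ec) / x.shape[0] / np.outer(xs, es)
    kme = np.clip(kme, -1.0, 1.0)
    return pd.DataFrame(kme, index=df.columns, columns=eigengenes.columns)


def _eigengene_frame(df: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    mes = {}
    for lab in sorted(set(labels) - {0}):
        feats = labels.index[labels == lab]
        mes[lab] = module_eigengene(df, feats)
    return pd.DataFrame(mes, index=df.index)


def merge_modules(table, labels: pd.Series, me_diss_threshold: float = 0.25
                  ) -> tuple[pd.Series, list[dict]]:
    """Merge modules whose eigengene dissimilarity 1 - cor(ME_i, ME_j) falls
    below the threshold; iterate (recomputing eigengenes) to a fixed point.
    """
    df = table.data if isinstance(table, OmicsFeatureTable) else table
    labels = labels.copy()
    history: list[dict] = []
    for _ in range(100):
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        mes = _eigengene_frame(df, labels)
        cor = np.corrcoef(mes.to_numpy(), rowvar=False)
        diss = 1.0 - cor
        np.fill_diagonal(diss, 0.0)
        tree = sch.linkage(ssd.squareform(np.clip(diss, 0, None), checks=False),
                           method="average")
        groups = sch.fcluster(tree, t=me_diss_threshold, criterion="distance")
        if len(set(groups)) == len(mods):
            break
        mapping = {}
        for g in np.unique(groups):
            members = [mods[i] for i in np.flatnonzero(groups == g)]
            target = members[0]
            for m in members:
                mapping[m] = target
            if len(members) > 1:
                history.append({"merged": members, "into": target})
        labels = labels.map(lambda v: mapping.get(v, v))
    return labels, history


def complete_membership(kme: pd.DataFrame, labels: pd.Series, kme_join: float = 0.50
                        ) -> pd.Series:
    """Re-admit unassigned features with strong module membership.

    The completion stage of the hybrid cut: the variable-height cut keeps
    tight cluster cores, so peripheral members can be stranded in the
    unassigned pool; a feature whose best signed kME is at least
    ``kme_join`` joins that module.  The floor is deliberately stricter
    than the retention floor so that chance-level noise never joins.
    """
    if kme.shape[1] == 0:
        return labels.copy()
    out = labels.copy()
    pool = labels.index[labels == 0]
    best = kme.loc[pool].idxmax(axis=1)
    best_val = kme.loc[pool].max(axis=1)
    for fid in pool:
        if best_val[fid] >= kme_join:
            out[fid] = best[fid]
    return out


def refine_membership(kme: pd.DataFrame, labels: pd.Series, kme_min: float = 0.30
                      ) -> pd.Series:
    """Move features whose own-module kME is below the floor to the pool.

    The threshold is inclusive: kME exactly at the floor is retained.
    """
    out = labels.copy()
    for fid, lab in labels.items():
        if lab == 0:
            continue
        if kme.loc[fid, lab] < kme_min:
            out[fid] = 0
    return out


# ---------------------------------------------------------------------------
# model / results


@dataclass
class ModuleSolution:
    """Results of a fitted co-abundance network.

    Attributes
    ----------
    labels
        Module color per feature; unassigned features carry "unclassified".
    eigengenes
        Samples x modules eigengene matrix (unit variance columns).
    kme
        Features x modules signed membership matrix.
    sft
        Soft-threshold scan table (power, scale-free R^2, connectivity).
    merge_history
        Record of eigengene-similarity merges.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    kme: pd.DataFrame
    sft: pd.DataFrame
    merge_history: list
    config: NetworkConfig
    correlation: pd.DataFrame | None = None

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)

    @property
    def unclassified(self) -> pd.Index:
        return self.labels.index[self.labels == UNCLASSIFIED]

    def members(self, color: str) -> pd.Index:
        return self.labels.index[self.labels == color]

    def module_sizes(self) -> pd.Series:
        sizes = self.labels[self.labels != UNCLASSIFIED].value_counts()
        return sizes.sort_values(ascending=False)

    def own_kme(self) -> pd.Series:
        """Each classified feature's membership in its own module."""
        vals = {}
        for fid, lab in self.labels.items():
            if lab != UNCLASSIFIED:
                vals[fid] = float(self.kme.loc[fid, lab])
        return pd.Series(vals, name="own_kme")

    def summary(self) -> str:
        sizes = self.module_sizes()
        lines = ["Co-abundance network module solution",
                 "=" * 40,
                 f"features: {len(self.labels)}  classified: "
                 f"{int((self.labels != UNCLASSIFIED).sum())}  unclassified: "
                 f"{len(self.unclassified)}",
                 f"modules: {len(sizes)}  power: {self.config.power} "
                 f"({self.config.network_sign})",
                 "", "module sizes:"]
        for color, size in sizes.items():
            lines.append(f"  {color:<14s} {size:>4d}")
        if not self.sft.empty:
            row = self.sft[self.sft["power"] == self.config.power]
            if len(row):
                lines.append("")
                lines.append(
                    f"scale-free fit at power {self.config.power}: "
                    f"R^2 = {row['scale_free_r2'].iloc[0]:.3f}, "
                    f"mean k = {row['mean_connectivity'].iloc[0]:.2f}")
        return "\n".join(lines)

    def to_frame(self, blocks: pd.Series | None = None) -> pd.DataFrame:
        """Per-feature table: block, module, own-module kME."""
        out = pd.DataFrame({"module": self.labels})
        if blocks is not None:
            out.insert(0, "block", blocks.reindex(out.index))
        own = self.own_kme()
        out["own_kme"] = own.reindex(out.index)
        return out


class CoAbundanceNetwork:
    """Weighted co-abundance network model over an omics feature table.

    Parameters
    ----------
    table
        :class:`OmicsFeatureTable` or plain samples x features DataFrame.
    config
        :class:`NetworkConfig`; defaults reproduce the reference settings.
    rank_transform
        Rank-transform features before anything else (the Spearman
        convention); the correlation step ranks internally anyway, but the
        eigengene/kME computations then also operate on ranks.
    """

    def __init__(self, table, config: NetworkConfig | None = None,
                 rank_transform: bool = True):
        self.table = table
        self.config = config or NetworkConfig()
        df = table.data if isinstance(table, OmicsFeatureTable) else table
        self.blocks = table.blocks if isinstance(table, OmicsFeatureTable) else None
        self._df = df.rank(axis=0, method="average") if rank_transform else df

    def fit(self, scan_powers: bool = True) -> ModuleSolution:
        cfg = self.config
        logger.info("network: power=%d sign=%s min_module_size=%d "
                    "me_diss=%.2f kme_min=%.2f", cfg.power, cfg.network_sign,
                    cfg.min_module_size, cfg.me_diss_threshold, cfg.kme_min)
        rho = correlation_matrix(self._df, method="pearson")  # ranks -> Spearman
        sft = (soft_threshold_scan(rho, cfg.power_range, cfg.network_sign)
               if scan_powers and rho.shape[0] >= 20 else pd.DataFrame())
        labels = detect_modules(self._df, rho, cfg)
        labels, history = merge_modules(self._df, labels, cfg.me_diss_threshold)
        mes = _eigengene_frame(self._df, labels)
        kme = signed_kme(self._df, mes)
        if not mes.empty:
            for _ in range(2):  # completion sharpens eigengenes; iterate once more
                labels = complete_membership(kme, labels, cfg.kme_join)
                mes = _eigengene_frame(self._df, labels)
                kme = signed_kme(self._df, mes)
            labels = refine_membership(kme, labels, cfg.kme_min)
            mes = _eigengene_frame(self._df, labels)
            kme = signed_kme(self._df, mes)

        # color labels by descending size
        sizes = labels[labels != 0].value_counts().sort_values(ascending=False)
        palette = {}
        for i, lab in enumerate(sizes.index):
            palette[lab] = (MODULE_COLORS[i] if i < len(MODULE_COLORS)
                            else f"module{i + 1}")
        colors = labels.map(lambda v: palette.get(v, UNCLASSIFIED))
        mes = mes.rename(columns=palette)
        kme = kme.rename(columns=palette)
        order = [palette[lab] for lab in sizes.index]
        mes = mes[order] if len(order) else mes
        kme = kme[order] if len(order) else kme
        return ModuleSolution(labels=colors, eigengenes=mes, kme=kme, sft=sft,
                              merge_history=history, config=cfg, correlation=rho)
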