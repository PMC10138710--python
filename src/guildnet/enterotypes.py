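"""Enterotyping and risk co-abundant groups (CAGs).

Baseline microbiome samples are partitioned by PAM (partitioning around
medoids) on a community distance — Jensen-Shannon by convention in the
enterotyping literature, Bray-Curtis by option.  The number of clusters is
chosen by average silhouette width over a candidate range.  Clusters are
labelled high/low risk by their baseline fecal-calprotectin medians;
cluster-dominant taxa are those present in at least 10% of subjects with a
Kruskal-Wallis FDR <= 0.1 across clusters; module enrichment for risk-CAG
taxa uses a one-sided hypergeometric test with BH correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from sklearn.metrics import silhouette_score

from .network import ModuleSolution, UNCLASSIFIED
from .stats import DistanceMatrix, bh_fdr, bray_curtis, jensen_shannon, kruskal_wallis

logger = logging.getLogger(__name__)

__all__ = ["CagPartition", "Enterotyper", "pam", "dominant_taxa",
           "classify_risk", "module_cag_enrichment"]


# ---------------------------------------------------------------------------
# PAM


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD phase: medoids chosen to minimise total distance."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def pam(d: DistanceMatrix | np.ndarray, k: int, seed: int | None = None,
        max_iter: int = 100) -> np.ndarray:
    """Partitioning around medoids: BUILD + iterated SWAP to convergence.

    Deterministic for a given input (greedy build, best-improvement swaps,
    index-order tie-breaks); ``seed`` is accepted for interface symmetry
    with the stochastic stages but does not influence the result.
    """
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    n = dm.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    if k < 1:
        raise ValueError("k must be at least 1")
    medoids = _pam_build(dm, k)
    for _ in range(max_iter):
        best_delta, best_swap = -1e-12, None
        cost = dm[:, medoids].min(axis=1).sum()
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                delta = cost - dm[:, cand].min(axis=1).sum()
                if delta > best_delta + 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    medoids = sorted(medoids)
    return np.argmin(dm[:, medoids], axis=1)


# ---------------------------------------------------------------------------
# model / results


@dataclass
class CagPartition:
    """Enterotype partition with risk labels and dominant-taxa statistics."""

    assignments: pd.Series  # sample -> cluster id (0-based)
    k: int
    distance: str
    silhouette: float | None
    risk: dict = field(default_factory=dict)  # cluster -> high/low/neutral
    dominant: pd.DataFrame | None = None
    fcp_kw: tuple[float, float] | None = None  # (H, p) of FCP across clusters
    silhouette_by_k: dict = field(default_factory=dict)

    def cluster_samples(self, cluster: int) -> pd.Index:
        return self.assignments.index[self.assignments == cluster]

    def risk_taxa(self, risk: str) -> set[str]:
        """Dominant taxa of all clusters carrying the given risk label."""
        if self.dominant is None:
            return set()
        clusters = [c for c, r in self.risk.items() if r == risk]
        return set(self.dominant.loc[self.dominant["cluster"].isin(clusters), "taxon"])

    def summary(self) -> str:
        lines = ["Enterotype partition", "=" * 40,
                 f"k = {self.k} ({self.distance} distance), "
                 f"avg silhouette = "
                 f"{'n/a' if self.silhouette is None else format(self.silhouette, '.3f')}"]
        counts = self.assignments.value_counts().sort_index()
        for c, cnt in counts.items():
            risk = self.risk.get(c, "?")
            nd = 0 if self.dominant is None else int((self.dominant["cluster"] == c).sum())
            lines.append(f"  cluster {c}: n={cnt:<3d} risk={risk:<8s} dominant taxa={nd}")
        if self.fcp_kw is not None:
            lines.append(f"baseline FCP Kruskal-Wallis: H={self.fcp_kw[0]:.2f} "
                         f"p={self.fcp_kw[1]:.3g}")
        return "\n".join(lines)


class Enterotyper:
    """PAM enterotyping model over a baseline relative-abundance table.

    Parameters
    ----------
    taxa
        Samples x taxa relative abundances (rows non-negative).
    k
        Cluster count, or an iterable of candidates (default 2..6) from
        which the silhouette-maximising k is chosen.
    distance
        "jsd" (Jensen-Shannon, default) or "braycurtis".
    """

    def __init__(self, taxa: pd.DataFrame, k=None, distance: str = "jsd",
                 seed: int | None = None):
        if (taxa.to_numpy() < 0).any():
            raise ValueError("relative abundances must be non-negative")
        self.taxa = taxa
        self.k = k
        self.distance = distance
        self.seed = seed

    def _distance_matrix(self) -> DistanceMatrix:
        if self.distance == "jsd":
            return jensen_shannon(self.taxa)
        if self.distance == "braycurtis":
            return bray_curtis(self.taxa)
        raise ValueError(f"unknown distance {self.distance!r}")

    def fit(self) -> CagPartition:
        d = self._distance_matrix()
        n = d.n
        if isinstance(self.k, int):
            candidates = [self.k]
        elif self.k is None:
            candidates = [k for k in range(2, 7) if k < n]
        else:
            candidates = [k for k in self.k if k < n]
        if not candidates:
            raise ValueError("no feasible cluster counts")
        best = None
        sil_by_k = {}
        for k in candidates:
            labels = pam(d, k, seed=self.seed)
            if k == 1 or len(set(labels)) < 2:
                sil = None
            else:
                sil = float(silhouette_score(d.values, labels, metric="precomputed"))
            sil_by_k[k] = sil
            key = -np.inf if sil is None else sil
            if best is None or key > best[0]:
                best = (key, k, labels, sil)
        _, k, labels, sil = best
        logger.info("enterotype: chose k=%d (silhouettes %s)", k,
                    {kk: None if s is None else round(s, 3) for kk, s in sil_by_k.items()})
        return CagPartition(
            assignments=pd.Series(labels, index=self.taxa.index, name="cluster"),
            k=k, distance=self.distance, silhouette=sil, silhouette_by_k=sil_by_k)


def enterotype(taxa: pd.DataFrame, k=None, distance: str = "jsd",
               seed: int | None = None) -> CagPartition:
    """Functional wrapper around :class:`Enterotyper`."""
    return Enterotyper(taxa, k=k, distance=distance, seed=seed).fit()


# ---------------------------------------------------------------------------
# dominant taxa / risk labels / enrichment


def dominant_taxa(taxa: pd.DataFrame, clusters: pd.Series,
                  prevalence_min: float = 0.10, fdr_max: float = 0.1
                  ) -> pd.DataFrame:
    """Cluster-dominant taxa: prevalence >= 10%, Kruskal-Wallis FDR <= 0.1.

    Prevalence is the fraction of subjects with non-zero abundance.
    Survivors are assigned to the cluster where their median abundance is
    highest.
    """
    clusters = clusters.reindex(taxa.index)
    labs = sorted(clusters.unique())
    if len(labs) < 2:
        raise ValueError("need at least two clusters")
    prevalence = (taxa > 0).mean(axis=0)
    tested = prevalence.index[prevalence >= prevalence_min]
    rows = []
    for col in tested:
        groups = [taxa.loc[clusters == c, col].to_numpy() for c in labs]
        h, p = kruskal_wallis(groups)
        medians = [float(np.median(g)) for g in groups]
        rows.append({"taxon": col, "prevalence": float(prevalence[col]),
                     "kw_h": h, "p": p,
                     "cluster": labs[int(np.argmax(medians))]})
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["taxon", "prevalence", "kw_h", "p", "q", "cluster"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    out = out[out["q"] <= fdr_max].sort_values("q", kind="stable").reset_index(drop=True)
    return out[["taxon", "prevalence", "kw_h", "p", "q", "cluster"]]


def classify_risk(clusters: pd.Series, fcp_baseline: pd.Series
                  ) -> tuple[dict, tuple[float, float]]:
    """Label clusters by baseline FCP: highest median high, lowest low.

    Returns (cluster -> label, (KW H, p)).  Ties in the extreme medians
    leave the tied clusters neutral, with a warning.
    """
    fcp = fcp_baseline.reindex(clusters.index)
    labs = sorted(clusters.unique())
    groups = [fcp[clusters == c].to_numpy() for c in labs]
    kw = kruskal_wallis(groups) if len(labs) >= 2 else (0.0, 1.0)
    medians = np.array([np.median(g) for g in groups])
    risk = {c: "neutral" for c in labs}
    if np.all(medians == medians[0]):
        warnings.warn("identical cluster FCP medians; all clusters neutral")
        return risk, kw
    hi, lo = medians.max(), medians.min()
    hi_idx = [c for c, m in zip(labs, medians) if m == hi]
    lo_idx = [c for c, m in zip(labs, medians) if m == lo]
    if len(hi_idx) == 1:
        risk[hi_idx[0]] = "high"
    else:
        warnings.warn("tied highest FCP medians; tied clusters left neutral")
    if len(lo_idx) == 1:
        risk[lo_idx[0]] = "low"
    else:
        warnings.warn("tied lowest FCP medians; tied clusters left neutral")
    return risk, kw


def module_cag_enrichment(solution: ModuleSolution, risk_taxa: dict,
                          fdr_max: float = 0.1) -> pd.DataFrame:
    """Hypergeometric over-representation of risk-CAG taxa in each module.

    The universe is every classified taxon-block feature; the test is
    one-sided (over-representation), BH-corrected across module x risk-set
    pairs and flagged at q <= ``fdr_max``.
    """
    taxa_labels = solution.labels[solution.labels.index.str.startswith("taxon:")]
    universe = set(taxa_labels.index[taxa_labels != UNCLASSIFIED])
    if not universe:
        raise ValueError("empty taxon universe: no classified taxa")
    rows = []
    for risk, taxa_set in risk_taxa.items():
        marked = set(taxa_set) & universe
        for color in solution.modules:
            members = set(solution.members(color)) & universe
            overlap = len(members & marked)
            # P(X >= overlap) under sampling len(members) from the universe
            p = float(sps.hypergeom.sf(overlap - 1, len(universe), len(marked),
                                       len(members))) if members else 1.0
            rows.append({"module": color, "risk_set": risk,
                         "module_taxa": len(members), "risk_taxa": len(marked),
                         "overlap": overlap, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["enriched"] = out["q"] <= fdr_max
    return out.sort_values("p", kind="stable").reset_index(drop=True)
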