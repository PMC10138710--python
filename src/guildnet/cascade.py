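"""Mediation cascades: inter-module and feature-level mediation networks.

Builds the directed association graph linking the diet score (MDS) to
fecal calprotectin (FCP) through module eigengenes and through screened
individual features: candidate screening at a module-level FDR, mediation
per candidate, multi-step chains and a joint mediator set, all assembled
into an acyclic graph whose edge signs follow the ACME (positive = green,
negative = red in the conventional rendering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import OmicsFeatureTable
from .mediation import MediationResult, Mediation, mediate_chain
from .stats import bh_fdr, spearman

logger = logging.getLogger(__name__)

__all__ = ["CandidateScreen", "MediationGraph", "screen_candidates",
           "module_mediation_network", "feature_mediation_network",
           "mediation_view"]


def mediation_view(table: OmicsFeatureTable, pseudocount: float = 1e-6
                   ) -> pd.DataFrame:
    """Feature matrix on the scale used for linear mediation models.

    Compositional taxa and positive concentration blocks (SCFAs, bile
    acids) are log-transformed; Gaussian-scale blocks pass through.
    """
    df = table.data.copy()
    for block in ("taxon", "scfa", "bile_acid"):
        cols = table.blocks.index[table.blocks == block]
        if len(cols):
            df[cols] = np.log(df[cols].to_numpy(dtype=float) + pseudocount)
    return df


# ---------------------------------------------------------------------------
# candidate screening


@dataclass
class CandidateScreen:
    """Outcome of the per-feature trait screen within one module."""

    admitted: list[str]
    stats: pd.DataFrame  # feature, trait, rho, p, q
    n_screened: int
    mode: str
    q_max: float

    def summary(self) -> str:
        return (f"screened {self.n_screened} features; admitted "
                f"{len(self.admitted)} at FDR <= {self.q_max} ({self.mode})")


def screen_candidates(features: pd.DataFrame, mds: pd.Series, fcp: pd.Series,
                      q_max: float = 0.20, mode: str = "any") -> CandidateScreen:
    """Admit features associated with MDS and/or FCP at a BH FDR <= q_max.

    BH is applied separately within the MDS family and the FCP family;
    ``mode`` is "any" (q <= q_max for at least one trait) or "both".  The
    threshold is inclusive.
    """
    if features.shape[1] == 0:
        raise ValueError("empty module: no features to screen")
    if mode not in ("any", "both"):
        raise ValueError("mode must be 'any' or 'both'")
    traits = {"MDS": pd.to_numeric(mds), "FCP": pd.to_numeric(fcp)}
    frames = []
    for tname, tvals in traits.items():
        rows = []
        for col in features.columns:
            x = features[col]
            if x.nunique() <= 1:
                rows.append({"feature": col, "trait": tname, "rho": np.nan, "p": 1.0})
                continue
            rho, p = spearman(x.to_numpy(), tvals.reindex(x.index).to_numpy())
            rows.append({"feature": col, "trait": tname, "rho": rho, "p": p})
        fam = pd.DataFrame(rows)
        fam["q"] = bh_fdr(fam["p"].to_numpy())
        frames.append(fam)
    stats = pd.concat(frames, ignore_index=True)
    hit = stats[stats["q"] <= q_max].groupby("feature")["trait"].nunique()
    need = 1 if mode == "any" else 2
    admitted = sorted(hit.index[hit >= need])
    logger.info("candidate screen: %d/%d features admitted (FDR<=%.2f, %s)",
                len(admitted), features.shape[1], q_max, mode)
    return CandidateScreen(admitted=admitted, stats=stats,
                           n_screened=features.shape[1], mode=mode, q_max=q_max)


# ---------------------------------------------------------------------------
# mediation graph


@dataclass
class MediationGraph:
    """Directed acyclic graph of mediated and direct associations."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    results: list = field(default_factory=list)

    def add_node(self, name: str, kind: str, block: str | None = None,
                 provenance: str | None = None) -> None:
        self.graph.add_node(name, kind=kind, block=block, provenance=provenance)

    def add_mediation(self, result: MediationResult, step: int = 0,
                      provenance: str | None = None) -> bool:
        """Add source -> mediator(s) -> sink edges for a significant result.

        Returns False (and adds nothing) if the result's CI includes zero
        or the edges would create a cycle.
        """
        if not result.significant:
            return False
        sign = 1 if result.acme > 0 else -1
        edges = []
        for m in result.mediators:
            edges.append((result.exposure, m))
            edges.append((m, result.outcome))
        probe = self.graph.copy()
        probe.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(probe):
            logger.warning("skipping mediation %s -> %s -> %s: would create a cycle",
                           result.exposure, result.mediators, result.outcome)
            return False
        for u, v in edges:
            self.graph.add_edge(u, v, sign=sign, acme=result.acme, p=result.p,
                                step=step, kind="mediation",
                                provenance=provenance)
        self.results.append(result)
        return True

    def add_direct(self, source: str, target: str, rho: float, p: float,
                   step: int = 0) -> bool:
        probe = self.graph.copy()
        probe.add_edge(source, target)
        if not nx.is_directed_acyclic_graph(probe):
            return False
        self.graph.add_edge(source, target, sign=1 if rho > 0 else -1,
                            rho=rho, p=p, step=step, kind="direct")
        return True

    def to_edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, attrs in self.graph.edges(data=True):
            rows.append({"source": u, "target": v, **attrs})
        cols = ["source", "target", "kind", "sign", "acme", "rho", "p", "step"]
        out = pd.DataFrame(rows)
        for c in cols:
            if c not in out.columns:
                out[c] = np.nan
        return out[cols] if len(out) else pd.DataFrame(columns=cols)

    def write_graphml(self, path) -> None:
        def clean(attrs: dict) -> None:
            for k, v in list(attrs.items()):
                if v is None:
                    attrs[k] = ""
                elif isinstance(v, (tuple, list)):
                    attrs[k] = ",".join(str(x) for x in v)

        g = self.graph.copy()
        clean(g.graph)
        for _, _, attrs in g.edges(data=True):
            clean(attrs)
        for _, attrs in g.nodes(data=True):
            clean(attrs)
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# network builders


def _marginal_p(x: pd.Series, y: pd.Series) -> tuple[float, float]:
    return spearman(x.to_numpy(), y.to_numpy())


def module_mediation_network(eigengenes: pd.DataFrame, mds: pd.Series,
                             fcp: pd.Series, n_sims: int = 1000,
                             seed: int | None = None,
                             prefilter_p: float = 0.10,
                             fcp_log1p: bool = True) -> MediationGraph:
    """Inter-module mediation graph.

    Candidate (source, sink) pairs are the MDS -> FCP trait pair plus every
    ordered module pair whose marginal Spearman association has p below
    ``prefilter_p``; every other module is tried as mediator and edges with
    an ACME interval excluding zero are retained.
    """
    if eigengenes.shape[1] < 1:
        raise ValueError("need at least one module eigengene")
    fcp_use = pd.Series(np.log1p(fcp), index=fcp.index) if fcp_log1p else fcp
    mds = pd.to_numeric(mds)
    graph = MediationGraph()
    graph.add_node("MDS", kind="trait")
    graph.add_node("FCP", kind="trait")
    for col in eigengenes.columns:
        graph.add_node(str(col), kind="eigengene")

    variables: dict[str, pd.Series] = {"MDS": mds, "FCP": fcp_use}
    for col in eigengenes.columns:
        variables[str(col)] = eigengenes[col]

    mods = [str(c) for c in eigengenes.columns]
    pairs = []
    for i, j in [("MDS", "FCP")] + [(i, j) for i in mods for j in mods if i != j]:
        _, p = _marginal_p(variables[i], variables[j])
        if p < prefilter_p:
            pairs.append((i, j))

    rho_direct, p_direct = _marginal_p(variables["MDS"], variables["FCP"])
    if p_direct < 0.05:
        graph.add_direct("MDS", "FCP", rho_direct, p_direct)

    run = 0
    for source, sink in pairs:
        for m in mods:
            if m in (source, sink):
                continue
            med_seed = None if seed is None else seed + run
            run += 1
            res = Mediation(variables[source], variables[m].rename(m),
                            variables[sink],
                            names=(source, sink)).fit(n_sims=n_sims,
                                                      seed=med_seed)
            graph.add_mediation(res, step=0, provenance="module-prefilter")
    return graph


def feature_mediation_network(data: pd.DataFrame, candidates: Sequence[str],
                              mds: pd.Series, fcp: pd.Series,
                              chains: Sequence[Sequence] | None = None,
                              joint: bool = True, n_sims: int = 1000,
                              seed: int | None = None,
                              fcp_log1p: bool = True,
                              covariates=None) -> MediationGraph:
    """Feature-level mediation graph over a screened candidate set.

    Runs MDS -> feature -> FCP per candidate, optional multi-step chain
    specifications (each step an (x, m, y) name triple over the candidate
    namespace plus MDS/FCP), and a joint model over the full candidate set.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    missing = [c for c in candidates if c not in data.columns]
    if missing:
        raise KeyError(f"candidates absent from data: {missing[:5]}")
    fcp_use = pd.Series(np.log1p(fcp), index=fcp.index) if fcp_log1p else fcp
    mds = pd.to_numeric(mds)
    frame = data[candidates].copy()
    frame["MDS"] = mds
    frame["FCP"] = fcp_use

    graph = MediationGraph()
    graph.add_node("MDS", kind="trait")
    graph.add_node("FCP", kind="trait")
    for c in candidates:
        graph.add_node(c, kind="feature", provenance="screen")

    for i, c in enumerate(candidates):
        med_seed = None if seed is None else seed + i
        res = Mediation(frame["MDS"], frame[[c]], frame["FCP"],
                        covariates=covariates,
                        names=("MDS", "FCP")).fit(n_sims=n_sims, seed=med_seed)
        added = graph.add_mediation(res, step=0, provenance="per-candidate")
        if not added:
            # direct-only features: associated with FCP but no mediation edge
            rho, p = _marginal_p(frame[c], frame["FCP"])
            if p < 0.05:
                graph.add_direct(c, "FCP", rho, p)

    if chains:
        allowed = set(candidates) | {"MDS", "FCP"}
        for spec in chains:
            names = set()
            for x_name, m_name, y_name in spec:
                names.update([x_name, y_name] +
                             ([m_name] if isinstance(m_name, str) else list(m_name)))
            bad = sorted(names - allowed)
            if bad:
                raise ValueError(f"chain references non-candidate features: {bad}")
            results = mediate_chain(frame, spec, covariates=covariates,
                                    n_sims=n_sims, seed=seed)
            for step_idx, res in enumerate(results, start=1):
                graph.add_mediation(res, step=step_idx, provenance="chain")

    if joint and len(candidates) > 1 and len(candidates) < len(frame) / 2:
        res = Mediation(frame["MDS"], frame[candidates], frame["FCP"],
                        covariates=covariates, names=("MDS", "FCP")).fit(
            n_sims=n_sims, seed=None if seed is None else seed + 10_000)
        graph.results.append(res)
        graph.graph.graph["joint_acme"] = res.acme
        graph.graph.graph["joint_ci"] = res.ci
        graph.graph.graph["joint_p"] = res.p
    return graph
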