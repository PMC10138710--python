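"""Readers, writers, configuration and the end-to-end pipeline driver.

Interchange format is plain TSV: ``features.tsv`` (samples x features) with
a ``blocks.tsv`` sidecar mapping feature id to omics block, and
``traits.tsv`` for the per-sample traits.  ``run_pipeline`` chains the
stages — cohort, network, trait association, enterotyping/CAGs, candidate
screen, mediation cascade — writing each stage's outputs plus a JSON
manifest of content hashes, so a rerun with the same configuration and
seed is verifiable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cascade as cascade_mod
from . import traits as traits_mod
from .datatypes import OmicsFeatureTable, TraitTable
from .enterotypes import Enterotyper, classify_risk, dominant_taxa, module_cag_enrichment
from .network import CoAbundanceNetwork, NetworkConfig
from .simulate import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "read_feature_tables", "write_cohort",
           "read_cohort_dir", "run_pipeline"]

# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def read_feature_tables(paths: dict, block_map: dict) -> OmicsFeatureTable:
    """Read per-block TSV/CSV tables (samples in rows) into one table.

    ``paths`` maps a label to a file path; ``block_map`` maps the same
    label to its block name.  Non-numeric cells are reported by position.
    """
    missing = set(paths) - set(block_map)
    if missing:
        raise ValueError(f"block map missing entries for: {sorted(missing)}")
    frames, labels = [], []
    for key, path in paths.items():
        df = _read_table(Path(path))
        num = df.apply(pd.to_numeric, errors="coerce")
        bad = num.isna() & df.notna()
        if bad.any().any():
            where = [(r, c) for c in bad.columns for r in bad.index[bad[c]]][:5]
            raise ValueError(f"{path}: non-numeric cells at {where}")
        df = num
        block = block_map[key]
        df.columns = [c if str(c).startswith(f"{block}:") else f"{block}:{c}"
                      for c in df.columns]
        frames.append(df)
        labels.extend([block] * df.shape[1])
    data = pd.concat(frames, axis=1, join="inner")
    return OmicsFeatureTable(data, pd.Series(labels, index=data.columns))


def write_cohort(cohort, outdir: Path) -> list[Path]:
    """Write features.tsv, blocks.tsv, traits.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    f = outdir / "features.tsv"
    cohort.features.data.to_csv(f, sep="\t")
    paths.append(f)
    b = outdir / "blocks.tsv"
    cohort.features.blocks.rename("block").to_frame().to_csv(b, sep="\t")
    paths.append(b)
    t = outdir / "traits.tsv"
    cohort.traits.data.to_csv(t, sep="\t")
    paths.append(t)
    truth_path = outdir / "truth.json"
    truth = {
        "module_labels": cohort.truth["module_labels"].to_dict(),
        "acme": cohort.truth["acme"],
        "chain_features": cohort.truth["chain_features"],
        "enterotype": {k: int(v) for k, v in cohort.truth["enterotype"].items()},
        "signature_taxa": {str(k): v for k, v in cohort.truth["signature_taxa"].items()},
        "high_fcp_cluster": cohort.truth["high_fcp_cluster"],
    }
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths.append(truth_path)
    return paths


def read_cohort_dir(directory: Path) -> tuple[OmicsFeatureTable, TraitTable]:
    """Read a features/blocks/traits TSV trio written by :func:`write_cohort`."""
    directory = Path(directory)
    data = _read_table(directory / "features.tsv")
    blocks = _read_table(directory / "blocks.tsv")["block"]
    traits = _read_table(directory / "traits.tsv")
    med = tuple(c for c in traits.columns if c.startswith("med_"))
    for c in med:
        traits[c] = traits[c].astype(str).isin(("True", "true", "1"))
    return OmicsFeatureTable(data, blocks), TraitTable(traits, medication_cols=med)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (see pipeline YAML docs)."""

    outdir: Path = Path("guildnet_out")
    seed: int = 0
    # cohort source: synthetic generator, or a directory of TSVs
    synthetic: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: Path | None = None
    # stage settings
    network: NetworkConfig = field(default_factory=NetworkConfig)
    trait_names: tuple = ("MDS", "FCP_week8")
    cag_k: object = None  # None = silhouette-chosen over 2..6
    cag_distance: str = "jsd"
    cag_prevalence_min: float = 0.10
    cag_fdr_max: float = 0.1
    screen_q_max: float = 0.20
    screen_mode: str = "any"
    screen_module: str = "auto"
    n_sims: int = 1000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        network = NetworkConfig(**raw.pop("network", {}))
        cfg = cls(cohort=cohort, network=network, **raw)
        cfg.outdir = Path(cfg.outdir)
        if cfg.input_dir is not None:
            cfg.input_dir = Path(cfg.input_dir)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the output manifest.

    The manifest maps each output file to its SHA-256 content hash; any
    stage failure aborts with the stage name, leaving prior outputs listed
    and flagged as partial.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}, "partial": False}
    written: list[Path] = []

    def record(stage: str, paths) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            written.append(Path(p))

    stage = "cohort"
    try:
        if config.synthetic:
            cohort = generate_cohort(config.cohort, seed=config.seed)
            record(stage, write_cohort(cohort, out))
            table, trait_table = cohort.features, cohort.traits
        else:
            if config.input_dir is None:
                raise ValueError("input_dir required when synthetic is false")
            table, trait_table = read_cohort_dir(config.input_dir)
            record(stage, [])

        stage = "network"
        model = CoAbundanceNetwork(table, config.network)
        solution = model.fit()
        mod_path = out / "modules.tsv"
        solution.to_frame(table.blocks).to_csv(mod_path, sep="\t")
        me_path = out / "eigengenes.tsv"
        solution.eigengenes.T.to_csv(me_path, sep="\t")
        sft_path = out / "sft.tsv"
        solution.sft.to_csv(sft_path, sep="\t", index=False)
        record(stage, [mod_path, me_path, sft_path])

        stage = "traits"
        trait_df = trait_table.data.assign(
            FCP_week8_log1p=np.log1p(trait_table["FCP_week8"]))
        assoc = traits_mod.associate(solution.eigengenes, trait_df,
                                     list(config.trait_names))
        assoc_path = out / "trait_assoc.tsv"
        assoc.to_csv(assoc_path, sep="\t", index=False)
        record(stage, [assoc_path])

        stage = "cags"
        taxa = table.taxa()
        partition = Enterotyper(taxa, k=config.cag_k,
                                distance=config.cag_distance,
                                seed=config.seed).fit()
        partition.dominant = dominant_taxa(taxa, partition.assignments,
                                           config.cag_prevalence_min,
                                           config.cag_fdr_max)
        partition.risk, partition.fcp_kw = classify_risk(
            partition.assignments, trait_table["FCP_baseline"])
        cag_path = out / "cags.tsv"
        pd.DataFrame({
            "cluster": partition.assignments,
            "risk": partition.assignments.map(partition.risk),
        }).to_csv(cag_path, sep="\t")
        dom_path = out / "dominant_taxa.tsv"
        partition.dominant.to_csv(dom_path, sep="\t", index=False)
        risk_sets = {r: partition.risk_taxa(r) for r in ("high", "low")}
        enr = module_cag_enrichment(solution, risk_sets)
        enr_path = out / "module_enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False)
        record(stage, [cag_path, dom_path, enr_path])

        stage = "screen"
        med_view = cascade_mod.mediation_view(table)
        if config.screen_module == "auto":
            pivot = assoc.pivot_table(index="entity", columns="trait", values="p")
            screen_module = str(pivot.sum(axis=1).idxmin())
        else:
            screen_module = config.screen_module
        members = solution.members(screen_module)
        screen = cascade_mod.screen_candidates(
            med_view[members], trait_table["MDS"], trait_table["FCP_week8"],
            q_max=config.screen_q_max, mode=config.screen_mode)
        screen_path = out / "screen.tsv"
        screen.stats.to_csv(screen_path, sep="\t", index=False)
        record(stage, [screen_path])

        stage = "mediate"
        module_graph = cascade_mod.module_mediation_network(
            solution.eigengenes, trait_table["MDS"], trait_table["FCP_week8"],
            n_sims=config.n_sims, seed=config.seed)
        mg_path = out / "module_mediation_edges.tsv"
        module_graph.to_edge_table().to_csv(mg_path, sep="\t", index=False)
        record(stage, [mg_path])

        stage = "cascade"
        paths = []
        if screen.admitted:
            feature_graph = cascade_mod.feature_mediation_network(
                med_view, screen.admitted, trait_table["MDS"],
                trait_table["FCP_week8"], n_sims=config.n_sims,
                seed=config.seed + 1)
            fg_path = out / "feature_mediation_edges.tsv"
            feature_graph.to_edge_table().to_csv(fg_path, sep="\t", index=False)
            gml_path = out / "mediation_graph.graphml"
            feature_graph.write_graphml(gml_path)
            paths = [fg_path, gml_path]
        record(stage, paths)
    except Exception as exc:
        manifest["partial"] = True
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        for p in written:
            manifest["files"][p.name] = _sha256(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for p in written:
        manifest["files"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
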