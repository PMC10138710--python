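"""Core in-memory containers shared across the pipeline.

Two tables drive every stage: a samples x features matrix whose columns are
annotated with the omics *block* they came from, and a per-sample trait
table carrying the Mediterranean diet score (MDS), fecal calprotectin (FCP)
at the two study time points, the FCP trajectory label and medication flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised feature-block labels.
BLOCK_LABELS = (
    "taxon",
    "serum_metabolite",
    "scfa",
    "bile_acid",
    "diet_total",
    "diet_adjusted",
    "food_group_freq",
)

TRAJECTORY_LABELS = ("increase", "decrease")


@dataclass
class OmicsFeatureTable:
    """Samples x features matrix with a block label per feature.

    Parameters
    ----------
    data
        Real-valued DataFrame, samples in rows, features in columns.
    blocks
        Series mapping every feature id to one of :data:`BLOCK_LABELS`.
    """

    data: pd.DataFrame
    blocks: pd.Series

    def __post_init__(self) -> None:
        self.blocks = pd.Series(self.blocks)
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in feature table")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature ids in feature table")
        missing = self.data.columns.difference(self.blocks.index)
        if len(missing):
            raise ValueError(f"features without a block label: {list(missing)[:5]}")
        self.blocks = self.blocks.reindex(self.data.columns)
        unknown = set(self.blocks.unique()) - set(BLOCK_LABELS)
        if unknown:
            raise ValueError(f"unknown block labels: {sorted(unknown)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def block(self, label: str) -> pd.DataFrame:
        """Sub-table of all features from one block."""
        if label not in BLOCK_LABELS:
            raise ValueError(f"unknown block label {label!r}")
        cols = self.blocks.index[self.blocks == label]
        return self.data[cols]

    def taxa(self) -> pd.DataFrame:
        """Relative-abundance sub-table (the compositional block)."""
        return self.block("taxon")

    def subset_samples(self, sample_ids) -> "OmicsFeatureTable":
        return OmicsFeatureTable(self.data.loc[sample_ids], self.blocks)

    def drop_constant_features(self) -> "OmicsFeatureTable":
        """Drop features with zero variance (they carry no rank information)."""
        sd = self.data.std(axis=0, ddof=0)
        keep = sd > 0
        dropped = list(self.data.columns[~keep])
        if dropped:
            logger.warning("dropping %d constant features: %s%s", len(dropped),
                           dropped[:5], "..." if len(dropped) > 5 else "")
        return OmicsFeatureTable(self.data.loc[:, keep], self.blocks[keep])


@dataclass
class TraitTable:
    """Per-sample traits: MDS, baseline/week-8 FCP, trajectory, medications.

    FCP values are concentrations in mcg/g and must be non-negative; the
    trajectory label must agree with the ordering of the two FCP values.
    """

    data: pd.DataFrame
    medication_cols: tuple = field(default_factory=tuple)

    REQUIRED = ("MDS", "FCP_baseline", "FCP_week8", "trajectory")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"trait table missing required column {col!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in trait table")
        fcp = self.data[["FCP_baseline", "FCP_week8"]]
        if (fcp.to_numpy() < 0).any():
            raise ValueError("FCP values must be non-negative")
        bad = set(self.data["trajectory"].unique()) - set(TRAJECTORY_LABELS)
        if bad:
            raise ValueError(f"unknown trajectory labels: {sorted(bad)}")
        up = self.data["FCP_week8"] > self.data["FCP_baseline"]
        want = np.where(up, "increase", "decrease")
        if (self.data["trajectory"].to_numpy() != want).any():
            raise ValueError("trajectory labels inconsistent with FCP values")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def __getitem__(self, col: str) -> pd.Series:
        return self.data[col]

    def subset_samples(self, sample_ids) -> "TraitTable":
        return TraitTable(self.data.loc[sample_ids], self.medication_cols)
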