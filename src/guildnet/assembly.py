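"""Assemble analysis-ready feature and trait tables.

Covers the pre-network bookkeeping: Mediterranean diet scoring (14-item
screener with the alcohol point removed, hence 13 criteria), per-1000-kcal
nutrient adjustment, fecal-calprotectin trajectory and clinical category
labels, and the column-binding of per-block feature tables into a single
samples x features matrix with block annotations.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from .datatypes import BLOCK_LABELS, OmicsFeatureTable, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "compute_mds",
    "adjust_per_1000kcal",
    "classify_fcp_trajectory",
    "fcp_category",
    "assemble",
    "rank_transform",
    "clr_transform",
    "FcpTieError",
]

N_MDS_ITEMS = 13  # 14-item screener minus the alcohol criterion


class FcpTieError(ValueError):
    """Raised when baseline and week-8 FCP are exactly equal: the cohort
    definition only admits participants whose FCP changed."""


def compute_mds(item_flags: Sequence[bool]) -> int:
    """Mediterranean diet score: the number of satisfied screener criteria.

    Expects exactly 13 booleans (the alcohol item of the 14-item screener
    is excluded, so the score lies in [0, 13]).
    """
    flags = list(item_flags)
    if len(flags) != N_MDS_ITEMS:
        raise ValueError(f"expected {N_MDS_ITEMS} criterion flags, got {len(flags)}")
    return int(sum(bool(f) for f in flags))


def adjust_per_1000kcal(amount: float, energy_kcal: float) -> float:
    """Energy-adjust a daily nutrient amount to a per-1000-kcal basis."""
    if energy_kcal <= 0:
        raise ValueError("energy_kcal must be positive")
    return amount * 1000.0 / energy_kcal


def classify_fcp_trajectory(fcp_baseline: float, fcp_week8: float) -> str:
    """"increase" or "decrease" in FCP between baseline and week 8."""
    if fcp_baseline < 0 or fcp_week8 < 0:
        raise ValueError("FCP values must be non-negative")
    if fcp_week8 > fcp_baseline:
        return "increase"
    if fcp_week8 < fcp_baseline:
        return "decrease"
    raise FcpTieError("FCP unchanged between time points")


def fcp_category(fcp: float) -> str:
    """Clinical FCP band: <100 remission, 100-250 grey zone, >250 active.

    Both boundaries fall in the grey zone (inclusive reading of the
    printed 100-250 interval).
    """
    if fcp < 0:
        raise ValueError("FCP must be non-negative")
    if fcp < 100:
        return "remission"
    if fcp <= 250:
        return "grey_zone"
    return "active"


def rank_transform(df: pd.DataFrame) -> pd.DataFrame:
    """Replace each feature by its within-feature mid-ranks across samples."""
    return df.rank(axis=0, method="average")


def clr_transform(df: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Centered log-ratio transform of a relative-abundance sub-table."""
    x = df.to_numpy(dtype=float) + pseudocount
    logx = np.log(x)
    return pd.DataFrame(logx - logx.mean(axis=1, keepdims=True),
                        index=df.index, columns=df.columns)


def _impute(df: pd.DataFrame, max_missing_frac: float = 0.20) -> pd.DataFrame:
    """Median-impute sparse missingness; drop features missing too often."""
    frac = df.isna().mean(axis=0)
    drop = frac.index[frac > max_missing_frac]
    if len(drop):
        logger.warning("dropping %d features with >%.0f%% missing values",
                       len(drop), 100 * max_missing_frac)
        df = df.drop(columns=drop)
    if df.isna().any().any():
        df = df.fillna(df.median(axis=0))
    return df


def assemble(
    block_tables: Mapping[str, pd.DataFrame],
    traits: pd.DataFrame | TraitTable,
    *,
    max_missing_frac: float = 0.20,
    clr_taxa: bool = False,
    min_shared_samples: int = 3,
) -> tuple[OmicsFeatureTable, TraitTable]:
    """Column-bind per-block tables into one annotated feature matrix.

    Samples are restricted to those present in every block and in the trait
    table with a defined trajectory.  Feature ids are namespaced by their
    block label, so the same name in two blocks cannot collide.  Missing
    values are median-imputed (features with >20% missing are dropped) and
    constant features removed.  The taxa block can optionally be
    centered-log-ratio transformed before binding.
    """
    if not block_tables:
        raise ValueError("no block tables supplied")
    unknown = set(block_tables) - set(BLOCK_LABELS)
    if unknown:
        raise ValueError(f"unknown block labels: {sorted(unknown)}")

    trait_df = traits.data if isinstance(traits, TraitTable) else traits.copy()
    shared = trait_df.index
    for block, df in block_tables.items():
        if not df.index.isin(shared).all():
            dropped = df.index.difference(shared)
            logger.info("block %s: %d samples absent from trait table", block, len(dropped))
        shared = shared.intersection(df.index)
    if "trajectory" in trait_df.columns:
        defined = trait_df.index[trait_df["trajectory"].isin(["increase", "decrease"])]
        shared = shared.intersection(defined)
    if len(shared) < min_shared_samples:
        raise ValueError(f"only {len(shared)} shared samples across blocks "
                         f"(need >= {min_shared_samples})")

    pieces, labels = [], []
    for block in BLOCK_LABELS:
        if block not in block_tables:
            continue
        df = block_tables[block].loc[shared].copy()
        df.columns = [c if str(c).startswith(f"{block}:") else f"{block}:{c}"
                      for c in df.columns]
        df = _impute(df, max_missing_frac)
        if block == "taxon" and clr_taxa:
            df = clr_transform(df)
        pieces.append(df)
        labels.extend([block] * df.shape[1])
    data = pd.concat(pieces, axis=1)
    blocks = pd.Series(labels, index=data.columns)

    table = OmicsFeatureTable(data, blocks).drop_constant_features()

    trait_df = trait_df.loc[shared]
    if "trajectory" not in trait_df.columns:
        trait_df = trait_df.assign(
            trajectory=[classify_fcp_trajectory(b, w) for b, w in
                        zip(trait_df["FCP_baseline"], trait_df["FCP_week8"])])
    med_cols = tuple(c for c in trait_df.columns if c.startswith("med_"))
    return table, TraitTable(trait_df, medication_cols=med_cols)
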