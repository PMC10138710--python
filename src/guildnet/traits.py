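"""Module- and feature-level trait association.

Associates module eigengenes (or raw features) with the diet score (MDS)
and fecal calprotectin (FCP) by Spearman correlation, with the three-tier
significance annotation used throughout the analysis: "*" for p < 0.05,
"@" for 0.05 <= p < 0.10, "N" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import TraitTable
from .stats import bh_fdr, spearman

__all__ = ["TraitAssociation", "tier", "associate", "species_trait_screen"]


@dataclass
class TraitAssociation:
    entity: str
    trait: str
    rho: float
    p: float
    tier: str


def tier(p: float) -> str:
    """Significance tier: '*' p<0.05, '@' 0.05<=p<0.10, 'N' otherwise."""
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "@"
    return "N"


def _trait_frame(traits) -> pd.DataFrame:
    return traits.data if isinstance(traits, TraitTable) else traits


def associate(entities: pd.DataFrame, traits, trait_names: Sequence[str]
              ) -> pd.DataFrame:
    """Spearman association of each column of ``entities`` (eigengenes or
    features) with each named trait.

    Returns a tidy frame with columns entity, trait, rho, p, tier.
    """
    tdf = _trait_frame(traits)
    rows = []
    for trait_name in trait_names:
        if trait_name not in tdf.columns:
            raise KeyError(f"unknown trait {trait_name!r}")
        t = pd.to_numeric(tdf[trait_name])
        if t.nunique() <= 1:
            raise ValueError(f"constant trait {trait_name!r}")
        for col in entities.columns:
            x = entities[col].reindex(t.index).dropna()
            paired = t.loc[x.index]
            if len(x) < 4:
                raise ValueError("need at least four paired observations")
            rho, p = spearman(x.to_numpy(), paired.to_numpy())
            rows.append({"entity": col, "trait": trait_name, "rho": rho,
                         "p": p, "tier": tier(p)})
    return pd.DataFrame(rows)


def species_trait_screen(taxa: pd.DataFrame, trait: pd.Series,
                         fdr_q: float = 0.05) -> pd.DataFrame:
    """Per-taxon Spearman association with a trait, BH-corrected.

    Positive rho means higher abundance with higher trait values.  Returns
    all taxa ranked by p with a boolean ``significant`` column at the
    requested FDR level.
    """
    trait = pd.to_numeric(trait).reindex(taxa.index)
    rows = []
    for col in taxa.columns:
        x = taxa[col]
        if x.nunique() <= 1:
            rows.append({"taxon": col, "rho": np.nan, "p": 1.0})
            continue
        rho, p = spearman(x.to_numpy(), trait.to_numpy())
        rows.append({"taxon": col, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] <= fdr_q
    return out.sort_values("p", kind="stable").reset_index(drop=True)
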