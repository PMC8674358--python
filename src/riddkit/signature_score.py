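"""RIDD/RIDDLE gene-signature scoring with a median split.

A sample's signature score for a gene set is the mean of its per-gene
Z-scores over the set members present in the expression matrix; genes
are Z-scored within each stratum (e.g. disease type). Samples are then
split into HIGH/LOW groups at the within-stratum median score. The
built-in sets are the decay-candidate signatures: RIDD (canonical
endomotif substrates) and RIDDLE (endomotif-lacking substrates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from riddkit.errors import CoverageError, InsufficientReplicationError

#: Canonical endomotif-containing decay substrates.
RIDD_GENES = ("BLOC1S1", "PIGQ", "TGOLN2", "DGAT2", "WT1", "GBA", "CD59", "BMP4")
#: Endomotif-lacking decay substrates.
RIDDLE_GENES = (
    "BCAM", "CCDC69", "MFAP2", "SNN", "SIX2", "AIM2", "OAS2", "CFAP45", "TNFAIP8L1"
)

BUILTIN_SETS: Dict[str, Sequence[str]] = {"RIDD": RIDD_GENES, "RIDDLE": RIDDLE_GENES}


@dataclass(frozen=True)
class GeneSet:
    """A named list of signature genes (duplicates count once)."""

    name: str
    members: tuple

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("gene set must be non-empty")

    @classmethod
    def builtin(cls, name: str) -> "GeneSet":
        return cls(name=name, members=tuple(BUILTIN_SETS[name]))

    @property
    def unique_members(self) -> List[str]:
        seen: Dict[str, None] = {}
        for g in self.members:
            seen.setdefault(g)
        return list(seen)


def _strata(samples: Sequence[str], strata: Optional[pd.Series]) -> pd.Series:
    if strata is None:
        return pd.Series("all", index=list(samples))
    return strata.loc[list(samples)]


def zscore_by_gene(expr: pd.DataFrame, strata: Optional[pd.Series] = None) -> pd.DataFrame:
    """Z-score each gene across samples, within each stratum.

    Uses the sample standard deviation (n−1 denominator). Zero-variance
    genes get an all-zero row with a warning. A stratum of size 1 raises:
    a single sample cannot be standardized.
    """
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()][:5]
        raise ValueError(f"duplicated gene ids: {list(dup)}")
    labels = _strata(expr.columns, strata)
    out = pd.DataFrame(np.nan, index=expr.index, columns=expr.columns)
    warned = False
    for stratum in labels.unique():
        cols = list(labels.index[labels == stratum])
        if len(cols) < 2:
            raise InsufficientReplicationError(
                f"stratum {stratum!r} has {len(cols)} sample(s); need >= 2 for Z-scoring"
            )
        block = expr[cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        zero = sd == 0
        if zero.any() and not warned:
            warnings.warn(
                f"{int(zero.sum())} zero-variance gene(s) set to Z=0", stacklevel=2
            )
            warned = True
        sd = sd.mask(zero, 1.0)
        out[cols] = block.sub(mu, axis=0).div(sd, axis=0).mask(zero, 0.0)
    return out


def score_samples(
    zexpr: pd.DataFrame,
    geneset: GeneSet,
    strata: Optional[pd.Series] = None,
    min_fraction_present: float = 0.5,
) -> pd.DataFrame:
    """Mean-Z signature score per sample with a median split.

    Returns a DataFrame indexed by sample with columns ``stratum``,
    ``score``, ``group`` (HIGH when the score exceeds the within-stratum
    median, LOW otherwise — ties at the median go LOW), and
    ``n_genes_used``. Raises :class:`CoverageError` when fewer than
    ``min_fraction_present`` of the set's members are present.
    """
    members = geneset.unique_members
    present = [g for g in members if g in zexpr.index]
    if len(present) < min_fraction_present * len(members):
        missing = sorted(set(members) - set(present))
        raise CoverageError(
            f"only {len(present)}/{len(members)} members of {geneset.name!r} present; "
            f"missing: {missing}"
        )
    labels = _strata(zexpr.columns, strata)
    scores = zexpr.loc[present].mean(axis=0)
    out = pd.DataFrame(
        {
            "stratum": labels,
            "score": scores,
            "n_genes_used": len(present),
        }
    )
    out["group"] = "LOW"
    for stratum in labels.unique():
        sel = out["stratum"] == stratum
        med = out.loc[sel, "score"].median()
        out.loc[sel & (out["score"] > med), "group"] = "HIGH"
    return out[["stratum", "score", "group", "n_genes_used"]]
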