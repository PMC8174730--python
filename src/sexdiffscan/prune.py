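"""LD-block pruning: at most one representative SNP per block.

The genome is partitioned into approximately LD-independent blocks
(half-open 1-based intervals).  Pruning a SNP set keeps, per occupied
block, the SNP minimizing a stated selection key — which P-value ranks
candidates differs by analysis:

``sexdiff_p``
    the sex-difference scan P (used for the cross-trait curated set),
``sex_specific_p``
    the GWAS P in one named sex (used for the sex-split SexDiff sets),
``phenotype_p``
    the smaller of the two sex-specific GWAS P-values (used for the
    general phenotype-associated pools).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import validate_blocks

logger = logging.getLogger(__name__)

KEY_COLUMNS = {
    "sexdiff_p": "p_sexdiff",
    "phenotype_p": "p_pheno",
    "sex_specific_p": "p_sex",
}


@dataclass
class PrunedSet:
    """Outcome of one pruning pass."""

    snps: pd.DataFrame  # retained rows, one per occupied block
    selection_key: str
    blocks_covered: int
    n_outside_blocks: int = 0

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()


def assign_blocks(snps: pd.DataFrame, blocks: pd.DataFrame) -> pd.Series:
    """Map each SNP to the block containing it, or NA if none does.

    A position belongs to the block with matching chromosome and
    ``start <= pos < end``.  Blocks are validated as sorted-compatible and
    non-overlapping.
    """
    validate_blocks(blocks)
    out = pd.Series(pd.NA, index=snps.index, dtype="object")
    for chrom, grp in blocks.groupby("chrom"):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        ids = g["block_id"].to_numpy()
        sel = snps["chrom"] == chrom
        pos = snps.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        vals = np.where(inside, ids[np.clip(idx, 0, len(ids) - 1)], None)
        out.loc[sel] = vals
    return out


def prune(
    snps: pd.DataFrame,
    blocks: pd.DataFrame,
    key: str,
    key_column: str | None = None,
) -> PrunedSet:
    """Reduce ``snps`` to at most one row per LD block, minimizing the key.

    ``key`` names the pruning mode (see module docstring); ``key_column``
    overrides the column holding the ranking value (defaults to the
    mode's conventional column).  Ties on the key break to the smaller
    position, then to the lexicographically smaller ``snp_id`` (logged).
    SNPs outside every block are dropped with a warning and counted.
    """
    if key not in KEY_COLUMNS:
        raise ValueError(f"unknown pruning key {key!r}; expected one of {sorted(KEY_COLUMNS)}")
    col = key_column or KEY_COLUMNS[key]
    if col not in snps.columns:
        raise ValueError(f"snps frame lacks key column {col!r}")

    work = snps.copy()
    work["_block"] = assign_blocks(work, blocks)
    outside = work["_block"].isna()
    n_outside = int(outside.sum())
    if n_outside:
        logger.warning("%d SNP(s) fall outside every LD block; dropped", n_outside)
        work = work[~outside]

    work = work.sort_values([col, "pos", "snp_id"], kind="mergesort")
    n_tied = int(work.duplicated(subset=["_block", col]).sum())
    if n_tied:
        logger.info("%d within-block key tie(s); broken by position, then snp_id", n_tied)
    kept = work.drop_duplicates(subset="_block", keep="first")
    kept = kept.sort_values(["chrom", "pos"]).reset_index(drop=True)
    kept = kept.rename(columns={"_block": "block_id"})
    return PrunedSet(
        snps=kept,
        selection_key=key,
        blocks_covered=kept["block_id"].nunique(),
        n_outside_blocks=n_outside,
    )
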