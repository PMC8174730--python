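"""Readers, writers, validation and filtering for sex-stratified GWAS inputs.

All tabular inputs are tab-separated text with a header row, optionally
gzip-compressed (transparent through pandas).  In-memory containers are
pandas DataFrames with fixed column schemas:

``sumstats``
    one row per variant for one trait and one sex:
    ``snp_id, chrom, pos, effect_allele, other_allele, maf, info, hwe_p,
    beta, se, pval``.  ``snp_id`` is the ``chrom:pos:other:effect`` key.
``sds``
    genome-wide singleton-density scores: ``snp_id, chrom, pos,
    ancestral_allele, derived_allele, maf, sds``.  Positive raw SDS means
    the derived allele rose in frequency over the last ~3,000 years.
``ihs``
    ``snp_id, chrom, pos, abs_ihs`` (absolute standardized iHS; SNPs
    without a score are simply absent).
``blocks``
    approximately LD-independent genome segments: ``chrom, start, end,
    block_id`` with half-open ``[start, end)`` 1-based intervals.
``genes``
    ``gene_id, chrom, start, end, go_terms`` where ``go_terms`` is a
    semicolon-joined set of GO identifiers.
``catalog``
    SNP-to-trait annotation pairs: ``snp_id, trait_label``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: GO term for "sexual differentiation", the biological-plausibility gene set.
GO_SEXUAL_DIFFERENTIATION = "GO:0007548"

_SUMSTAT_FILE_COLUMNS = [
    "variant",
    "effect_allele",
    "other_allele",
    "minor_AF",
    "info",
    "hwe_p",
    "beta",
    "se",
    "pval",
]

SUMSTAT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "maf",
    "info",
    "hwe_p",
    "beta",
    "se",
    "pval",
]


class SchemaError(ValueError):
    """A required column is missing or an input violates its contract."""


@dataclass
class FilterCounts:
    """Per-predicate drop accounting for one filtering pass."""

    n_in: int
    n_kept: int
    dropped: dict[str, int]

    def as_dict(self) -> dict:
        return {"n_in": self.n_in, "n_kept": self.n_kept, **self.dropped}


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# summary statistics


def read_sumstats(path: str | Path, sex: str | None = None, trait: str | None = None) -> pd.DataFrame:
    """Read one per-trait, per-sex summary-statistics table.

    Malformed rows (non-positive SE, MAF outside (0, 0.5], unparseable
    variant key) are rejected and logged with their line numbers.  The
    ``sex``/``trait`` arguments are carried through as metadata columns
    when given.

    Raises
    ------
    SchemaError
        if a required column is absent, or on duplicate variant keys.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant": str})
    _require_columns(df, _SUMSTAT_FILE_COLUMNS, f"summary statistics file {path}")

    parts = df["variant"].str.split(":", expand=True)
    ok_key = parts.shape[1] == 4 and parts.notna().all(axis=1)
    if parts.shape[1] != 4:
        ok_key = pd.Series(False, index=df.index)

    ok_se = pd.to_numeric(df["se"], errors="coerce") > 0
    maf = pd.to_numeric(df["minor_AF"], errors="coerce")
    ok_maf = (maf > 0) & (maf <= 0.5)
    ok = ok_key & ok_se & ok_maf
    if not ok.all():
        bad_lines = (df.index[~ok] + 2).tolist()  # +2: header + 1-based
        logger.warning(
            "%s: rejected %d malformed row(s) at file line(s) %s",
            path, len(bad_lines), bad_lines[:20],
        )
    df = df[ok].copy()
    parts = parts[ok]

    dup = df["variant"].duplicated(keep=False)
    if dup.any():
        dups = sorted(df.loc[dup, "variant"].unique())
        raise SchemaError(f"duplicate snp_id(s) in {path}: {', '.join(dups[:10])}")

    out = pd.DataFrame(
        {
            "snp_id": df["variant"].to_numpy(),
            "chrom": parts[0].to_numpy(),
            "pos": parts[1].astype(np.int64).to_numpy(),
            "effect_allele": df["effect_allele"].to_numpy(),
            "other_allele": df["other_allele"].to_numpy(),
            "maf": maf[ok].to_numpy(float),
            "info": df["info"].to_numpy(float),
            "hwe_p": df["hwe_p"].to_numpy(float),
            "beta": df["beta"].to_numpy(float),
            "se": df["se"].to_numpy(float),
            "pval": df["pval"].to_numpy(float),
        }
    )
    if sex is not None:
        out["sex"] = sex
    if trait is not None:
        out["trait"] = trait
    return out


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write a sumstats frame in the on-disk dialect (inverse of read)."""
    _require_columns(df, SUMSTAT_COLUMNS, "sumstats frame")
    out = pd.DataFrame(
        {
            "variant": df["snp_id"],
            "effect_allele": df["effect_allele"],
            "other_allele": df["other_allele"],
            "minor_AF": df["maf"],
            "info": df["info"],
            "hwe_p": df["hwe_p"],
            "beta": df["beta"],
            "se": df["se"],
            "pval": df["pval"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# selection scores and annotations


def read_sds(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "ID": str})
    _require_columns(df, ["CHR", "POS", "ID", "AA", "DA", "MAF", "SDS"], f"SDS file {path}")
    out = df.rename(
        columns={
            "CHR": "chrom", "POS": "pos", "ID": "snp_id",
            "AA": "ancestral_allele", "DA": "derived_allele",
            "MAF": "maf", "SDS": "sds",
        }
    )
    bad = out["ancestral_allele"] == out["derived_allele"]
    if bad.any():
        raise SchemaError(f"SDS rows with identical ancestral/derived alleles in {path}")
    return out[["snp_id", "chrom", "pos", "ancestral_allele", "derived_allele", "maf", "sds"]]


def write_sds(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "CHR": df["chrom"], "POS": df["pos"], "ID": df["snp_id"],
            "AA": df["ancestral_allele"], "DA": df["derived_allele"],
            "MAF": df["maf"], "SDS": df["sds"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_ihs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "ID": str})
    _require_columns(df, ["CHR", "POS", "ID", "ABS_IHS"], f"iHS file {path}")
    out = df.rename(columns={"CHR": "chrom", "POS": "pos", "ID": "snp_id", "ABS_IHS": "abs_ihs"})
    if (out["abs_ihs"] < 0).any():
        raise SchemaError(f"negative |iHS| values in {path}")
    return out[["snp_id", "chrom", "pos", "abs_ihs"]]


def write_ihs(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {"CHR": df["chrom"], "POS": df["pos"], "ID": df["snp_id"], "ABS_IHS": df["abs_ihs"]}
    )
    out.to_csv(path, sep="\t", index=False)


def read_blocks(path: str | Path) -> pd.DataFrame:
    """Read a BED-like LD-block file (chrom, start, end, block_id).

    Blocks are validated as non-overlapping within each chromosome
    under the half-open ``[start, end)`` convention.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "block_id": str})
    _require_columns(df, ["chrom", "start", "end", "block_id"], f"LD block file {path}")
    validate_blocks(df)
    return df[["chrom", "start", "end", "block_id"]]


def validate_blocks(blocks: pd.DataFrame) -> None:
    if (blocks["start"] >= blocks["end"]).any():
        raise SchemaError("LD block with start >= end")
    for chrom, grp in blocks.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise SchemaError(f"overlapping LD blocks on chromosome {chrom}")


def write_blocks(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "block_id"]].to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str}, keep_default_na=False)
    _require_columns(df, ["gene_id", "chrom", "start", "end", "go_terms"], f"gene file {path}")
    if (df["start"] >= df["end"]).any():
        raise SchemaError("gene with start >= end")
    out = df[["gene_id", "chrom", "start", "end"]].copy()
    out["go_terms"] = [
        frozenset(t for t in str(s).split(";") if t) for s in df["go_terms"]
    ]
    return out


def write_genes(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["gene_id", "chrom", "start", "end"]].copy()
    out["go_terms"] = [";".join(sorted(s)) for s in df["go_terms"]]
    out.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["snp_id", "trait_label"], f"catalog file {path}")
    return df[["snp_id", "trait_label"]]


def write_catalog(df: pd.DataFrame, path: str | Path) -> None:
    df[["snp_id", "trait_label"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering

def apply_primary_filters(
    records: pd.DataFrame,
    maf_min: float = 0.001,
    info_min: float = 0.8,
    hwe_min: float = 1e-10,
) -> tuple[pd.DataFrame, FilterCounts]:
    """Variant-level QC: keep rows strictly exceeding all three thresholds.

    Mirrors the standard imputation-era QC applied to biobank summary
    statistics: minor allele frequency > ``maf_min``, imputation INFO
    score > ``info_min``, Hardy–Weinberg equilibrium P > ``hwe_min``.
    All comparisons are strict.

    Returns the kept frame and per-filter drop counts (a row failing
    several predicates is counted once under each).
    """
    ok_maf = records["maf"] > maf_min
    ok_info = records["info"] > info_min
    ok_hwe = records["hwe_p"] > hwe_min
    kept = records[ok_maf & ok_info & ok_hwe]
    counts = FilterCounts(
        n_in=len(records),
        n_kept=len(kept),
        dropped={
            "dropped_maf": int((~ok_maf).sum()),
            "dropped_info": int((~ok_info).sum()),
            "dropped_hwe": int((~ok_hwe).sum()),
            "dropped_total": int(len(records) - len(kept)),
        },
    )
    if counts.n_kept == 0:
        logger.warning("primary filters removed every record (n_in=%d)", counts.n_in)
    return kept.reset_index(drop=True), counts


def apply_analysis_filters(
    records: pd.DataFrame,
    sds_table: pd.DataFrame,
    maf_min: float = 0.05,
) -> tuple[pd.DataFrame, FilterCounts]:
    """Pre-analysis filters: common variants with a selection score.

    Removes SNPs with MAF < ``maf_min`` (a SNP at exactly the threshold
    is retained) and SNPs absent from the SDS table, since downstream
    evolutionary analyses need a score for every variant.  Presence in
    the SDS table is keyed on chromosome + position.
    """
    ok_maf = records["maf"] >= maf_min
    sds_keys = set(zip(sds_table["chrom"], sds_table["pos"]))
    ok_sds = pd.Series(
        [key in sds_keys for key in zip(records["chrom"], records["pos"])],
        index=records.index,
    )
    kept = records[ok_maf & ok_sds]
    counts = FilterCounts(
        n_in=len(records),
        n_kept=len(kept),
        dropped={
            "dropped_maf": int((~ok_maf).sum()),
            "dropped_no_sds": int((~ok_sds).sum()),
            "dropped_total": int(len(records) - len(kept)),
        },
    )
    return kept.reset_index(drop=True), counts


def select_phenotype_associated(
    female: pd.DataFrame, male: pd.DataFrame, alpha: float = 5e-8
) -> set[str]:
    """SNPs genome-wide significant (P < alpha) in either sex or both.

    Both frames must cover the same variants; the association threshold
    defaults to the conventional genome-wide 5e-8.
    """
    f = female.set_index("snp_id")["pval"]
    m = male.set_index("snp_id")["pval"]
    common = f.index.intersection(m.index)
    f = f.loc[common]
    m = m.loc[common]
    hit = (f < alpha) | (m < alpha)
    return set(common[hit])
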