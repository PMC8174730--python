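"""The sex-difference association scan.

For each trait the male- and female-specific GWAS yield, per SNP, effect
estimates ``b_m``, ``b_f`` with standard errors ``se_m``, ``se_f``.  Because
both estimates come from overlapping genetic architectures, their errors
are correlated; the scan statistic corrects for this with the genome-wide
Spearman rank correlation ``rho`` between male and female effect sizes:

    t = (b_m - b_f) / sqrt(se_m^2 + se_f^2 - 2 * rho * se_m * se_f)

``t`` is converted to a two-sided P-value under a Student-t (or, in the
default infinite-df limit, normal) reference, and Benjamini–Hochberg
adjusted within the trait's phenotype-associated SNP set.  SNPs whose
adjusted q falls below a threshold are "SexDiff-associated" at that
threshold, and are split by the sex with the stronger association.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: FDR thresholds at which SexDiff-associated SNPs are classified,
#: most to least permissive.
FDR_THRESHOLDS = (0.05, 0.01, 0.005, 0.001)


@dataclass(frozen=True)
class TraitCorrelation:
    """Genome-wide male/female effect-size rank correlation for one trait."""

    trait: str
    rho: float
    n_snps_used: int


class DegenerateStatisticError(ValueError):
    """The heterogeneity variance is non-positive (rho ~ 1 with equal SEs)."""


def compute_rho(
    betas_f: np.ndarray, betas_m: np.ndarray, trait: str = ""
) -> TraitCorrelation:
    """Spearman rank correlation between female and male effect sizes.

    Ties receive average ranks.  Raises on length mismatch, fewer than
    three points, or a constant vector (undefined correlation).
    """
    betas_f = np.asarray(betas_f, dtype=float)
    betas_m = np.asarray(betas_m, dtype=float)
    if betas_f.shape != betas_m.shape:
        raise ValueError(
            f"beta vectors differ in length: {betas_f.shape} vs {betas_m.shape}"
        )
    if betas_f.size < 3:
        raise ValueError("need at least 3 SNPs to estimate rho")
    if np.ptp(betas_f) == 0 or np.ptp(betas_m) == 0:
        raise ValueError("constant beta vector: Spearman correlation undefined")
    rho = stats.spearmanr(betas_f, betas_m).statistic
    return TraitCorrelation(trait=trait, rho=float(rho), n_snps_used=betas_f.size)


def t_sexdiff_statistic(b_m, b_f, se_m, se_f, rho: float, clamp_eps: float | None = None):
    """Correlated-error heterogeneity statistic (b_m - b_f) / pooled SE.

    Vectorized over numpy arrays.  The variance term
    ``se_m^2 + se_f^2 - 2*rho*se_m*se_f`` can collapse to zero when
    rho ~ 1 and the SEs coincide; by default that raises
    :class:`DegenerateStatisticError`, or set ``clamp_eps`` to floor the
    variance at a small positive value (the clamp is logged).
    """
    b_m = np.asarray(b_m, dtype=float)
    b_f = np.asarray(b_f, dtype=float)
    se_m = np.asarray(se_m, dtype=float)
    se_f = np.asarray(se_f, dtype=float)
    if np.any(se_m <= 0) or np.any(se_f <= 0):
        raise ValueError("standard errors must be positive")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    var = se_m**2 + se_f**2 - 2.0 * rho * se_m * se_f
    if np.any(var <= 0):
        if clamp_eps is None:
            raise DegenerateStatisticError(
                "non-positive heterogeneity variance (rho=%.6g); "
                "pass clamp_eps to floor it" % rho
            )
        n_clamped = int(np.sum(var <= 0))
        logger.warning("clamped %d non-positive variance term(s) to %g", n_clamped, clamp_eps)
        var = np.maximum(var, clamp_eps)
    t = (b_m - b_f) / np.sqrt(var)
    return t if t.ndim else float(t)


def sexdiff_pvalue(t, df: float = math.inf):
    """Two-sided P for the heterogeneity statistic.

    ``df=inf`` (default) uses the normal limit; with the effective sample
    sizes of biobank GWAS the two are indistinguishable, but a finite df
    is accepted for exact replication of a t reference.
    """
    t = np.asarray(t, dtype=float)
    if df <= 0:
        raise ValueError("df must be positive (or inf)")
    if math.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return p if p.ndim else float(p)


def classify_sexdiff(
    results: pd.DataFrame,
    thresholds: tuple[float, ...] = FDR_THRESHOLDS,
) -> pd.DataFrame:
    """BH-adjust sex-difference P-values within one trait and flag thresholds.

    ``results`` must carry ``snp_id`` and ``p_sexdiff`` for the trait's
    full phenotype-associated SNP set (that set is the multiple-testing
    universe).  Adds ``q_sexdiff`` and one boolean ``pass_<t>`` column per
    threshold, with ``pass`` meaning q strictly below the threshold.
    """
    if len(results) == 0:
        raise ValueError("cannot classify an empty result set")
    out = results.copy()
    _, q, _, _ = multipletests(out["p_sexdiff"].to_numpy(), method="fdr_bh")
    out["q_sexdiff"] = q
    for thr in sorted(thresholds, reverse=True):
        out[_pass_col(thr)] = out["q_sexdiff"] < thr
    return out


def _pass_col(threshold: float) -> str:
    return f"pass_{threshold:g}"


def split_by_stronger_sex(results: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Partition SNPs by the sex with the stronger (lower-P) association.

    ``results`` needs ``snp_id, p_f, p_m, beta_f, beta_m``.  Exact P
    ties go to the sex with the larger absolute effect size, then to
    female; ties are logged.
    """
    p_f = results["p_f"].to_numpy()
    p_m = results["p_m"].to_numpy()
    female = p_f < p_m
    tie = p_f == p_m
    if tie.any():
        logger.info("%d SNP(s) with tied sex-specific P; breaking by |beta|, then female", tie.sum())
        beta_tie = np.abs(results["beta_f"].to_numpy()) >= np.abs(results["beta_m"].to_numpy())
        female = female | (tie & beta_tie)
    ids = results["snp_id"].to_numpy()
    return set(ids[female]), set(ids[~female])


def scan_trait(
    female: pd.DataFrame,
    male: pd.DataFrame,
    trait: str,
    associated_ids: set[str],
    rho: float | None = None,
    df: float = math.inf,
    thresholds: tuple[float, ...] = FDR_THRESHOLDS,
    clamp_eps: float | None = None,
) -> pd.DataFrame:
    """Run the full scan for one trait.

    ``female``/``male`` are analysis-filtered sumstats frames covering the
    same variants.  ``rho`` defaults to the Spearman correlation over the
    full filtered set (the genome-wide estimate); pass a value to use a
    different universe.  Returns one row per phenotype-associated SNP with
    t, p, q, threshold flags and ``stronger_sex``.
    """
    merged = female.merge(
        male, on=["snp_id", "chrom", "pos"], suffixes=("_f", "_m")
    )
    if rho is None:
        rho = compute_rho(merged["beta_f"].to_numpy(), merged["beta_m"].to_numpy(), trait).rho
    assoc = merged[merged["snp_id"].isin(associated_ids)].reset_index(drop=True)
    if len(assoc) == 0:
        raise ValueError(f"no phenotype-associated SNPs for trait {trait!r}")
    t = t_sexdiff_statistic(
        assoc["beta_m"], assoc["beta_f"], assoc["se_m"], assoc["se_f"], rho, clamp_eps
    )
    res = pd.DataFrame(
        {
            "snp_id": assoc["snp_id"],
            "trait": trait,
            "chrom": assoc["chrom"],
            "pos": assoc["pos"],
            "beta_f": assoc["beta_f"],
            "beta_m": assoc["beta_m"],
            "se_f": assoc["se_f"],
            "se_m": assoc["se_m"],
            "p_f": assoc["pval_f"],
            "p_m": assoc["pval_m"],
            "maf": assoc["maf_f"],
            "effect_allele": assoc["effect_allele_f"],
            "other_allele": assoc["other_allele_f"],
            "t_sexdiff": t,
            "p_sexdiff": sexdiff_pvalue(t, df),
            "rho": rho,
        }
    )
    res = classify_sexdiff(res, thresholds)
    female_ids, _ = split_by_stronger_sex(res)
    res["stronger_sex"] = np.where(res["snp_id"].isin(female_ids), "female", "male")
    return res
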