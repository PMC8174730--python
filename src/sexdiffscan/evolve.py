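"""Effect-size-ratio diagnostics and recent-selection permutation tests.

Two score families quantify recent positive selection per SNP: the
singleton density score (SDS; sensitive to allele-frequency change over
the last ~3,000 years — a positive raw value means the *derived* allele
rose) and the absolute integrated haplotype score (|iHS|; ~25,000
years).  To make SDS directional with respect to a phenotype, its sign
is fixed so that positive "trait-SDS" means the *trait-increasing*
allele rose in frequency.

All group comparisons use subset-vs-pool resampling: draw |subset| SNPs
from the phenotype-associated pool, recompute the mean statistic, repeat,
and report the doubled one-tail proportion of replicate means at least
as extreme as the observed subset mean (the tail taken in the direction
of the observed deviation from the pool mean).  The ten (trait, sex)
tests of one family are then Benjamini–Hochberg adjusted together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_CHUNK = 2000


@dataclass
class PermutationResult:
    """One subset-vs-pool resampling comparison."""

    label: str
    observed_stat: float
    pool_size: int
    subset_size: int
    reps: int
    n_extreme: int
    p: float
    tails: int
    floored: bool = False  # True when zero exceedances: p is "< tails/reps"
    q: float | None = None

    def p_text(self) -> str:
        if self.floored:
            return f"< {self.tails / self.reps:g}"
        return f"{self.p:g}"


class MatchingError(RuntimeError):
    """A MAF-matched replicate could not be completed."""


# ---------------------------------------------------------------------------
# effect-size ratio diagnostics


def log2_effect_ratios(
    beta_f, beta_m, stronger_sex=None
) -> tuple[np.ndarray, int]:
    """Per-SNP log2 of female over male effect size, after alignment.

    Both betas are oriented to the trait-increasing allele of the more
    significantly associated sex (``stronger_sex``: array of "female"/
    "male"; defaults to female for all).  Pairs left with opposite signs
    after alignment have no meaningful log ratio; they are excluded and
    counted.  Zero betas are likewise excluded.

    Returns (ratios, n_excluded).
    """
    beta_f = np.asarray(beta_f, dtype=float)
    beta_m = np.asarray(beta_m, dtype=float)
    if stronger_sex is None:
        anchor = beta_f
    else:
        stronger_sex = np.asarray(stronger_sex)
        anchor = np.where(stronger_sex == "female", beta_f, beta_m)
    sign = np.sign(anchor)
    bf = beta_f * sign
    bm = beta_m * sign
    ok = (bf > 0) & (bm > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info(
            "excluded %d SNP(s) with zero or discordant-sign betas from log2 ratios",
            n_excluded,
        )
    return np.log2(bf[ok] / bm[ok]), n_excluded


def ratio_ttest(ratios, direction: str) -> float:
    """One-sample, one-sided t-test of mean log2 ratio against zero.

    ``direction`` is "greater" for female-stronger sets (expect positive
    ratios) and "less" for male-stronger sets.  All-zero input sits
    exactly on the null (t = 0) and returns the one-sided boundary 0.5;
    any other constant input has undefined variance and raises.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 2:
        raise ValueError("need at least 2 ratios for a t-test")
    if np.ptp(ratios) == 0:
        if ratios[0] == 0.0:
            logger.info("all ratios exactly zero: returning the t=0 boundary P of 0.5")
            return 0.5
        raise ValueError("constant nonzero ratios: t-test variance undefined")
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    return float(stats.ttest_1samp(ratios, 0.0, alternative=direction).pvalue)


# ---------------------------------------------------------------------------
# trait-SDS alignment


def align_trait_sds(sds, effect_is_derived, beta):
    """Sign-fix raw SDS into trait-SDS.

    Raw SDS is positive when the derived allele rose in frequency.  The
    trait-aligned score flips sign once if the effect allele is the
    ancestral allele, and once more if the effect estimate is negative,
    so that positive trait-SDS always means the trait-increasing allele
    rose.  Vectorized.
    """
    sds = np.asarray(sds, dtype=float)
    effect_is_derived = np.asarray(effect_is_derived, dtype=bool)
    beta = np.asarray(beta, dtype=float)
    out = np.where(effect_is_derived, sds, -sds)
    out = np.where(beta < 0, -out, out)
    return out if out.ndim else float(out)


def align_trait_sds_frame(
    snps: pd.DataFrame, sds_table: pd.DataFrame, beta_column: str
) -> pd.DataFrame:
    """Join SNPs to the SDS table and attach ``trait_sds``.

    The join is on chromosome + position; the SNP's effect allele must
    equal the ancestral or the derived allele, otherwise the SNP is
    dropped and logged as an allele mismatch.
    """
    merged = snps.merge(
        sds_table[["chrom", "pos", "ancestral_allele", "derived_allele", "sds"]],
        on=["chrom", "pos"],
        how="inner",
    )
    is_der = merged["effect_allele"] == merged["derived_allele"]
    is_anc = merged["effect_allele"] == merged["ancestral_allele"]
    ok = is_der | is_anc
    if (~ok).any():
        logger.warning(
            "dropped %d SNP(s) whose effect allele matches neither SDS allele",
            int((~ok).sum()),
        )
        merged = merged[ok]
        is_der = is_der[ok]
    merged = merged.copy()
    merged["trait_sds"] = align_trait_sds(
        merged["sds"].to_numpy(), is_der.to_numpy(), merged[beta_column].to_numpy()
    )
    return merged


# ---------------------------------------------------------------------------
# resampling engines


def _finalize(
    label: str,
    observed: float,
    pool_size: int,
    subset_size: int,
    reps: int,
    n_extreme: int,
    tails: int,
) -> PermutationResult:
    p = min(1.0, tails * n_extreme / reps)
    return PermutationResult(
        label=label,
        observed_stat=float(observed),
        pool_size=pool_size,
        subset_size=subset_size,
        reps=reps,
        n_extreme=n_extreme,
        p=p,
        tails=tails,
        floored=n_extreme == 0,
    )


def _tail_count(means: np.ndarray, observed: float, pool_mean: float) -> int:
    """Replicates at least as extreme as ``observed``, in its direction."""
    if observed >= pool_mean:
        return int((means >= observed).sum())
    return int((means <= observed).sum())


def subset_vs_pool_permutation(
    subset_values,
    pool_values,
    reps: int = 10_000,
    tails: int = 2,
    seed: int | np.random.Generator = 0,
    label: str = "",
) -> PermutationResult:
    """Compare a subset's mean against draws of equal size from the pool.

    The one-tail proportion of replicate means at least as extreme as the
    observed mean — extremeness measured in the direction of the observed
    deviation from the pool mean — is multiplied by ``tails`` (2 for the
    usual two-tailed report) and capped at 1.
    """
    subset = np.asarray(subset_values, dtype=float)
    pool = np.asarray(pool_values, dtype=float)
    if subset.size == 0:
        raise ValueError("empty subset")
    if subset.size > pool.size:
        raise ValueError("subset larger than pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = subset.mean()
    pool_mean = pool.mean()
    k = subset.size
    n_extreme = 0
    for lo in range(0, reps, _CHUNK):
        m = min(_CHUNK, reps - lo)
        keys = rng.random((m, pool.size))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        means = pool[idx].mean(axis=1)
        n_extreme += _tail_count(means, observed, pool_mean)
    return _finalize(label, observed, pool.size, k, reps, n_extreme, tails)


def maf_matched_permutation(
    subset: pd.DataFrame,
    pool: pd.DataFrame,
    value_column: str = "trait_sds",
    maf_window: float = 0.05,
    reps: int = 10_000,
    tails: int = 2,
    seed: int | np.random.Generator = 0,
    label: str = "",
    max_retries: int = 20,
) -> PermutationResult:
    """Subset-vs-pool resampling with per-SNP minor-allele-frequency matching.

    Per replicate the subset order is shuffled; each subset SNP draws,
    without replacement within the replicate, one pool SNP whose MAF lies
    within ``maf_window`` of its own.  A replicate that exhausts legal
    matches is abandoned and redrawn, up to ``max_retries`` consecutive
    failures; persistent failure raises :class:`MatchingError` advising a
    wider window.  Both frames need ``maf`` and ``value_column``.
    """
    if len(subset) == 0:
        raise ValueError("empty subset")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub_maf = subset["maf"].to_numpy(float)
    pool_maf = pool["maf"].to_numpy(float)
    pool_vals = pool[value_column].to_numpy(float)
    observed = subset[value_column].to_numpy(float).mean()
    pool_mean = pool_vals.mean()
    # precompute candidate pool indices per subset SNP
    candidates = [
        np.flatnonzero(np.abs(pool_maf - m) <= maf_window + 1e-12) for m in sub_maf
    ]
    for i, c in enumerate(candidates):
        if c.size == 0:
            raise MatchingError(
                f"subset SNP with MAF {sub_maf[i]:.3f} has no pool match within "
                f"±{maf_window}; widen the MAF window"
            )
    k = len(candidates)
    means = np.empty(reps)
    done = 0
    failures = 0
    while done < reps:
        order = rng.permutation(k)
        used: set[int] = set()
        total = 0.0
        ok = True
        for i in order:
            cand = candidates[i]
            if len(used) and cand.size <= len(used):
                cand = cand[~np.isin(cand, list(used), assume_unique=False)]
            elif len(used):
                cand = cand[[c not in used for c in cand]]
            if cand.size == 0:
                ok = False
                break
            j = int(cand[rng.integers(cand.size)])
            used.add(j)
            total += pool_vals[j]
        if not ok:
            failures += 1
            if failures > max_retries:
                raise MatchingError(
                    "MAF-matched resampling repeatedly exhausted matches; "
                    "widen the MAF window"
                )
            continue
        failures = 0
        means[done] = total / k
        done += 1
    n_extreme = _tail_count(means, observed, pool_mean)
    return _finalize(label, observed, len(pool), k, reps, n_extreme, tails)


def ihs_permutation(
    subset_abs_ihs,
    pool_abs_ihs,
    reps: int = 10_000,
    tails: int = 2,
    seed: int | np.random.Generator = 0,
    label: str = "",
) -> PermutationResult:
    """Subset-vs-pool resampling on mean |iHS|.

    Callers must first drop SNPs lacking an iHS score; NaNs here are an
    error to make that contract explicit.
    """
    subset = np.asarray(subset_abs_ihs, dtype=float)
    pool = np.asarray(pool_abs_ihs, dtype=float)
    if np.isnan(subset).any() or np.isnan(pool).any():
        raise ValueError("missing |iHS| values: remove unscored SNPs first")
    return subset_vs_pool_permutation(subset, pool, reps, tails, seed, label)


def genic_intergenic_test(
    subset_genic_flags,
    pool_genic_flags,
    reps: int = 10_000,
    tails: int = 2,
    seed: int | np.random.Generator = 0,
    label: str = "",
) -> PermutationResult:
    """Resampling test on the count of intergenic SNPs in the subset.

    A SNP is genic when within ±10 kb of an annotated gene; the statistic
    is the number of intergenic SNPs among a drawn subset, with the
    doubled one-tail empirical P as elsewhere.
    """
    sub = np.asarray(subset_genic_flags, dtype=bool)
    pool = np.asarray(pool_genic_flags, dtype=bool)
    if sub.size == 0:
        raise ValueError("empty subset")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = float((~sub).sum())
    pool_inter = (~pool).astype(float)
    expected = pool_inter.mean() * sub.size
    k = sub.size
    n_extreme = 0
    for lo in range(0, reps, _CHUNK):
        m = min(_CHUNK, reps - lo)
        keys = rng.random((m, pool.size))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        counts = pool_inter[idx].sum(axis=1)
        n_extreme += _tail_count(counts, observed, expected)
    return _finalize(label, observed, pool.size, k, reps, n_extreme, tails)


def family_fdr(results: list[PermutationResult]) -> list[PermutationResult]:
    """BH-adjust one analysis family (normally the 10 trait-by-sex tests)."""
    if not results:
        return []
    _, q, _, _ = multipletests([r.p for r in results], method="fdr_bh")
    return [replace(r, q=float(qi)) for r, qi in zip(results, q)]
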