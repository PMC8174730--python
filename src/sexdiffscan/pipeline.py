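"""End-to-end orchestration: filter → select → scan → prune → co-localize → evolve.

`run_pipeline` consumes an in-memory :class:`~sexdiffscan.simulate.Bundle`
(generated synthetically or loaded from disk) plus a
:class:`PipelineConfig`, and returns every stage's tables together with a
machine-readable manifest of counts at each filtering step.  Each random
stage draws its own child seed from the master seed, so stages can be
rerun in isolation and the whole run is reproducible.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc, evolve, io as sio, prune as ldprune, scan
from .simulate import Bundle, SHBG_LABEL

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    alpha: float = 5e-8
    fdr_thresholds: tuple[float, ...] = scan.FDR_THRESHOLDS
    working_threshold: float = 0.001
    reps: int = 10_000
    seed: int = 0
    df: float = math.inf
    rho_universe: str = "filtered"  # or "significant"
    maf_window: float = 0.05
    tails_sds: int = 2
    tails_ratio: int = 1
    maf_min_primary: float = 0.001
    info_min: float = 0.8
    hwe_min: float = 1e-10
    maf_min_analysis: float = 0.05
    gene_window: int = 10_000
    pleiotropy_label: str = SHBG_LABEL
    intersect_traits: bool = False
    run_maf_matched: bool = True

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if list(self.fdr_thresholds) != sorted(self.fdr_thresholds, reverse=True):
            raise ValueError("fdr_thresholds must be sorted descending")
        if self.working_threshold not in self.fdr_thresholds:
            raise ValueError("working_threshold must be one of fdr_thresholds")


@dataclass
class PipelineResult:
    scans: dict[str, pd.DataFrame]
    rho: dict[str, float]
    enrichment: coloc.EnrichmentReport | None
    pleiotropy: coloc.PleiotropyReport | None
    families: dict[str, list[evolve.PermutationResult]]
    ratio_tests: pd.DataFrame
    summary: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for trait, df in self.scans.items():
            df.to_csv(outdir / f"scan.{trait}.tsv", sep="\t", index=False)
        self.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        self.ratio_tests.to_csv(outdir / "ratio_tests.tsv", sep="\t", index=False)
        for name, fam in self.families.items():
            pd.DataFrame([asdict(r) for r in fam]).to_csv(
                outdir / f"family.{name}.tsv", sep="\t", index=False
            )
        reports = {}
        if self.enrichment is not None:
            reports["enrichment"] = asdict(self.enrichment)
        if self.pleiotropy is not None:
            reports["pleiotropy"] = asdict(self.pleiotropy)
        (outdir / "reports.json").write_text(json.dumps(reports, indent=2))
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return outdir


def _child_seed(master: int, label: str) -> int:
    # stable per-stage seed below 2**31 (crc32 is process-independent,
    # unlike the builtin str hash)
    h = np.random.SeedSequence([master, zlib.crc32(label.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Totals over per-trait associated / SexDiff counts.

    ``counts`` needs columns ``trait, n_associated, n_sexdiff``.  Appends
    per-trait proportions, a TOTAL row, and the overall SexDiff
    percentage (one decimal).
    """
    out = counts.copy()
    out["proportion"] = out["n_sexdiff"] / out["n_associated"].where(out["n_associated"] > 0)
    total_assoc = int(out["n_associated"].sum())
    total_sd = int(out["n_sexdiff"].sum())
    pct = round(100.0 * total_sd / total_assoc, 1) if total_assoc else 0.0
    total = pd.DataFrame(
        [
            {
                "trait": "TOTAL",
                "n_associated": total_assoc,
                "n_sexdiff": total_sd,
                "proportion": total_sd / total_assoc if total_assoc else np.nan,
                "percentage": pct,
            }
        ]
    )
    return pd.concat([out, total], ignore_index=True)


def run_pipeline(bundle: Bundle, config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    traits = sorted({t for t, _ in bundle.sumstats})
    manifest: dict = {"traits": traits, "stages": {}, "seed": config.seed}

    # ------------------------------------------------------------------ scan
    scans: dict[str, pd.DataFrame] = {}
    rhos: dict[str, float] = {}
    filtered: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    kept_ids_per_trait: dict[str, set] = {}
    for trait in traits:
        stage: dict = {}
        fr, fr_counts = sio.apply_primary_filters(
            bundle.sumstats[(trait, "female")],
            config.maf_min_primary, config.info_min, config.hwe_min,
        )
        ma, ma_counts = sio.apply_primary_filters(
            bundle.sumstats[(trait, "male")],
            config.maf_min_primary, config.info_min, config.hwe_min,
        )
        stage["primary_female"] = fr_counts.as_dict()
        stage["primary_male"] = ma_counts.as_dict()
        fr, fa_counts = sio.apply_analysis_filters(fr, bundle.sds, config.maf_min_analysis)
        ma, ma2_counts = sio.apply_analysis_filters(ma, bundle.sds, config.maf_min_analysis)
        stage["analysis_female"] = fa_counts.as_dict()
        stage["analysis_male"] = ma2_counts.as_dict()
        common = set(fr["snp_id"]) & set(ma["snp_id"])
        fr = fr[fr["snp_id"].isin(common)].reset_index(drop=True)
        ma = ma[ma["snp_id"].isin(common)].reset_index(drop=True)
        stage["n_both_sexes"] = len(common)
        filtered[trait] = (fr, ma)
        kept_ids_per_trait[trait] = common
        manifest["stages"][trait] = stage

    if config.intersect_traits:
        shared = set.intersection(*kept_ids_per_trait.values())
        for trait in traits:
            fr, ma = filtered[trait]
            filtered[trait] = (
                fr[fr["snp_id"].isin(shared)].reset_index(drop=True),
                ma[ma["snp_id"].isin(shared)].reset_index(drop=True),
            )
        manifest["n_intersected"] = len(shared)

    count_rows = []
    for trait in traits:
        fr, ma = filtered[trait]
        associated = sio.select_phenotype_associated(fr, ma, config.alpha)
        manifest["stages"][trait]["n_associated"] = len(associated)
        if not associated:
            logger.warning("trait %s: no phenotype-associated SNPs; skipped", trait)
            continue
        if config.rho_universe == "significant":
            sig_fr = fr[fr["snp_id"].isin(associated)]
            sig_ma = ma[ma["snp_id"].isin(associated)]
            rho = scan.compute_rho(
                sig_fr.sort_values("snp_id")["beta"].to_numpy(),
                sig_ma.sort_values("snp_id")["beta"].to_numpy(),
                trait,
            ).rho
        else:
            rho = None  # scan_trait estimates over the full filtered set
        res = scan.scan_trait(
            fr, ma, trait, associated,
            rho=rho, df=config.df, thresholds=config.fdr_thresholds,
        )
        scans[trait] = res
        rhos[trait] = float(res["rho"].iloc[0])
        pass_col = f"pass_{config.working_threshold:g}"
        n_sd = int(res[pass_col].sum())
        manifest["stages"][trait]["n_sexdiff"] = {
            f"{t:g}": int(res[f"pass_{t:g}"].sum()) for t in config.fdr_thresholds
        }
        count_rows.append(
            {"trait": trait, "n_associated": len(res), "n_sexdiff": n_sd}
        )
    summary = summarize_counts(pd.DataFrame(count_rows)) if count_rows else pd.DataFrame()

    pass_col = f"pass_{config.working_threshold:g}"
    genes = bundle.genes
    go_genes = coloc.go_term_genes(genes)

    # --------------------------------------------------- gene co-localization
    all_scans = pd.concat(scans.values(), ignore_index=True) if scans else pd.DataFrame()
    enrichment = None
    if len(all_scans):
        sd_ids = set(all_scans.loc[all_scans[pass_col], "snp_id"])
        assoc_ids = set(all_scans["snp_id"])
        non_sd_ids = assoc_ids - sd_ids
        positions = all_scans.drop_duplicates("snp_id")[["snp_id", "chrom", "pos"]]
        mapping = coloc.map_snps_to_genes(positions, genes, config.gene_window)
        sd_genes = coloc.genes_hit(mapping, sd_ids)
        non_sd_genes = coloc.genes_hit(mapping, non_sd_ids)
        pool_genes = coloc.genes_hit(mapping, assoc_ids)
        if sd_genes and non_sd_genes:
            enrichment = coloc.go_enrichment(
                sd_genes, non_sd_genes, go_genes, config.working_threshold
            )
            enrichment.perm_p = coloc.gene_permutation_test(
                sorted(pool_genes), go_genes,
                n_draw=len(sd_genes),
                observed_go_count=enrichment.n_go_genes_sexdiff,
                reps=config.reps,
                seed=_child_seed(config.seed, "gene_perm"),
            )
            enrichment.n_perm = config.reps
        manifest["coloc"] = {
            "n_sexdiff_snps": len(sd_ids),
            "n_nonsexdiff_snps": len(non_sd_ids),
            "n_genes_pool": len(pool_genes),
        }

    # ------------------------------------------------------------- pleiotropy
    pleiotropy = None
    if len(all_scans):
        # one row per SNP, ranked by its best sex-difference P across traits
        best = all_scans.sort_values("p_sexdiff").drop_duplicates("snp_id")
        best = best.rename(columns={"p_sexdiff": "p_sexdiff_best"})
        best["p_sexdiff"] = best["p_sexdiff_best"]
        sd_any = set(all_scans.loc[all_scans[pass_col], "snp_id"])
        pruned = ldprune.prune(best, bundle.blocks, "sexdiff_p")
        pruned_df = pruned.snps
        annotated = set(
            bundle.catalog.loc[
                bundle.catalog["trait_label"] == config.pleiotropy_label, "snp_id"
            ]
        )
        is_sd = pruned_df["snp_id"].isin(sd_any).to_numpy()
        is_annot = pruned_df["snp_id"].isin(annotated).to_numpy()
        n_sd = int(is_sd.sum())
        k_sd = int((is_sd & is_annot).sum())
        k_non = int((~is_sd & is_annot).sum())
        fisher_p = coloc.pleiotropy_fisher(k_sd, n_sd, k_non, len(pruned_df) - n_sd)
        perm_p = None
        if n_sd:
            perm_p = coloc.pleiotropy_permutation(
                is_annot, n_sd, k_sd,
                reps=config.reps, seed=_child_seed(config.seed, "pleio_perm"),
            )
        pleiotropy = coloc.PleiotropyReport(
            n_total=len(pruned_df),
            n_sexdiff=n_sd,
            n_annotated_sexdiff=k_sd,
            n_annotated_nonsexdiff=k_non,
            fisher_p=fisher_p,
            perm_p=perm_p,
            n_perm=config.reps,
        )

    # -------------------------------------------------------------- evolution
    families: dict[str, list[evolve.PermutationResult]] = {
        "trait_sds": [], "trait_sds_maf_matched": [], "ihs": [], "genic": [],
        "log2_ratio_perm": [],
    }
    ratio_rows = []
    # dict lookup: positions can recur across variants (multiallelic sites)
    ihs_by_key = {
        (c, p): v
        for c, p, v in zip(bundle.ihs["chrom"], bundle.ihs["pos"], bundle.ihs["abs_ihs"])
    }
    for trait in traits:
        if trait not in scans:
            continue
        res = scans[trait]
        # pool: phenotype-associated SNPs pruned by best GWAS P either sex
        pool_df = res.copy()
        pool_df["p_pheno"] = np.minimum(pool_df["p_f"], pool_df["p_m"])
        pool_pruned = ldprune.prune(pool_df, bundle.blocks, "phenotype_p").snps
        pool_aligned = evolve.align_trait_sds_frame(
            pool_pruned.assign(
                beta_strong=np.where(
                    pool_pruned["stronger_sex"] == "female",
                    pool_pruned["beta_f"], pool_pruned["beta_m"],
                )
            ),
            bundle.sds,
            "beta_strong",
        )
        pool_ratios, _ = evolve.log2_effect_ratios(
            pool_pruned["beta_f"], pool_pruned["beta_m"], pool_pruned["stronger_sex"]
        )
        pool_genic = _genic_flags(pool_pruned, genes, config.gene_window)
        pool_ihs = _ihs_values(pool_pruned, ihs_by_key)
        for sex in ("female", "male"):
            label = f"{trait}:{sex}"
            sd_set = res[res[pass_col] & (res["stronger_sex"] == sex)].copy()
            if len(sd_set) == 0:
                logger.info("%s: no SexDiff SNPs at q<%g; tests skipped",
                            label, config.working_threshold)
                continue
            sd_set["p_sex"] = sd_set["p_f"] if sex == "female" else sd_set["p_m"]
            sd_pruned = ldprune.prune(sd_set, bundle.blocks, "sex_specific_p").snps
            beta_col = "beta_f" if sex == "female" else "beta_m"
            sd_aligned = evolve.align_trait_sds_frame(sd_pruned, bundle.sds, beta_col)
            if len(sd_aligned) == 0 or len(pool_aligned) == 0:
                continue
            seed = _child_seed(config.seed, f"sds:{label}")
            families["trait_sds"].append(
                evolve.subset_vs_pool_permutation(
                    sd_aligned["trait_sds"], pool_aligned["trait_sds"],
                    reps=config.reps, tails=config.tails_sds, seed=seed, label=label,
                )
            )
            if config.run_maf_matched:
                try:
                    families["trait_sds_maf_matched"].append(
                        evolve.maf_matched_permutation(
                            sd_aligned, pool_aligned,
                            value_column="trait_sds",
                            maf_window=config.maf_window,
                            reps=config.reps, tails=config.tails_sds,
                            seed=_child_seed(config.seed, f"sdsmaf:{label}"),
                            label=label,
                        )
                    )
                except evolve.MatchingError as exc:
                    logger.warning("%s: MAF-matched resampling failed: %s", label, exc)
            sd_ihs = _ihs_values(sd_pruned, ihs_by_key)
            if sd_ihs.size and pool_ihs.size:
                families["ihs"].append(
                    evolve.ihs_permutation(
                        sd_ihs, pool_ihs, reps=config.reps, tails=config.tails_sds,
                        seed=_child_seed(config.seed, f"ihs:{label}"), label=label,
                    )
                )
            sd_genic = _genic_flags(sd_pruned, genes, config.gene_window)
            families["genic"].append(
                evolve.genic_intergenic_test(
                    sd_genic, pool_genic, reps=config.reps, tails=config.tails_sds,
                    seed=_child_seed(config.seed, f"genic:{label}"), label=label,
                )
            )
            ratios, n_excl = evolve.log2_effect_ratios(
                sd_pruned["beta_f"], sd_pruned["beta_m"],
                np.full(len(sd_pruned), sex),
            )
            row = {
                "trait": trait, "sex": sex, "n_pruned": len(sd_pruned),
                "n_ratio_excluded": n_excl,
                "mean_log2_ratio": float(np.mean(ratios)) if ratios.size else np.nan,
            }
            direction = "greater" if sex == "female" else "less"
            if ratios.size >= 2 and np.ptp(ratios) > 0:
                row["ttest_p"] = evolve.ratio_ttest(ratios, direction)
            else:
                row["ttest_p"] = np.nan
            if ratios.size and pool_ratios.size >= ratios.size:
                families["log2_ratio_perm"].append(
                    evolve.subset_vs_pool_permutation(
                        ratios, pool_ratios,
                        reps=config.reps, tails=config.tails_ratio,
                        seed=_child_seed(config.seed, f"ratio:{label}"), label=label,
                    )
                )
            ratio_rows.append(row)

    families = {k: evolve.family_fdr(v) for k, v in families.items()}
    ratio_tests = pd.DataFrame(ratio_rows)

    return PipelineResult(
        scans=scans,
        rho=rhos,
        enrichment=enrichment,
        pleiotropy=pleiotropy,
        families=families,
        ratio_tests=ratio_tests,
        summary=summary,
        manifest=manifest,
    )


def _genic_flags(snps: pd.DataFrame, genes: pd.DataFrame, window: int) -> np.ndarray:
    mapping = coloc.map_snps_to_genes(snps, genes, window)
    return np.array([sid in mapping for sid in snps["snp_id"]], dtype=bool)


def _ihs_values(snps: pd.DataFrame, ihs_by_key: dict) -> np.ndarray:
    vals = [
        ihs_by_key.get((c, p), np.nan)
        for c, p in zip(snps["chrom"], snps["pos"])
    ]
    arr = np.asarray(vals, dtype=float)
    return arr[~np.isnan(arr)]
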