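"""Seeded synthetic input bundles with known ground truth.

The generator emulates the statistical structure of sex-stratified GWAS
summary statistics plus the side tables the downstream analyses consume:
a singleton-density-score (SDS) table, an |iHS| table, LD-block
intervals, gene/GO annotations and catalog-style SNP-trait pairs.

The generative model, per SNP:

* MAF ~ Uniform over the configured range.
* A fraction ``frac_assoc`` of SNPs carries a true effect on exactly one
  trait; true female/male effects are bivariate normal with standard
  deviation ``effect_sd`` and correlation ``rho_target``.  At the
  default ``rho_target = 1`` the two sexes share one true effect — the
  exact null of the sex-difference scan for non-sex-differentiated
  SNPs; values below 1 inject diffuse genome-wide heterogeneity.
* A fraction ``frac_sexdiff`` of those additionally get a sex-specific
  magnitude boost of scale ``sexdiff_effect_sd`` in one ("stronger")
  sex, so the boosted sex has the larger absolute effect.
* Observed betas are true betas plus Normal(0, SE) noise, with the
  allele-frequency SE of a quantitative-trait GWAS,
  SE = 1 / sqrt(2 * n_sex * MAF * (1 - MAF)), and two-sided Wald P.
* Raw SDS is standard normal; an optional mean shift is injected on the
  female-stronger sex-differentiated SNPs so that their *trait-aligned*
  SDS rises by ``sds_shift`` in expectation.
* The genome is a single chromosome of ``n_blocks`` equal-width LD
  blocks; genes are tiled uniformly, a fraction flagged with the sexual
  differentiation GO term, and sex-differentiated causal SNPs are
  placed inside flagged-gene windows with a configurable enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as sio
from .io import GO_SEXUAL_DIFFERENTIATION

DEFAULT_TRAITS = (
    "height",
    "body_mass",
    "hip_circumference",
    "body_fat_percent",
    "waist_circumference",
)

#: catalog label used for the pleiotropy analysis
SHBG_LABEL = "sex hormone binding globulin level"

_ALLELES = np.array(list("ACGT"))


class DegenerateConfigError(ValueError):
    """A configuration that cannot produce the requested structure."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic bundle.

    Cohort sizes default to the female/male sample sizes of the
    motivating biobank analysis; effect scales are in trait standard
    deviations per allele.
    """

    n_snps: int = 100_000
    n_traits: int = 5
    n_female: int = 194_174
    n_male: int = 167_020
    maf_dist: tuple[float, float] = (0.05, 0.5)
    frac_assoc: float = 0.05
    frac_sexdiff: float = 0.10
    effect_sd: float = 0.05
    sexdiff_effect_sd: float = 0.02
    rho_target: float = 1.0
    sds_shift: float = 0.0
    n_blocks: int = 1_703
    n_genes: int = 2_570
    frac_go_sexdev: float = 0.02
    sexdiff_placement_enrichment: float = 1.0
    seed: int = 0
    # generator plumbing beyond the headline conditions
    derived_allele_frac: float = 0.5
    block_size: int = 200_000
    gene_span: int = 20_000
    sds_coverage: float = 0.9
    ihs_coverage: float = 0.9
    catalog_rate: float = 0.005
    catalog_enrichment: float = 5.0
    gene_window: int = 10_000

    def __post_init__(self):
        for name in ("frac_assoc", "frac_sexdiff", "frac_go_sexdev",
                     "derived_allele_frac", "sds_coverage", "ihs_coverage",
                     "catalog_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DegenerateConfigError(f"{name}={v} outside [0, 1]")
        lo, hi = self.maf_dist
        if not (0.0 < lo <= hi <= 0.5):
            raise DegenerateConfigError(f"maf_dist={self.maf_dist} outside (0, 0.5]")
        for name in ("n_snps", "n_traits", "n_female", "n_male", "n_blocks", "n_genes"):
            if getattr(self, name) < 1:
                raise DegenerateConfigError(f"{name} must be positive")
        if not -1.0 <= self.rho_target <= 1.0:
            raise DegenerateConfigError("rho_target outside [-1, 1]")
        n_assoc = round(self.frac_assoc * self.n_snps)
        if self.frac_assoc > 0 and n_assoc < 1:
            raise DegenerateConfigError(
                f"frac_assoc={self.frac_assoc} yields no associated SNPs at n_snps={self.n_snps}"
            )
        if self.frac_sexdiff > 0 and n_assoc >= 1 and round(self.frac_sexdiff * n_assoc) < 1:
            raise DegenerateConfigError(
                "frac_sexdiff yields no sex-differentiated SNPs; increase fractions or n_snps"
            )

    @property
    def traits(self) -> tuple[str, ...]:
        if self.n_traits <= len(DEFAULT_TRAITS):
            return DEFAULT_TRAITS[: self.n_traits]
        extra = tuple(f"trait_{i}" for i in range(len(DEFAULT_TRAITS), self.n_traits))
        return DEFAULT_TRAITS + extra

    @property
    def genome_length(self) -> int:
        return self.n_blocks * self.block_size


@dataclass
class Bundle:
    """In-memory synthetic dataset: one frame per on-disk file."""

    config: SimConfig
    sumstats: dict[tuple[str, str], pd.DataFrame]  # (trait, sex) -> frame
    sds: pd.DataFrame
    ihs: pd.DataFrame
    blocks: pd.DataFrame
    genes: pd.DataFrame
    catalog: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        try:
            outdir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create bundle directory {outdir}: {exc}") from exc
        for (trait, sex), df in self.sumstats.items():
            sio.write_sumstats(df, outdir / f"sumstats.{trait}.{sex}.tsv")
        sio.write_sds(self.sds, outdir / "sds.tsv")
        sio.write_ihs(self.ihs, outdir / "ihs.tsv")
        sio.write_blocks(self.blocks, outdir / "blocks.tsv")
        sio.write_genes(self.genes, outdir / "genes.tsv")
        sio.write_catalog(self.catalog, outdir / "catalog.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        return outdir


def _tile_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    spacing = config.genome_length / config.n_genes
    starts = (np.arange(config.n_genes) * spacing).astype(np.int64) + 1
    span = min(config.gene_span, int(spacing) - 1) or 1
    ends = starts + span
    n_flag = round(config.frac_go_sexdev * config.n_genes)
    flagged = np.zeros(config.n_genes, dtype=bool)
    if n_flag:
        flagged[rng.choice(config.n_genes, n_flag, replace=False)] = True
    terms = [
        frozenset({"GO:0008150", GO_SEXUAL_DIFFERENTIATION}) if f else frozenset({"GO:0008150"})
        for f in flagged
    ]
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(config.n_genes)],
            "chrom": "1",
            "start": starts,
            "end": ends,
            "go_terms": terms,
        }
    )


def _place_positions(
    config: SimConfig,
    rng: np.random.Generator,
    is_sexdiff: np.ndarray,
    genes: pd.DataFrame,
) -> np.ndarray:
    """SNP positions: uniform, except sex-differentiated causal SNPs may be
    drawn inside flagged-gene windows with boosted probability."""
    pos = rng.integers(1, config.genome_length + 1, size=config.n_snps)
    flagged = genes[[GO_SEXUAL_DIFFERENTIATION in t for t in genes["go_terms"]]]
    if len(flagged) == 0 or config.sexdiff_placement_enrichment <= 0:
        return pos
    w = config.gene_window
    span = flagged["end"].to_numpy() - flagged["start"].to_numpy() + 2 * w
    base_rate = min(1.0, span.sum() / config.genome_length)
    p_place = min(1.0, base_rate * config.sexdiff_placement_enrichment)
    sd_idx = np.flatnonzero(is_sexdiff)
    place = rng.random(sd_idx.size) < p_place
    for i in sd_idx[place]:
        g = flagged.iloc[int(rng.integers(len(flagged)))]
        lo = max(1, g["start"] - w)
        hi = min(config.genome_length, g["end"] - 1 + w)
        pos[i] = rng.integers(lo, hi + 1)
    return pos


def generate_bundle(config: SimConfig, outdir: str | Path | None = None) -> Bundle:
    """Generate a complete synthetic bundle (and optionally write it).

    Byte-identical for identical (config, seed).  Returns the in-memory
    :class:`Bundle`; ``bundle.truth`` carries the ground-truth labels.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    traits = config.traits

    # --- ground truth -----------------------------------------------------
    n_assoc = round(config.frac_assoc * n)
    assoc_idx = rng.choice(n, n_assoc, replace=False) if n_assoc else np.array([], dtype=int)
    is_assoc = np.zeros(n, dtype=bool)
    is_assoc[assoc_idx] = True
    trait_of = np.full(n, "", dtype=object)
    trait_of[assoc_idx] = [traits[i % len(traits)] for i in range(n_assoc)]

    n_sexdiff = round(config.frac_sexdiff * n_assoc)
    sd_idx = rng.choice(assoc_idx, n_sexdiff, replace=False) if n_sexdiff else np.array([], dtype=int)
    is_sexdiff = np.zeros(n, dtype=bool)
    is_sexdiff[sd_idx] = True
    stronger = np.full(n, "none", dtype=object)
    stronger[sd_idx] = np.where(rng.random(n_sexdiff) < 0.5, "female", "male")

    # true effects on the assigned trait; explicit Cholesky construction so
    # rho_target = 1 (shared-effect null) is exact rather than singular
    z1 = rng.normal(0.0, 1.0, size=n_assoc)
    z2 = rng.normal(0.0, 1.0, size=n_assoc)
    r = config.rho_target
    bf_assoc = config.effect_sd * z1
    bm_assoc = config.effect_sd * (r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * z2)
    true_bf = np.zeros(n)
    true_bm = np.zeros(n)
    true_bf[assoc_idx] = bf_assoc
    true_bm[assoc_idx] = bm_assoc
    boost = np.abs(rng.normal(0.0, config.sexdiff_effect_sd, size=n_sexdiff))
    for i, b in zip(sd_idx, boost):
        if stronger[i] == "female":
            true_bf[i] += np.sign(true_bf[i]) * b if true_bf[i] != 0 else b
        else:
            true_bm[i] += np.sign(true_bm[i]) * b if true_bm[i] != 0 else b

    # --- genome layout ----------------------------------------------------
    genes = _tile_genes(config, rng)
    pos = _place_positions(config, rng, is_sexdiff, genes)
    maf = rng.uniform(config.maf_dist[0], config.maf_dist[1], size=n)
    allele_pair = rng.integers(0, 4, size=(n, 2))
    allele_pair[:, 1] = (allele_pair[:, 0] + 1 + rng.integers(0, 3, size=n)) % 4
    effect_allele = _ALLELES[allele_pair[:, 0]]
    other_allele = _ALLELES[allele_pair[:, 1]]
    snp_id = np.array(
        [f"1:{p}:{o}:{e}" for p, o, e in zip(pos, other_allele, effect_allele)],
        dtype=object,
    )
    # collisions in position are possible but keys must be unique
    dup = pd.Series(snp_id).duplicated(keep=False)
    if dup.any():
        for i in np.flatnonzero(dup.to_numpy()):
            pos[i] = int(pos[i]) + int(rng.integers(1, 50))
            snp_id[i] = f"1:{pos[i]}:{other_allele[i]}:{effect_allele[i]}"

    effect_is_derived = rng.random(n) < config.derived_allele_frac

    # --- SDS / iHS --------------------------------------------------------
    raw_sds = rng.normal(0.0, 1.0, size=n)
    info = rng.uniform(0.9, 1.0, size=n)
    hwe_p = rng.uniform(0.0, 1.0, size=n)

    selection_injected = np.zeros(n, dtype=bool)
    if config.sds_shift != 0.0 and n_sexdiff:
        target = np.flatnonzero(is_sexdiff & (stronger == "female"))
        # shift the raw score so the trait-aligned value rises by sds_shift
        beta_strong = true_bf[target]
        align = np.where(effect_is_derived[target], 1.0, -1.0) * np.where(
            beta_strong < 0, -1.0, 1.0
        )
        raw_sds[target] += config.sds_shift * align
        selection_injected[target] = True

    sds_mask = rng.random(n) < config.sds_coverage
    # always keep associated SNPs scored, so injected signal survives filtering
    sds_mask[assoc_idx] = True
    ancestral = np.where(effect_is_derived, other_allele, effect_allele)
    derived = np.where(effect_is_derived, effect_allele, other_allele)
    sds = pd.DataFrame(
        {
            "snp_id": snp_id[sds_mask],
            "chrom": "1",
            "pos": pos[sds_mask],
            "ancestral_allele": ancestral[sds_mask],
            "derived_allele": derived[sds_mask],
            "maf": maf[sds_mask],
            "sds": raw_sds[sds_mask],
        }
    )

    ihs_mask = rng.random(n) < config.ihs_coverage
    ihs = pd.DataFrame(
        {
            "snp_id": snp_id[ihs_mask],
            "chrom": "1",
            "pos": pos[ihs_mask],
            "abs_ihs": np.abs(rng.normal(0.0, 1.0, size=int(ihs_mask.sum()))),
        }
    )

    # --- summary statistics -----------------------------------------------
    sumstats: dict[tuple[str, str], pd.DataFrame] = {}
    for trait in traits:
        on_trait = trait_of == trait
        for sex, n_cohort in (("female", config.n_female), ("male", config.n_male)):
            se = 1.0 / np.sqrt(2.0 * n_cohort * maf * (1.0 - maf))
            true_b = np.where(on_trait, true_bf if sex == "female" else true_bm, 0.0)
            beta = true_b + rng.normal(0.0, 1.0, size=n) * se
            z = beta / se
            pval = 2.0 * stats.norm.sf(np.abs(z))
            sumstats[(trait, sex)] = pd.DataFrame(
                {
                    "snp_id": snp_id,
                    "chrom": "1",
                    "pos": pos,
                    "effect_allele": effect_allele,
                    "other_allele": other_allele,
                    "maf": maf,
                    "info": info,
                    "hwe_p": hwe_p,
                    "beta": beta,
                    "se": se,
                    "pval": pval,
                }
            )

    # --- LD blocks ----------------------------------------------------------
    starts = np.arange(config.n_blocks, dtype=np.int64) * config.block_size + 1
    blocks = pd.DataFrame(
        {
            "chrom": "1",
            "start": starts,
            "end": starts + config.block_size,
            "block_id": [f"B{i:05d}" for i in range(config.n_blocks)],
        }
    )

    # --- catalog annotations -------------------------------------------------
    p_annot = np.where(
        is_sexdiff,
        min(1.0, config.catalog_rate * config.catalog_enrichment),
        config.catalog_rate,
    )
    annotated = rng.random(n) < p_annot
    catalog = pd.DataFrame(
        {"snp_id": snp_id[annotated], "trait_label": SHBG_LABEL}
    )

    truth = pd.DataFrame(
        {
            "snp_id": snp_id,
            "trait": trait_of,
            "is_associated": is_assoc,
            "is_sexdiff": is_sexdiff,
            "stronger_sex": stronger,
            "true_beta_f": true_bf,
            "true_beta_m": true_bm,
            "selection_injected": selection_injected,
        }
    )

    bundle = Bundle(
        config=config,
        sumstats=sumstats,
        sds=sds,
        ihs=ihs,
        blocks=blocks,
        genes=genes,
        catalog=catalog,
        truth=truth,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def load_bundle(indir: str | Path, traits: tuple[str, ...]) -> Bundle:
    """Read a written bundle back through the standard readers."""
    indir = Path(indir)
    sumstats = {
        (trait, sex): sio.read_sumstats(indir / f"sumstats.{trait}.{sex}.tsv", sex, trait)
        for trait in traits
        for sex in ("female", "male")
    }
    truth_path = indir / "truth.tsv"
    truth = (
        pd.read_csv(truth_path, sep="\t", dtype={"snp_id": str})
        if truth_path.exists()
        else pd.DataFrame()
    )
    return Bundle(
        config=None,  # type: ignore[arg-type]
        sumstats=sumstats,
        sds=sio.read_sds(indir / "sds.tsv"),
        ihs=sio.read_ihs(indir / "ihs.tsv"),
        blocks=sio.read_blocks(indir / "blocks.tsv"),
        genes=sio.read_genes(indir / "genes.tsv"),
        catalog=sio.read_catalog(indir / "catalog.tsv"),
        truth=truth,
    )


def inject_selection(
    sds_table: pd.DataFrame,
    snp_subset,
    shift: float,
    align_sign=None,
) -> pd.DataFrame:
    """Shift raw SDS so trait-aligned values rise by ``shift`` in expectation.

    ``align_sign`` maps each subset SNP to ±1, the factor converting a
    raw-SDS increment into a trait-SDS increment for that SNP (it is +1
    when the trait-increasing allele is the derived allele); default +1
    for all.  Returns a new table; rows outside the subset are untouched.

    Raises ``KeyError`` listing ids absent from the table.
    """
    subset = list(snp_subset)
    out = sds_table.copy()
    if not subset or shift == 0.0:
        return out
    idx = out.set_index("snp_id").index
    missing = [s for s in subset if s not in idx]
    if missing:
        raise KeyError(f"SNP id(s) not in SDS table: {', '.join(map(str, missing[:10]))}")
    if align_sign is None:
        align = {s: 1.0 for s in subset}
    elif isinstance(align_sign, dict):
        align = align_sign
    else:
        align = dict(zip(subset, np.asarray(align_sign, dtype=float)))
    delta = out["snp_id"].map(lambda s: shift * align.get(s, 0.0)).fillna(0.0)
    out["sds"] = out["sds"] + delta
    return out
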