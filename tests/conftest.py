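import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sexdiffscan import SimConfig, generate_bundle

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def signal_bundle():
    """Bundle with injected sex-specific effects, GO placement enrichment
    and catalog enrichment — the shared 'there is something to find' dataset."""
    cfg = SimConfig(
        n_snps=20_000,
        frac_assoc=0.08,
        frac_sexdiff=0.30,
        sexdiff_effect_sd=0.04,
        frac_go_sexdev=0.05,
        sexdiff_placement_enrichment=8.0,
        catalog_enrichment=10.0,
        seed=11,
    )
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def null_bundle():
    """Bundle with associated SNPs but no sex-differentiated effects."""
    cfg = SimConfig(n_snps=20_000, frac_assoc=0.10, frac_sexdiff=0.0, seed=23)
    return generate_bundle(cfg)


def toy_sumstats(rows, sex=None, trait=None):
    """Build a sumstats frame from (snp_id, maf, info, hwe_p, beta, se, pval)."""
    recs = []
    for snp_id, maf, info, hwe_p, beta, se, pval in rows:
        chrom, pos, other, effect = snp_id.split(":")
        recs.append(
            dict(
                snp_id=snp_id, chrom=chrom, pos=int(pos),
                effect_allele=effect, other_allele=other,
                maf=maf, info=info, hwe_p=hwe_p, beta=beta, se=se, pval=pval,
            )
        )
    df = pd.DataFrame(recs)
    if sex is not None:
        df["sex"] = sex
    if trait is not None:
        df["trait"] = trait
    return df


def toy_blocks(spans):
    """Blocks from (chrom, start, end) triples."""
    return pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e, "block_id": f"B{i}"}
            for i, (c, s, e) in enumerate(spans)
        ]
    )


def toy_genes(spans):
    """Genes from (gene_id, chrom, start, end, go_terms-set) tuples."""
    return pd.DataFrame(
        [
            {"gene_id": g, "chrom": c, "start": s, "end": e, "go_terms": frozenset(t)}
            for g, c, s, e, t in spans
        ]
    )
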