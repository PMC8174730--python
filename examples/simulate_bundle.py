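"""Generate a synthetic sex-stratified GWAS bundle and inspect its truth.

The generator emits per-trait/per-sex summary statistics, SDS and |iHS|
score tables, LD blocks, gene/GO annotations and catalog pairs, plus
ground-truth labels for every SNP.
"""

from sexdiffscan import SimConfig, generate_bundle

cfg = SimConfig(n_snps=10_000, frac_assoc=0.08, frac_sexdiff=0.25, seed=1)
bundle = generate_bundle(cfg)

truth = bundle.truth
print(f"SNPs simulated:            {len(truth)}")
print(f"truly trait-associated:    {truth.is_associated.sum()}")
print(f"truly sex-differentiated:  {truth.is_sexdiff.sum()}")
print(f"  of which female-stronger: {(truth.stronger_sex == 'female').sum()}")
print(f"SNPs with an SDS score:    {len(bundle.sds)}")
print(f"LD blocks / genes:         {len(bundle.blocks)} / {len(bundle.genes)}")

# The SE of each sex's effect estimate follows the allele-frequency form
# 1/sqrt(2*n*MAF*(1-MAF)); a SNP at MAF 0.25 in ~194k females:
df = bundle.sumstats[("height", "female")]
row = df.iloc[(df["maf"] - 0.25).abs().argmin()]
print(f"example SE at MAF {row['maf']:.3f}: {row['se']:.5f} trait SD per allele")
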