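import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sexdiffscan import (
    gene_permutation_test,
    genes_hit,
    go_enrichment,
    map_snps_to_genes,
    pleiotropy_fisher,
    pleiotropy_permutation,
)
from sexdiffscan.io import GO_SEXUAL_DIFFERENTIATION as GO_SD

from conftest import toy_genes

REPS = 10_000


def mc_band(p_exact: float) -> float:
    """Three Monte Carlo standard errors of an empirical proportion."""
    return 3 * np.sqrt(p_exact * (1 - p_exact) / REPS)


def snp_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


class TestMapping:
    GENES = toy_genes([("g1", "1", 50_000, 60_000, {"GO:1"})])

    def test_boundary_at_exactly_window_is_mapped(self):
        # gene occupies [50000, 60000): last base 59999, +10kb -> 69999
        got = map_snps_to_genes(snp_frame([("a", "1", 69_999)]), self.GENES)
        assert got == {"a": frozenset({"g1"})}

    def test_one_bp_past_window_is_unmapped(self):
        assert map_snps_to_genes(snp_frame([("a", "1", 70_000)]), self.GENES) == {}

    def test_upstream_window_boundary(self):
        assert "a" in map_snps_to_genes(snp_frame([("a", "1", 40_000)]), self.GENES)
        assert map_snps_to_genes(snp_frame([("a", "1", 39_999)]), self.GENES) == {}

    def test_hand_mapping_with_overlapping_windows(self):
        genes = toy_genes(
            [
                ("g1", "1", 10_000, 20_000, set()),
                ("g2", "1", 25_000, 35_000, set()),
                ("g3", "2", 10_000, 20_000, set()),
            ]
        )
        snps = snp_frame(
            [("s1", "1", 14_000), ("s2", "1", 22_000), ("s3", "1", 80_000), ("s4", "2", 5_000)]
        )
        got = map_snps_to_genes(snps, genes)
        assert got == {
            "s1": frozenset({"g1"}),  # 1 bp short of g2's upstream window
            "s2": frozenset({"g1", "g2"}),  # within 10kb of both
            "s4": frozenset({"g3"}),
        }

    def test_gene_counting_is_snp_multiplicity_invariant(self):
        snps = snp_frame([("s1", "1", 55_000), ("s2", "1", 55_001)])
        mapping = map_snps_to_genes(snps, self.GENES)
        assert genes_hit(mapping, ["s1"]) == genes_hit(mapping, ["s1", "s2"])


class TestEnrichmentRatio:
    def test_printed_counts_reproduce_reported_ratio(self):
        sd = {f"a{i}" for i in range(162)}
        non = {f"b{i}" for i in range(2_544)}
        go = {f"a{i}" for i in range(9)} | {f"b{i}" for i in range(52)}
        rep = go_enrichment(sd, non, go)
        assert rep.prop_sexdiff_rounded == 0.0556
        assert rep.prop_nonsexdiff_rounded == 0.0204
        assert rep.ratio_rounded == 2.73

    def test_identical_sets_give_unit_ratio(self):
        s = {"a", "b", "c", "d"}
        rep = go_enrichment(s, s, {"a"})
        assert rep.ratio == pytest.approx(1.0)

    def test_zero_numerator_gives_zero_ratio(self):
        rep = go_enrichment({f"a{i}" for i in range(50)}, {f"b{i}" for i in range(100)},
                            {f"b{i}" for i in range(5)})
        assert rep.prop_sexdiff == 0.0 and rep.ratio == 0.0

    def test_empty_nonsexdiff_set_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            go_enrichment({"a"}, set(), {"a"})


class TestGenePermutation:
    def test_matches_hypergeometric_tail(self):
        pool = [f"g{i}" for i in range(20)]
        go = set(pool[:5])
        exact = stats.hypergeom.sf(3, 20, 5, 4)  # P(X >= 4) = 5/4845
        p = gene_permutation_test(pool, go, n_draw=4, observed_go_count=4, reps=REPS, seed=1)
        assert abs(p - exact) <= mc_band(exact) + 1e-12

    def test_observed_zero_is_certain(self):
        pool = [f"g{i}" for i in range(10)]
        assert gene_permutation_test(pool, {"g0"}, 3, 0, reps=200, seed=0) == 1.0

    def test_fully_flagged_pool_is_certain(self):
        pool = [f"g{i}" for i in range(10)]
        assert gene_permutation_test(pool, set(pool), 4, 4, reps=200, seed=0) == 1.0

    def test_observed_above_draw_is_error(self):
        with pytest.raises(ValueError):
            gene_permutation_test(["a", "b"], {"a"}, 1, 2, reps=10, seed=0)


class TestPleiotropyFisher:
    def test_printed_table_reproduces_reported_p(self):
        assert pleiotropy_fisher(3, 117, 4, 576) == pytest.approx(0.098, abs=5e-4)

    def test_empty_annotations_give_one(self):
        assert pleiotropy_fisher(0, 10, 0, 10) == pytest.approx(1.0)

    def test_full_enumeration_of_extreme_table(self):
        assert pleiotropy_fisher(5, 5, 0, 5) == pytest.approx(2 / 252, rel=1e-9)

    def test_doubling_convention_available(self):
        p = pleiotropy_fisher(5, 5, 0, 5, convention="double")
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            pleiotropy_fisher(5, 3, 0, 5)


class TestPleiotropyPermutation:
    def test_no_flags_observed_zero_is_certain(self):
        assert pleiotropy_permutation(np.zeros(20, bool), 5, 0, reps=200, seed=0) == 1.0

    def test_small_closed_form(self):
        flags = np.array([True, True] + [False] * 8)
        exact = 56 / 252  # C(2,2)C(8,3)/C(10,5)
        p = pleiotropy_permutation(flags, 5, 2, reps=REPS, seed=2)
        assert abs(p - exact) <= mc_band(exact)

    @pytest.mark.parametrize(
        "n_pool,n_flag,n_draw,observed",
        [(693, 7, 117, 3), (50, 10, 12, 4), (30, 15, 10, 8)],
    )
    def test_matches_hypergeometric_generally(self, n_pool, n_flag, n_draw, observed):
        flags = np.zeros(n_pool, bool)
        flags[:n_flag] = True
        exact = stats.hypergeom.sf(observed - 1, n_pool, n_flag, n_draw)
        p = pleiotropy_permutation(flags, n_draw, observed, reps=REPS, seed=3)
        assert abs(p - exact) <= mc_band(exact)


class TestEnrichmentOnSyntheticBundles:
    def test_placement_enrichment_raises_observed_ratio(self, signal_bundle):
        """Sex-differentiated causal SNPs placed near flagged genes should
        produce an enrichment ratio above the neutral-placement value."""
        from sexdiffscan import SimConfig, generate_bundle, go_term_genes

        def observed_ratio(bundle):
            truth = bundle.truth
            genes = bundle.genes
            sd = truth.loc[truth.is_sexdiff, "snp_id"]
            non = truth.loc[truth.is_associated & ~truth.is_sexdiff, "snp_id"]
            frame = bundle.sumstats[list(bundle.sumstats)[0]][["snp_id", "chrom", "pos"]]
            mapping = map_snps_to_genes(frame, genes)
            rep = go_enrichment(
                genes_hit(mapping, sd), genes_hit(mapping, non), go_term_genes(genes)
            )
            return rep.ratio

        flat = generate_bundle(
            SimConfig(
                n_snps=20_000, frac_assoc=0.08, frac_sexdiff=0.30,
                frac_go_sexdev=0.05, sexdiff_placement_enrichment=1.0, seed=11,
            )
        )
        assert observed_ratio(signal_bundle) > observed_ratio(flat)
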