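import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sexdiffscan import (
    align_trait_sds,
    align_trait_sds_frame,
    family_fdr,
    genic_intergenic_test,
    ihs_permutation,
    log2_effect_ratios,
    maf_matched_permutation,
    ratio_ttest,
    subset_vs_pool_permutation,
)
from sexdiffscan.evolve import MatchingError, PermutationResult

REPS = 10_000


def mc_band(p):
    return 3 * np.sqrt(p * (1 - p) / REPS)


class TestLog2Ratios:
    def test_equal_betas_give_zero(self):
        r, n = log2_effect_ratios([0.2], [0.2])
        assert r.tolist() == [0.0] and n == 0

    def test_doubling_gives_one(self):
        r, _ = log2_effect_ratios([0.4], [0.2])
        assert r.tolist() == pytest.approx([1.0])

    def test_quarter_gives_minus_two(self):
        r, _ = log2_effect_ratios([0.1], [0.4])
        assert r.tolist() == pytest.approx([-2.0])

    def test_negative_anchor_is_reoriented(self):
        # female-stronger SNP with negative female beta: both flipped
        r, n = log2_effect_ratios([-0.4], [-0.2], ["female"])
        assert r.tolist() == pytest.approx([1.0]) and n == 0

    def test_discordant_sign_pairs_excluded_and_counted(self):
        r, n = log2_effect_ratios([0.4, 0.3], [-0.2, 0.3], ["female", "female"])
        assert n == 1 and r.tolist() == pytest.approx([0.0])

    def test_zero_beta_excluded(self):
        r, n = log2_effect_ratios([0.4, 0.0], [0.2, 0.2])
        assert n == 1 and len(r) == 1


class TestRatioTTest:
    def test_hand_computed_t(self):
        # mean 1.0, sd 0.5: t = 3.464 on 2 df, one-sided P ~ 0.0371
        assert ratio_ttest([0.5, 1.5, 1.0], "greater") == pytest.approx(0.0371, abs=2e-4)

    def test_all_zero_is_boundary_half(self):
        assert ratio_ttest([0.0, 0.0, 0.0], "greater") == 0.5

    def test_constant_nonzero_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            ratio_ttest([1.0, 1.0, 1.0, 1.0], "greater")

    def test_direction_flips_tail(self):
        p_hi = ratio_ttest([0.5, 1.5, 1.0], "greater")
        p_lo = ratio_ttest([0.5, 1.5, 1.0], "less")
        assert p_hi + p_lo == pytest.approx(1.0)


class TestAlignTraitSds:
    @pytest.mark.parametrize(
        "sds,is_derived,beta,expected",
        [
            (1.2, True, 0.5, 1.2),    # effect = derived, trait-increasing
            (1.2, False, 0.5, -1.2),  # effect = ancestral: flip
            (-0.8, True, -0.5, 0.8),  # negative beta: flip again
            (-0.8, False, -0.5, -0.8),
        ],
    )
    def test_sign_fixing(self, sds, is_derived, beta, expected):
        assert align_trait_sds(sds, is_derived, beta) == pytest.approx(expected)

    def test_magnitude_preserved(self):
        rng = np.random.default_rng(0)
        sds = rng.normal(size=50)
        out = align_trait_sds(sds, rng.random(50) < 0.5, rng.normal(size=50))
        assert np.abs(out) == pytest.approx(np.abs(sds))

    def test_allele_mismatch_dropped(self, caplog):
        snps = pd.DataFrame(
            {
                "snp_id": ["a", "b"], "chrom": "1", "pos": [10, 20],
                "effect_allele": ["G", "T"], "beta_f": [0.5, 0.5],
            }
        )
        sds = pd.DataFrame(
            {
                "snp_id": ["a", "b"], "chrom": "1", "pos": [10, 20],
                "ancestral_allele": ["A", "A"], "derived_allele": ["G", "C"],
                "sds": [1.0, 1.0],
            }
        )
        with caplog.at_level("WARNING"):
            out = align_trait_sds_frame(snps, sds, "beta_f")
        assert out["snp_id"].tolist() == ["a"]
        assert "neither SDS allele" in caplog.text


class TestSubsetVsPool:
    def test_exhaustive_pair_enumeration(self):
        # pool {0,1,2,3}, draws of 2: only {2,3} has mean >= 2.5
        res = subset_vs_pool_permutation([2.5, 2.5], [0, 1, 2, 3], reps=REPS, seed=4)
        assert abs(res.p - 1 / 3) <= 2 * mc_band(1 / 6)

    def test_subset_equal_to_pool_is_certain(self):
        res = subset_vs_pool_permutation([1, 2, 3], [1, 2, 3], reps=500, seed=0)
        assert res.p == 1.0

    def test_null_subset_is_unremarkable(self):
        rng = np.random.default_rng(8)
        pool = rng.normal(size=200)
        res = subset_vs_pool_permutation(pool[:20], pool, reps=2000, seed=1)
        assert res.p > 0.05

    def test_floor_flag_when_no_exceedances(self):
        # observed mean 2.0 exceeds every pool value: no replicate can match
        pool = list(np.zeros(100)) + [1.0]
        res = subset_vs_pool_permutation([2.0], pool, reps=500, seed=0)
        assert res.floored and res.p == 0.0 and res.p_text().startswith("<")

    def test_empty_subset_is_error(self):
        with pytest.raises(ValueError):
            subset_vs_pool_permutation([], [1, 2], reps=10, seed=0)


def _frame(values, mafs):
    return pd.DataFrame({"trait_sds": values, "maf": mafs})


class TestMafMatched:
    def test_vacuous_matching_equals_unmatched(self):
        rng = np.random.default_rng(9)
        pool_vals = rng.normal(size=60)
        sub_vals = rng.normal(1.0, 1.0, size=6)
        plain = subset_vs_pool_permutation(sub_vals, pool_vals, reps=REPS, seed=5)
        matched = maf_matched_permutation(
            _frame(sub_vals, [0.2] * 6), _frame(pool_vals, [0.2] * 60),
            reps=REPS, seed=6,
        )
        assert abs(plain.p - matched.p) <= 2 * mc_band(max(plain.p, 1 / REPS)) + 0.02

    def test_window_constrains_draws(self):
        # only the MAF-0.10 pool SNP is ever drawable
        res = maf_matched_permutation(
            _frame([5.0], [0.10]), _frame([7.0, -3.0], [0.10, 0.40]),
            reps=200, seed=0,
        )
        # every replicate mean is exactly 7.0; observed 5.0 vs pool mean 2.0 (upper tail)
        assert res.n_extreme == 200 and res.p == 1.0

    def test_enumeration_oracle_two_subset_three_pool(self):
        # subset MAFs (0.1, 0.4); pool MAFs (0.1, 0.12, 0.4), values (1, 3, 5)
        # legal replicate means: (1+5)/2=3 or (3+5)/2=4, equally likely;
        # observed mean 3.5 > pool mean 3 -> one-tail P = 1/2, doubled to 1
        res = maf_matched_permutation(
            _frame([3.0, 4.0], [0.1, 0.4]),
            _frame([1.0, 3.0, 5.0], [0.1, 0.12, 0.4]),
            reps=REPS, seed=7,
        )
        assert abs(res.n_extreme / REPS - 0.5) <= mc_band(0.5)
        assert res.p == 1.0

    def test_no_match_in_window_is_error(self):
        with pytest.raises(MatchingError, match="window"):
            maf_matched_permutation(
                _frame([1.0], [0.05]), _frame([1.0], [0.4]), reps=10, seed=0
            )


class TestIhsPermutation:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(10)
        pool = np.abs(rng.normal(size=300))
        res = ihs_permutation(pool[:30], pool, reps=2000, seed=2)
        assert res.p > 0.05

    def test_strong_shift_hits_floor(self):
        rng = np.random.default_rng(11)
        pool = np.abs(rng.normal(size=300))
        res = ihs_permutation(pool[:15] + 2.0, pool, reps=2000, seed=3)
        assert res.floored and res.p == 0.0

    def test_missing_scores_rejected(self):
        with pytest.raises(ValueError, match="iHS"):
            ihs_permutation([1.0, np.nan], [1.0, 2.0], reps=10, seed=0)


class TestGenicIntergenic:
    def test_all_genic_pool_is_certain(self):
        res = genic_intergenic_test([True, True], [True] * 20, reps=500, seed=0)
        assert res.observed_stat == 0.0 and res.p == 1.0

    def test_hypergeometric_closed_form(self):
        # pool: 4 intergenic of 10; subset of 3 all intergenic
        pool = [False] * 4 + [True] * 6
        exact = stats.hypergeom.sf(2, 10, 4, 3)  # 4/120
        res = genic_intergenic_test([False] * 3, pool, reps=REPS, seed=8)
        assert abs(res.p - 2 * exact) <= 2 * mc_band(exact)

    def test_subset_equal_to_pool_is_certain(self):
        flags = [True, False, True, False]
        res = genic_intergenic_test(flags, flags, reps=500, seed=0)
        assert res.p == 1.0


class TestFamilyFdr:
    def _results(self, pvals):
        return [
            PermutationResult(
                label=f"t{i}", observed_stat=0.0, pool_size=10, subset_size=2,
                reps=100, n_extreme=1, p=p, tails=2,
            )
            for i, p in enumerate(pvals)
        ]

    def test_reported_minimum_q(self):
        pvals = [0.0038] + [0.5 + 0.05 * i for i in range(9)]
        fam = family_fdr(self._results(pvals))
        assert fam[0].q == pytest.approx(0.038)

    def test_equal_ps_share_q(self):
        fam = family_fdr(self._results([0.2] * 10))
        assert all(r.q == pytest.approx(0.2) for r in fam)

    def test_hand_bh_on_ten_values(self):
        pvals = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        fam = family_fdr(self._results(pvals))
        m = 10
        raw = [p * m / (i + 1) for i, p in enumerate(pvals)]
        expect = [min(raw[i:]) for i in range(m)]
        assert [r.q for r in fam] == pytest.approx(expect)
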