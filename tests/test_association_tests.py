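import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trioassoc.association_tests import (
    PowerParams,
    allelic_power,
    allelic_test,
    best_model,
    genotypic_test,
    maxT_permutation,
    multigroup_allele_test,
    table_test,
)
from trioassoc.genotypes_io import GenotypeCounts
from trioassoc.synthetic_cohort import DiseaseModel, simulate_case_control, simulate_haplotype_pool

from helpers import cohort_from_dosages, exhaustive_maxt_oracle, pearson_chi2_2x2

cells = st.integers(1, 200)


class TestAllelic:
    def test_equal_frequencies_give_null_result(self):
        r = allelic_test(GenotypeCounts(10, 20, 10), GenotypeCounts(20, 40, 20))
        assert r.or_hat == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_odds_ratio_is_the_cross_product(self):
        r = table_test(10, 90, 20, 80)
        assert r.or_hat == pytest.approx(10 * 80 / (90 * 20))

    def test_degenerate_margin_flagged_not_crashed(self):
        r = table_test(0, 0, 10, 10)
        assert r.flagged and math.isnan(r.p)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_group_swap_inverts_or_and_preserves_p(self, a, b, c, d):
        r1 = table_test(a, b, c, d)
        r2 = table_test(c, d, a, b)
        assert r2.or_hat == pytest.approx(1 / r1.or_hat)
        assert r2.chi2 == pytest.approx(r1.chi2)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_allele_swap_inverts_or_and_preserves_p(self, a, b, c, d):
        r1 = table_test(a, b, c, d)
        r2 = table_test(b, a, d, c)
        assert r2.or_hat == pytest.approx(1 / r1.or_hat)
        assert r2.p == pytest.approx(r1.p)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_chi2_matches_expected_count_formulation(self, a, b, c, d):
        assert table_test(a, b, c, d).chi2 == pytest.approx(pearson_chi2_2x2(a, b, c, d))


class TestGenotypic:
    def test_recessive_zero_cell_uses_haldane_and_flags(self):
        r = genotypic_test(GenotypeCounts(0, 30, 70), GenotypeCounts(0, 25, 75), "recessive")
        assert r.flagged and r.or_hat > 0

    def test_dominant_equals_recessive_without_heterozygotes(self):
        case = GenotypeCounts(30, 0, 70)
        ctrl = GenotypeCounts(20, 0, 80)
        dom = genotypic_test(case, ctrl, "dominant")
        rec = genotypic_test(case, ctrl, "recessive")
        assert dom.or_hat == pytest.approx(rec.or_hat)
        assert dom.p == pytest.approx(rec.p)

    def test_recessive_on_published_genotype_rows(self):
        # printed genotype counts: cases TT 66 / TG 271 / GG 179,
        # controls TT 47 / TG 118 / GG 67 -> OR (66*185)/(450*47)
        r = genotypic_test(GenotypeCounts(66, 271, 179), GenotypeCounts(47, 118, 67), "recessive")
        assert r.or_hat == pytest.approx(66 * 185 / (450 * 47))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            genotypic_test(GenotypeCounts(1, 1, 1), GenotypeCounts(1, 1, 1), "additive")


class TestBestModel:
    def make(self, model, p):
        import dataclasses

        return dataclasses.replace(table_test(10, 90, 20, 80), model=model, p=p)

    def test_single_candidate_returned(self):
        only = self.make("allelic", 0.04)
        assert best_model([only]) is only

    def test_smallest_p_wins(self):
        picked = best_model([self.make("allelic", 0.04), self.make("recessive", 0.003)])
        assert picked.model == "recessive"

    def test_tie_broken_by_model_precedence(self):
        picked = best_model(
            [self.make("recessive", 0.01), self.make("dominant", 0.01), self.make("allelic", 0.01)]
        )
        assert picked.model == "allelic"


class TestMultigroup:
    def test_identical_groups_give_p_one(self):
        c = GenotypeCounts(10, 20, 10)
        chi2, df, p = multigroup_allele_test([c, c, c])
        assert df == 2 and p == pytest.approx(1.0)

    def test_two_groups_reduce_to_allelic_test(self):
        a, b = GenotypeCounts(15, 40, 45), GenotypeCounts(30, 50, 20)
        chi2, df, _ = multigroup_allele_test([a, b])
        assert df == 1
        assert chi2 == pytest.approx(allelic_test(a, b).chi2)

    def test_three_groups_match_direct_pearson_formula(self):
        counts = [GenotypeCounts(10, 30, 60), GenotypeCounts(12, 28, 60), GenotypeCounts(30, 40, 30)]
        chi2, df, p = multigroup_allele_test(counts)
        obs = np.array([[c.allele_count_minor, c.allele_count_major] for c in counts], float)
        exp = obs.sum(1, keepdims=True) @ obs.sum(0, keepdims=True) / obs.sum()
        assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum())
        assert df == 2

    def test_degenerate_margin_flagged(self):
        chi2, df, p = multigroup_allele_test([GenotypeCounts(0, 0, 0), GenotypeCounts(1, 1, 1)])
        assert math.isnan(p)


class TestMaxT:
    def test_exhaustive_mode_matches_enumeration_oracle(self, rng):
        dosages = rng.integers(0, 3, size=(6, 2)).astype(np.int8)
        cohort = cohort_from_dosages(dosages, ["CASE"] * 3 + ["CONTROL"] * 3)
        res = maxT_permutation(cohort, exhaustive=True)
        expected = exhaustive_maxt_oracle(dosages, 3)
        assert np.allclose(res.adjusted_p, expected)

    def test_random_sampling_converges_to_exhaustive(self, rng):
        dosages = rng.integers(0, 3, size=(10, 3)).astype(np.int8)
        cohort = cohort_from_dosages(dosages, ["CASE"] * 5 + ["CONTROL"] * 5)
        exact = maxT_permutation(cohort, exhaustive=True).adjusted_p
        sampled = maxT_permutation(cohort, n_perm=5_000, seed=1).adjusted_p
        assert np.allclose(sampled, exact, atol=0.03)

    def test_constant_marker_gets_adjusted_p_one(self):
        dosages = np.column_stack([np.ones(8), [0, 1, 2, 0, 1, 2, 0, 1]]).astype(np.int8)
        cohort = cohort_from_dosages(dosages, ["CASE"] * 4 + ["CONTROL"] * 4)
        res = maxT_permutation(cohort, n_perm=200, seed=2)
        assert res.adjusted_p[0] == 1.0

    def test_adjusted_p_bounds_and_monotonicity(self, rng):
        dosages = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        cohort = cohort_from_dosages(dosages, ["CASE"] * 20 + ["CONTROL"] * 20)
        res = maxT_permutation(cohort, n_perm=500, seed=3)
        assert (res.adjusted_p >= 1 / 501).all() and (res.adjusted_p <= 1).all()
        order = np.argsort(-res.raw_chi2)
        assert (np.diff(res.adjusted_p[order]) >= -1e-12).all()

    def test_rejects_empty_sides_and_bad_n_perm(self):
        cohort = cohort_from_dosages(np.zeros((4, 1), dtype=np.int8), ["CASE"] * 4)
        with pytest.raises(ValueError):
            maxT_permutation(cohort, n_perm=100)
        with pytest.raises(ValueError):
            maxT_permutation(
                cohort_from_dosages(np.zeros((4, 1), dtype=np.int8), ["CASE"] * 2 + ["CONTROL"] * 2),
                n_perm=0,
            )


def test_allelic_type_one_error_is_nominal_under_null():
    """Null simulations: rejection rate at alpha=0.05 within 2 binomial SE."""
    pool = simulate_haplotype_pool([(0.4, 0)], 20_000, 0.0, seed=41)
    model = DiseaseModel()
    reps = 2_000
    rejections = 0
    for i in range(reps):
        cohort = simulate_case_control(pool, model, 250, 250, seed=100_000 + i)
        case = GenotypeCounts.from_dosages(cohort.dosages("snp1", ("CASE",)))
        ctrl = GenotypeCounts.from_dosages(cohort.dosages("snp1", ("CONTROL",)))
        if allelic_test(case, ctrl).p < 0.05:
            rejections += 1
    se = math.sqrt(0.05 * 0.95 / reps)
    assert rejections / reps == pytest.approx(0.05, abs=2 * se)


class TestPower:
    def test_null_odds_ratio_gives_power_alpha(self):
        p = allelic_power(PowerParams(500, 500, 0.4, 1.0, alpha=0.05))
        assert p == pytest.approx(0.05, abs=1e-9)

    @pytest.mark.parametrize(
        "n_case, expected",
        [(541, 90), (298, 72), (134, 36), (109, 28)],
    )
    def test_reproduces_published_power_percentages(self, n_case, expected):
        power = allelic_power(PowerParams(n_case, 488, 0.4, 1.5, 0.001))
        assert round(100 * power) == expected

    def test_monotone_in_sample_size_effect_and_alpha(self):
        base = PowerParams(200, 200, 0.4, 1.5, 0.01)
        p0 = allelic_power(base)
        assert allelic_power(PowerParams(400, 400, 0.4, 1.5, 0.01)) > p0
        assert allelic_power(PowerParams(200, 200, 0.4, 2.0, 0.01)) > p0
        assert allelic_power(PowerParams(200, 200, 0.4, 1.5, 0.05)) > p0
        # monotone in |ln psi| on the protective side too
        assert allelic_power(PowerParams(200, 200, 0.4, 0.5, 0.01)) > allelic_power(
            PowerParams(200, 200, 0.4, 1 / 1.5, 0.01)
        )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PowerParams(100, 100, 0.0, 1.5)
        with pytest.raises(ValueError):
            PowerParams(100, 100, 0.4, -1.0)
        with pytest.raises(ValueError):
            PowerParams(100, 100, 0.4, 1.5, alpha=0.0)
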