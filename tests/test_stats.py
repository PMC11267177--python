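"""Odds ratios, alpha index, prevalence, weight normalisation, selection."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from pjindex import (
    TwoByTwo,
    alpha_index,
    contingency,
    odds_ratio,
    prevalence,
    select_feature_set,
    t_critical,
    tscore,
    zscore_normalize,
)

from conftest import manual_cohort, random_table

cells = st.integers(min_value=1, max_value=2000)


class TestContingency:
    def test_reproduces_worked_two_by_two(self, table1_cohort):
        t = contingency(table1_cohort, "514")
        assert (t.a, t.b, t.c, t.d) == (20, 2, 80, 98)
        t = contingency(table1_cohort, "427")
        assert (t.a, t.b, t.c, t.d) == (40, 6, 60, 94)

    def test_absent_code_gives_empty_margin(self, table1_cohort):
        t = contingency(table1_cohort, "999")
        assert (t.a, t.b, t.c, t.d) == (0, 0, 100, 100)

    def test_matches_brute_force_membership_scan(self, small_sim):
        _, _, _, cohort = small_sim
        for code in ["514", "427", "250", "780"]:
            t = contingency(cohort, code)
            a = sum(code in cohort.codes_of(s) for s in cohort.case_ids)
            b = sum(code in cohort.codes_of(s) for s in cohort.control_ids)
            assert (t.a, t.b) == (a, b)
            assert t.n == len(cohort)


class TestOddsRatio:
    def test_uncorrected_worked_values(self):
        assert odds_ratio(TwoByTwo(20, 2, 80, 98), correction=0) == pytest.approx(12.25)
        assert round(odds_ratio(TwoByTwo(40, 6, 60, 94), correction=0), 1) == 10.4

    @pytest.mark.parametrize(
        "table, expected",
        [
            (TwoByTwo(248, 21, 8249, 21043), 29.48345),
            (TwoByTwo(738, 161, 7759, 20903), 12.31865),
            (TwoByTwo(247, 91, 8250, 20973), 6.876141),
            (TwoByTwo(147, 54, 8350, 21010), 6.809566),
        ],
    )
    def test_haldane_corrected_feature_table_values(self, table, expected):
        assert odds_ratio(table, correction=0.5) == pytest.approx(expected, abs=1e-4)

    def test_zero_cell_protection(self):
        t = TwoByTwo(10, 0, 90, 100)
        assert math.isfinite(odds_ratio(t, correction=0.5))
        with pytest.raises(ZeroDivisionError, match="correction"):
            odds_ratio(t, correction=0)

    def test_group_transposition_inverts(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = random_table(rng)
            inv = TwoByTwo(t.b, t.a, t.d, t.c)
            assert odds_ratio(t, 0) * odds_ratio(inv, 0) == pytest.approx(1.0)

    def test_monotone_in_a(self):
        t1 = TwoByTwo(10, 5, 50, 95)
        t2 = TwoByTwo(11, 5, 50, 95)
        assert odds_ratio(t2) > odds_ratio(t1)
        assert alpha_index(t2) > alpha_index(t1)


class TestAlpha:
    def test_equals_log_of_uncorrected_or(self):
        t = TwoByTwo(20, 2, 80, 98)
        assert alpha_index(t, 0) == pytest.approx(math.log(12.25), abs=1e-12)

    def test_symmetric_table_gives_zero(self):
        assert alpha_index(TwoByTwo(20, 10, 80, 40), 0) == pytest.approx(0.0, abs=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells,
           corr=st.sampled_from([0.0, 0.5, 1.0]))
    @settings(max_examples=200, derandomize=True)
    def test_identity_with_log_odds_ratio(self, a, b, c, d, corr):
        t = TwoByTwo(a, b, c, d)
        assert alpha_index(t, corr) == pytest.approx(
            math.log(odds_ratio(t, corr)), abs=1e-12
        )


class TestPrevalence:
    def test_worked_proportions(self):
        assert prevalence(TwoByTwo(20, 2, 80, 98)) == (0.2, 0.02)
        assert prevalence(TwoByTwo(40, 6, 60, 94)) == (0.4, 0.06)

    def test_pseudo_count_only_on_zero(self):
        case_prev, ctrl_prev = prevalence(TwoByTwo(0, 5, 100, 95), pseudo_count=1)
        assert case_prev == pytest.approx(0.01)
        assert ctrl_prev == pytest.approx(0.05)


class TestWeightTransforms:
    def test_zscore_closed_form(self):
        z = zscore_normalize([1, 2, 3])
        assert z == pytest.approx([-1.2247448, 0.0, 1.2247448], abs=1e-6)

    def test_zscore_constant_input_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            zscore_normalize([2.0, 2.0, 2.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40, unique=True))
    @settings(max_examples=100, derandomize=True)
    def test_zscore_mean_zero_sd_one(self, values):
        assume(np.std(values) > 1e-6)
        z = zscore_normalize(values)
        assert abs(z.mean()) < 1e-10
        assert z.std() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(z[np.argsort(values)]) >= 0).all()  # order-preserving

    def test_tscore_zero_maps_to_zero(self):
        assert tscore(0.0, 100) == 0.0

    def test_tscore_direct_evaluation(self):
        assert tscore(1.0, 100, C=1.96) == pytest.approx(10 / 1.96, abs=1e-6)
        # default C is the 97.5% t critical value at n-1 df
        assert tscore(1.0, 100) == pytest.approx(10 / t_critical(100), abs=1e-9)

    def test_tscore_scales_with_sqrt_n(self):
        C = 2.0
        assert tscore(1.5, 200, C=C) == pytest.approx(
            math.sqrt(2) * tscore(1.5, 100, C=C)
        )

    def test_tscore_classic_style(self):
        assert tscore(1.0, 100, style="classic_50_plus_10z") == 60.0

    def test_tscore_bad_critical_value(self):
        with pytest.raises(ValueError):
            tscore(1.0, 100, C=-1.0)


class TestFeatureSelection:
    def test_thresholds_drop_weak_features(self):
        # code "514": OR 12.25, prevalence 0.2; code "427" diluted to OR ~1.5
        cohort = manual_cohort(
            [{"514", "427"}] * 20 + [{"427"}] * 25 + [set()] * 55,
            [{"514"}] * 2 + [{"427"}] * 35 + [set()] * 63,
        )
        fs = select_feature_set(cohort, correction=0)
        assert fs.codes == ["514"]

    def test_ranked_by_descending_odds_ratio(self, small_sim):
        _, _, _, cohort = small_sim
        fs = select_feature_set(cohort)
        ors = [s.odds_ratio for s in fs]
        assert ors == sorted(ors, reverse=True)
        assert all(s.odds_ratio >= 2 and s.case_prevalence >= 0.01 for s in fs)

    def test_zscores_over_selected_members_only(self, small_sim):
        _, _, _, cohort = small_sim
        fs = select_feature_set(cohort)
        zs = np.array([s.or_z for s in fs])
        assert abs(zs.mean()) < 1e-9 and zs.std() == pytest.approx(1.0, abs=1e-9)

    def test_all_below_threshold_errors(self):
        cohort = manual_cohort([{"250"}] * 50 + [set()] * 50,
                               [{"250"}] * 50 + [set()] * 50)
        with pytest.raises(ValueError, match="relaxing"):
            select_feature_set(cohort)

    def test_invariant_to_input_order(self, small_sim):
        _, _, _, cohort = small_sim
        fs1 = select_feature_set(cohort)
        shuffled = cohort.subset(
            np.random.default_rng(1).permutation(len(cohort)))
        fs2 = select_feature_set(shuffled)
        assert fs1.codes == fs2.codes
        assert [s.odds_ratio for s in fs1] == [s.odds_ratio for s in fs2]

    def test_serialises_feature_table(self, small_sim, tmp_path):
        _, _, _, cohort = small_sim
        fs = select_feature_set(cohort)
        out = tmp_path / "features.csv"
        fs.to_csv(out)
        frame = fs.to_frame()
        assert list(frame["code"]) == fs.codes
        assert out.exists()
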