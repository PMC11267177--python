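"""The JI/PJI/OPJI/APJI indices and per-subject similarity features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pjindex import (
    GroupProfile,
    cohort_group_profile,
    featurize_cohort,
    jaccard,
    pji,
    select_feature_set,
    subject_profile,
    weighted_pji,
)

from conftest import manual_cohort


def profiles(draw_codes=st.sets(st.sampled_from([f"c{i}" for i in range(8)]),
                                min_size=1, max_size=6)):
    """Hypothesis strategy for a valid normalised profile."""
    @st.composite
    def _profile(draw):
        codes = sorted(draw(draw_codes))
        raw = [draw(st.floats(0.05, 1.0)) for _ in codes]
        total = sum(raw)
        return GroupProfile({c: v / total for c, v in zip(codes, raw)})
    return _profile()


class TestJaccard:
    def test_identity_and_closed_form(self):
        assert jaccard({"x", "y"}, {"x", "y"}).value == 1.0
        r = jaccard({"x", "y"}, {"y", "z"})
        assert r.value == pytest.approx(1 / 3)
        assert r.shared_codes == {"y"}
        assert r.exclusive_a == {"x"} and r.exclusive_b == {"z"}

    def test_empty_vs_empty_is_zero(self):
        assert jaccard(set(), set()).value == 0.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        universe = [f"c{i}" for i in range(10)]
        for _ in range(100):
            a = {c for c in universe if rng.random() < 0.4}
            b = {c for c in universe if rng.random() < 0.4}
            inter = sum(1 for c in universe if c in a and c in b)
            union = sum(1 for c in universe if c in a or c in b)
            expect = inter / union if union else 0.0
            assert jaccard(a, b).value == pytest.approx(expect)


class TestPJI:
    def test_identical_profiles_give_one(self):
        p = GroupProfile({"X": 0.3, "Y": 0.7})
        assert pji(p, p).value == pytest.approx(1.0)

    def test_hand_worked_value(self):
        a = GroupProfile({"X": 0.5, "Y": 0.5})
        b = GroupProfile({"X": 1.0})
        # q = (0.5+1)/2 = 0.75 shared; s = 0.5 exclusive -> 0.75/1.25
        assert pji(a, b).value == pytest.approx(0.6)

    def test_disjoint_supports_give_zero(self):
        a = GroupProfile({"X": 1.0})
        b = GroupProfile({"Y": 1.0})
        assert pji(a, b).value == 0.0

    def test_degenerates_to_jaccard_on_singleton_indicators(self):
        a = GroupProfile({"X": 1.0})
        assert pji(a, a).value == jaccard({"X"}, {"X"}).value

    def test_shared_mass_raises_exclusive_lowers(self):
        a = GroupProfile({"X": 0.5, "Y": 0.5})
        b = GroupProfile({"X": 0.5, "Z": 0.5})
        base = pji(a, b).value
        richer = pji(GroupProfile({"X": 0.4, "Y": 0.4, "W": 0.2}),
                     GroupProfile({"X": 0.4, "Z": 0.4, "W": 0.2}))
        assert richer.value > base  # added shared code W
        poorer = pji(GroupProfile({"X": 0.4, "Y": 0.4, "V": 0.2}),
                     GroupProfile({"X": 0.5, "Z": 0.5}))
        assert poorer.value < richer.value  # V is exclusive


class TestWeightedPJI:
    def test_hand_worked_value(self):
        a = GroupProfile({"X": 0.5, "Y": 0.5})
        b = GroupProfile({"X": 1.0})
        # q*w = 0.75*2 = 1.5; s*w = 0.5*1 -> 1.5/2.0
        r = weighted_pji(a, b, {"X": 2.0, "Y": 1.0})
        assert r.value == pytest.approx(0.75)

    def test_missing_weight_names_the_code(self):
        a = GroupProfile({"X": 1.0})
        with pytest.raises(KeyError, match="X"):
            weighted_pji(a, a, {"Y": 1.0})

    @given(profiles(), profiles(), st.floats(0.1, 50.0))
    @settings(max_examples=200, derandomize=True)
    def test_constant_weights_reduce_to_pji(self, a, b, w):
        codes = a.support | b.support
        r = weighted_pji(a, b, {c: w for c in codes})
        assert r.value == pytest.approx(pji(a, b).value, abs=1e-12)

    @given(profiles(), profiles(), st.floats(0.5, 20.0))
    @settings(max_examples=100, derandomize=True)
    def test_invariant_to_weight_scaling(self, a, b, scale):
        codes = sorted(a.support | b.support)
        w = {c: 0.5 + i for i, c in enumerate(codes)}
        r1 = weighted_pji(a, b, w)
        r2 = weighted_pji(a, b, {c: v * scale for c, v in w.items()})
        assert r1.value == pytest.approx(r2.value, abs=1e-10)

    @given(profiles(), profiles())
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_and_unit_interval(self, a, b):
        codes = sorted(a.support | b.support)
        w = {c: 0.1 + i for i, c in enumerate(codes)}
        for fn in (lambda x, y: pji(x, y).value,
                   lambda x, y: weighted_pji(x, y, w).value,
                   lambda x, y: jaccard(x.support, y.support).value):
            v1, v2 = fn(a, b), fn(b, a)
            assert v1 == pytest.approx(v2, abs=1e-12)
            assert 0.0 <= v1 <= 1.0

    def test_negative_weights_floored_keep_unit_interval(self):
        a = GroupProfile({"X": 0.5, "Y": 0.5})
        b = GroupProfile({"X": 0.9, "Z": 0.1})
        r = weighted_pji(a, b, {"X": -3.0, "Y": 2.0, "Z": -1.0})
        assert 0.0 <= r.value <= 1.0


class TestSubjectFeatures:
    @pytest.fixture
    def cohort_and_fs(self, small_sim):
        _, _, _, cohort = small_sim
        fs = select_feature_set(cohort)
        return cohort, fs

    def test_subject_profile_uniform_over_retained(self, cohort_and_fs):
        _, fs = cohort_and_fs
        two = set(fs.codes[:2])
        prof = subject_profile(two | {"XXX"}, fs)
        assert prof.proportions == {c: 0.5 for c in two}

    def test_subject_profile_empty_when_disjoint(self, cohort_and_fs):
        _, fs = cohort_and_fs
        assert len(subject_profile({"XXX"}, fs)) == 0

    def test_full_overlap_uniform(self, cohort_and_fs):
        _, fs = cohort_and_fs
        prof = subject_profile(set(fs.codes), fs)
        assert all(v == pytest.approx(1 / len(fs)) for v in prof.proportions.values())

    def test_group_profile_normalised_counts(self, table1_cohort):
        cohort = table1_cohort
        fs = select_feature_set(cohort, correction=0, or_min=0.01, prevalence_min=0.0)
        prof = cohort_group_profile(cohort, "case", fs)
        # case carriage counts: 514->20, 427->40, 250->60
        assert prof["514"] == pytest.approx(20 / 120)
        assert prof["427"] == pytest.approx(40 / 120)

    @pytest.mark.parametrize("kind", ["JI", "PJI", "OPJI", "APJI"])
    def test_vectorised_features_match_scalar_indices(self, cohort_and_fs, kind):
        cohort, fs = cohort_and_fs
        case_prof = cohort_group_profile(cohort, "case", fs)
        ctrl_prof = cohort_group_profile(cohort, "control", fs)
        feats = featurize_cohort(cohort, fs, case_prof, ctrl_prof, kind)
        assert len(feats) == len(cohort)
        w = fs.weights(kind) if kind in ("OPJI", "APJI") else None
        rng = np.random.default_rng(5)
        for row in rng.choice(len(feats), size=40, replace=False):
            sid = feats["subject_id"].iloc[row]
            sp = subject_profile(cohort.codes_of(sid), fs)
            for col, ref in [("sim_to_case", case_prof), ("sim_to_control", ctrl_prof)]:
                if kind == "JI":
                    expect = jaccard(sp.support, ref.support).value
                elif kind == "PJI":
                    expect = pji(sp, ref).value
                else:
                    expect = weighted_pji(sp, ref, w, kind).value
                assert feats[col].iloc[row] == pytest.approx(expect, abs=1e-12)

    def test_empty_profile_subject_gets_zero_features(self, cohort_and_fs):
        cohort, fs = cohort_and_fs
        case_prof = cohort_group_profile(cohort, "case", fs)
        ctrl_prof = cohort_group_profile(cohort, "control", fs)
        bare = manual_cohort([{"XXX"}], [set()])
        feats = featurize_cohort(bare, fs, case_prof, ctrl_prof, "PJI")
        assert (feats[["sim_to_case", "sim_to_control"]].to_numpy() == 0).all()

    def test_exact_match_subject_scores_one_on_ji(self, cohort_and_fs):
        cohort, fs = cohort_and_fs
        case_prof = cohort_group_profile(cohort, "case", fs)
        ctrl_prof = cohort_group_profile(cohort, "control", fs)
        twin = manual_cohort([set(case_prof.support)], [set()])
        feats = featurize_cohort(twin, fs, case_prof, ctrl_prof, "JI")
        assert feats["sim_to_case"].iloc[0] == pytest.approx(1.0)
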