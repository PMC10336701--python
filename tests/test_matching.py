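import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surrobayes import (
    Covariate,
    CovariateProfile,
    CovariateSpec,
    DistanceMatrix,
    derive_threshold,
    distance_matrix,
    scaled_difference,
    select_matches,
    total_distance,
)
from surrobayes.datasets import mcrc_distance_matrix
from surrobayes.matching import default_covariate_spec


def profile(study_id, role="treatment", **values):
    spec = default_covariate_spec()
    base = {c.name: 0.5 * (c.min + c.max) for c in spec}
    base.update(values)
    return CovariateProfile(study_id=study_id, role=role, values=base)


SPEC = default_covariate_spec()


class TestScaledDifference:
    def test_identical_values_give_zero(self):
        assert scaled_difference(profile("a", age=60), profile("b", age=60), "age", SPEC) == 0.0

    def test_age_range_scaling(self):
        d = scaled_difference(profile("a", age=59), profile("b", age=100), "age", SPEC)
        assert d == pytest.approx(41 / 82)

    def test_performance_score_hand_arithmetic(self):
        d = scaled_difference(
            profile("a", performance_score=0.4),
            profile("b", performance_score=1.3),
            "performance_score",
            SPEC,
        )
        assert d == pytest.approx(0.3)

    def test_missing_covariate_names_study(self):
        a = CovariateProfile("incomplete", "treatment", {"age": 60.0})
        with pytest.raises(KeyError, match="incomplete"):
            scaled_difference(a, profile("b"), "female_proportion", SPEC)


class TestTotalDistance:
    def test_identical_profiles(self):
        assert total_distance(profile("a"), profile("b"), SPEC) == 0.0

    def test_maximal_differences_give_one(self):
        a = profile("a", treatment_line=1, age=18, performance_score=0,
                    colon_proportion=0, female_proportion=0)
        b = profile("b", treatment_line=3, age=100, performance_score=3,
                    colon_proportion=1, female_proportion=1)
        assert total_distance(a, b, SPEC) == pytest.approx(1.0)

    def test_weighted_average_hand_arithmetic(self):
        # scaled differences (0.1, 0.2, 0.0, 0.3, 0.5) with weights (2,2,2,2,1)
        a = profile("a", treatment_line=1.0, age=18.0, performance_score=0.0,
                    colon_proportion=0.0, female_proportion=0.0)
        b = profile("b", treatment_line=1.2, age=34.4, performance_score=0.0,
                    colon_proportion=0.3, female_proportion=0.5)
        assert total_distance(a, b, SPEC) == pytest.approx(1.7 / 9, abs=1e-12)

    def test_symmetry(self):
        t, c = profile("a", age=55.0), profile("b", age=70.0, colon_proportion=0.7)
        assert total_distance(t, c, SPEC) == total_distance(c, t, SPEC)

    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_weight_rescaling_leaves_distance_unchanged(self, scale):
        scaled = CovariateSpec(
            tuple(Covariate(c.name, c.weight * scale, c.min, c.max) for c in SPEC)
        )
        a = profile("a", age=62.0, female_proportion=0.44)
        b = profile("b", age=68.0, colon_proportion=0.61)
        assert total_distance(a, b, scaled) == pytest.approx(total_distance(a, b, SPEC))


class TestDistanceMatrix:
    def test_one_by_one_identical(self):
        m = distance_matrix([profile("t")], [profile("c")], SPEC)
        assert m.values.tolist() == [[0.0]]

    def test_permutation_moves_rows_not_values(self):
        treat = [profile("t1", age=60), profile("t2", age=70)]
        ctrl = [profile("c1", age=65), profile("c2", age=58)]
        m = distance_matrix(treat, ctrl, SPEC)
        mp = distance_matrix(treat[::-1], ctrl, SPEC)
        assert np.allclose(m.values[::-1], mp.values)
        assert mp.row_ids == ("t2", "t1")

    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("r",), ("c",), np.array([[1.5]]))

    def test_display_rounding_only(self):
        treat = [profile("t", age=60.123)]
        ctrl = [profile("c", age=61.987)]
        m = distance_matrix(treat, ctrl, SPEC)
        shown = m.to_frame().iloc[0, 0]
        assert shown == round(m.values[0, 0], 3)
        assert m.values[0, 0] != shown  # full precision retained internally


class TestThreshold:
    def test_single_reference_pair(self):
        a, b = profile("arm1", age=62.0), profile("arm2", age=64.2)
        expected = total_distance(a, b, SPEC)
        assert derive_threshold([(a, b)], SPEC) == pytest.approx(expected)

    def test_identical_arms_give_zero(self):
        assert derive_threshold([(profile("x"), profile("y"))], SPEC) == 0.0

    def test_maximum_over_pairs(self):
        pairs = [
            (profile("a1", age=60), profile("a2", age=60.82)),  # 0.01 on age
            (profile("b1", age=60), profile("b2", age=64.51)),
            (profile("c1", age=60), profile("c2", age=62.46)),
        ]
        dists = [total_distance(a, b, SPEC) for a, b in pairs]
        assert derive_threshold(pairs, SPEC) == pytest.approx(max(dists))

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            derive_threshold([], SPEC)


class TestSelectMatches:
    def test_greedy_two_by_two(self):
        m = DistanceMatrix(("r1", "r2"), ("c1", "c2"),
                           np.array([[0.01, 0.02], [0.02, 0.05]]))
        got = select_matches(m, 0.05)
        assert got.pairs == (("r1", "c1", 0.01), ("r2", "c2", 0.05))

    def test_threshold_below_minimum_gives_no_pairs(self):
        m = DistanceMatrix(("r",), ("c",), np.array([[0.4]]))
        assert select_matches(m, 0.1).pairs == ()

    def test_ties_broken_lexicographically(self):
        m = DistanceMatrix(("b", "a"), ("d", "c"),
                           np.array([[0.02, 0.02], [0.02, 0.02]]))
        got = select_matches(m, 0.05)
        assert got.pairs == (("a", "c", 0.02), ("b", "d", 0.02))

    def test_distances_nondecreasing_and_ids_unique(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 0.2, size=(6, 5))
        m = DistanceMatrix(tuple(f"r{i}" for i in range(6)),
                           tuple(f"c{j}" for j in range(5)), vals)
        got = select_matches(m, 0.15)
        d = [p[2] for p in got.pairs]
        assert d == sorted(d)
        ids = [p[0] for p in got.pairs] + [p[1] for p in got.pairs]
        assert len(ids) == len(set(ids))
        assert all(p[2] <= 0.15 for p in got.pairs)


class TestMCRCMatrix:
    def test_dimensions(self):
        m = mcrc_distance_matrix()
        assert m.values.shape == (16, 8)

    def test_candidate_counts_at_both_thresholds(self):
        m = mcrc_distance_matrix()
        assert m.count_at_or_below(0.030) == 7
        assert m.count_at_or_below(0.055) == 30

    def test_final_matched_pairs(self):
        got = select_matches(mcrc_distance_matrix(), 0.030)
        assert got.pairs == (
            ("Van Cutsem 2009 (3)", "Yoshino 2007", 0.013),
            ("Bendell 2012 (1)", "Dong 2015", 0.029),
        )
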