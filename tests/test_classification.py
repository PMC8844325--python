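import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mbfvs.classification import (
    ClassificationError,
    ClassificationVector,
    NormalRange,
    build_normal_range,
    classify,
    compare_dc_groups,
    dice_agreement,
    pool_agreement,
)
from mbfvs.kinetics import FlowProfile


def _profile(values, positions=None, vessel="LAD", state="stress"):
    values = np.asarray(values, float)
    if positions is None:
        positions = 4.0 * np.arange(len(values)) + 2.0
    return FlowProfile(
        vessel=vessel,
        state=state,
        positions=np.asarray(positions, float),
        mbf=values,
        residuals=np.zeros(values.size),
        converged=np.ones(values.size, bool),
    )


def _vec(labels, positions=None, vessel="LAD", state="stress"):
    labels = np.asarray(labels, bool)
    if positions is None:
        positions = 4.0 * np.arange(labels.size) + 2.0
    return ClassificationVector(
        labels=labels, positions=np.asarray(positions, float), vessel=vessel, state=state
    )


def _oracle_dice(la, lb, mode):
    """Independent enumeration-style oracle for both DC definitions."""
    n = len(la)
    if mode == "matched-fraction":
        m = sum(1 for x, y in zip(la, lb) if x == y)
        return 2 * m / (n + n)
    a_set = {i for i, x in enumerate(la) if x}
    b_set = {i for i, x in enumerate(lb) if x}
    if not a_set and not b_set:
        return 1.0
    return 2 * len(a_set & b_set) / (len(a_set) + len(b_set))


class TestBuildNormalRange:
    def test_identical_profiles_zero_width(self):
        p = _profile([1.0, 2.0, 3.0])
        band = build_normal_range([p, _profile([1.0, 2.0, 3.0])], k_sd=2.0)
        assert np.allclose(band.lower, band.upper)

    def test_k_sd_zero_collapses_to_mean(self):
        band = build_normal_range([_profile([1.0, 1.0, 1.0]), _profile([3.0, 3.0, 3.0])], k_sd=0.0)
        assert np.allclose(band.lower, 2.0)
        assert np.allclose(band.upper, 2.0)

    def test_sample_sd_of_two_values(self):
        # SD of {1, 3} (ddof=1) = sqrt(2); band = 2 +/- k * sqrt(2)
        band = build_normal_range([_profile([1.0, 1.0]), _profile([3.0, 3.0])], k_sd=1.0)
        assert np.allclose(band.lower, 2.0 - np.sqrt(2.0))
        assert np.allclose(band.upper, 2.0 + np.sqrt(2.0))

    def test_mismatched_labels_error(self):
        with pytest.raises(ClassificationError):
            build_normal_range([_profile([1, 2]), _profile([1, 2], vessel="LCX")])

    def test_needs_two_profiles(self):
        with pytest.raises(ClassificationError):
            build_normal_range([_profile([1, 2])])

    def test_lower_clipped_at_zero(self):
        band = build_normal_range([_profile([0.1, 0.1]), _profile([0.3, 0.3])], k_sd=5.0)
        assert np.all(band.lower >= 0)


class TestClassify:
    def _band(self, lower, upper=10.0, span=200.0, vessel="LAD", state="stress"):
        return NormalRange(
            vessel=vessel,
            state=state,
            positions=np.array([0.0, span]),
            lower=np.array([lower, lower]),
            upper=np.array([upper, upper]),
        )

    def test_all_above_lower_all_normal(self):
        vec = classify(_profile([2.0, 3.0, 9.0, 20.0]), self._band(1.5))
        assert not np.any(vec.labels)  # above the upper bound is still normal

    def test_boundary_value_is_normal(self):
        vec = classify(_profile([1.5]), self._band(1.5))
        assert not vec.labels[0]

    def test_hand_example(self):
        vec = classify(_profile([2.0, 1.0, 2.0]), self._band(1.5))
        assert vec.labels.tolist() == [False, True, False]

    def test_outside_span_errors(self):
        with pytest.raises(ClassificationError, match="outside"):
            classify(_profile([1.0], positions=[300.0]), self._band(1.5))

    @given(
        st.lists(st.floats(0.1, 5.0), min_size=2, max_size=12),
        st.integers(0, 11),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotonicity_decreasing_never_unflags(self, values, drop_idx):
        drop_idx = drop_idx % len(values)
        band = self._band(1.5)
        before = classify(_profile(values), band).labels
        values2 = list(values)
        values2[drop_idx] = max(values2[drop_idx] - 1.0, 0.0)
        after = classify(_profile(values2), band).labels
        assert np.all(before <= after)  # abnormal set only grows


class TestDiceAgreement:
    def test_identical_both_modes(self):
        v = _vec([True, False, True])
        for mode in ("matched-fraction", "abnormal-set"):
            assert dice_agreement(v, v, mode=mode).dc == 1.0

    def test_total_mismatch_matched_fraction(self):
        a = _vec([True, True, False])
        b = _vec([False, False, True])
        assert dice_agreement(a, b).dc == 0.0

    def test_hand_enumeration_example(self):
        a = _vec([False, False, True, True, True])
        b = _vec([False, True, True, True, False])
        assert dice_agreement(a, b, mode="matched-fraction").dc == pytest.approx(0.6)
        assert dice_agreement(a, b, mode="abnormal-set").dc == pytest.approx(2 * 2 / 6)

    def test_both_empty_abnormal_sets(self):
        a = _vec([False, False])
        assert dice_agreement(a, a, mode="abnormal-set").dc == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ClassificationError):
            dice_agreement(_vec([True]), _vec([True, False]))

    def test_position_mismatch_errors(self):
        with pytest.raises(ClassificationError):
            dice_agreement(_vec([True], positions=[2.0]), _vec([True], positions=[6.0]))

    @given(st.integers(1, 8), st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, n, abits, bbits):
        la = [(abits >> i) & 1 == 1 for i in range(n)]
        lb = [(bbits >> i) & 1 == 1 for i in range(n)]
        for mode in ("matched-fraction", "abnormal-set"):
            got = dice_agreement(_vec(la), _vec(lb), mode=mode).dc
            assert got == pytest.approx(_oracle_dice(la, lb, mode))

    @given(st.integers(1, 10), st.integers(0, 2**20), st.integers(0, 2**20))
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, n, abits, bbits):
        la = [(abits >> i) & 1 == 1 for i in range(n)]
        lb = [(bbits >> i) & 1 == 1 for i in range(n)]
        for mode in ("matched-fraction", "abnormal-set"):
            assert (
                dice_agreement(_vec(la), _vec(lb), mode=mode).dc
                == dice_agreement(_vec(lb), _vec(la), mode=mode).dc
            )


class TestPooling:
    def test_single_vessel_pool_equals_own_dc(self):
        a = _vec([True, False, True])
        b = _vec([True, True, True])
        own = dice_agreement(a, b).dc
        table = pool_agreement([(a, b)])
        assert table[table["group"] == "global"]["dc"].iloc[0] == pytest.approx(own)

    def test_all_matched_two_vessels(self):
        p1 = (_vec([True, False]), _vec([True, False]))
        p2 = (_vec([False], vessel="LCX"), _vec([False], vessel="LCX"))
        table = pool_agreement([p1, p2])
        assert np.allclose(table["dc"], 1.0)

    def test_pooled_counts_not_mean_of_dcs(self):
        # vessel1: 4/5 matched, vessel2: 6/10 matched -> pooled 10/15
        a1 = _vec([True] * 5)
        b1 = _vec([True, True, True, True, False])
        a2 = _vec([True] * 10, vessel="LCX")
        b2 = _vec([True] * 6 + [False] * 4, vessel="LCX")
        table = pool_agreement([(a1, b1), (a2, b2)])
        pooled = table[table["group"] == "global"]["dc"].iloc[0]
        assert pooled == pytest.approx(10 / 15)
        assert pooled != pytest.approx(np.mean([0.8, 0.6]))

    def test_pooled_between_min_and_max(self):
        a1 = _vec([True, True, False, False])
        b1 = _vec([True, False, False, False])
        a2 = _vec([True, True], vessel="rPDA")
        b2 = _vec([True, True], vessel="rPDA")
        table = pool_agreement([(a1, b1), (a2, b2)])
        per = table[table["group"] != "global"]["dc"]
        pooled = table[table["group"] == "global"]["dc"].iloc[0]
        assert per.min() - 1e-12 <= pooled <= per.max() + 1e-12


class TestTTests:
    def test_identical_paired(self):
        res = compare_dc_groups([0.9, 0.8, 1.0], [0.9, 0.8, 1.0], paired=True)
        assert res.t == 0.0 and res.p == 1.0

    def test_unpaired_closed_form_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 4.0, 5.0])
        # textbook pooled-variance formula
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
        t_exp = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        p_exp = 2 * sps.t.sf(abs(t_exp), a.size + b.size - 2)
        res = compare_dc_groups(a, b, paired=False)
        assert res.t == pytest.approx(t_exp)
        assert res.p == pytest.approx(p_exp)

    def test_scale_invariance(self):
        a = [0.5, 0.7, 0.9]
        b = [0.6, 0.8, 0.7]
        t1 = compare_dc_groups(a, b).t
        t2 = compare_dc_groups([10 * x for x in a], [10 * x for x in b]).t
        assert t1 == pytest.approx(t2)

    def test_zero_variance_unequal_means_flagged(self):
        res = compare_dc_groups([1.0, 1.0], [0.5, 0.5], paired=False)
        assert res.degenerate and res.p == 0.0

    def test_too_small_groups(self):
        with pytest.raises(ClassificationError):
            compare_dc_groups([1.0], [0.5])
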