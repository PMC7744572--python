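"""Normalization, joint histograms, mutual information, characteristic
filters and feature-level assignment."""

import numpy as np
import pytest

from cortexmap import activation_analysis as aa
from cortexmap.cnn_arch import ActivationStack


def make_stack(maps, layers):
    st = ActivationStack()
    for i, (m, l) in enumerate(zip(maps, layers)):
        st.maps.append(np.asarray(m, np.float32))
        st.branch.append("hr")
        st.network_layer.append(l)
        st.unit.append(i)
    return st


class TestNormalize:
    def test_smallest_positive_is_lower_bound(self):
        nm = aa.normalize_activation(np.array([[0.0, 0.2], [0.6, 1.0]]))
        assert np.allclose(nm.values, [[0.0, 0.0], [0.5, 1.0]])
        assert nm.lower_bound == pytest.approx(0.2)
        assert not nm.degenerate

    def test_all_zero_flagged_degenerate(self):
        nm = aa.normalize_activation(np.zeros((4, 4)))
        assert nm.degenerate
        assert not nm.values.any()

    def test_constant_positive_flagged_degenerate(self):
        nm = aa.normalize_activation(np.full((3, 3), 2.5))
        assert nm.degenerate

    def test_range_contract(self, rng):
        nm = aa.normalize_activation(rng.random((20, 20)) * 7)
        assert nm.values.min() == 0.0
        assert nm.values.max() == 1.0

    def test_non_finite_errors(self):
        with pytest.raises(ValueError):
            aa.normalize_activation(np.array([[np.nan, 1.0]]))


class TestJointHistogram:
    def test_constant_zero_pair_single_cell(self):
        z = np.zeros((8, 8))
        p = aa.joint_histogram(z, z)
        assert p[0, 0] == 1.0
        assert p.sum() == 1.0

    def test_marginal_is_own_histogram(self, rng):
        x = rng.random((50, 50))
        y = rng.random((50, 50))
        p = aa.joint_histogram(x, y)
        marg = p.sum(axis=1)
        own = np.bincount(np.clip((x * 256).astype(int), 0, 255).ravel(),
                          minlength=256) / x.size
        assert np.allclose(marg, own)

    def test_matches_counting_oracle(self, rng):
        x = rng.random((12, 12))
        y = rng.random((12, 12))
        p = aa.joint_histogram(x, y)
        oracle = np.zeros((256, 256))
        for xv, yv in zip(x.ravel(), y.ravel()):
            i = min(int(xv * 256), 255)
            j = min(int(yv * 256), 255)
            oracle[i, j] += 1
        assert np.array_equal(p, oracle / x.size)

    def test_sums_to_one_exactly(self, rng):
        x, y = rng.random((30, 30)), rng.random((30, 30))
        assert aa.joint_histogram(x, y).sum() == pytest.approx(1.0, abs=1e-12)

    def test_top_bin_closed(self):
        x = np.ones((4, 4))
        p = aa.joint_histogram(x, x)
        assert p[255, 255] == 1.0

    def test_size_mismatch_errors(self):
        with pytest.raises(ValueError, match="resample"):
            aa.joint_histogram(np.zeros((4, 4)), np.zeros((5, 5)))


class TestMutualInformation:
    def test_self_mi_equals_entropy(self, rng):
        x = rng.random((40, 40))
        assert aa.mutual_information(x, x) == pytest.approx(aa.entropy_bits(x), abs=1e-9)

    def test_binary_pair_one_bit(self):
        # joint mass (0.5, 0, 0, 0.5): x == y, both half 0 / half 1
        x = np.zeros((10, 10))
        x[:5] = 1.0
        assert aa.mutual_information(x, x.copy()) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_low_mi(self):
        rng = np.random.default_rng(42)
        x = rng.random((1000, 1000))
        y = rng.random((1000, 1000))
        mi = aa.mutual_information(x, y)
        assert 0.0 <= mi < 0.05

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(5):
            x, y = rng.random((60, 60)), rng.random((60, 60)) ** 2
            assert aa.mutual_information(x, y) == pytest.approx(
                aa.mutual_information(y, x), abs=1e-12)
            assert aa.mutual_information(x, y) >= -1e-12

    def test_blurring_does_not_increase_mi(self, rng):
        from scipy import ndimage

        base = rng.random((80, 80))
        x = base + 0.1 * rng.random((80, 80))
        y = base + 0.1 * rng.random((80, 80))
        mi_orig = aa.mutual_information(x, y)
        y_blur = ndimage.gaussian_filter(y, 6.0)
        assert aa.mutual_information(x, y_blur) <= mi_orig + 0.05


class TestPairwiseMI:
    def test_three_maps_symmetric(self, rng):
        stack = make_stack([rng.random((16, 16)) for _ in range(3)], [1, 1, 2])
        m = aa.pairwise_mi(stack)
        assert m.values.shape == (3, 3)
        assert np.allclose(m.values, m.values.T)
        for i in range(3):
            nm = aa.normalize_activation(stack.maps[i])
            assert m.values[i, i] == pytest.approx(aa.entropy_bits(nm.values), abs=1e-9)

    def test_duplicated_map_identical_rows(self, rng):
        x = rng.random((16, 16))
        stack = make_stack([x, x.copy(), rng.random((16, 16))], [1, 1, 2])
        m = aa.pairwise_mi(stack).values
        assert m[0, 2] == pytest.approx(m[1, 2], abs=1e-12)

    def test_entries_match_single_pair_recomputation(self, rng):
        maps = [rng.random((16, 16)) for _ in range(4)]
        stack = make_stack(maps, [1, 1, 2, 2])
        m = aa.pairwise_mi(stack).values
        n0 = aa.normalize_activation(maps[0]).values
        n3 = aa.normalize_activation(maps[3]).values
        assert m[0, 3] == pytest.approx(aa.mutual_information(n0, n3), abs=1e-9)

    def test_degenerate_map_flagged_zero_row(self, rng):
        stack = make_stack(
            [rng.random((8, 8)), np.zeros((8, 8)), rng.random((8, 8))], [1, 1, 1])
        m = aa.pairwise_mi(stack)
        assert m.degenerate[1]
        assert np.all(m.values[1] == 0)

    def test_mixed_resolutions_resampled(self, rng):
        stack = make_stack([rng.random((32, 32)), rng.random((8, 8))], [1, 2])
        m = aa.pairwise_mi(stack)
        assert np.isfinite(m.values).all()


class TestCharacteristicFilters:
    def _mi_with_partners(self, n, unit, partners, high=5.0):
        m = np.random.default_rng(0).random((n, n)) * 0.1
        m = (m + m.T) / 2
        for p in partners:
            m[unit, p] = m[p, unit] = high
        return aa.MIMatrix(values=m)

    def test_five_same_layer_partners_characteristic(self):
        layers = [1] * 8 + [2] * 12
        mi = self._mi_with_partners(20, 0, partners=range(1, 6))
        cs = aa.characteristic_filters(mi, layers)
        assert cs.characteristic[0]
        assert cs.same_layer_count[0] >= 3

    def test_two_same_layer_partners_not_characteristic(self):
        layers = [1] * 3 + [2] * 17
        mi = self._mi_with_partners(20, 0, partners=[1, 2])
        cs = aa.characteristic_filters(mi, layers)
        assert not cs.characteristic[0]
        assert cs.same_layer_count[0] == 2

    def test_all_identical_maps_tie_break_combinatorics(self, rng):
        # every pair has identical MI; ties break toward the lower unit
        # index, so each unit's top-12 is exactly the lowest 12 indices
        # other than itself
        x = rng.random((16, 16))
        layers = [1] * 6 + [2] * 14
        stack = make_stack([x.copy() for _ in range(20)], layers)
        m = aa.pairwise_mi(stack)
        cs = aa.characteristic_filters(m, stack.network_layer)
        assert cs.tie_broken
        for i in range(20):
            expected_top = [j for j in range(20) if j != i][:12]
            assert cs.neighbours[i] == expected_top
            want = sum(1 for j in expected_top if layers[j] == layers[i])
            assert cs.same_layer_count[i] == want
        assert cs.characteristic.all()  # every unit still has >= 3 same-layer

    def test_k_too_large_errors(self):
        mi = aa.MIMatrix(values=np.eye(5))
        with pytest.raises(ValueError, match="smaller"):
            aa.characteristic_filters(mi, [1] * 5, k=5)


class TestAssignLevels:
    @pytest.fixture(scope="class")
    def phantom(self, two_area_phantom):
        return two_area_phantom

    def _stack_for(self, phantom, maps):
        st = make_stack(maps, list(range(1, len(maps) + 1)))
        flags = np.ones(len(maps), bool)
        cs = aa.CharacteristicSet(
            characteristic=flags, neighbours=[[] for _ in maps],
            same_layer_count=np.full(len(maps), 3),
        )
        return st, cs

    def test_smoothed_cell_density_is_first_level(self, phantom):
        density = aa.local_cell_density(phantom)
        st, cs = self._stack_for(phantom, [density])
        res = aa.assign_levels(st, cs, phantom, seed=0)
        assert res.level[0] == "first"
        assert res.score_cell[0] > 0.9

    def test_layer_indicator_is_second_level(self, phantom):
        ivc = next(k for k, v in phantom.layer_names.items() if v.endswith("/IVc"))
        st, cs = self._stack_for(phantom, [(phantom.layer_labels == ivc).astype(float)])
        res = aa.assign_levels(st, cs, phantom, seed=0)
        assert res.level[0] == "second"
        assert res.score_layer[0] == pytest.approx(1.0, abs=1e-6)

    def test_area_indicator_plus_noise_is_third_level(self, phantom, rng):
        ind = (phantom.area_labels == phantom.area_ids[0]).astype(float)
        noisy = ind + 0.05 * rng.random(ind.shape)
        st, cs = self._stack_for(phantom, [noisy])
        res = aa.assign_levels(st, cs, phantom, seed=0)
        assert res.level[0] == "third"
        assert res.score_area[0] > 0.95
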