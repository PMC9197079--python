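import numpy as np
import pytest

from connnlm import (
    ConnectomeMatrix,
    FilterParams,
    ParcellationVolume,
    Volume3D,
    conn_nlm_filter,
    conn_nlm_oracle,
    estimate_h2,
    extract_patch,
    gaussian_baseline,
    gaussian_patch_kernel,
    nlm_filter,
    patch_distance,
    similarity_weight,
    tv_baseline,
    weight_field,
)
from conftest import hybrid, random_case


class TestPatchExtraction:
    def test_full_slice(self, rng):
        data = rng.random((5, 5, 1))
        vol = Volume3D(data=data)
        patch = extract_patch(vol, (2, 2, 0), 5)
        assert np.array_equal(patch, data[:, :, 0])

    def test_corner_reflects(self):
        data = np.arange(27, dtype=float).reshape(3, 3, 3)
        patch = extract_patch(Volume3D(data=data), (0, 0, 1), 3)
        # reflect (mirror without edge repeat): index -1 maps to index 1
        assert patch[0, 0] == data[1, 1, 1]
        assert patch[1, 1] == data[0, 0, 1]
        assert patch[2, 2] == data[1, 1, 1]

    def test_single_voxel_patch(self, rng):
        data = rng.random((4, 4, 4))
        assert extract_patch(Volume3D(data=data), (1, 2, 3), 1) == data[1, 2, 3]

    def test_even_patch_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            extract_patch(Volume3D(data=rng.random((4, 4, 4))), (1, 1, 1), 4)

    def test_center_outside_volume(self, rng):
        with pytest.raises(IndexError):
            extract_patch(Volume3D(data=rng.random((4, 4, 4))), (4, 0, 0), 3)


class TestPatchDistance:
    def test_identical_patches(self, rng):
        kern = gaussian_patch_kernel(3, 1.0)
        p = rng.random((3, 3))
        assert patch_distance(p, p, kern) == 0.0

    def test_center_only_difference(self):
        kern = gaussian_patch_kernel(3, 0.8)
        p = np.zeros((3, 3))
        q = p.copy()
        q[1, 1] = 0.5
        assert patch_distance(p, q, kern) == pytest.approx(kern.weights[1, 1] * 0.25)

    def test_unit_distance_for_unit_offset(self):
        # all-ones vs all-zeros: sum of normalized kernel weights = 1
        kern = gaussian_patch_kernel(3, 1.0)
        assert patch_distance(np.ones((3, 3)), np.zeros((3, 3)), kern) == pytest.approx(1.0)

    def test_shape_mismatch(self):
        kern = gaussian_patch_kernel(3, 1.0)
        with pytest.raises(ValueError):
            patch_distance(np.ones((3, 3)), np.ones((5, 5)), kern)

    def test_kernel_normalized_and_symmetric(self):
        kern = gaussian_patch_kernel(5, 1.3)
        assert kern.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(kern.weights, kern.weights[::-1, :])
        assert np.allclose(kern.weights, kern.weights[:, ::-1])
        # centre voxel carries the largest weight
        assert kern.weights[2, 2] == kern.weights.max()


class TestSimilarityWeight:
    def test_closed_form(self):
        assert similarity_weight(0.0, 0.5) == 1.0
        assert similarity_weight(0.5, 0.5) == pytest.approx(np.exp(-1))

    def test_strictly_decreasing(self):
        ws = [similarity_weight(d, 0.3) for d in np.linspace(0, 5, 20)]
        assert np.all(np.diff(ws) < 0)

    def test_h2_zero_rejected(self):
        with pytest.raises(ValueError):
            similarity_weight(1.0, 0.0)
        with pytest.raises(ValueError):
            FilterParams(h2=0.0)


class TestEstimateH2:
    def test_noise_proportional_rule(self):
        # C=8 with background variance 0.023 gives 0.184 (prints as 0.18)
        delta = np.sqrt(0.023 / 2)
        data = np.zeros((4, 4, 4))
        data[0, 0, 0], data[0, 0, 1] = -delta, delta
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, :2] = True
        h2 = estimate_h2(Volume3D(data=data), mask, 8.0)
        assert h2 == pytest.approx(0.184, rel=1e-12)
        assert round(h2, 2) == 0.18

    def test_constant_region_gives_zero(self):
        vol = Volume3D(data=np.full((3, 3, 3), 2.0))
        assert estimate_h2(vol, np.ones((3, 3, 3), bool), 8.0) == 0.0

    def test_linear_in_C(self, rng):
        vol = Volume3D(data=rng.random((4, 4, 4)))
        m = np.ones((4, 4, 4), bool)
        assert estimate_h2(vol, m, 16.0) == pytest.approx(2 * estimate_h2(vol, m, 8.0))

    def test_degenerate_mask(self, rng):
        vol = Volume3D(data=rng.random((3, 3, 3)))
        with pytest.raises(ValueError):
            estimate_h2(vol, np.zeros((3, 3, 3), bool), 8.0)


class TestConnNLMFilter:
    def test_two_voxel_hand_value(self):
        vol = Volume3D(data=np.array([0.0, 1.0]).reshape(2, 1, 1))
        parc = ParcellationVolume(labels=np.ones((2, 1, 1), dtype=int))
        sc = ConnectomeMatrix(values=np.zeros((1, 1)), node_ids=[1], normalized=True)
        H = hybrid(sc, 1.0)
        out = conn_nlm_filter(vol, parc, H, FilterParams(h2=1.0, patch_size=1))
        e = np.exp(-1.0)
        assert out.data[0, 0, 0] == pytest.approx(e / (1 + e), rel=1e-12)
        assert out.data[1, 0, 0] == pytest.approx(1 / (1 + e), rel=1e-12)

    def test_uniform_image_fixed_point(self, rng):
        vol, parc, sc = random_case(rng, (6, 6, 4), 3)
        vol = Volume3D(data=np.full((6, 6, 4), 3.7), mask=vol.mask)
        out = conn_nlm_filter(vol, parc, hybrid(sc, 1.0), FilterParams(h2=0.2, patch_size=3))
        assert np.allclose(out.data, 3.7, atol=1e-12)

    def test_unmasked_voxels_copied(self, rng):
        vol, parc, sc = random_case(rng, (6, 6, 4), 3, mask_p=0.6)
        out = conn_nlm_filter(vol, parc, hybrid(sc, 0.5), FilterParams(h2=0.3, patch_size=3))
        outside = ~vol.mask
        assert np.array_equal(out.data[outside], vol.data[outside])

    def test_convexity(self, rng):
        vol, parc, sc = random_case(rng, (8, 8, 4), 4)
        out = conn_nlm_filter(vol, parc, hybrid(sc, 2.0), FilterParams(h2=0.1, patch_size=3))
        inside = vol.mask
        assert out.data[inside].min() >= vol.data[inside].min() - 1e-12
        assert out.data[inside].max() <= vol.data[inside].max() + 1e-12

    def test_lambda_zero_restricts_to_same_node(self, rng):
        """With lam=0, perturbing an other-node voxel beyond patch reach changes nothing."""
        shape = (12, 12, 3)
        data = rng.random(shape)
        labels = np.zeros(shape, dtype=int)
        labels[:4] = 1
        labels[8:] = 2  # 4-voxel gap: outside any node's patch radius (M=3 -> r=1)
        parc = ParcellationVolume(labels=labels)
        sc = ConnectomeMatrix(values=np.zeros((2, 2)), node_ids=[1, 2], normalized=True)
        params = FilterParams(h2=0.3, patch_size=3)
        base = conn_nlm_filter(Volume3D(data=data), parc, hybrid(sc, 0.0), params)
        poked = data.copy()
        poked[10, 5, 1] += 5.0  # inside node 2
        out = conn_nlm_filter(Volume3D(data=poked), parc, hybrid(sc, 0.0), params)
        assert np.array_equal(out.data[labels == 1], base.data[labels == 1])
        assert not np.array_equal(out.data[labels == 2], base.data[labels == 2])

    def test_lambda_zero_equals_per_node_nlm(self, rng):
        """lam=0 output inside a node equals plain NLM run with that node as mask."""
        vol, parc, sc = random_case(rng, (7, 7, 3), 3, mask_p=1.0)
        params = FilterParams(h2=0.25, patch_size=3)
        out = conn_nlm_filter(vol, parc, hybrid(sc, 0.0), params)
        for node in parc.node_ids:
            node_mask = parc.labels == node
            sub = nlm_filter(Volume3D(data=vol.data, mask=node_mask), params)
            assert np.allclose(out.data[node_mask], sub.data[node_mask], atol=1e-12)

    def test_single_node_equals_plain_nlm(self, rng):
        data = rng.random((8, 8, 3))
        mask = rng.random((8, 8, 3)) < 0.9
        vol = Volume3D(data=data, mask=mask)
        parc = ParcellationVolume(labels=np.where(mask, 1, 0))
        sc = ConnectomeMatrix(values=np.zeros((1, 1)), node_ids=[1], normalized=True)
        params = FilterParams(h2=0.3, patch_size=3)
        a = conn_nlm_filter(vol, parc, hybrid(sc, 1.0), params)
        b = nlm_filter(vol, params)
        assert np.allclose(a.data, b.data, atol=1e-12)

    def test_label_missing_from_connectome_rejected(self, rng):
        vol, parc, sc = random_case(rng, (6, 6, 3), 3)
        bad = ParcellationVolume(labels=np.full((6, 6, 3), 9))
        with pytest.raises(ValueError, match="absent from connectome"):
            conn_nlm_filter(vol, bad, hybrid(sc, 1.0), FilterParams(h2=0.2, patch_size=3))

    def test_empty_mask_rejected(self, rng):
        vol = Volume3D(data=rng.random((4, 4, 4)), mask=np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError, match="empty mask"):
            nlm_filter(vol, FilterParams(h2=0.2, patch_size=3))

    def test_monotone_smoothing_in_h2(self, rng):
        """Masked output variance decreases as h2 grows on noisy uniform truth."""
        data = 1.0 + rng.normal(0, 0.2, (10, 10, 4))
        vol = Volume3D(data=data, mask=np.ones((10, 10, 4), bool))
        variances = [
            np.var(nlm_filter(vol, FilterParams(h2=h2, patch_size=3)).data)
            for h2 in (0.05, 0.2, 0.8, 3.2)
        ]
        assert np.all(np.diff(variances) < 0)


class TestWeightField:
    @pytest.mark.parametrize("lam", [0.0, 0.1, 1.0, 10.0])
    def test_weights_normalized_and_include_self(self, rng, lam):
        vol, parc, sc = random_case(rng, (8, 8, 4), 4)
        params = FilterParams(h2=0.25, patch_size=3)
        center = tuple(np.argwhere(vol.mask)[5])
        wf = weight_field(vol, parc, hybrid(sc, lam), params, center)
        assert wf.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(wf.weights >= 0)
        self_rows = np.where((wf.indices == np.asarray(center)).all(axis=1))[0]
        assert len(self_rows) == 1 and wf.weights[self_rows[0]] > 0


class TestOracleEquivalence:
    def test_seeded_volumes_match(self):
        rng = np.random.default_rng(99)
        for _ in range(6):
            shape = tuple(rng.integers(3, 8, 3))
            vol, parc, sc = random_case(rng, shape, int(rng.integers(2, 5)))
            lam = float(rng.choice([0.0, 0.3, 1.0, 8.0]))
            params = FilterParams(
                h2=float(rng.uniform(0.05, 1.0)),
                a=float(rng.uniform(0.5, 2.0)),
                patch_size=int(rng.choice([1, 3, 5])),
            )
            a = conn_nlm_filter(vol, parc, hybrid(sc, lam), params)
            b = conn_nlm_oracle(vol, parc, hybrid(sc, lam), params)
            assert np.abs(a.data - b.data).max() < 1e-10

    def test_windowed_search_matches(self, rng):
        vol, parc, sc = random_case(rng, (8, 8, 4), 3)
        params = FilterParams(h2=0.3, patch_size=3, window=(5, 3))
        a = conn_nlm_filter(vol, parc, hybrid(sc, 0.7), params)
        b = conn_nlm_oracle(vol, parc, hybrid(sc, 0.7), params)
        assert np.abs(a.data - b.data).max() < 1e-10

    def test_plain_nlm_matches_oracle(self, rng):
        data = rng.random((8, 8, 2))
        vol = Volume3D(data=data, mask=rng.random((8, 8, 2)) < 0.9)
        params = FilterParams(h2=0.2, patch_size=3)
        a = nlm_filter(vol, params)
        b = conn_nlm_oracle(vol, None, None, params)
        assert np.abs(a.data - b.data).max() < 1e-10

    def test_oracle_rejects_large_volumes(self, rng):
        vol = Volume3D(data=rng.random((20, 20, 20)))
        with pytest.raises(ValueError, match="at most"):
            conn_nlm_oracle(vol, None, None, FilterParams(h2=0.2, patch_size=3))

    def test_single_voxel_unchanged(self):
        vol = Volume3D(data=np.array([[[2.5]]]))
        out = conn_nlm_oracle(vol, None, None, FilterParams(h2=0.2, patch_size=1))
        assert out.data[0, 0, 0] == 2.5


class TestBaselines:
    def test_gaussian_delta_gives_normalized_kernel(self):
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        out = gaussian_baseline(Volume3D(data=data), 2.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.data[7, 7, 7] == out.data.max()

    def test_gaussian_uniform_unchanged(self):
        out = gaussian_baseline(Volume3D(data=np.full((8, 8, 8), 4.2)), 3.0)
        assert np.allclose(out.data, 4.2, atol=1e-12)

    def test_gaussian_mass_conserved_reflect(self, rng):
        data = rng.random((10, 10, 10))
        out = gaussian_baseline(Volume3D(data=data), 2.5)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-9)

    def test_tv_uniform_unchanged(self):
        out = tv_baseline(Volume3D(data=np.full((6, 6, 6), 1.5)), weight=0.2)
        assert np.allclose(out.data, 1.5, atol=1e-10)

    def test_tv_range_and_objective_decrease(self, rng):
        data = 1.0 + rng.normal(0, 0.3, (10, 10, 6))
        out = tv_baseline(Volume3D(data=data), weight=0.15)
        assert out.data.min() >= data.min() - 1e-9
        assert out.data.max() <= data.max() + 1e-9

        def tv_norm(x):
            return sum(np.abs(np.diff(x, axis=ax)).sum() for ax in range(3))

        assert tv_norm(out.data) <= tv_norm(data)

    def test_tv_deterministic(self, rng):
        data = rng.random((8, 8, 4))
        a = tv_baseline(Volume3D(data=data), weight=0.1)
        b = tv_baseline(Volume3D(data=data), weight=0.1)
        assert np.array_equal(a.data, b.data)
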