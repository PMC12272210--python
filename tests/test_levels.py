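"""Level derivation, centerline geometry and PMJ distances."""

import numpy as np
import pytest
from scipy.integrate import quad

from rootlet_levels import (
    LabelVolume,
    PhantomSpec,
    PhysicalPoint,
    derive_spinal_levels,
    dilate_mask,
    extract_centerline,
    generate_phantom,
    intersect_rootlets,
    measure_levels,
    pmj_distance,
    random_phantom_spec,
    resample,
)

from conftest import make_volume


def sine_arc_quadrature(spec: PhantomSpec, z0: float, z1: float) -> float:
    """Independent oracle: arc length of the generating sagittal-sine curve
    between superior-inferior positions z0 and z1 (mm)."""
    w = 2.0 * np.pi / spec.sine_period

    def integrand(z):
        return np.sqrt(1.0 + (spec.sine_amplitude * w * np.cos(w * z)) ** 2)

    val, _ = quad(integrand, z0, z1, limit=200)
    return val


class TestDilate:
    def test_radius_zero_is_identity(self, rng):
        m = make_volume((rng.random((6, 6, 6)) < 0.3).astype(np.int16))
        out = dilate_mask(m, 0)
        assert np.array_equal(out.data, m.data)

    def test_single_voxel_radius_3_manhattan_ball(self):
        """Brute-force enumeration of the 7^3 neighbourhood: iterating the
        6-neighbour element 3 times yields the Manhattan ball |d|_1 <= 3."""
        data = np.zeros((9, 9, 9), dtype=np.int16)
        data[4, 4, 4] = 1
        out = dilate_mask(make_volume(data), 3)
        expected = 0
        for di in range(-3, 4):
            for dj in range(-3, 4):
                for dk in range(-3, 4):
                    if abs(di) + abs(dj) + abs(dk) <= 3:
                        expected += 1
                        assert out.data[4 + di, 4 + dj, 4 + dk] == 1
        assert int(out.data.sum()) == expected == 63

    def test_dilation_composes(self, rng):
        m = make_volume((rng.random((8, 8, 8)) < 0.2).astype(np.int16))
        once_then_twice = dilate_mask(dilate_mask(m, 1), 2)
        assert np.array_equal(once_then_twice.data, dilate_mask(m, 3).data)

    def test_input_subset_of_output(self, rng):
        m = make_volume((rng.random((8, 8, 8)) < 0.2).astype(np.int16))
        out = dilate_mask(m, 2)
        assert np.all(out.data[m.data > 0] == 1)

    def test_non_binary_rejected(self):
        data = np.zeros((3, 3, 3), dtype=np.int16)
        data[1, 1, 1] = 2
        with pytest.raises(ValueError, match="binary"):
            dilate_mask(make_volume(data), 1)


class TestIntersect:
    def test_full_mask_is_identity(self, rng):
        r = make_volume(rng.integers(0, 5, size=(5, 5, 5)).astype(np.int16))
        ones = make_volume(np.ones((5, 5, 5), dtype=np.int16))
        assert np.array_equal(intersect_rootlets(r, ones).data, r.data)

    def test_disjoint_supports_give_zero(self):
        r = np.zeros((5, 5, 5), dtype=np.int16)
        c = np.zeros((5, 5, 5), dtype=np.int16)
        r[0, 0, 0] = 3
        c[4, 4, 4] = 1
        out = intersect_rootlets(make_volume(r), make_volume(c))
        assert not out.data.any()

    def test_grid_mismatch_rejected(self):
        a = make_volume(np.zeros((4, 4, 4), dtype=np.int16))
        b = make_volume(np.zeros((4, 4, 4), dtype=np.int16), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="grid"):
            intersect_rootlets(a, b)

    def test_phantom_rootlets_intersect_every_level(self, default_phantom):
        _, cord, rootlets, truth = default_phantom
        inter = intersect_rootlets(rootlets, dilate_mask(cord, 3))
        for v in truth.spans:
            assert (inter.data == v).any()


class TestDeriveSpinalLevels:
    def test_noise_free_phantom_recovers_truth(self, default_phantom):
        _, cord, rootlets, truth = default_phantom
        ls = derive_spinal_levels(rootlets, cord, 3)
        assert ls.absent_labels == []
        for s in ls.spans:
            assert (s.rostral_slice, s.caudal_slice) == truth.spans[s.label]

    @pytest.mark.parametrize("seed", range(6))
    def test_randomized_phantoms_recover_truth(self, seed):
        rng = np.random.default_rng(seed)
        spec = random_phantom_spec(rng)
        cord, rootlets, truth = generate_phantom(spec)
        ls = derive_spinal_levels(rootlets, cord, 3)
        assert ls.absent_labels == []
        got = {s.label: (s.rostral_slice, s.caudal_slice) for s in ls.spans}
        assert got == truth.spans

    def test_all_zero_rootlets_all_absent(self, default_phantom):
        _, cord, _, _ = default_phantom
        empty = LabelVolume(np.zeros(cord.shape, dtype=np.int16), cord.affine)
        ls = derive_spinal_levels(empty, cord, 3, labels=range(2, 9))
        assert ls.absent_labels == list(range(2, 9))
        assert not ls.levels_volume.data.any()

    def test_levels_volume_subset_of_cord(self, default_phantom):
        _, cord, rootlets, _ = default_phantom
        ls = derive_spinal_levels(rootlets, cord, 3)
        assert not ls.levels_volume.data[cord.data == 0].any()

    def test_shared_boundary_slice_goes_rostral(self):
        """Two levels overlapping on one slice: the slice belongs to the
        more rostral (smaller) label and a warning is raised."""
        cord, _, _ = generate_phantom(PhantomSpec())
        shared = 15
        rootlets = np.zeros(cord.shape, dtype=np.int16)
        rootlets[22, 23, 6 : shared + 1] = 2  # near the cord center
        rootlets[25, 23, shared:24] = 3  # starts on level 2's caudal slice
        rootlets_vol = LabelVolume(rootlets, cord.affine)
        with pytest.warns(UserWarning, match="overlap"):
            ls = derive_spinal_levels(rootlets_vol, cord, 3)
        vol = ls.levels_volume.data
        assert set(np.unique(vol[:, :, shared])) == {0, 2}
        assert ls.span(2).caudal_slice == shared
        assert ls.span(3).rostral_slice == shared

    def test_empty_cord_rejected(self, default_phantom):
        _, _, rootlets, _ = default_phantom
        empty = LabelVolume(np.zeros(rootlets.shape, dtype=np.int16), rootlets.affine)
        with pytest.raises(ValueError, match="cord"):
            derive_spinal_levels(rootlets, empty, 3)

    def test_dilation_radius_monotone(self, sine_phantom):
        _, cord, rootlets, _ = sine_phantom
        prev = None
        for radius in (1, 2, 3, 5):
            ls = derive_spinal_levels(rootlets, cord, radius)
            spans = {s.label: (s.rostral_slice, s.caudal_slice) for s in ls.spans}
            if prev is not None:
                for v, (r0, c0) in prev.items():
                    r1, c1 = spans[v]
                    assert r1 <= r0 and c1 >= c0
            prev = spans


class TestCenterline:
    def test_straight_tube_arc_exact(self):
        spec = PhantomSpec(shape=(32, 32, 50), levels=[(2, 5.0, 12.0)])
        cord, _, _ = generate_phantom(spec)
        cl = extract_centerline(cord)
        assert cl.cumulative_arc_mm[-1] == pytest.approx(49 * 0.8, abs=1e-9)
        assert np.allclose(np.diff(cl.cumulative_arc_mm), 0.8, atol=1e-9)

    def test_sine_arc_matches_quadrature(self, sine_phantom):
        spec, cord, _, _ = sine_phantom
        cl = extract_centerline(cord)
        z_total = (spec.shape[2] - 1) * spec.spacing[2]
        oracle = sine_arc_quadrature(spec, 0.0, z_total)
        assert abs(cl.cumulative_arc_mm[-1] - oracle) / oracle < 0.01

    def test_arc_at_least_euclidean(self, sine_phantom):
        _, cord, _, _ = sine_phantom
        cl = extract_centerline(cord)
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = sorted(rng.integers(0, len(cl.points), size=2))
            arc = cl.cumulative_arc_mm[j] - cl.cumulative_arc_mm[i]
            chord = np.linalg.norm(cl.points[j] - cl.points[i])
            assert arc >= chord - 1e-9

    def test_multi_component_slice_uses_largest(self):
        data = np.zeros((12, 12, 4), dtype=np.int16)
        data[2:7, 2:7, :] = 1  # 25-voxel component
        data[9:11, 9:11, 1] = 1  # small spurious island on one slice
        with pytest.warns(UserWarning, match="largest"):
            cl = extract_centerline(make_volume(data))
        # centerline stays at the big component's center on every slice
        assert np.allclose(cl.points[:, 0], cl.points[0, 0])

    def test_single_slice_cord_rejected(self):
        data = np.zeros((6, 6, 3), dtype=np.int16)
        data[2:4, 2:4, 1] = 1
        with pytest.raises(ValueError, match="2 slices"):
            extract_centerline(make_volume(data))

    def test_smoothing_preserves_straight_line(self):
        spec = PhantomSpec(shape=(32, 32, 50), levels=[(2, 5.0, 12.0)])
        cord, _, _ = generate_phantom(spec)
        cl = extract_centerline(cord, smoothing_mm=4.0)
        assert np.allclose(np.diff(cl.cumulative_arc_mm), 0.8, atol=1e-9)


class TestPmjDistance:
    def test_straight_cord_distance_is_slice_offset(self, default_phantom):
        spec, cord, _, truth = default_phantom
        cl = extract_centerline(cord)
        k_pmj = round(spec.pmj_offset / spec.spacing[2])
        d = pmj_distance(cl, truth.pmj, k_pmj + 10)
        assert d == pytest.approx(8.0, abs=1e-6)

    def test_distance_to_own_slice_is_euclidean_offset(self, default_phantom):
        spec, cord, _, truth = default_phantom
        cl = extract_centerline(cord)
        k_pmj = round(spec.pmj_offset / spec.spacing[2])
        d = pmj_distance(cl, truth.pmj, k_pmj)
        offset = np.linalg.norm(cl.point_at(k_pmj) - truth.pmj.as_array())
        assert d == pytest.approx(offset, abs=1e-9)

    def test_curved_distance_matches_quadrature(self, sine_phantom):
        spec, cord, _, truth = sine_phantom
        cl = extract_centerline(cord)
        sz = spec.spacing[2]
        k_pmj = round(spec.pmj_offset / sz)
        k_mid = 48
        oracle = sine_arc_quadrature(spec, k_pmj * sz, k_mid * sz)
        d = pmj_distance(cl, truth.pmj, k_mid)
        assert abs(d - oracle) <= sz

    def test_slice_outside_coverage_rejected(self, default_phantom):
        _, cord, _, truth = default_phantom
        cl = extract_centerline(cord)
        with pytest.raises(ValueError, match="coverage"):
            pmj_distance(cl, truth.pmj, 10_000)


class TestMeasureLevels:
    def test_straight_span_length(self, default_phantom):
        _, cord, rootlets, truth = default_phantom
        ls = derive_spinal_levels(rootlets, cord, 3)
        cl = extract_centerline(cord)
        measure_levels(ls, cl, truth.pmj)
        for s in ls.spans:
            n_slices = s.caudal_slice - s.rostral_slice
            assert s.length_mm == pytest.approx(n_slices * 0.8, abs=1e-6)
            assert s.d_rostral <= s.d_middle <= s.d_caudal
            assert s.length_mm == pytest.approx(s.d_caudal - s.d_rostral)

    def test_single_slice_span_degenerate(self):
        spec = PhantomSpec(levels=[(2, 8.0, 8.7)])  # rounds to one slice pair
        cord, rootlets, truth = generate_phantom(spec)
        ls = derive_spinal_levels(rootlets, cord, 3)
        cl = extract_centerline(cord)
        measure_levels(ls, cl, truth.pmj)
        (s,) = ls.spans
        if s.rostral_slice == s.caudal_slice:
            assert s.length_mm == 0.0
            assert s.d_rostral == s.d_middle == s.d_caudal

    def test_curved_length_matches_quadrature(self, sine_phantom):
        spec, cord, rootlets, truth = sine_phantom
        ls = derive_spinal_levels(rootlets, cord, 3)
        cl = extract_centerline(cord)
        measure_levels(ls, cl, truth.pmj)
        sz = spec.spacing[2]
        for s in ls.spans:
            oracle = sine_arc_quadrature(spec, s.rostral_slice * sz, s.caudal_slice * sz)
            assert abs(s.length_mm - oracle) <= sz

    def test_rostral_distance_ordered_by_level(self, sine_phantom):
        _, cord, rootlets, truth = sine_phantom
        ls = derive_spinal_levels(rootlets, cord, 3)
        cl = extract_centerline(cord)
        measure_levels(ls, cl, truth.pmj)
        d = [s.d_rostral for s in sorted(ls.spans, key=lambda s: s.label)]
        assert all(a < b for a, b in zip(d, d[1:]))


class TestResolutionRobustness:
    def test_level_positions_stable_under_downsampling(self, default_phantom):
        """Nearest-neighbour downsampling 0.8 -> 1.6 mm shifts each level's
        PMJ-to-middle distance by at most 2 mm."""
        spec, cord, rootlets, truth = default_phantom
        ls_hi = measure_levels(
            derive_spinal_levels(rootlets, cord, 3),
            extract_centerline(cord),
            truth.pmj,
        )
        cord_lo = resample(cord, 1.6, mode="nearest")
        rootlets_lo = resample(rootlets, 1.6, mode="nearest")
        ls_lo = measure_levels(
            derive_spinal_levels(rootlets_lo, cord_lo, 3),
            extract_centerline(cord_lo),
            truth.pmj,
        )
        hi = {s.label: s.d_middle for s in ls_hi.spans}
        lo = {s.label: s.d_middle for s in ls_lo.spans}
        assert set(hi) == set(lo)
        for v in hi:
            assert abs(hi[v] - lo[v]) <= 2.0
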