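"""Segmentation primitives against brute-force oracles and ground truth."""

import numpy as np
import pytest
from scipy import ndimage

from syncap import (
    CapFieldSpec,
    Image2D,
    SegmentationParams,
    blur,
    enhance_ridges,
    find_seeds,
    generate_cap_field,
    label_map_table,
    scale_intensity,
    segment_caps,
)
from syncap.cap_segmentation import boundary_lines, flood_assignment

NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------------------
# brute-force oracles


def regional_minima_bruteforce(img: np.ndarray) -> np.ndarray:
    """Exhaustive plateau search: flood each equal-value component and
    check that no 8-neighbor outside it is strictly lower."""
    h, w = img.shape
    seen = np.zeros((h, w), dtype=bool)
    minima = np.zeros((h, w), dtype=bool)
    for r0 in range(h):
        for c0 in range(w):
            if seen[r0, c0]:
                continue
            value = img[r0, c0]
            stack = [(r0, c0)]
            component = []
            seen[r0, c0] = True
            is_min = True
            while stack:
                r, c = stack.pop()
                component.append((r, c))
                for dr, dc in NEIGHBORS:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w):
                        continue
                    if img[rr, cc] == value:
                        if not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                    elif img[rr, cc] < value:
                        is_min = False
            if is_min:
                for r, c in component:
                    minima[r, c] = True
    return minima


def flood_bruteforce(relief: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Exhaustive-selection flood with the documented deterministic order.

    No heap: every step rescans the frontier for the smallest
    (relief value, frontier-entry age, row-major index) key. Frontier
    entry ages are assigned in the same documented enumeration order
    (marker pixels row-major, neighbors NW,N,NE,W,E,SW,S,SE).
    """
    h, w = relief.shape
    labels = np.asarray(markers, dtype=np.int64).copy()
    entry = {}
    assigned_entry = {}
    age = 0

    def neighbors(r, c):
        for dr, dc in NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                yield rr, cc

    def enter(r, c):
        nonlocal age
        for rr, cc in neighbors(r, c):
            if labels[rr, cc] == 0 and (rr, cc) not in entry:
                entry[(rr, cc)] = (relief[rr, cc], age, rr * w + cc)
                age += 1

    for r in range(h):
        for c in range(w):
            if labels[r, c] > 0:
                enter(r, c)

    while entry:
        pixel = min(entry, key=entry.get)
        key = entry.pop(pixel)
        r, c = pixel
        best = None
        best_label = 0
        for rr, cc in neighbors(r, c):
            if labels[rr, cc] > 0:
                if markers[rr, cc] > 0:
                    nb_key = (relief[rr, cc], -1, rr * w + cc)
                else:
                    nb_key = assigned_entry[(rr, cc)]
                if best is None or nb_key < best:
                    best = nb_key
                    best_label = labels[rr, cc]
        labels[r, c] = best_label
        assigned_entry[pixel] = key
        enter(r, c)
    return labels


def random_case(rng, max_side=16, n_values=6):
    h = int(rng.integers(4, max_side + 1))
    w = int(rng.integers(4, max_side + 1))
    relief = rng.integers(0, n_values, (h, w)).astype(float)
    markers, _ = ndimage.label(
        regional_minima_bruteforce(relief), structure=np.ones((3, 3), dtype=int)
    )
    return relief, markers


# ---------------------------------------------------------------------------
# elementwise steps


class TestScaleIntensity:
    def test_uniform_image_times_published_factor(self):
        img = Image2D(np.full((6, 6), 100.0), 0.35)
        assert np.all(scale_intensity(img, 1.25).pixels == 125.0)

    def test_identity_factor(self):
        img = Image2D(np.random.default_rng(0).random((8, 8)), 0.35)
        assert np.array_equal(scale_intensity(img, 1.0).pixels, img.pixels)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(1)
        pixels = rng.random((8, 8)) * 200
        out = scale_intensity(Image2D(pixels, 0.35), 1.25).pixels
        for r in range(8):
            for c in range(8):
                assert out[r, c] == pixels[r, c] * 1.25

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            scale_intensity(Image2D(np.ones((4, 4)), 1.0), 0.0)


class TestBlur:
    def test_delta_impulse_gives_gaussian_kernel_peaked_at_impulse(self):
        pixels = np.zeros((33, 33))
        pixels[16, 16] = 1.0
        out = blur(Image2D(pixels, 1.0), 4.0).pixels
        assert out.argmax() == 16 * 33 + 16
        assert out.sum() == pytest.approx(1.0, rel=1e-6)

    def test_uniform_image_unchanged(self):
        out = blur(Image2D(np.full((20, 20), 7.0), 1.0), 5.0).pixels
        assert np.allclose(out, 7.0, rtol=1e-12)

    def test_matches_dense_reflective_convolution_oracle(self):
        rng = np.random.default_rng(2)
        pixels = rng.random((16, 16))
        sigma = 4.0
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        padded = np.pad(pixels, radius, mode="symmetric")
        expected = np.empty_like(pixels)
        for r in range(16):
            for c in range(16):
                window = padded[r : r + 2 * radius + 1, c : c + 2 * radius + 1]
                expected[r, c] = kernel @ window @ kernel
        out = blur(Image2D(pixels, 1.0), sigma).pixels
        assert np.allclose(out, expected, rtol=1e-6, atol=1e-9)


class TestEnhanceRidges:
    def test_constant_image_has_zero_response(self):
        params = SegmentationParams()
        out = enhance_ridges(Image2D(np.full((40, 40), 50.0), 1.0), params)
        assert np.all(out.pixels == 0)

    def test_bright_line_dominates_background_tenfold(self):
        pixels = np.full((48, 48), 10.0)
        pixels[24:26, :] = 200.0
        out = enhance_ridges(Image2D(pixels, 1.0), SegmentationParams()).pixels
        on_line = out[24, 24]
        off_line = max(out[29, 24], out[19, 24])
        assert on_line >= 10 * off_line
        assert 0 <= out.max() <= 1

    def test_large_disk_interior_flat_boundary_elevated(self):
        h = w = 96
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        disk = (rr - 48) ** 2 + (cc - 48) ** 2 <= 30**2
        pixels = np.where(disk, 200.0, 10.0)
        out = enhance_ridges(Image2D(pixels, 1.0), SegmentationParams()).pixels
        interior = out[40:57, 40:57].max()
        ring = out[48, 48 - 31 : 48 - 27].max()
        assert ring > 10 * interior

    def test_empty_scale_list_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(frangi_scales_px=())


class TestFindSeeds:
    def test_two_strict_minima_give_two_seeds(self):
        pixels = np.full((11, 11), 5.0)
        pixels[2, 2] = 1.0
        pixels[8, 8] = 0.5
        markers = find_seeds(Image2D(pixels, 1.0))
        assert markers.max() == 2

    def test_constant_image_is_one_plateau(self):
        markers = find_seeds(Image2D(np.full((9, 9), 3.0), 1.0))
        assert markers.max() == 1
        assert np.all(markers == 1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_plateau_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pixels = rng.integers(0, 5, (12, 12)).astype(float)
        markers = find_seeds(Image2D(pixels, 1.0))
        expected = regional_minima_bruteforce(pixels)
        assert np.array_equal(markers > 0, expected)
        n_expected, _ = ndimage.label(expected, structure=np.ones((3, 3), dtype=int))[1], None
        assert markers.max() == ndimage.label(expected, structure=np.ones((3, 3), dtype=int))[1]


# ---------------------------------------------------------------------------
# watershed flooding


class TestFloodAssignment:
    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_exhaustive_selection_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        relief, markers = random_case(rng)
        if markers.max() == 0:
            pytest.skip("degenerate random case without markers")
        fast = flood_assignment(relief, markers)
        slow = flood_bruteforce(relief, markers)
        assert np.array_equal(fast, slow)

    def test_flat_plateau_split_evenly_between_two_markers(self):
        relief = np.zeros((5, 12))
        markers = np.zeros((5, 12), dtype=int)
        markers[2, 0] = 1
        markers[2, 11] = 2
        out = flood_assignment(relief, markers)
        assert np.all(out[:, :6] == 1)
        assert np.all(out[:, 6:] == 2)

    def test_every_pixel_assigned_to_exactly_one_marker_basin(self):
        rng = np.random.default_rng(42)
        relief, markers = random_case(rng)
        out = flood_assignment(relief, markers)
        assert np.all(out > 0)
        assert set(np.unique(out)) == set(range(1, markers.max() + 1))

    def test_lines_are_thin_and_separate_basins(self):
        rng = np.random.default_rng(7)
        relief, markers = random_case(rng, max_side=14)
        assignment = flood_assignment(relief, markers)
        lined = boundary_lines(assignment)
        # non-line pixels keep their basin; every basin survives
        assert np.all((lined == 0) | (lined == assignment))
        if markers.max() > 1:
            assert (lined == 0).any()


class TestSegmentCaps:
    def test_two_cap_field_recovers_both_areas_within_five_percent(self, cap_params):
        spec = CapFieldSpec(
            field_size_px=(36, 72),
            pixel_size_um=0.35,
            n_caps=2,
            cap_area_mean_um2=120.0,
            cap_area_sd_um2=10.0,
            noise_sd=0.0,
            seed=0,
        )
        img, gt = generate_cap_field(spec)
        label_map = segment_caps(img, cap_params)
        assert label_map.n_regions == 2
        table = label_map_table(label_map)
        recovered = np.sort(table["area_um2"].to_numpy())
        truth = np.sort(gt.table["area_um2"].to_numpy())
        assert np.all(np.abs(recovered - truth) / truth < 0.05)

    def test_constant_image_degenerates_to_single_region(self, cap_params):
        img = Image2D(np.full((48, 48), 80.0), 0.35)
        label_map = segment_caps(img, cap_params)
        assert label_map.n_regions == 1

    def test_partition_and_seed_region_bijection(self, cap_params):
        spec = CapFieldSpec(field_size_px=(132, 132), n_caps=16, seed=8)
        img, _ = generate_cap_field(spec)
        scaled = scale_intensity(img, cap_params.intensity_scale)
        ridge = enhance_ridges(scaled, cap_params)
        blurred = blur(ridge, cap_params.gauss_sigma_px)
        n_seeds = find_seeds(blurred, cap_params.seed_quantize_levels).max()
        label_map = segment_caps(img, cap_params)
        labels = label_map.labels
        # labels and boundary cover the raster; regions are 1..n_seeds
        assert labels.min() == 0
        assert set(np.unique(labels[labels > 0])) <= set(range(1, n_seeds + 1))
        assert label_map.n_regions == n_seeds
        for lab in range(1, n_seeds + 1):
            _, n_components = ndimage.label(labels == lab, structure=np.ones((3, 3), int))
            assert n_components <= 1

    def test_small_region_merge(self, cap_params):
        spec = CapFieldSpec(field_size_px=(132, 132), n_caps=16, seed=8)
        img, _ = generate_cap_field(spec)
        merged_params = cap_params.model_copy(update={"min_region_area_um2": 40.0})
        label_map = segment_caps(img, merged_params)
        table = label_map_table(label_map, boundary_attribution=False)
        assert (table["area_um2"] >= 40.0).all()

    def test_area_error_does_not_grow_as_noise_vanishes(self, cap_params):
        """Monotone robustness: noiseless error <= noisy error (same field)."""
        from conftest import segment_and_match

        errs = {}
        for noise in (0.0, 12.0):
            spec = CapFieldSpec(seed=4, noise_sd=noise)
            _, errors, _, _ = segment_and_match(spec, cap_params)
            errs[noise] = np.median(errors)
        assert errs[0.0] <= errs[12.0] + 1e-3
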