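"""Morphology, thresholding and watershed against brute-force oracles."""

import heapq

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumicat import segment


# ---------------------------------------------------------------------------
# Set-theoretic oracles: dilation as union of translates, erosion as
# intersection of translates.
# ---------------------------------------------------------------------------

def oracle_dilate(a: np.ndarray, offsets) -> np.ndarray:
    h, w = a.shape
    out = np.zeros_like(a, dtype=bool)
    for r in range(h):
        for c in range(w):
            if a[r, c]:
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        out[rr, cc] = True
    return out


def oracle_erode(a: np.ndarray, offsets) -> np.ndarray:
    h, w = a.shape
    out = np.zeros_like(a, dtype=bool)
    for r in range(h):
        for c in range(w):
            out[r, c] = all(
                0 <= r + dr < h and 0 <= c + dc < w and a[r + dr, c + dc]
                for dr, dc in offsets
            )
    return out


def oracle_reconstruct_by_dilation(marker, mask):
    """Iterated 8-connected geodesic dilation under the mask, to stability."""
    cur = np.minimum(marker, mask)
    n8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    while True:
        grown = cur.copy()
        for dr, dc in n8:
            shifted = np.full_like(cur, -np.inf)
            h, w = cur.shape
            rs = slice(max(0, dr), min(h, h + dr))
            cs = slice(max(0, dc), min(w, w + dc))
            rs_s = slice(max(0, -dr), min(h, h - dr))
            cs_s = slice(max(0, -dc), min(w, w - dc))
            shifted[rs, cs] = cur[rs_s, cs_s]
            grown = np.maximum(grown, shifted)
        grown = np.minimum(grown, mask)
        if np.array_equal(grown, cur):
            return cur
        cur = grown


def oracle_priority_flood(height, markers, connectivity=1):
    """Exhaustive priority flood with a sorted frontier (ties: raster order)."""
    h, w = height.shape
    labels = np.zeros((h, w), dtype=int)
    heap = []
    order = 0
    for r in range(h):
        for c in range(w):
            if markers[r, c]:
                labels[r, c] = markers[r, c]
                heapq.heappush(heap, (height[r, c], order, r, c))
                order += 1
    neigh = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    while heap:
        _, _, r, c = heapq.heappop(heap)
        for dr, dc in neigh:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] == 0:
                labels[rr, cc] = labels[r, c]
                heapq.heappush(heap, (height[rr, cc], order, rr, cc))
                order += 1
    return labels


@pytest.fixture
def small_sets(rng):
    """Random binary rasters with random small structuring elements."""
    cases = []
    for _ in range(40):
        h, w = rng.integers(3, 9, size=2)
        a = rng.random((h, w)) < 0.4
        n_off = rng.integers(1, 5)
        offs = {
            (int(dr), int(dc))
            for dr, dc in rng.integers(-2, 3, size=(n_off, 2))
        }
        cases.append((a, sorted(offs)))
    return cases


class TestBinaryMorphology:
    def test_identity_element(self, rng):
        a = rng.random((6, 6)) < 0.5
        se = [(0, 0)]
        assert np.array_equal(segment.dilate(a, se), a)
        assert np.array_equal(segment.erode(a, se), a)

    def test_two_cell_se_matches_union_oracle(self):
        a = np.zeros((4, 4), dtype=bool)
        a[1, 1] = True
        se = [(0, 0), (0, 1)]
        out = segment.dilate(a, se)
        assert out.sum() == 2 and out[1, 1] and out[1, 2]
        assert np.array_equal(out, oracle_dilate(a, se))
        pair = np.zeros((3, 4), dtype=bool)
        pair[1, 1] = pair[1, 2] = True
        assert np.array_equal(segment.erode(pair, se), oracle_erode(pair, se))
        assert segment.erode(pair, se).sum() == 1

    def test_matches_set_oracles_on_random_rasters(self, small_sets):
        for a, offs in small_sets:
            assert np.array_equal(segment.dilate(a, offs), oracle_dilate(a, offs))
            assert np.array_equal(segment.erode(a, offs), oracle_erode(a, offs))

    def test_extensivity_and_sandwich(self, rng):
        a = rng.random((8, 8)) < 0.4
        se = [(0, 0), (1, 0), (0, 1)]
        dil = segment.dilate(a, se)
        assert (a <= dil).all()  # A subset of A+B when origin in B
        opened = segment.opening(a, se)
        closed = segment.closing(a, se)
        assert (opened <= a).all() and (a <= closed).all()

    def test_opening_removes_small_objects_closing_fills_holes(self):
        a = np.zeros((9, 9), dtype=bool)
        a[4, 4] = True  # single pixel, smaller than a 3x3 SE
        se3 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
        assert not segment.opening(a, se3).any()
        b = np.ones((9, 9), dtype=bool)
        b[4, 4] = False  # 1-pixel hole
        assert segment.closing(b, se3).all()

    def test_opening_idempotent(self, small_sets):
        for a, offs in small_sets[:15]:
            once = segment.opening(a, offs)
            assert np.array_equal(segment.opening(once, offs), once)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_duality_dilation_vs_erosion(self, seed):
        """dilate(A,B) is the complement of eroding the complement with -B."""
        local = np.random.default_rng(seed)
        a = local.random((8, 8)) < 0.5
        offs = [(0, 0), (1, 1), (-1, 0)]
        reflected = [(-dr, -dc) for dr, dc in offs]
        pad = 3
        big = np.zeros((8 + 2 * pad, 8 + 2 * pad), dtype=bool)
        big[pad:-pad, pad:-pad] = a
        left = segment.dilate(big, offs)[pad:-pad, pad:-pad]
        right = ~segment.erode(~big, reflected)[pad:-pad, pad:-pad]
        assert np.array_equal(left, right)


class TestGrayscaleMorphologyAndReconstruction:
    def test_flat_image_unchanged(self):
        f = np.full((6, 6), 3.0)
        se = segment.disc_se(1)
        assert np.array_equal(segment.open_by_reconstruction(f, se), f)
        assert np.array_equal(segment.close_by_reconstruction(f, se), f)

    def test_reconstruction_sandwich(self, rng):
        f = rng.integers(0, 10, size=(10, 10)).astype(float)
        se = segment.disc_se(1)
        rec = segment.open_by_reconstruction(f, se)
        plain = segment.opening(f, se)
        assert np.all(rec >= plain - 1e-12)
        assert np.all(rec <= f + 1e-12)

    def test_two_peak_profile_levels_only_the_narrow_peak(self):
        f = np.zeros((1, 30))
        f[0, 5] = 10.0  # one-pixel peak: leveled by a 3-wide SE
        f[0, 15:20] = 7.0  # broad plateau: preserved at full height
        se = [(0, -1), (0, 0), (0, 1)]
        rec = segment.open_by_reconstruction(f, se)
        marker = segment.erode(f, se)
        expected = oracle_reconstruct_by_dilation(marker, f)
        assert np.allclose(rec, expected)
        assert rec[0, 5] == 0.0
        assert rec[0, 17] == 7.0

    def test_matches_geodesic_oracle_on_random_rasters(self, rng):
        se = [(0, 0), (0, 1), (1, 0)]
        for _ in range(10):
            f = rng.integers(0, 8, size=(7, 7)).astype(float)
            rec = segment.open_by_reconstruction(f, se)
            marker = segment.erode(f, se)
            assert np.allclose(rec, oracle_reconstruct_by_dilation(marker, f))


class TestGradient:
    def test_constant_raster_zero(self):
        assert np.all(segment.gradient_magnitude(np.full((6, 6), 9.0)) == 0)

    def test_ramp_matches_finite_difference_oracle(self):
        f = np.tile(np.arange(5, dtype=float), (5, 1))  # f(r,c) = c
        mag = segment.gradient_magnitude(f)
        # Sobel weights sum to 8 on a unit ramp; g_y = 0
        assert np.allclose(mag[1:-1, 1:-1], 8.0)

    def test_step_edge_peaks_on_the_edge(self):
        f = np.zeros((7, 7))
        f[:, 4:] = 10.0
        mag = segment.gradient_magnitude(f)
        assert mag[3, 3] > 0 and mag[3, 4] > 0
        assert mag[3, 1] == 0.0


class TestThreshold:
    def test_bimodal_separated_exactly(self):
        f = np.zeros((4, 8))
        f[:, 4:] = 255.0
        bg = segment.threshold_background(f)
        assert bg[:, :4].all() and not bg[:, 4:].any()

    def test_constant_input_single_class(self):
        assert not segment.threshold_background(np.full((5, 5), 7.0)).any()

    def test_two_gaussian_histogram_matches_variance_scan(self, rng):
        vals = np.concatenate(
            [rng.normal(60, 10, 600), rng.normal(180, 10, 600)]
        ).clip(0, 255)
        f = vals.reshape(30, 40)
        bg = segment.threshold_background(f)
        # the implied threshold separates the two cluster cores: essentially
        # all low-mode mass below it, all high-mode mass above it
        assert bg.sum() == pytest.approx(600, abs=12)
        assert f[bg].max() < 150 and f[~bg].max() > 150
        # brute-force between-class variance maximization over 256 candidates
        best_t, best_v = None, -1.0
        for t in np.linspace(f.min(), f.max(), 256):
            lo, hi = f[f < t], f[f >= t]
            if lo.size == 0 or hi.size == 0:
                continue
            v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_v, best_t = v, t
        th = f[~bg].min()
        assert abs(th - best_t) <= 3

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            segment.threshold_background(np.ones((3, 3)), np.zeros((3, 3), bool))


class TestWatershed:
    def test_single_marker_floods_whole_mask(self):
        grad = np.zeros((9, 9))
        fg = np.zeros((9, 9), dtype=bool)
        fg[4, 4] = True
        labels = segment.watershed_segment(grad, fg)
        assert (labels > 0).all()
        assert len(np.unique(labels)) == 1

    def test_empty_markers_rejected(self):
        with pytest.raises(ValueError):
            segment.watershed_segment(np.zeros((5, 5)), np.zeros((5, 5), bool))

    def test_region_count_equals_marker_components(self, rng):
        grad = rng.random((12, 12))
        fg = np.zeros((12, 12), dtype=bool)
        fg[2, 2] = fg[2, 9] = fg[9, 5] = True
        labels = segment.watershed_segment(grad, fg)
        assert len([l for l in np.unique(labels) if l > 0]) == 3

    def test_two_markers_on_flat_raster_split_equidistantly(self):
        """4-connected flooding grows city-block balls: away from city-block
        ties every pixel joins its nearer marker; the ridge sits on the tie
        set (within 1 step)."""
        grad = np.zeros((11, 11))
        fg = np.zeros((11, 11), dtype=bool)
        fg[2, 2] = fg[8, 8] = True
        labels = segment.watershed_segment(grad, fg)
        # partition: every pixel is ridge (0) or exactly one region
        assert set(np.unique(labels)) <= {0, 1, 2}
        d1 = np.fromfunction(
            lambda r, c: np.abs(r - 2) + np.abs(c - 2), (11, 11)
        )
        d2 = np.fromfunction(
            lambda r, c: np.abs(r - 8) + np.abs(c - 8), (11, 11)
        )
        lab1, lab2 = labels[2, 2], labels[8, 8]
        assert np.all(labels[d1 < d2] == lab1)
        assert np.all(labels[d2 < d1] == lab2)
        assert np.all(np.abs(d1 - d2)[labels == 0] <= 1.0)
        # on the main diagonal the metrics agree: the ridge crosses it at the
        # Euclidean midpoint
        assert labels[5, 5] == 0

    def test_matches_priority_flood_oracle_away_from_ties(self, rng):
        grad = rng.random((9, 9))  # continuous: no priority ties
        fg = np.zeros((9, 9), dtype=bool)
        fg[1, 1] = fg[7, 7] = True
        labels = segment.watershed_segment(grad, fg)
        markers = np.zeros((9, 9), dtype=int)
        markers[1, 1], markers[7, 7] = 1, 2
        oracle = oracle_priority_flood(grad, markers)
        agree = (labels > 0)  # ignore ridge pixels
        relabeled = np.where(labels == labels[1, 1], 1, 2)
        assert (relabeled[agree] == oracle[agree]).mean() > 0.9


class TestOverlay:
    def test_empty_labels_return_original(self, rng):
        img = rng.integers(0, 255, size=(6, 6, 3)).astype(np.uint8)
        out = segment.overlay_segmentation(img, np.zeros((6, 6), dtype=int))
        assert np.array_equal(out, img)

    def test_all_ridge_with_mask_fully_recolored(self):
        img = np.zeros((5, 5, 3), dtype=np.uint8)
        out = segment.overlay_segmentation(
            img, np.zeros((5, 5), dtype=int), mask=np.ones((5, 5), bool)
        )
        assert (out != 0).any(axis=2).all()

    def test_nondestructive_outside_ridges(self, rng):
        img = rng.integers(0, 255, size=(8, 8, 3)).astype(np.uint8)
        labels = np.ones((8, 8), dtype=int)
        labels[4, :] = 0
        out = segment.overlay_segmentation(img, labels, mask=np.ones((8, 8), bool))
        assert np.array_equal(out[labels > 0], img[labels > 0])


class TestSegmentRoi:
    def test_partitions_the_lens_mask(self, masked_lens):
        labels, overlay = segment.segment_roi(masked_lens)
        assert labels.shape == masked_lens.mask.shape
        assert overlay.shape == masked_lens.image.shape
        assert labels.max() >= 1
        # outside the ROI nothing is labeled
        assert np.all(labels[~masked_lens.mask] == 0)
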