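"""Coarse boundary stage: thresholding, morphology, edges, contour tracing."""

import numpy as np
import pytest

from boundaryseg import (
    DISK_5X5,
    SQUARE_2X2,
    StructuringElement,
    binarize,
    dilate,
    erode,
    extract_coarse_contour,
    extract_edges,
    iou,
    otsu_threshold,
    region_from_keypoints,
    trace_contour,
)
from boundaryseg.errors import (
    DegenerateInputError,
    EmptyMaskError,
    OpenContourError,
    PipelineStageError,
)

from conftest import random_blob_mask


# ---------------------------------------------------------------- oracles


def otsu_exhaustive(img):
    """Independent Otsu oracle: scan all 256 histogram bins for the
    threshold maximizing between-class variance."""
    arr = np.asarray(img, dtype=np.float64)
    counts, edges = np.histogram(arr.ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    variances = np.full(255, -np.inf)
    for k in range(255):  # split between bin k and k+1; threshold at bin-k centre
        n0 = counts[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        w0 = n0 / total
        w1 = 1.0 - w0
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / n1
        variances[k] = w0 * w1 * (mu0 - mu1) ** 2
    best = variances.max()
    # floating-point ties across adjacent splits are legitimate maximizers
    tied = np.nonzero(variances >= best * (1 - 1e-12))[0]
    return centers[tied]


def morph_bruteforce(mask, se, op, border=0):
    """Pure-python structuring-element sliding (erosion/dilation oracle)."""
    m = np.asarray(mask) > 0
    h, w = m.shape
    out = np.zeros((h, w), dtype=np.uint8)
    offs = np.argwhere(np.asarray(se.footprint, bool)) - np.asarray(se.origin)
    if op == "dilate":
        offs = -offs
    for r in range(h):
        for c in range(w):
            vals = []
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                vals.append(m[rr, cc] if 0 <= rr < h and 0 <= cc < w else bool(border))
            out[r, c] = all(vals) if op == "erode" else any(vals)
    return out


def inner_boundary_bruteforce(mask):
    """4-neighbour inner-boundary oracle (background padding)."""
    m = np.asarray(mask) > 0
    h, w = m.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            if not m[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                    out[r, c] = 1
                    break
    return out


# ---------------------------------------------------------------- Otsu


class TestOtsu:
    def test_bimodal_image_separates_modes(self):
        img = np.empty((16, 16), dtype=np.uint8)
        img[:8] = 10
        img[8:] = 200
        t = otsu_threshold(img)
        fg = binarize(img, t)
        assert fg.sum() == 128
        assert (fg[8:] == 1).all() and (fg[:8] == 0).all()

    def test_constant_image_raises_naming_value(self):
        with pytest.raises(DegenerateInputError, match="0.5"):
            otsu_threshold(np.full((8, 8), 0.5))

    def test_two_value_threshold_strictly_between(self):
        img = np.zeros((8, 8))
        img[0, 0] = 1.0
        t = otsu_threshold(img)
        assert 0.0 < t < 1.0

    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(50):
            img = rng.random((12, 12))
            t = otsu_threshold(img)
            tied_maximizers = otsu_exhaustive(img)
            assert np.isclose(tied_maximizers, t, atol=1e-12).any()


class TestBinarize:
    @pytest.mark.parametrize(
        "values,threshold,expected_fraction",
        [((0.9, 0.9), 0.5, 1.0), ((0.1, 0.1), 0.5, 0.0), ((0.2, 0.8), 0.5, 0.5)],
    )
    def test_threshold_semantics(self, values, threshold, expected_fraction):
        img = np.array([[values[0], values[1]]] * 4)
        mask = binarize(img, threshold)
        assert mask.mean() == expected_fraction
        assert set(np.unique(mask)) <= {0, 1}


# ---------------------------------------------------------------- morphology


class TestMorphology:
    def test_erode_square_matches_footprint_sliding(self):
        m = np.zeros((6, 6), dtype=np.uint8)
        m[1:4, 1:4] = 1  # 3x3 block
        out = erode(m, SQUARE_2X2)
        assert np.array_equal(out, morph_bruteforce(m, SQUARE_2X2, "erode"))
        assert out.sum() == 4  # 2x2 anchors that fit

    def test_dilate_single_pixel_stamps_disk(self):
        m = np.zeros((9, 9), dtype=np.uint8)
        m[4, 4] = 1
        out = dilate(m, DISK_5X5)
        assert np.array_equal(out, morph_bruteforce(m, DISK_5X5, "dilate"))
        assert out.sum() == DISK_5X5.footprint.sum()

    def test_empty_mask_fixed_points(self):
        empty = np.zeros((8, 8), dtype=np.uint8)
        assert erode(empty, SQUARE_2X2).sum() == 0
        assert dilate(empty, DISK_5X5).sum() == 0

    @pytest.mark.parametrize("se", [SQUARE_2X2, DISK_5X5], ids=["square2", "disk5"])
    def test_anti_extensivity_and_extensivity(self, rng, se):
        for _ in range(20):
            m = random_blob_mask(rng)
            er = erode(m, se)
            di = dilate(m, se)
            assert not (er & ~m).any()  # erosion shrinks
            assert not (m & ~di).any()  # dilation grows

    @pytest.mark.parametrize("se", [SQUARE_2X2, DISK_5X5], ids=["square2", "disk5"])
    def test_matches_bruteforce_on_random_masks(self, rng, se):
        for _ in range(100):
            m = random_blob_mask(rng)
            assert np.array_equal(erode(m, se), morph_bruteforce(m, se, "erode"))
            assert np.array_equal(dilate(m, se), morph_bruteforce(m, se, "dilate"))

    @pytest.mark.parametrize("se", [SQUARE_2X2, DISK_5X5], ids=["square2", "disk5"])
    def test_erosion_dilation_duality(self, rng, se):
        # dilate(m) == ~erode(~m, reflected se); the complement's exterior is
        # foreground, so its erosion pads with 1.
        for _ in range(100):
            m = random_blob_mask(rng)
            lhs = dilate(m, se)
            rhs = 1 - erode(1 - m, se.reflected(), border=1)
            assert np.array_equal(lhs, rhs)

    def test_structuring_element_validation(self):
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((2, 2), bool), (0, 0))
        with pytest.raises(ValueError):
            StructuringElement(np.ones((2, 2), bool), (2, 0))


# ---------------------------------------------------------------- edges


class TestExtractEdges:
    def test_centered_square_perimeter(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[1:4, 1:4] = 1
        edges = extract_edges(m)
        assert np.array_equal(edges, inner_boundary_bruteforce(m))
        assert edges.sum() == 8

    def test_all_ones_mask_gives_border_ring(self):
        m = np.ones((6, 6), dtype=np.uint8)
        edges = extract_edges(m)
        assert np.array_equal(edges, inner_boundary_bruteforce(m))
        assert edges.sum() == 20

    def test_single_pixel_is_its_own_boundary(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 3] = 1
        assert np.array_equal(extract_edges(m), m)

    def test_empty_foreground_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_edges(np.zeros((5, 5), dtype=np.uint8))

    def test_matches_oracle_on_random_masks(self, rng):
        for _ in range(50):
            m = random_blob_mask(rng)
            if not m.any():
                continue
            assert np.array_equal(extract_edges(m), inner_boundary_bruteforce(m))


# ---------------------------------------------------------------- tracing


class TestTraceContour:
    def test_square_ring_traced_clockwise_from_topleft(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[1:4, 1:4] = 1
        ring = extract_edges(m)
        contour = trace_contour(ring)
        expected = [
            (1, 1), (1, 2), (1, 3), (2, 3), (3, 3), (3, 2), (3, 1), (2, 1),
        ]
        assert [tuple(p) for p in contour.points] == expected
        assert contour.clockwise

    def test_keeps_only_longest_loop(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[2:10, 2:10] = 1   # big square
        m[14:17, 14:17] = 1  # small square
        ring = extract_edges(m)
        contour = trace_contour(ring)
        assert contour.points[:, 0].max() < 10  # only the big loop survives

    def test_open_arc_reports_endpoints(self):
        arc = np.zeros((8, 8), dtype=np.uint8)
        arc[4, 1:7] = 1  # open 1-px line: 2 endpoints
        with pytest.raises(OpenContourError) as exc:
            trace_contour(arc)
        assert exc.value.n_endpoints == 2

    def test_trace_is_closed_and_8_connected(self, ellipse_mask):
        contour = trace_contour(extract_edges(ellipse_mask))
        contour.validate()  # bounds, uniqueness, cyclic 8-connectivity
        first, last = contour.points[0], contour.points[-1]
        assert np.abs(first - last).max() <= 1


# ---------------------------------------------------------------- pipeline


class TestCoarsePipeline:
    def test_ellipse_contour_faithful_to_mask(self, ellipse_mask):
        contour = extract_coarse_contour(ellipse_mask)
        contour.validate()
        region = region_from_keypoints(contour.points, ellipse_mask.shape)
        assert iou(region, ellipse_mask) >= 0.9

    def test_blank_image_raises_degenerate(self):
        with pytest.raises(PipelineStageError) as exc:
            extract_coarse_contour(np.zeros((32, 32)))
        assert exc.value.stage == "binarize"

    def test_square_gives_adjusted_square_perimeter(self, square_mask):
        contour = extract_coarse_contour(square_mask)
        pts = contour.points
        # morphological clean-up preserves the square; contour spans its perimeter
        assert pts[:, 0].min() >= 19 and pts[:, 0].max() <= 40
        region = region_from_keypoints(pts, square_mask.shape)
        assert iou(region, square_mask) >= 0.9

    def test_grayscale_input_is_otsu_binarized(self, ellipse_mask):
        img = np.where(ellipse_mask > 0, 0.8, 0.2)
        contour = extract_coarse_contour(img)
        region = region_from_keypoints(contour.points, ellipse_mask.shape)
        assert iou(region, ellipse_mask) >= 0.9

    def test_idempotent_on_own_polygon_fill(self, ellipse_mask):
        c1 = extract_coarse_contour(ellipse_mask)
        fill1 = region_from_keypoints(c1.points, ellipse_mask.shape)
        c2 = extract_coarse_contour(fill1)
        fill2 = region_from_keypoints(c2.points, ellipse_mask.shape)
        assert iou(fill1, fill2) >= 0.95
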