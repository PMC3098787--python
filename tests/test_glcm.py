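"""Co-occurrence counting against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.feature import graycomatrix

from phenotexture.glcm import (
    DEFAULT_ANGLES_DEG,
    DEFAULT_DISTANCES,
    DEFAULT_HARALICK_SET,
    CooccurrenceMatrix,
    QuantizedImage,
    compute_glcm,
    glcm_feature_names,
    glcm_feature_vector,
    haralick_stats,
    offset_for_angle,
    quantize_image,
)
from phenotexture.synthetic import make_fixture_image

ALL_OFFSETS = [offset_for_angle(a, d) for a in DEFAULT_ANGLES_DEG for d in DEFAULT_DISTANCES]


def brute_force_glcm(pixels, levels, offset):
    """Independent double-loop pair enumeration."""
    dx, dy = offset
    h, w = pixels.shape
    counts = np.zeros((levels, levels), dtype=int)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[pixels[r, c], pixels[r2, c2]] += 1
    return counts


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def test_quantize_constant_image_maps_to_zero():
    q = quantize_image(np.full((6, 6), 7.3), levels=16)
    assert (q.pixels == 0).all() and q.levels == 16


def test_quantize_ramp_endpoints():
    q = quantize_image(np.arange(256, dtype=float).reshape(16, 16), levels=32)
    flat = q.pixels.ravel()
    assert flat[0] == 0 and flat[-1] == 31
    assert flat.min() == 0 and flat.max() == 31


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6), st.integers(2, 16))
def test_quantize_matches_per_pixel_oracle(seed, levels):
    img = np.random.default_rng(seed).uniform(-5, 5, size=(8, 8))
    q = quantize_image(img, levels=levels)
    lo, hi = img.min(), img.max()
    for r in range(8):
        for c in range(8):
            expected = min(int((img[r, c] - lo) / (hi - lo) * levels), levels - 1)
            assert q.pixels[r, c] == expected


def test_quantize_rejects_bad_input():
    with pytest.raises(ValueError):
        quantize_image(np.empty((0, 3)))
    with pytest.raises(ValueError):
        quantize_image(np.ones((4, 4)), levels=1)


# ---------------------------------------------------------------------------
# co-occurrence counting
# ---------------------------------------------------------------------------

def test_worked_example_counts():
    img = make_fixture_image("worked_4x4")
    m = compute_glcm(QuantizedImage(img, 4), offset=(1, 0))
    expected = {(0, 0): 2, (0, 1): 2, (1, 1): 2, (0, 2): 1, (2, 2): 3, (2, 3): 1, (3, 3): 1}
    for (i, j), n in expected.items():
        assert m.counts[i, j] == n
    assert m.counts.sum() == 12
    assert m.counts.sum() == sum(expected.values())


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_glcm_equals_bruteforce_for_all_configured_offsets(seed):
    pixels = np.random.default_rng(seed).integers(0, 8, size=(8, 8))
    q = QuantizedImage(pixels, 8)
    for offset in ALL_OFFSETS:
        got = compute_glcm(q, offset).counts
        np.testing.assert_array_equal(got, brute_force_glcm(pixels, 8, offset))


def test_glcm_cross_checked_against_skimage(rng):
    # skimage's graycomatrix displaces by (d*sin(theta), d*cos(theta)) in
    # (row, col); with our (dx, dy)=(col, row) convention the angle 0 and 90
    # degree cases line up directly.
    pixels = rng.integers(0, 6, size=(12, 12))
    q = QuantizedImage(pixels, 6)
    img8 = pixels.astype(np.uint8)
    for d in (1, 2, 3):
        ref_h = graycomatrix(img8, [d], [0], levels=6)[:, :, 0, 0]
        np.testing.assert_array_equal(compute_glcm(q, (d, 0)).counts, ref_h)
        ref_v = graycomatrix(img8, [d], [np.pi / 2], levels=6)[:, :, 0, 0]
        np.testing.assert_array_equal(compute_glcm(q, (0, d)).counts, ref_v)


def test_total_pairs_and_probability_normalization(rng):
    pixels = rng.integers(0, 5, size=(9, 7))
    q = QuantizedImage(pixels, 5)
    for dx, dy in [(1, 0), (-2, 3), (3, -1), (0, 4)]:
        m = compute_glcm(q, (dx, dy))
        assert m.counts.sum() == (7 - abs(dx)) * (9 - abs(dy))
        assert abs(m.probabilities.sum() - 1.0) < 1e-12


def test_constant_image_has_single_nonzero_entry():
    m = compute_glcm(QuantizedImage(np.zeros((5, 5), dtype=int), 4), (1, 1))
    assert m.counts[0, 0] == 16 and m.counts.sum() == 16


def test_offset_larger_than_image_rejected():
    q = QuantizedImage(np.zeros((4, 4), dtype=int), 2)
    with pytest.raises(ValueError):
        compute_glcm(q, (4, 0))


# ---------------------------------------------------------------------------
# Haralick statistics
# ---------------------------------------------------------------------------

def haralick_oracle(p):
    """Direct double-loop evaluation of the 12 textbook formulas."""
    g = p.shape[0]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = sum(i * px[i] for i in range(g))
    muy = sum(j * py[j] for j in range(g))
    sx = np.sqrt(sum((i - mux) ** 2 * px[i] for i in range(g)))
    sy = np.sqrt(sum((j - muy) ** 2 * py[j] for j in range(g)))
    psum = np.zeros(2 * g - 1)
    pdiff = np.zeros(g)
    for i in range(g):
        for j in range(g):
            psum[i + j] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]
    log2 = lambda v: np.log2(v) if v > 0 else 0.0
    sa = sum(k * psum[k] for k in range(len(psum)))
    da = sum(k * pdiff[k] for k in range(len(pdiff)))
    out = {
        "energy": sum(p[i, j] ** 2 for i in range(g) for j in range(g)),
        "entropy": -sum(p[i, j] * log2(p[i, j]) for i in range(g) for j in range(g)),
        "contrast": sum((i - j) ** 2 * p[i, j] for i in range(g) for j in range(g)),
        "correlation": 0.0 if sx == 0 or sy == 0 else
        sum((i - mux) * (j - muy) * p[i, j] for i in range(g) for j in range(g)) / (sx * sy),
        "variance": sum((i - mux) ** 2 * p[i, j] for i in range(g) for j in range(g)),
        "homogeneity": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g)),
        "sum_variance": sum((k - sa) ** 2 * psum[k] for k in range(len(psum))),
        "sum_entropy": -sum(psum[k] * log2(psum[k]) for k in range(len(psum))),
        "difference_variance": sum((k - da) ** 2 * pdiff[k] for k in range(len(pdiff))),
        "cluster_prominence": sum((i + j - mux - muy) ** 4 * p[i, j] for i in range(g) for j in range(g)),
        "cluster_shade": sum((i + j - mux - muy) ** 3 * p[i, j] for i in range(g) for j in range(g)),
        "inverse_difference_normalized": sum(p[i, j] / (1 + abs(i - j) / g) for i in range(g) for j in range(g)),
    }
    return np.array([out[name] for name in DEFAULT_HARALICK_SET])


def test_haralick_point_mass():
    p = np.zeros((4, 4))
    p[2, 2] = 1.0
    v = dict(zip(DEFAULT_HARALICK_SET, haralick_stats(p)))
    assert v["energy"] == 1.0 and v["entropy"] == 0.0 and v["contrast"] == 0.0


def test_haralick_uniform_closed_form():
    p = np.full((4, 4), 1 / 16)
    v = dict(zip(DEFAULT_HARALICK_SET, haralick_stats(p)))
    assert v["energy"] == pytest.approx(1 / 16)
    assert v["entropy"] == pytest.approx(4.0)


def test_haralick_matches_formula_oracle_on_worked_image(rng):
    img = make_fixture_image("worked_4x4")
    m = compute_glcm(QuantizedImage(img, 4), (1, 0))
    np.testing.assert_allclose(haralick_stats(m), haralick_oracle(m.probabilities), rtol=1e-12)
    # and on a random matrix
    pixels = rng.integers(0, 6, size=(10, 10))
    m2 = compute_glcm(QuantizedImage(pixels, 6), (1, 1))
    np.testing.assert_allclose(haralick_stats(m2), haralick_oracle(m2.probabilities), rtol=1e-10)


def test_haralick_depends_only_on_probabilities(rng):
    pixels = rng.integers(0, 4, size=(8, 8))
    m = compute_glcm(QuantizedImage(pixels, 4), (1, 0))
    scaled = CooccurrenceMatrix(counts=m.counts * 7, offset=m.offset)
    np.testing.assert_allclose(haralick_stats(m), haralick_stats(scaled), rtol=1e-12)


def test_haralick_rejects_unnormalized_matrix():
    with pytest.raises(ValueError):
        haralick_stats(np.ones((4, 4)))


# ---------------------------------------------------------------------------
# full descriptor
# ---------------------------------------------------------------------------

def test_offset_rounding_for_diagonal_distances():
    assert offset_for_angle(45, 3) == (2, 2)
    assert offset_for_angle(45, 2) == (1, 1)
    assert offset_for_angle(90, 4) == (0, 4)
    assert offset_for_angle(135, 1) == (-1, 1)


def test_feature_vector_length_and_names(rng):
    img = rng.uniform(size=(32, 32))
    v = glcm_feature_vector(img)
    names = glcm_feature_names()
    assert len(v) == 192 and len(names) == 192
    assert names[0] == "glcm_0_1_energy" and names[-1].startswith("glcm_135_4")
    assert np.isfinite(v).all()


def test_constant_image_blocks_identical_across_offsets():
    v = glcm_feature_vector(np.full((16, 16), 3.0)).reshape(16, 12)
    for row in v[1:]:
        np.testing.assert_allclose(row, v[0])


def test_small_image_rejected():
    with pytest.raises(ValueError):
        glcm_feature_vector(np.zeros((4, 4)))


def test_rotation_permutes_angle_offsets(rng):
    # Rotating the raster 90 degrees maps horizontal pairs to vertical ones:
    # GLCM(rot90(I), (1,0)) == GLCM(I, (0,1)), and the reverse direction is
    # the transpose of the original horizontal matrix.
    pixels = rng.integers(0, 6, size=(16, 16))
    rot = np.rot90(pixels)
    q, qr = QuantizedImage(pixels, 6), QuantizedImage(rot, 6)
    np.testing.assert_array_equal(
        compute_glcm(qr, (1, 0)).counts, compute_glcm(q, (0, 1)).counts
    )
    np.testing.assert_array_equal(
        compute_glcm(qr, (0, 1)).counts, compute_glcm(q, (1, 0)).counts.T
    )
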