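"""Gray-level co-occurrence matrices (GLCM) and Haralick texture statistics.

A co-occurrence matrix ``C`` over an image ``I`` counts, for a fixed pixel
displacement ``(dx, dy)``, how often gray level ``i`` occurs at a pixel whose
displaced neighbour holds gray level ``j``::

    C[i, j] = #{ (r, c) : I[r, c] = i  and  I[r + dy, c + dx] = j }

Counting is *ordered* (the matrix is not symmetrized), so the descriptor is
sensitive to rotations other than 180 degrees -- a deliberate property for
texture discrimination.  ``dx`` displaces columns (positive = right) and
``dy`` displaces rows (positive = down, the usual raster convention).

From each normalized matrix ``P = C / C.sum()`` a fixed, documented set of
twelve scalar Haralick statistics is computed.  The full image descriptor
concatenates those statistics over a grid of 16 offsets: four orientations
(0, 45, 90, 135 degrees) times four distances (1..4 pixels), giving the
192-dimensional GLCM feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "QuantizedImage",
    "CooccurrenceMatrix",
    "quantize_image",
    "compute_glcm",
    "haralick_stats",
    "glcm_feature_vector",
    "glcm_feature_names",
    "offset_for_angle",
    "HARALICK_STATS",
    "DEFAULT_HARALICK_SET",
    "DEFAULT_ANGLES_DEG",
    "DEFAULT_DISTANCES",
]

DEFAULT_ANGLES_DEG = (0, 45, 90, 135)
DEFAULT_DISTANCES = (1, 2, 3, 4)


@dataclass(frozen=True)
class QuantizedImage:
    """Integer raster with values in ``[0, levels)``."""

    pixels: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 2 or p.size == 0:
            raise ValueError("quantized image must be a non-empty 2-D array")
        if p.min() < 0 or p.max() >= self.levels:
            raise ValueError("quantized values must lie in [0, levels)")


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Ordered pair-count matrix for one displacement, plus its normalization."""

    counts: np.ndarray
    offset: tuple[int, int]  # (dx, dy): column and row displacement
    probabilities: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = self.counts
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        total = c.sum()
        if total == 0:
            raise ValueError("co-occurrence matrix has no pixel pairs")
        object.__setattr__(self, "probabilities", c.astype(float) / float(total))


def quantize_image(image: np.ndarray, levels: int = 32) -> QuantizedImage:
    """Linearly map the intensity range of ``image`` onto ``{0 .. levels-1}``.

    A constant image maps to all zeros.  Quantization is per-image min-max,
    which makes the descriptor robust to global staining/exposure offsets.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    lo, hi = img.min(), img.max()
    if hi == lo:
        q = np.zeros(img.shape, dtype=np.int64)
    else:
        q = np.floor((img - lo) / (hi - lo) * levels).astype(np.int64)
        q[q == levels] = levels - 1  # the single point at the max
    return QuantizedImage(pixels=q, levels=levels)


def compute_glcm(qimg: QuantizedImage, offset: tuple[int, int]) -> CooccurrenceMatrix:
    """Ordered co-occurrence counts for displacement ``offset = (dx, dy)``.

    Out-of-bounds pairs are skipped, so the total count equals
    ``(width - |dx|) * (height - |dy|)``.
    """
    dx, dy = int(offset[0]), int(offset[1])
    h, w = qimg.pixels.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"offset {offset!r} exceeds image extent {w}x{h}")
    p = qimg.pixels
    r0, r1 = max(0, -dy), h - max(0, dy)
    c0, c1 = max(0, -dx), w - max(0, dx)
    src = p[r0:r1, c0:c1]
    dst = p[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
    g = qimg.levels
    counts = np.bincount((src * g + dst).ravel(), minlength=g * g).reshape(g, g)
    return CooccurrenceMatrix(counts=counts, offset=(dx, dy))


# ---------------------------------------------------------------------------
# Haralick statistics
# ---------------------------------------------------------------------------

def _xlog2(p: np.ndarray) -> np.ndarray:
    """``p * log2(p)`` with the 0*log(0) := 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _marginals(p: np.ndarray):
    g = p.shape[0]
    lv = np.arange(g, dtype=float)
    px, py = p.sum(axis=1), p.sum(axis=0)
    mux, muy = lv @ px, lv @ py
    sx = np.sqrt(((lv - mux) ** 2) @ px)
    sy = np.sqrt(((lv - muy) ** 2) @ py)
    return lv, px, py, mux, muy, sx, sy


def _sum_dist(p: np.ndarray) -> np.ndarray:
    g = p.shape[0]
    i, j = np.indices((g, g))
    return np.bincount((i + j).ravel(), weights=p.ravel(), minlength=2 * g - 1)


def _diff_dist(p: np.ndarray) -> np.ndarray:
    g = p.shape[0]
    i, j = np.indices((g, g))
    return np.bincount(np.abs(i - j).ravel(), weights=p.ravel(), minlength=g)


def _stat_energy(p):
    return float((p ** 2).sum())


def _stat_entropy(p):
    return float(-_xlog2(p).sum())


def _stat_contrast(p):
    g = p.shape[0]
    i, j = np.indices((g, g))
    return float(((i - j) ** 2 * p).sum())


def _stat_correlation(p):
    g = p.shape[0]
    lv, _, _, mux, muy, sx, sy = _marginals(p)
    if sx == 0 or sy == 0:
        return 0.0
    i, j = np.indices((g, g))
    return float(((i - mux) * (j - muy) * p).sum() / (sx * sy))


def _stat_variance(p):
    # "sum of squares: variance" -- dispersion of gray level i about the
    # row-marginal mean, weighted by the joint distribution.
    g = p.shape[0]
    _, _, _, mux, _, _, _ = _marginals(p)
    i, _ = np.indices((g, g))
    return float(((i - mux) ** 2 * p).sum())


def _stat_homogeneity(p):
    g = p.shape[0]
    i, j = np.indices((g, g))
    return float((p / (1.0 + (i - j) ** 2)).sum())


def _stat_sum_variance(p):
    # Defined about the sum average (the usual reading of Haralick's f7).
    ps = _sum_dist(p)
    k = np.arange(ps.size, dtype=float)
    sa = k @ ps
    return float(((k - sa) ** 2) @ ps)


def _stat_sum_entropy(p):
    return float(-_xlog2(_sum_dist(p)).sum())


def _stat_difference_variance(p):
    pd = _diff_dist(p)
    k = np.arange(pd.size, dtype=float)
    da = k @ pd
    return float(((k - da) ** 2) @ pd)


def _stat_cluster_prominence(p):
    g = p.shape[0]
    _, _, _, mux, muy, _, _ = _marginals(p)
    i, j = np.indices((g, g))
    return float(((i + j - mux - muy) ** 4 * p).sum())


def _stat_cluster_shade(p):
    g = p.shape[0]
    _, _, _, mux, muy, _, _ = _marginals(p)
    i, j = np.indices((g, g))
    return float(((i + j - mux - muy) ** 3 * p).sum())


def _stat_inverse_difference(p):
    g = p.shape[0]
    i, j = np.indices((g, g))
    return float((p / (1.0 + np.abs(i - j))).sum())


def _stat_inverse_difference_normalized(p):
    g = p.shape[0]
    i, j = np.indices((g, g))
    return float((p / (1.0 + np.abs(i - j) / g)).sum())


#: Registry of all supported statistics (13 named candidates).
HARALICK_STATS = {
    "energy": _stat_energy,
    "entropy": _stat_entropy,
    "contrast": _stat_contrast,
    "correlation": _stat_correlation,
    "variance": _stat_variance,
    "homogeneity": _stat_homogeneity,
    "sum_variance": _stat_sum_variance,
    "sum_entropy": _stat_sum_entropy,
    "difference_variance": _stat_difference_variance,
    "cluster_prominence": _stat_cluster_prominence,
    "cluster_shade": _stat_cluster_shade,
    "inverse_difference": _stat_inverse_difference,
    "inverse_difference_normalized": _stat_inverse_difference_normalized,
}

#: Default 12-statistic set, in fixed output order.  The plain inverse
#: difference (INV) is dropped in favour of its normalized form (INN).
DEFAULT_HARALICK_SET = (
    "energy",
    "entropy",
    "contrast",
    "correlation",
    "variance",
    "homogeneity",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "cluster_prominence",
    "cluster_shade",
    "inverse_difference_normalized",
)


def haralick_stats(
    glcm: CooccurrenceMatrix | np.ndarray,
    stats: Sequence[str] = DEFAULT_HARALICK_SET,
) -> np.ndarray:
    """Scalar texture statistics of a normalized co-occurrence matrix.

    Entropies are in bits (log base 2); correlation is defined as 0 when a
    marginal standard deviation vanishes.  ``stats`` selects and orders the
    statistics (default: the documented 12).
    """
    if isinstance(glcm, CooccurrenceMatrix):
        p = glcm.probabilities
    else:
        p = np.asarray(glcm, dtype=float)
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("matrix is not normalized: probabilities must sum to 1")
    unknown = [s for s in stats if s not in HARALICK_STATS]
    if unknown:
        raise ValueError(f"unknown Haralick statistics: {unknown}")
    return np.array([HARALICK_STATS[s](p) for s in stats], dtype=float)


def offset_for_angle(angle_deg: float, distance: int) -> tuple[int, int]:
    """Displacement ``(dx, dy)`` for a polar offset, rounded to the pixel grid.

    Rounding is to nearest (ties to even), so the 45-degree direction at
    distance 3 gives ``(2, 2)``.  Rows grow downward, so 90 degrees displaces
    toward larger row index.
    """
    th = np.deg2rad(angle_deg)
    return int(np.rint(distance * np.cos(th))), int(np.rint(distance * np.sin(th)))


def glcm_feature_names(
    angles_deg: Sequence[float] = DEFAULT_ANGLES_DEG,
    distances: Sequence[int] = DEFAULT_DISTANCES,
    stats: Sequence[str] = DEFAULT_HARALICK_SET,
) -> list[str]:
    return [
        f"glcm_{int(a)}_{d}_{s}"
        for a in angles_deg
        for d in distances
        for s in stats
    ]


def glcm_feature_vector(
    image: np.ndarray,
    levels: int = 32,
    angles_deg: Sequence[float] = DEFAULT_ANGLES_DEG,
    distances: Sequence[int] = DEFAULT_DISTANCES,
    stats: Sequence[str] = DEFAULT_HARALICK_SET,
) -> np.ndarray:
    """Concatenated Haralick statistics over the offset grid (angle-major).

    Defaults give 4 angles x 4 distances x 12 statistics = 192 features.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 5:
        raise ValueError("image must be 2-D and at least 5x5")
    qimg = quantize_image(img, levels=levels)
    parts = []
    for a in angles_deg:
        for d in distances:
            glcm = compute_glcm(qimg, offset_for_angle(a, d))
            parts.append(haralick_stats(glcm, stats=stats))
    return np.concatenate(parts)
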