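"""Wavelet and Gabor filter-bank descriptors.

Two classical multiresolution descriptors complement the co-occurrence and
curvelet features:

* a two-level separable Daubechies-D4 pyramid, summarised by the mean and
  standard deviation of each detail matrix (12 values), and
* a Gabor filter bank (6 orientations x 4 scales = 24 complex kernels) whose
  response magnitudes are summarised per kernel within a grid of image
  subregions (default 4 x 5 cells -> 20 x 24 x 2 = 960 values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

__all__ = [
    "dwt2_features",
    "dwt2_feature_names",
    "GaborBank",
    "build_gabor_bank",
    "gabor_feature_vector",
    "gabor_feature_names",
]

_DWT_ORIENTS = ("horizontal", "vertical", "diagonal")


def dwt2_features(image: np.ndarray, wavelet: str = "db2", levels: int = 2) -> np.ndarray:
    """Mean and standard deviation of each D4 detail matrix over two levels.

    ``db2`` is the four-tap Daubechies filter (D4).  Boundaries use symmetric
    (half-sample) extension.  Order: level 1 (finest) then level 2, each with
    (horizontal, vertical, diagonal) details and (mean, std) per detail.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValueError("image must be 2-D with both sides >= 8")
    coeffs = pywt.wavedec2(img, wavelet, mode="symmetric", level=levels)
    # coeffs = [cA_L, (cH_L, cV_L, cD_L), ..., (cH_1, cV_1, cD_1)]
    out = []
    for level in range(1, levels + 1):
        details = coeffs[-level]  # level 1 = finest = last tuple
        for d in details:
            out.append(float(d.mean()))
            out.append(float(d.std()))
    return np.asarray(out)


def dwt2_feature_names(levels: int = 2) -> list[str]:
    return [
        f"dwt_{level}_{orient}_{stat}"
        for level in range(1, levels + 1)
        for orient in _DWT_ORIENTS
        for stat in ("mean", "std")
    ]


@dataclass(frozen=True)
class GaborBank:
    """Bank of complex Gabor kernels, scale-major (orientation inner)."""

    kernels: tuple[np.ndarray, ...]
    frequencies: tuple[float, ...]   # one per kernel, cycles/pixel
    orientations: tuple[float, ...]  # one per kernel, radians
    n_orientations: int
    n_scales: int

    def __len__(self) -> int:
        return len(self.kernels)


def build_gabor_bank(
    orientations: int = 6,
    scales: int = 4,
    f_max: float = 0.25,
    bandwidth: float = 1.0,
    dc_correct: bool = True,
) -> GaborBank:
    """Gabor kernels at ``theta_k = k*pi/orientations`` and geometric frequencies.

    Frequencies start at ``f_max`` cycles/pixel and halve per scale.  With
    ``dc_correct`` the kernel mean is subtracted so that responses ignore the
    absolute intensity level (the kernels become strictly bandpass).
    """
    if orientations < 1 or scales < 1:
        raise ValueError("orientations and scales must be >= 1")
    kernels, freqs, thetas = [], [], []
    for s in range(scales):
        f = f_max / 2.0 ** s
        for k in range(orientations):
            theta = k * np.pi / orientations
            kern = gabor_kernel(frequency=f, theta=theta, bandwidth=bandwidth)
            kern = np.asarray(kern, dtype=complex)
            if dc_correct:
                kern = kern - kern.mean()
            kernels.append(kern)
            freqs.append(f)
            thetas.append(theta)
    return GaborBank(
        kernels=tuple(kernels),
        frequencies=tuple(freqs),
        orientations=tuple(thetas),
        n_orientations=orientations,
        n_scales=scales,
    )


def _grid_edges(n: int, cells: int) -> list[tuple[int, int]]:
    # Equal cells of size n // cells; trailing remainder goes to the last cell.
    base = n // cells
    edges = [(i * base, (i + 1) * base) for i in range(cells)]
    lo, _ = edges[-1]
    edges[-1] = (lo, n)
    return edges


def gabor_feature_vector(
    image: np.ndarray,
    bank: GaborBank | None = None,
    grid: tuple[int, int] = (4, 5),
) -> np.ndarray:
    """Per-subregion (mean, std) of Gabor response magnitudes.

    The image is partitioned into a ``grid = (rows, cols)`` layout of
    non-overlapping cells (remainder pixels fall into the last cell in each
    axis).  Ordering is kernel-major (scale, then orientation), cell inner
    (row-major), with (mean, std) per cell.  Defaults: 24 kernels x 20 cells
    x 2 stats = 960 features.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if bank is None:
        bank = build_gabor_bank()
    rows, cols = grid
    if rows < 1 or cols < 1 or rows > img.shape[0] or cols > img.shape[1]:
        raise ValueError(f"grid {grid!r} does not fit image of shape {img.shape}")
    redges = _grid_edges(img.shape[0], rows)
    cedges = _grid_edges(img.shape[1], cols)
    out = []
    for kern in bank.kernels:
        mag = np.abs(fftconvolve(img, kern, mode="same"))
        for r0, r1 in redges:
            for c0, c1 in cedges:
                cell = mag[r0:r1, c0:c1]
                out.append(float(cell.mean()))
                out.append(float(cell.std()))
    return np.asarray(out)


def gabor_feature_names(
    orientations: int = 6, scales: int = 4, grid: tuple[int, int] = (4, 5)
) -> list[str]:
    rows, cols = grid
    return [
        f"gabor_s{s}_o{o}_c{cell}_{stat}"
        for s in range(scales)
        for o in range(orientations)
        for cell in range(rows * cols)
        for stat in ("mean", "std")
    ]
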