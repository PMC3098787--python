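"""Seeded synthetic texture datasets and small deterministic fixtures.

Stands in for multi-class microscopy benchmarks during development and
testing: each class is a texture recipe combining an oriented sinusoidal
grating (orientation and spatial frequency), a 1/f^beta random field
(second-order statistics), Gaussian blobs at a class-specific density
(punctate structure), and additive Gaussian noise.  Classes therefore differ
in exactly the properties that co-occurrence statistics and the curvelet
transform are meant to discriminate: orientation, spatial frequency, and
spectral slope.  Images are quantized to 8 bits, matching common microscopy
file formats.  The same spec and seed always produce bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ClassRecipe",
    "SyntheticDatasetSpec",
    "make_texture_dataset",
    "make_fixture_image",
    "write_dataset",
    "default_recipes",
]

#: The small co-occurrence worked example used throughout the unit tests.
WORKED_4X4 = np.array(
    [[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]], dtype=np.int64
)


@dataclass(frozen=True)
class ClassRecipe:
    """Texture parameters for one synthetic class."""

    name: str
    orientation: float       # grating orientation, radians
    frequency: float         # grating spatial frequency, cycles/pixel
    spectral_slope: float    # beta of the 1/f^beta background field
    blob_density: float      # expected blobs per pixel
    noise_sigma: float       # additive Gaussian noise, relative amplitude


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    n_classes: int = 5
    n_per_class: int = 20
    size: tuple[int, int] = (256, 256)
    seed: int = 0
    recipes: tuple[ClassRecipe, ...] | None = None

    def resolved_recipes(self) -> tuple[ClassRecipe, ...]:
        if self.recipes is not None:
            if len(self.recipes) != self.n_classes:
                raise ValueError("number of recipes must equal n_classes")
            return self.recipes
        return default_recipes(self.n_classes)


def default_recipes(n_classes: int) -> tuple[ClassRecipe, ...]:
    """Well-separated recipes: evenly spread orientations, geometric frequencies."""
    freqs = np.geomspace(0.06, 0.16, n_classes)
    slopes = np.linspace(1.0, 2.0, n_classes)
    densities = np.linspace(2e-4, 8e-4, n_classes)
    return tuple(
        ClassRecipe(
            name=f"class{c}",
            orientation=c * np.pi / n_classes,
            frequency=float(freqs[c]),
            spectral_slope=float(slopes[c]),
            blob_density=float(densities[c]),
            noise_sigma=0.05,
        )
        for c in range(n_classes)
    )


def _spectral_field(shape: tuple[int, int], beta: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean random field with a 1/f^beta amplitude spectrum, unit std."""
    h, w = shape
    white = rng.normal(size=shape)
    f1 = np.fft.fftfreq(h)[:, None]
    f2 = np.fft.fftfreq(w)[None, :]
    radial = np.hypot(f1, f2)
    radial[0, 0] = radial.flat[np.abs(radial).argsort(axis=None)[1]]  # avoid /0 at DC
    filt = radial ** (-beta / 2.0)
    filt.flat[0] = 0.0  # drop the mean
    field = np.fft.ifft2(np.fft.fft2(white) * filt).real
    sd = field.std()
    return field / sd if sd > 0 else field


def _blobs(
    shape: tuple[int, int], density: float, rng: np.random.Generator
) -> np.ndarray:
    h, w = shape
    n = rng.poisson(density * h * w)
    out = np.zeros(shape)
    if n == 0:
        return out
    ys = rng.uniform(0, h, size=n)
    xs = rng.uniform(0, w, size=n)
    sigmas = rng.uniform(2.0, 5.0, size=n)
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    for y0, x0, s in zip(ys, xs, sigmas):
        r0, r1 = max(0, int(y0 - 4 * s)), min(h, int(y0 + 4 * s) + 1)
        c0, c1 = max(0, int(x0 - 4 * s)), min(w, int(x0 + 4 * s) + 1)
        out[r0:r1, c0:c1] += np.exp(
            -((yy[r0:r1] - y0) ** 2 + (xx[:, c0:c1] - x0) ** 2) / (2 * s * s)
        )
    return out


def _render(recipe: ClassRecipe, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    phase = rng.uniform(0, 2 * np.pi)
    carrier = xx * np.cos(recipe.orientation) + yy * np.sin(recipe.orientation)
    grating = np.sin(2 * np.pi * recipe.frequency * carrier + phase)
    img = (
        1.0 * grating
        + 0.6 * _spectral_field(shape, recipe.spectral_slope, rng)
        + 1.2 * _blobs(shape, recipe.blob_density, rng)
        + rng.normal(scale=recipe.noise_sigma, size=shape)
    )
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * 256.0)
    return np.clip(q, 0, 255).astype(np.uint8)


def make_texture_dataset(
    spec: SyntheticDatasetSpec,
) -> tuple[list[np.ndarray], list[str]]:
    """Generate the labeled image collection for ``spec`` (deterministic)."""
    if spec.n_classes < 2:
        raise ValueError("need at least 2 classes")
    if spec.n_per_class < 5:
        raise ValueError("need at least 5 images per class")
    recipes = spec.resolved_recipes()
    if len({(r.orientation, r.frequency, r.spectral_slope, r.blob_density) for r in recipes}) != len(recipes):
        raise ValueError("class recipes must be pairwise distinct")
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for recipe in recipes:
        for _ in range(spec.n_per_class):
            images.append(_render(recipe, spec.size, rng))
            labels.append(recipe.name)
    return images, labels


def make_fixture_image(kind: str, size: tuple[int, int] = (8, 8), **params) -> np.ndarray:
    """Small deterministic rasters for oracle tests.

    Kinds: ``constant`` (``value``), ``ramp``, ``checker``, ``grating``
    (``theta``, ``f``) and ``worked_4x4`` (a fixed 4x4 co-occurrence example).
    """
    h, w = size
    if kind == "constant":
        return np.full(size, float(params.get("value", 0.0)))
    if kind == "ramp":
        return np.tile(np.linspace(0.0, 255.0, w), (h, 1))
    if kind == "checker":
        return ((np.arange(h)[:, None] + np.arange(w)[None, :]) % 2).astype(float) * 255.0
    if kind == "grating":
        theta = float(params.get("theta", 0.0))
        f = float(params.get("f", 0.125))
        yy = np.arange(h)[:, None]
        xx = np.arange(w)[None, :]
        carrier = xx * np.cos(theta) + yy * np.sin(theta)
        return 127.5 * (1.0 + np.sin(2 * np.pi * f * carrier))
    if kind == "worked_4x4":
        return WORKED_4X4.copy()
    raise ValueError(f"unknown fixture kind {kind!r}")


def write_dataset(
    images: list[np.ndarray], labels: list[str], root: str | Path
) -> Path:
    """Write a class-per-directory PNG tree (the layout the readers expect)."""
    root = Path(root)
    counters: dict[str, int] = {}
    for img, label in zip(images, labels):
        d = root / label
        d.mkdir(parents=True, exist_ok=True)
        k = counters.get(label, 0)
        counters[label] = k + 1
        iio.imwrite(d / f"{label}_{k:04d}.png", np.asarray(img, dtype=np.uint8))
    return root
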