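"""Dataset discovery and grayscale image loading.

Datasets follow the class-per-directory convention: every immediate
subdirectory of the dataset root is a class, and the image files inside it
(PNG/TIFF and friends) are its samples.  Scanning is deterministic (sorted
class and file order) so feature tables are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["DatasetIndex", "scan_dataset", "load_gray_image"]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

#: ITU-R BT.601 luminance weights for color -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class DatasetIndex:
    root: Path
    classes: tuple[str, ...]
    files: dict[str, tuple[Path, ...]]  # class -> sorted image paths

    @property
    def n_images(self) -> int:
        return sum(len(v) for v in self.files.values())

    def items(self):
        """Yield (image_id, path, label) deterministically."""
        for cls in self.classes:
            for p in self.files[cls]:
                yield f"{cls}/{p.name}", p, cls


def load_gray_image(path: str | Path) -> np.ndarray:
    """Read an image as a float 2-D array; color inputs collapse to luminance.

    16-bit intensities are preserved as-is (no rescaling): downstream
    quantization and normalization are range-adaptive.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[-1] == 4:
            arr = arr[..., :3]
        if arr.shape[-1] == 3:
            arr = arr @ _LUMA
        else:
            arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return arr.astype(float)


def scan_dataset(root: str | Path) -> DatasetIndex:
    """Index a class-per-directory image tree with sorted, stable ordering."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    classes = sorted(d.name for d in root.iterdir() if d.is_dir())
    files: dict[str, tuple[Path, ...]] = {}
    for cls in classes:
        paths = tuple(
            sorted(
                p
                for p in (root / cls).iterdir()
                if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES
            )
        )
        if paths:
            files[cls] = paths
    kept = tuple(c for c in classes if c in files)
    if len(kept) < 2:
        raise ValueError(
            f"no class subdirectories with images found under {root} "
            "(need at least 2 classes)"
        )
    return DatasetIndex(root=root, classes=kept, files=files)
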