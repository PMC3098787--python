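"""Configuration and orchestration: extract features, then evaluate.

``run_extract`` walks a dataset index, computes the enabled descriptor
blocks for every image, and returns (or writes) one feature table row per
image.  ``run_evaluate`` loads a feature table and delegates to the repeated
stratified-holdout evaluation of the random-subspace ensemble.  Both are
deterministic given the same inputs, configuration, and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .curvelet import curvelet_feature_names, curvelet_feature_vector, plan_geometry
from .dataset import DatasetIndex, load_gray_image
from .ensemble import BaseClassifierConfig, EvaluationReport, evaluate_holdout
from .fusion import FeatureTable
from .glcm import glcm_feature_names, glcm_feature_vector
from .multiresolution import (
    build_gabor_bank,
    dwt2_feature_names,
    dwt2_features,
    gabor_feature_names,
    gabor_feature_vector,
)

__all__ = ["RunConfig", "run_extract", "run_evaluate"]

logger = logging.getLogger("phenotexture")

_KNOWN_BLOCKS = ("glcm", "curvelet", "dwt", "gabor")


@dataclass(frozen=True)
class RunConfig:
    """Serializable pipeline configuration (unknown JSON keys are rejected)."""

    blocks: tuple[str, ...] = ("glcm", "curvelet")
    curvelet_stats: tuple[str, ...] = ("mean", "std", "entropy")
    curvelet_nscales: int = 5
    curvelet_nangles_coarse: int = 16
    glcm_levels: int = 32
    gabor_grid: tuple[int, int] = (4, 5)
    ensemble_size: int = 20
    subspace_fraction: float = 0.8
    runs: int = 100
    test_fraction: float = 0.2
    hidden_range: tuple[int, int] = (30, 50)
    epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [b for b in self.blocks if b not in _KNOWN_BLOCKS]
        if bad:
            raise ValueError(f"unknown feature blocks: {bad} (known: {_KNOWN_BLOCKS})")
        if not self.blocks:
            raise ValueError("at least one feature block must be enabled")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        data = json.loads(text)
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("blocks", "curvelet_stats", "gabor_grid", "hidden_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _extract_one(img: np.ndarray, config: RunConfig, bank) -> tuple[np.ndarray, list[str]]:
    values, names = [], []
    for block in config.blocks:
        if block == "glcm":
            values.append(glcm_feature_vector(img, levels=config.glcm_levels))
            names.extend(glcm_feature_names())
        elif block == "curvelet":
            geom = plan_geometry(
                img.shape,
                nscales=config.curvelet_nscales,
                nangles_coarse=config.curvelet_nangles_coarse,
            )
            values.append(curvelet_feature_vector(img, geom, config.curvelet_stats))
            names.extend(curvelet_feature_names(geom, config.curvelet_stats))
        elif block == "dwt":
            values.append(dwt2_features(img))
            names.extend(dwt2_feature_names())
        elif block == "gabor":
            values.append(gabor_feature_vector(img, bank, grid=config.gabor_grid))
            names.extend(
                gabor_feature_names(bank.n_orientations, bank.n_scales, config.gabor_grid)
            )
    return np.concatenate(values), names


def run_extract(
    index: DatasetIndex, config: RunConfig, out_csv: str | Path | None = None
) -> FeatureTable:
    """One feature row per image, columns per enabled block (block order kept)."""
    bank = build_gabor_bank() if "gabor" in config.blocks else None
    logger.info(
        "extract: %d images, blocks=%s, config=%s", index.n_images,
        ",".join(config.blocks), config.digest(),
    )
    ids, labels, rows = [], [], []
    names: list[str] | None = None
    for image_id, path, label in index.items():
        try:
            img = load_gray_image(path)
            vec, names = _extract_one(img, config, bank)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for {image_id}: {exc}") from exc
        ids.append(image_id)
        labels.append(label)
        rows.append(vec)
    table = FeatureTable(
        X=pd.DataFrame(np.vstack(rows), index=ids, columns=names),
        y=pd.Series(labels, index=ids, name="label"),
    )
    if out_csv is not None:
        table.to_csv(out_csv)
    return table


def run_evaluate(
    features: FeatureTable | str | Path,
    config: RunConfig,
    report_json: str | Path | None = None,
) -> EvaluationReport:
    """Repeated-holdout evaluation of the random-subspace MLP ensemble."""
    if not isinstance(features, FeatureTable):
        features = FeatureTable.from_csv(features)
    logger.info(
        "evaluate: %d samples x %d features, seed=%d, config=%s",
        features.n_samples, features.n_features, config.seed, config.digest(),
    )
    report = evaluate_holdout(
        features,
        L=config.ensemble_size,
        fraction=config.subspace_fraction,
        runs=config.runs,
        test_fraction=config.test_fraction,
        base_config=BaseClassifierConfig(
            hidden_range=config.hidden_range, epochs=config.epochs
        ),
        seed=config.seed,
    )
    for r, acc in enumerate(report.accuracies):
        logger.info("run %3d: accuracy %.2f%%", r, acc)
    if report_json is not None:
        Path(report_json).write_text(json.dumps(report.to_dict(), indent=2))
    return report
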