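"""End-to-end orchestration: configuration, manifest handling, feature
tables, model fitting, single-image diagnosis and manifest-level
cross-validation.

The flow is preprocess -> segment -> extract_descriptor -> normalize
-> classify.  Every constant that the method leaves open (smoothing
kernel, mask-combination rule, Gabor sigma/support, entropic order,
histogram bins, activation and training parameters, CV fold count) is a
field of :class:`PipelineConfig` with its default, and a config file
round-trips through YAML unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import evaluation, gabor_features, mnn, preprocess, segmentation

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, with its default."""

    # preprocessing
    smooth_kernel: int = 5
    smooth_sigma: float = 1.0
    equalize: bool = True
    # segmentation
    combination_rule: str = "majority"
    min_area: int = segmentation.DEFAULT_MIN_AREA
    size_fraction: float = segmentation.SIZE_FILTER_FRACTION
    element_radius: Optional[int] = None
    open_close_iterations: int = 2
    # Gabor features
    gabor_sigma: float = gabor_features.DEFAULT_SIGMA
    gabor_support: int = gabor_features.DEFAULT_SUPPORT
    alpha: float = gabor_features.DEFAULT_ALPHA
    bins: int = gabor_features.DEFAULT_BINS
    # classifier
    hidden_sizes: Tuple[int, int] = (10, 10)
    hidden_beta: float = 1.0
    hidden_levels: int = 3
    hidden_c: float = 10.0
    output_levels: int = 2
    mse_threshold: float = 1e-3
    max_epochs: int = 100
    mu_init: float = 1e-3
    mu_up: float = 10.0
    mu_down: float = 0.1
    decision_threshold: float = 0.5
    # evaluation
    k_folds: int = 5
    seed: int = 0

    def hidden_activation(self) -> mnn.ActivationSpec:
        return mnn.ActivationSpec(beta=self.hidden_beta,
                                  levels=self.hidden_levels, c=self.hidden_c)

    def output_activation(self) -> mnn.ActivationSpec:
        return mnn.ActivationSpec(beta=self.hidden_beta,
                                  levels=self.output_levels, c=self.hidden_c)

    def train_config(self) -> mnn.TrainConfig:
        return mnn.TrainConfig(mse_threshold=self.mse_threshold,
                               max_epochs=self.max_epochs,
                               mu_init=self.mu_init, mu_up=self.mu_up,
                               mu_down=self.mu_down, seed=self.seed)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["hidden_sizes"] = list(self.hidden_sizes)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "hidden_sizes" in doc:
            doc["hidden_sizes"] = tuple(doc["hidden_sizes"])
        return cls(**doc)


def load_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest CSV with columns path,label[,mask_path]."""
    df = pd.read_csv(path)
    if "path" not in df.columns or "label" not in df.columns:
        raise ValueError("manifest needs `path` and `label` columns")
    return df


def preprocess_image(img: preprocess.DermoscopyImage,
                     config: PipelineConfig
                     ) -> Tuple[preprocess.DermoscopyImage, np.ndarray]:
    """Smoothed RGB image (for per-plane Otsu) and the enhanced gray plane."""
    smoothed_planes = [preprocess.smooth(img.pixels[:, :, c],
                                         config.smooth_kernel,
                                         config.smooth_sigma)
                       for c in range(3)]
    smoothed = preprocess.DermoscopyImage(
        pixels=np.stack(smoothed_planes, axis=-1),
        source_path=img.source_path, label=img.label)
    gray = preprocess.to_grayscale(smoothed)
    if config.equalize:
        gray = preprocess.equalize(gray)
    return smoothed, gray


def segment_image(img: preprocess.DermoscopyImage, config: PipelineConfig
                  ) -> Tuple[segmentation.LesionMask,
                             List[segmentation.Contour], np.ndarray]:
    """Preprocess and segment one standardized image.

    Returns (mask, contours, enhanced_gray); segmentation thresholds the
    smoothed RGB planes while features later use the enhanced gray.
    """
    smoothed, gray = preprocess_image(img, config)
    mask, contours = segmentation.segment(
        smoothed, combination_rule=config.combination_rule,
        min_area=config.min_area, size_fraction=config.size_fraction,
        element_radius=config.element_radius,
        open_close_iterations=config.open_close_iterations)
    return mask, contours, gray


def image_descriptor(img: preprocess.DermoscopyImage, config: PipelineConfig,
                     bank: Optional[gabor_features.GaborBank] = None
                     ) -> Tuple[gabor_features.FeatureVector,
                                segmentation.LesionMask, bool]:
    """Segment one image and extract its descriptor.

    Returns (features, mask, degenerate) — ``degenerate`` is True when
    segmentation was empty and the whole frame served as fallback ROI.
    """
    if bank is None:
        bank = gabor_features.build_bank(config.gabor_sigma,
                                         config.gabor_support)
    mask, _, gray = segment_image(img, config)
    degenerate = mask.area == 0
    roi = mask.mask if not degenerate else np.ones_like(mask.mask, dtype=bool)
    fv = gabor_features.extract_descriptor(gray, roi, bank,
                                           alpha=config.alpha,
                                           bins=config.bins)
    return fv, mask, degenerate


def extract_features(manifest: pd.DataFrame,
                     config: Optional[PipelineConfig] = None
                     ) -> pd.DataFrame:
    """Feature table for a manifest: columns path,label,f000..f119."""
    config = config or PipelineConfig()
    bank = gabor_features.build_bank(config.gabor_sigma, config.gabor_support)
    rows = []
    for rec in manifest.itertuples(index=False):
        img = preprocess.standardize(rec.path, label=int(rec.label))
        fv, _, degenerate = image_descriptor(img, config, bank)
        if degenerate:
            logger.warning("degenerate segmentation for %s; descriptor "
                           "computed on the whole frame", rec.path)
        row = {"path": rec.path, "label": int(rec.label)}
        row.update({f"f{i:03d}": v for i, v in enumerate(fv.values)})
        rows.append(row)
    return pd.DataFrame(rows)


def features_from_samples(samples, config: Optional[PipelineConfig] = None
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """(X, y) for in-memory synthetic samples (no disk round-trip)."""
    config = config or PipelineConfig()
    bank = gabor_features.build_bank(config.gabor_sigma, config.gabor_support)
    X, y = [], []
    for sample in samples:
        fv, _, _ = image_descriptor(sample.image, config, bank)
        X.append(fv.values)
        y.append(sample.label)
    return np.stack(X), np.asarray(y, dtype=int)


def feature_matrix(table: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    cols = [c for c in table.columns if c.startswith("f")]
    return table[cols].to_numpy(dtype=float), table["label"].to_numpy(int)


def fit(features: np.ndarray, labels: np.ndarray,
        config: Optional[PipelineConfig] = None
        ) -> Tuple[mnn.MNNModel, gabor_features.MinMaxNormalizer]:
    """Fit the normalizer and train the MNN on a full training set."""
    config = config or PipelineConfig()
    X = np.atleast_2d(np.asarray(features, float))
    norm = gabor_features.MinMaxNormalizer(data_min=X.min(axis=0),
                                           data_max=X.max(axis=0))
    model = mnn.init_model((X.shape[1], *config.hidden_sizes, 1),
                           seed=config.seed,
                           hidden_activation=config.hidden_activation(),
                           output_activation=config.output_activation())
    model, trace = mnn.train(model, norm.transform_matrix(X),
                             labels, config.train_config())
    logger.info("training finished: %d epochs, final MSE %.3g, converged=%s",
                trace.epochs_run, trace.epoch_mse[-1], trace.converged)
    return model, norm


def evaluate_manifest(manifest: pd.DataFrame,
                      config: Optional[PipelineConfig] = None
                      ) -> evaluation.EvalReport:
    """Full-pipeline stratified k-fold CV on a manifest."""
    config = config or PipelineConfig()
    table = extract_features(manifest, config)
    X, y = feature_matrix(table)
    return evaluation.cross_validate(
        X, y, k=config.k_folds, seed=config.seed,
        layer_sizes=(X.shape[1], *config.hidden_sizes, 1),
        hidden_activation=config.hidden_activation(),
        output_activation=config.output_activation(),
        train_config=config.train_config(),
        threshold=config.decision_threshold)


def run_diagnose(image_path, model_path, config: Optional[PipelineConfig] = None,
                 out_path=None) -> dict:
    """Diagnose one image with a persisted model.

    Returns (and optionally writes as JSON) a result record with the
    score, the 0/1 label and the segmentation provenance.
    """
    config = config or PipelineConfig()
    model, norm, _ = mnn.load_model(model_path)
    if norm is None:
        raise ValueError(f"model file {model_path} carries no normalizer; "
                         "refit with pipeline.fit")
    img = preprocess.standardize(image_path)
    fv, mask, degenerate = image_descriptor(img, config)
    label, score = mnn.predict_label(model, norm.transform(fv),
                                     threshold=config.decision_threshold)
    result = {
        "image": str(image_path),
        "label": int(label),
        "score": float(score),
        "lesion_area_px": int(mask.area),
        "n_components": int(mask.n_components),
        "degenerate_segmentation": bool(degenerate),
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(result, indent=2, sort_keys=True))
    return result
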