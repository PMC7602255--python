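"""Seeded generator of dermoscopy-like labeled images with ground truth.

Each sample is a darker, textured lesion blob on a lighter skin-toned
background.  The lesion outline is a perturbed ellipse whose boundary
irregularity depends on the class (malignant lesions are markedly more
irregular), and the lesion interior carries class-scaled multiscale
texture; malignant lesions additionally get intensity variegation (two
sub-regions with distinct means), mimicking the border-irregularity and
pigment-variegation cues dermatologists use.  Every sample comes with
its exact rasterized ground-truth mask, so segmentation quality is
measurable and the two classes are texture-separable by construction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import draw

from .preprocess import DermoscopyImage
from .segmentation import LesionMask


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    Intensities are 8-bit units.  ``irregularity`` and
    ``texture_contrast`` are per-class (benign, malignant) values: the
    boundary-perturbation amplitude as a fraction of the radius, and the
    amplitude of the multiscale intra-lesion texture.
    """

    n_images: int = 80
    image_size: int = 256
    class_balance: float = 0.2
    lesion_area_range: Tuple[float, float] = (0.10, 0.35)
    background_level: float = 190.0
    lesion_level: float = 80.0
    noise_sd: float = 12.0
    irregularity: Tuple[float, float] = (0.08, 0.35)
    texture_contrast: Tuple[float, float] = (5.0, 20.0)
    texture_octaves: int = 3
    variegation_delta: float = 25.0
    shading_amplitude: float = 10.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("lesion_area_range fractions must satisfy "
                             "0 < lo < hi < 1")
        if self.lesion_level >= self.background_level:
            raise ValueError("lesion must be darker than the background")


@dataclasses.dataclass
class LabeledSample:
    image: DermoscopyImage
    truth_mask: LesionMask
    label: int


def generate_lesion_mask(config: SyntheticConfig, rng: np.random.Generator,
                         label: int = 0) -> LesionMask:
    """Perturbed-ellipse lesion blob as a single 8-connected component.

    The polar radius is modulated by a low-order random harmonic series
    (orders 2-6) whose amplitude is the class irregularity; draws are
    repeated (<= 50 attempts) until the rasterized area falls in the
    configured range.
    """
    size = config.image_size
    lo, hi = config.lesion_area_range
    amp = config.irregularity[label]
    for _ in range(50):
        target_area = rng.uniform(lo, hi) * size * size
        # ellipse with mild eccentricity and matching area
        aspect = rng.uniform(0.7, 1.0)
        r_b = np.sqrt(target_area / (np.pi * aspect))
        r_a = r_b * aspect
        theta0 = rng.uniform(0, 2 * np.pi)
        cx = size / 2 + rng.uniform(-0.08, 0.08) * size
        cy = size / 2 + rng.uniform(-0.08, 0.08) * size

        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        modulation = np.zeros_like(theta)
        for order in range(2, 7):
            a = rng.normal(0.0, amp / np.sqrt(5))
            phase = rng.uniform(0, 2 * np.pi)
            modulation += a * np.cos(order * theta + phase)
        radius_a = r_a * (1.0 + modulation)
        radius_b = r_b * (1.0 + modulation)
        radius_a = np.clip(radius_a, 0.2 * r_a, None)
        radius_b = np.clip(radius_b, 0.2 * r_b, None)
        x = radius_a * np.cos(theta)
        y = radius_b * np.sin(theta)
        rows = cy + x * np.sin(theta0) + y * np.cos(theta0)
        cols = cx + x * np.cos(theta0) - y * np.sin(theta0)
        rr, cc = draw.polygon(rows, cols, shape=(size, size))
        mask = np.zeros((size, size), dtype=bool)
        mask[rr, cc] = True
        # keep the largest piece should the polygon self-intersect
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        if n == 0:
            continue
        if n > 1:
            areas = np.bincount(labels.ravel())[1:]
            mask = labels == (int(np.argmax(areas)) + 1)
        frac = mask.sum() / (size * size)
        if lo <= frac <= hi:
            return LesionMask(mask)
    raise RuntimeError("could not draw a lesion mask within the "
                       "configured area range in 50 attempts")


def _multiscale_texture(shape: Tuple[int, int], octaves: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Sum of band-limited noise octaves, unit variance."""
    field = np.zeros(shape)
    for i in range(octaves):
        sigma = 2.0 ** (i + 1)  # 2, 4, 8 px
        layer = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
        layer /= layer.std() + 1e-12
        field += layer
    return field / (field.std() + 1e-12)


def render_sample(config: SyntheticConfig, label: int,
                  rng: np.random.Generator) -> LabeledSample:
    """One labeled dermoscopy-like image plus its ground-truth mask."""
    size = config.image_size
    truth = generate_lesion_mask(config, rng, label=label)
    m = truth.mask

    # skin background: mean level + pixel noise + smooth shading
    gray = np.full((size, size), config.background_level, dtype=float)
    gray += rng.normal(0.0, config.noise_sd, size=(size, size))
    shading = ndimage.gaussian_filter(rng.normal(size=(size, size)), 40.0)
    shading /= np.abs(shading).max() + 1e-12
    gray += config.shading_amplitude * shading

    # lesion interior: darker level + class-scaled multiscale texture
    texture = _multiscale_texture((size, size), config.texture_octaves, rng)
    lesion = config.lesion_level \
        + config.texture_contrast[label] * texture \
        + rng.normal(0.0, config.noise_sd / 2.0, size=(size, size))
    if label == 1:
        # pigment variegation: two sub-regions split by a random line
        # through the lesion centroid, with distinct mean intensities
        rows, cols = np.nonzero(m)
        cy, cx = rows.mean(), cols.mean()
        ang = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:size, 0:size]
        side = (np.cos(ang) * (xx - cx) + np.sin(ang) * (yy - cy)) >= 0
        lesion = lesion + np.where(side, config.variegation_delta,
                                   -config.variegation_delta)
    gray[m] = lesion[m]
    gray = np.clip(gray, 0, 255)

    # skin-tone tint: reddish background, brownish lesion
    r = np.clip(gray * 1.00 + 25, 0, 255)
    g = np.clip(gray * 0.82 + 10, 0, 255)
    b = np.clip(gray * 0.70, 0, 255)
    pixels = np.stack([r, g, b], axis=-1).astype(np.uint8)
    image = DermoscopyImage(pixels=pixels, source_path="", label=label)
    return LabeledSample(image=image, truth_mask=truth, label=label)


def class_sequence(config: SyntheticConfig) -> np.ndarray:
    """Deterministic label sequence honouring the class balance."""
    n_mal = int(round(config.n_images * config.class_balance))
    labels = np.zeros(config.n_images, dtype=int)
    labels[:n_mal] = 1
    rng = np.random.default_rng(config.seed)
    rng.shuffle(labels)
    return labels


def generate_samples(config: SyntheticConfig) -> List[LabeledSample]:
    """The full in-memory cohort; deterministic for a fixed config."""
    labels = class_sequence(config)
    samples = []
    for i, label in enumerate(labels):
        rng = np.random.default_rng((config.seed, i))
        samples.append(render_sample(config, int(label), rng))
    return samples


def generate_dataset(config: SyntheticConfig, out_dir) -> pd.DataFrame:
    """Write images, truth masks and a ``manifest.csv`` to ``out_dir``.

    The manifest has columns path,label,mask_path; regenerating with the
    same config reproduces identical file bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sample in enumerate(generate_samples(config)):
        img_path = out_dir / f"sample_{i:04d}.png"
        mask_path = out_dir / f"sample_{i:04d}_mask.png"
        Image.fromarray(sample.image.pixels).save(img_path)
        Image.fromarray((sample.truth_mask.mask * 255).astype(np.uint8)
                        ).save(mask_path)
        rows.append({"path": str(img_path), "label": sample.label,
                     "mask_path": str(mask_path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_ph2_layout(root) -> pd.DataFrame:
    """Map a PH2-style directory tree onto the manifest schema.

    Expects ``<root>/<CASE>/<CASE>_Dermoscopic_Image/<CASE>.bmp`` and the
    matching ``<CASE>_lesion/<CASE>_lesion.bmp`` mask; labels come from a
    ``labels.csv`` (columns case,label) at the root if present, else -1.
    """
    root = Path(root)
    label_map: Dict[str, int] = {}
    label_file = root / "labels.csv"
    if label_file.exists():
        df = pd.read_csv(label_file)
        label_map = dict(zip(df["case"].astype(str), df["label"].astype(int)))
    rows = []
    for case_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        case = case_dir.name
        img = case_dir / f"{case}_Dermoscopic_Image" / f"{case}.bmp"
        mask = case_dir / f"{case}_lesion" / f"{case}_lesion.bmp"
        if img.exists():
            rows.append({"path": str(img),
                         "label": label_map.get(case, -1),
                         "mask_path": str(mask) if mask.exists() else ""})
    return pd.DataFrame(rows)
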