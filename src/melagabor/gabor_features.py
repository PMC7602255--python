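"""Gabor filter bank, ROI convolution, and entropic feature reduction.

The texture descriptor is built in three steps:

1. a bank of 40 complex Gabor wavelets (5 scales x 8 orientations),
   each a complex plane wave under a Gaussian envelope with the DC
   response removed;
2. convolution of the lesion ROI (bounding-box crop of the grayscale
   image, statistics restricted to lesion pixels) with every kernel;
3. reduction of each max-normalized magnitude map to three scalar
   measures of its response histogram — Rényi entropy, Tsallis entropy
   and a discrete Fisher-information surrogate — giving a 120-value
   descriptor (3 measures x 40 filters).

Because each magnitude map is divided by its own maximum before the
histogram is taken, the descriptor is invariant to a global rescaling
of the ROI intensities (illumination scale).
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import fftconvolve
from sklearn.preprocessing import MinMaxScaler

from .segmentation import LesionMask

#: default Gaussian-envelope parameter of the wavelet family
DEFAULT_SIGMA = 2.0 * np.pi
#: default spatial support of each sampled kernel, in pixels (odd)
DEFAULT_SUPPORT = 31
#: default entropic order for the Rényi / Tsallis measures
DEFAULT_ALPHA = 2.0
#: default number of histogram bins over the normalized-response range
DEFAULT_BINS = 64

N_SCALES = 5
N_ORIENTATIONS = 8
N_FILTERS = N_SCALES * N_ORIENTATIONS
#: descriptor length: (renyi, tsallis, fisher) per filter
DESCRIPTOR_LENGTH = 3 * N_FILTERS


class EmptyROIError(ValueError):
    """The lesion mask selects no pixels."""


def wave_number(scale: int) -> float:
    """Radial wave number k_v = 2^(-(v+2)/2) * pi of scale v."""
    return 2.0 ** (-(scale + 2) / 2.0) * np.pi


def orientation_angle(orientation: int) -> float:
    """Orientation angle phi_mu = mu * pi / 8."""
    return orientation * np.pi / 8.0


@dataclasses.dataclass
class GaborBank:
    """40 complex Gabor kernels indexed by j = mu + 8*v."""

    kernels: List[np.ndarray]
    sigma: float
    support: int

    def __getitem__(self, j: int) -> np.ndarray:
        return self.kernels[j]

    def __len__(self) -> int:
        return len(self.kernels)

    @staticmethod
    def index(orientation: int, scale: int) -> int:
        return orientation + N_ORIENTATIONS * scale


@dataclasses.dataclass
class GaborResponseStack:
    """Complex ROI responses of all 40 kernels plus their magnitudes."""

    responses: List[np.ndarray]
    magnitudes: List[np.ndarray]
    roi_mask: np.ndarray


@dataclasses.dataclass
class FeatureVector:
    """120-value Gabor-entropic descriptor of one lesion."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (DESCRIPTOR_LENGTH,):
            raise ValueError(
                f"descriptor must have {DESCRIPTOR_LENGTH} values, "
                f"got {self.values.shape}")


def gabor_kernel(scale: int, orientation: int, sigma: float = DEFAULT_SIGMA,
                 support: int = DEFAULT_SUPPORT) -> np.ndarray:
    """One complex Gabor wavelet sampled on an odd square grid.

    psi(z) = (|k|^2 / sigma^2) exp(-|k|^2 |z|^2 / (2 sigma^2))
             * [exp(i k.z) - exp(-sigma^2 / 2)]

    with wave vector k of magnitude 2^(-(v+2)/2)*pi at angle mu*pi/8.
    The residual mean of the sampled grid is subtracted so the kernel is
    exactly DC-free despite truncation to a finite support.
    """
    if support % 2 == 0 or support < 7:
        raise ValueError(f"support must be odd and >= 7, got {support}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    k = wave_number(scale)
    phi = orientation_angle(orientation)
    kx, ky = k * np.cos(phi), k * np.sin(phi)
    half = support // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    r2 = x * x + y * y
    envelope = (k * k / sigma ** 2) * np.exp(-k * k * r2 / (2.0 * sigma ** 2))
    carrier = np.exp(1j * (kx * x + ky * y)) - np.exp(-sigma ** 2 / 2.0)
    kernel = envelope * carrier
    kernel -= kernel.mean()  # enforce exact DC-freeness on the sampled grid
    return kernel


def build_bank(sigma: float = DEFAULT_SIGMA,
               support: int = DEFAULT_SUPPORT) -> GaborBank:
    """The full 40-kernel bank, index j = mu + 8*v, v in 0..4, mu in 0..7."""
    kernels = [gabor_kernel(v, mu, sigma=sigma, support=support)
               for v in range(N_SCALES) for mu in range(N_ORIENTATIONS)]
    return GaborBank(kernels=kernels, sigma=sigma, support=support)


def _roi_crop(gray: np.ndarray, mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    return gray[r0:r1, c0:c1], mask[r0:r1, c0:c1]


def convolve_roi(gray: np.ndarray, mask, bank: GaborBank) -> GaborResponseStack:
    """Convolve the ROI bounding-box crop with every kernel in the bank.

    Full 2-D convolution with reflective borders; the cropped mask marks
    which response pixels enter downstream statistics.
    """
    mask_arr = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, bool)
    if not mask_arr.any():
        raise EmptyROIError("lesion mask selects no pixels")
    gray = np.asarray(gray, dtype=float)
    if gray.shape != mask_arr.shape:
        raise ValueError("gray image and mask must share dimensions")
    crop, roi_mask = _roi_crop(gray, mask_arr)
    half = bank.support // 2
    # half-sample symmetric reflection (edge repeated), matching
    # scipy.ndimage's "reflect" convention
    padded = np.pad(crop, half, mode="symmetric")
    responses, magnitudes = [], []
    for kernel in bank.kernels:
        resp = fftconvolve(padded, kernel, mode="valid")
        responses.append(resp)
        magnitudes.append(np.abs(resp))
    return GaborResponseStack(responses=responses, magnitudes=magnitudes,
                              roi_mask=roi_mask)


def normalize_responses(stack: GaborResponseStack) -> GaborResponseStack:
    """Divide each magnitude map by its maximum over valid ROI pixels.

    An all-zero map is left untouched (no division by zero).
    """
    normalized = []
    for mag in stack.magnitudes:
        peak = mag[stack.roi_mask].max() if stack.roi_mask.any() else 0.0
        normalized.append(mag / peak if peak > 0 else mag.copy())
    return GaborResponseStack(responses=stack.responses, magnitudes=normalized,
                              roi_mask=stack.roi_mask)


def response_histogram(magnitudes: np.ndarray, mask: np.ndarray,
                       bins: int = DEFAULT_BINS) -> np.ndarray:
    """Probability vector of normalized responses over [0, 1]."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(magnitudes, dtype=float)[mask]
    if values.size == 0:
        raise EmptyROIError("no valid pixels for the response histogram")
    counts, _ = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return counts / counts.sum()


def renyi_entropy(p: np.ndarray, alpha: float = DEFAULT_ALPHA) -> float:
    """Rényi entropy H_alpha(P) = log2(sum p_i^alpha) / (1 - alpha), in bits."""
    p = _check_probabilities(p)
    if alpha < 0 or alpha == 1.0:
        raise ValueError("alpha must be >= 0 and != 1 "
                         "(use the Shannon limit for alpha = 1)")
    support = p[p > 0]
    return float(np.log2(np.sum(support ** alpha)) / (1.0 - alpha))


def tsallis_entropy(p: np.ndarray, alpha: float = DEFAULT_ALPHA) -> float:
    """Tsallis entropy H_alpha(P) = (1 - sum p_i^alpha) / (alpha - 1)."""
    p = _check_probabilities(p)
    if alpha < 0 or alpha == 1.0:
        raise ValueError("alpha must be >= 0 and != 1")
    support = p[p > 0]
    return float((1.0 - np.sum(support ** alpha)) / (alpha - 1.0))


def fisher_information(p: np.ndarray) -> float:
    """Discrete Fisher-information surrogate sum (p_{i+1}-p_i)^2 / p_i.

    Terms whose denominator p_i is zero are skipped, keeping the measure
    finite without an epsilon.
    """
    p = _check_probabilities(p)
    diffs = np.diff(p)
    base = p[:-1]
    valid = base > 0
    return float(np.sum(diffs[valid] ** 2 / base[valid]))


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits (the alpha -> 1 limit of both entropies)."""
    p = _check_probabilities(p)
    support = p[p > 0]
    return float(-np.sum(support * np.log2(support)))


def _check_probabilities(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("probabilities must sum to 1")
    return p


def extract_descriptor(gray: np.ndarray, mask, bank: Optional[GaborBank] = None,
                       alpha: float = DEFAULT_ALPHA,
                       bins: int = DEFAULT_BINS) -> FeatureVector:
    """The 120-value descriptor of one lesion ROI.

    For each filter j = 0..39, the max-normalized magnitude map is
    histogrammed over lesion pixels and reduced to the triple
    (renyi, tsallis, fisher); triples are concatenated in filter order.
    A filter with an all-zero response map (e.g. a constant ROI under a
    DC-free kernel) contributes the degenerate triple (0, 0, 0).
    """
    if bank is None:
        bank = build_bank()
    stack = convolve_roi(gray, mask, bank)
    # degenerate-response floor: raw magnitudes at the level of float
    # noise (DC-free kernel on a constant ROI) carry no texture; their
    # max-normalization would only amplify rounding error
    floor = 1e-9 * max(float(np.abs(np.asarray(gray, float)).max()), 1.0)
    values = np.empty(3 * len(bank.kernels))
    for j, mag in enumerate(stack.magnitudes):
        peak = mag[stack.roi_mask].max()
        if peak <= floor:
            values[3 * j: 3 * j + 3] = 0.0
            continue
        p = response_histogram(mag / peak, stack.roi_mask, bins=bins)
        values[3 * j] = renyi_entropy(p, alpha)
        values[3 * j + 1] = tsallis_entropy(p, alpha)
        values[3 * j + 2] = fisher_information(p)
    return FeatureVector(values=values, normalized=False)


@dataclasses.dataclass
class MinMaxNormalizer:
    """Per-component min-max normalization fitted on training vectors only.

    Maps each component affinely to [0, 1]; unseen values are clipped and
    a constant training component maps to 0.
    """

    data_min: np.ndarray
    data_max: np.ndarray

    @classmethod
    def fit(cls, train_features: Sequence[FeatureVector]) -> "MinMaxNormalizer":
        if len(train_features) < 2:
            raise ValueError("need at least 2 training vectors to fit "
                             "the normalizer")
        X = np.stack([fv.values for fv in train_features])
        scaler = MinMaxScaler(feature_range=(0, 1), clip=True).fit(X)
        return cls(data_min=scaler.data_min_, data_max=scaler.data_max_)

    def transform(self, fv: FeatureVector) -> FeatureVector:
        span = self.data_max - self.data_min
        safe = np.where(span > 0, span, 1.0)
        out = np.clip((fv.values - self.data_min) / safe, 0.0, 1.0)
        out = np.where(span > 0, out, 0.0)
        return FeatureVector(values=out, normalized=True)

    def transform_matrix(self, X: np.ndarray) -> np.ndarray:
        span = self.data_max - self.data_min
        safe = np.where(span > 0, span, 1.0)
        out = np.clip((np.asarray(X, float) - self.data_min) / safe, 0.0, 1.0)
        return np.where(span > 0, out, 0.0)

    def to_dict(self) -> dict:
        return {"data_min": self.data_min.tolist(),
                "data_max": self.data_max.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxNormalizer":
        return cls(data_min=np.asarray(d["data_min"], float),
                   data_max=np.asarray(d["data_max"], float))


def minmax_normalize(train_features: Sequence[FeatureVector]
                     ) -> Tuple[MinMaxNormalizer, List[FeatureVector]]:
    """Fit a normalizer on training descriptors and normalize them."""
    norm = MinMaxNormalizer.fit(train_features)
    return norm, [norm.transform(fv) for fv in train_features]
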