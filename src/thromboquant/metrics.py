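"""Coverage parameters from brightfield and fluorescence microscopy.

Implements the continuous surface-area-coverage (SAC) parameters of the
thrombus-formation assay:

* P1 — platelet adhesion, % of the field covered by platelets (brightfield);
* P2 — platelet aggregate coverage, % of the field covered by multilayered
  aggregates (brightfield);
* P6/P7/P8 — % of the field staining positive for phosphatidylserine,
  P-selectin, and bound fibrinogen (one fluorescence channel each).

Segmentation is fully automatic: a flat-field correction (subtraction of a
large-radius Gaussian background estimate) followed by Otsu thresholding with
the appropriate polarity (platelets are darker than the brightfield
background; stains are brighter than the fluorescence background).  A fixed
absolute threshold can be supplied instead for images where automatic
thresholding is unsuitable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger("thromboquant")

__all__ = [
    "BRIGHTFIELD",
    "FLUOR_CHANNELS",
    "CHANNEL_PARAMETER",
    "IntensityImage",
    "BinaryMask",
    "ParameterSet",
    "AggregateSegmentation",
    "SegmentationConfig",
    "segment_platelets",
    "segment_aggregates",
    "segment_fluor_positive",
    "sac_percent",
]

BRIGHTFIELD = "brightfield"
FLUOR_CHANNELS = ("PS", "P-selectin", "fibrinogen")
#: which SAC parameter each fluorescence channel feeds
CHANNEL_PARAMETER = {"PS": "P6", "P-selectin": "P7", "fibrinogen": "P8"}


@dataclass(frozen=True)
class IntensityImage:
    """Single-channel grayscale image with physical pixel size (µm/pixel)."""

    pixels: np.ndarray
    channel: str
    pixel_size: float = 0.2

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("image must be a non-empty 2-D grid")
        if not np.isfinite(px).all():
            raise ValueError("image intensities must be finite")
        if self.channel != BRIGHTFIELD and self.channel not in FLUOR_CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass(frozen=True)
class BinaryMask:
    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))

    @property
    def coverage_percent(self) -> float:
        return sac_percent(self)


@dataclass
class ParameterSet:
    """The eight thrombus parameters; NaN marks a missing measurement."""

    P1: float = np.nan  # platelet adhesion (% SAC)
    P2: float = np.nan  # platelet aggregate coverage (% SAC)
    P3: float = np.nan  # thrombus morphological score (0–5)
    P4: float = np.nan  # thrombus multilayer score (0–3)
    P5: float = np.nan  # thrombus contraction score (0–3)
    P6: float = np.nan  # PS exposure (% SAC)
    P7: float = np.nan  # P-selectin expression (% SAC)
    P8: float = np.nan  # fibrinogen binding (% SAC)

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in PARAMETERS}


PARAMETERS = ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8")
BRIGHTFIELD_PARAMETERS = ("P1", "P2", "P3", "P4", "P5")
FLUORESCENCE_PARAMETERS = ("P6", "P7", "P8")


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the automatic segmentation, exposed in the pipeline config."""

    method: str = "otsu"              # "otsu" | "fixed"
    fixed_threshold: Optional[float] = None
    flatfield_sigma: float = 150.0    # px; background-estimation Gaussian
    min_aggregate_area: float = 20.0  # µm²; smallest multilayered aggregate
    multilayer_offset: float = 0.33   # relative depth above the monolayer level
    monolayer_quantile: float = 0.40  # corrected-intensity quantile of the
                                      # platelet mask taken as monolayer level
                                      # (sits on the single-layer plateau,
                                      # above the edge-dimmed rim pixels)
    min_core_area: float = 2.0        # µm² of multilayer core required
    min_core_fraction: float = 0.05   # ... and at least this fraction of the
                                      # component area (guards against noise)
    tier_smooth_sigma: float = 1.0    # px; smoothing before tier classification
    noise_k: float = 4.0              # Otsu guard: class separation must exceed
                                      # k × the robust spread of the background class

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "fixed"):
            raise ValueError(f"unknown segmentation method {self.method!r}")
        if self.method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        if not (0.0 < self.monolayer_quantile < 1.0):
            raise ValueError("monolayer_quantile must lie in (0, 1)")


def sac_percent(mask: BinaryMask | np.ndarray) -> float:
    """Surface area coverage: 100 × true pixels / total pixels."""
    px = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    return 100.0 * float(px.sum()) / px.size


def _smooth_surface(img: np.ndarray, sigma: float) -> np.ndarray:
    """Large-scale Gaussian smoothing, computed on a decimated grid.

    The background is by definition smooth at the scale of ``sigma``, so it
    can be estimated on a subsampled image and interpolated back, which keeps
    the cost independent of the smoothing radius.
    """
    f = max(1, int(sigma // 16))
    if f == 1:
        return ndimage.gaussian_filter(img, sigma)
    small = ndimage.gaussian_filter(img[::f, ::f], sigma / f, mode="nearest")
    zoom = (img.shape[0] / small.shape[0], img.shape[1] / small.shape[1])
    return ndimage.zoom(small, zoom, order=1, mode="nearest", grid_mode=True)


def _corrected(
    image: IntensityImage,
    sigma: float,
    polarity: str,
    exclude: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Flat-field-corrected image with objects positive regardless of polarity.

    With ``exclude`` (an object mask), the background is re-estimated from
    non-object pixels only via normalized convolution; this removes the bias
    the objects themselves impose on a plain smoothed-background estimate in
    densely covered fields.
    """
    if exclude is not None and exclude.any() and not exclude.all():
        w = (~exclude).astype(np.float64)
        num = _smooth_surface(image.pixels * w, sigma)
        den = _smooth_surface(w, sigma)
        background = num / np.maximum(den, 1e-6)
    else:
        background = _smooth_surface(image.pixels, sigma)
    if polarity == "dark":
        return background - image.pixels
    return image.pixels - background


def _auto_mask(corrected: np.ndarray, noise_k: float, what: str) -> np.ndarray:
    """Otsu threshold with degenerate-image and pure-noise guards."""
    lo, hi = float(corrected.min()), float(corrected.max())
    if hi - lo < 1e-9 * max(1.0, abs(hi), abs(lo)) or hi == lo:
        logger.warning("%s: constant image, returning empty mask", what)
        warnings.warn(f"{what}: constant image, empty mask returned", stacklevel=3)
        return np.zeros(corrected.shape, dtype=bool)
    thr = threshold_otsu(corrected)
    below = corrected[corrected <= thr]
    above = corrected[corrected > thr]
    if below.size == 0 or above.size == 0:
        return corrected > thr
    # Pure noise split by Otsu gives two classes ~1.6 robust-σ apart; genuine
    # objects sit many σ above the background class.  Scale-equivariant.
    med_b = float(np.median(below))
    sigma_b = 1.4826 * float(np.median(np.abs(below - med_b)))
    separation = float(np.mean(above)) - float(np.mean(below))
    if sigma_b > 0 and separation <= noise_k * sigma_b:
        logger.warning(
            "%s: no intensity population above the noise floor, empty mask", what
        )
        warnings.warn(f"{what}: nothing above noise floor, empty mask", stacklevel=3)
        return np.zeros(corrected.shape, dtype=bool)
    return corrected > thr


def segment_platelets(
    image: IntensityImage,
    config: SegmentationConfig = SegmentationConfig(),
    polarity: str = "dark",
) -> BinaryMask:
    """Mask of platelet-covered pixels in a brightfield image (P1 source).

    Default: flat-field correction then Otsu with dark-object polarity.  A
    constant image yields an empty mask with a warning rather than an error.
    """
    if image.channel != BRIGHTFIELD:
        raise ValueError("platelet segmentation expects a brightfield image")
    if config.method == "fixed":
        thr = float(config.fixed_threshold)
        px = image.pixels <= thr if polarity == "dark" else image.pixels >= thr
        return BinaryMask(px, provenance=f"fixed_threshold={thr:g}")
    corrected = _corrected(image, config.flatfield_sigma, polarity)
    mask = _auto_mask(corrected, config.noise_k, "segment_platelets")
    if mask.any():
        # second pass: background re-estimated away from the detected objects
        corrected = _corrected(image, config.flatfield_sigma, polarity, exclude=mask)
        mask = _auto_mask(corrected, config.noise_k, "segment_platelets")
    return BinaryMask(mask, provenance="flatfield2+otsu(dark)")


@dataclass(frozen=True)
class AggregateSegmentation:
    """Multilayered-aggregate mask plus the multilayer intensity tier."""

    aggregate_mask: BinaryMask
    multilayer_mask: BinaryMask
    monolayer_level: float = np.nan
    multilayer_threshold: float = np.nan


def segment_aggregates(
    image: IntensityImage,
    platelet_mask: BinaryMask,
    config: SegmentationConfig = SegmentationConfig(),
) -> AggregateSegmentation:
    """Multilayered platelet aggregates within the platelet mask (P2 source).

    A connected platelet component counts as an aggregate when it exceeds
    ``min_aggregate_area`` and contains a multilayer core: pixels whose
    corrected (darkness) intensity exceeds the monolayer reference level by
    the relative ``multilayer_offset``.  The monolayer reference is a low
    quantile of corrected intensities inside the platelet mask, which stays
    anchored to the single-layer population even when multilayered regions
    dominate the covered area.  The output is a subset of ``platelet_mask``,
    so P2 ≤ P1 by construction.
    """
    if platelet_mask.pixels.shape != image.pixels.shape:
        raise ValueError("platelet mask and image shapes differ")
    empty = AggregateSegmentation(
        BinaryMask(np.zeros_like(platelet_mask.pixels), "aggregates"),
        BinaryMask(np.zeros_like(platelet_mask.pixels), "multilayer"),
    )
    if not platelet_mask.pixels.any():
        return empty
    corrected = _corrected(
        image, config.flatfield_sigma, "dark", exclude=platelet_mask.pixels
    )
    if config.tier_smooth_sigma > 0:
        # damp pixel noise before comparing against the tier threshold
        corrected = ndimage.gaussian_filter(corrected, config.tier_smooth_sigma)
    inside = corrected[platelet_mask.pixels]
    mono_level = float(np.quantile(inside, config.monolayer_quantile))
    if mono_level <= 0:
        return empty
    ml_thr = mono_level * (1.0 + config.multilayer_offset)
    multilayer = platelet_mask.pixels & (corrected > ml_thr)

    px_area = image.pixel_size**2
    min_area_px = config.min_aggregate_area / px_area
    min_core_px = config.min_core_area / px_area
    labels, n = ndimage.label(platelet_mask.pixels)
    if n == 0:
        return empty
    areas = ndimage.sum_labels(platelet_mask.pixels, labels, index=np.arange(1, n + 1))
    cores = ndimage.sum_labels(multilayer, labels, index=np.arange(1, n + 1))
    keep = (areas > min_area_px) & (
        cores >= np.maximum(min_core_px, config.min_core_fraction * areas)
    )
    agg = keep[labels - 1] & platelet_mask.pixels
    return AggregateSegmentation(
        aggregate_mask=BinaryMask(agg, "aggregates"),
        multilayer_mask=BinaryMask(multilayer & agg, "multilayer"),
        monolayer_level=mono_level,
        multilayer_threshold=ml_thr,
    )


def segment_fluor_positive(
    image: IntensityImage,
    config: SegmentationConfig = SegmentationConfig(),
) -> BinaryMask:
    """Mask of stain-positive pixels in a fluorescence image (P6–P8 source)."""
    if image.channel not in FLUOR_CHANNELS:
        raise ValueError(
            f"expected a fluorescence channel {FLUOR_CHANNELS}, got {image.channel!r}"
        )
    if config.method == "fixed":
        thr = float(config.fixed_threshold)
        return BinaryMask(image.pixels >= thr, provenance=f"fixed_threshold={thr:g}")
    corrected = _corrected(image, config.flatfield_sigma, "bright")
    mask = _auto_mask(corrected, config.noise_k, f"segment_fluor[{image.channel}]")
    if mask.any():
        corrected = _corrected(image, config.flatfield_sigma, "bright", exclude=mask)
        mask = _auto_mask(corrected, config.noise_k, f"segment_fluor[{image.channel}]")
    return BinaryMask(mask, provenance="flatfield2+otsu(bright)")


def measure_brightfield(
    image: IntensityImage,
    config: SegmentationConfig = SegmentationConfig(),
) -> Tuple[ParameterSet, BinaryMask, AggregateSegmentation]:
    """P1 and P2 (plus masks) from one brightfield image."""
    platelets = segment_platelets(image, config)
    aggregates = segment_aggregates(image, platelets, config)
    ps = ParameterSet(P1=sac_percent(platelets), P2=sac_percent(aggregates.aggregate_mask))
    return ps, platelets, aggregates


def measure_fluorescence(
    images: Dict[str, IntensityImage],
    config: SegmentationConfig = SegmentationConfig(),
) -> ParameterSet:
    """P6–P8 from the channel images of one fluorescence field."""
    ps = ParameterSet()
    for ch, img in images.items():
        if ch not in CHANNEL_PARAMETER:
            raise ValueError(f"unknown fluorescence channel {ch!r}")
        setattr(ps, CHANNEL_PARAMETER[ch], sac_percent(segment_fluor_positive(img, config)))
    return ps
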