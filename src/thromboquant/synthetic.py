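"""Synthetic flow-chamber microscopy experiments with known ground truth.

Emulates the study design of a whole-blood thrombus-formation assay: blood
from several donors is perfused in duplicate runs over collagen microspots
(collagen I/III/IV) at a low (venous, 150 s⁻¹) or high (arterial,
1000–1600 s⁻¹) wall-shear rate, after pre-incubation with an inhibitor or
vehicle.  Per run the microscope captures two brightfield fields and three
multicolor fluorescence fields (phosphatidylserine / P-selectin / fibrinogen
channels).

Each synthetic field is built from an explicit geometric model — single
platelets are 2–4 µm discs, aggregates are Gaussian-clustered disc groups
merged into blobs, and multilayered thrombus cores are a second, darker
brightfield intensity tier inside aggregates — so every generated image comes
with exact pixel masks and coverage fractions as a recovery oracle for the
measurement pipeline.  Condition effects are encoded as per-shear
multiplicative factors on the generative intensities (platelet seeding
density, aggregate share, multilayer share, per-channel positivity); donor
variation is a lognormal multiplier on seeding density shared across a
donor's runs.  No fluid dynamics or adhesion kinetics are modeled.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .metrics import IntensityImage, FLUOR_CHANNELS, BRIGHTFIELD

__all__ = [
    "ConditionSpec",
    "ExperimentDesign",
    "GroundTruth",
    "RunMetadata",
    "FieldImages",
    "FlowRun",
    "GenerationError",
    "DesignError",
    "sample_ground_truth",
    "render_brightfield",
    "render_fluorescence",
    "generate_experiment",
    "write_experiment",
    "BASELINES",
]

# ---------------------------------------------------------------------------
# Rendering constants (16-bit grayscale counts)

BRIGHTFIELD_BACKGROUND = 40_000.0
MONOLAYER_DEPTH = 12_000.0      # intensity drop of a single platelet layer
MULTILAYER_EXTRA_DEPTH = 8_000.0  # additional drop of the multilayer tier
FLUOR_BACKGROUND = 800.0
FLUOR_POSITIVE = 18_000.0
DEFAULT_NOISE_SD = 1_500.0      # additive Gaussian pixel noise
ILLUMINATION_AMPLITUDE = 0.03   # ±3 % linear ramp across the field
EDGE_SIGMA_PX = 0.6             # optical blur of the level map (≈ diffraction
                                # scale of a 60× oil objective at 0.2 µm/px)

_GROUPS = ("seeding", "aggregate", "multilayer", "PS", "P-selectin", "fibrinogen")


class GenerationError(RuntimeError):
    pass


class DesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Design types


@dataclass(frozen=True)
class ConditionSpec:
    """One perfusion condition and its per-shear generative effect.

    ``effect_multipliers`` maps a wall-shear rate (s⁻¹) to multiplicative
    factors on the generative intensities; groups not listed default to 1.
    ``seeding`` scales overall platelet deposition (platelet and aggregate
    field coverage together), ``aggregate`` the share of platelet area inside
    aggregates, ``multilayer`` the share of aggregate area with a multilayer
    core, and the three channel names the positive share of platelet area.
    """

    name: str
    effect_multipliers: Mapping[float, Mapping[str, float]] = field(
        default_factory=dict
    )
    donor_sd: float = 0.20
    noise_sd: float = DEFAULT_NOISE_SD

    def multiplier(self, shear_rate: float, group: str) -> float:
        if group not in _GROUPS:
            raise DesignError(f"unknown effect group {group!r}")
        value = float(self.effect_multipliers.get(shear_rate, {}).get(group, 1.0))
        if value < 0:
            raise DesignError(
                f"condition {self.name!r}: multiplier for {group!r} at "
                f"{shear_rate} s⁻¹ is negative"
            )
        return value

    @staticmethod
    def control(name: str = "control", **kwargs) -> "ConditionSpec":
        return ConditionSpec(name=name, effect_multipliers={}, **kwargs)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a synthetic flow-assay experiment."""

    donors: int = 3
    duplicate_runs_per_condition: int = 2
    microspots: Tuple[str, ...] = ("collagen-I", "collagen-III", "collagen-IV")
    shear_rates: Tuple[float, ...] = (1000.0, 150.0)
    conditions: Tuple[ConditionSpec, ...] = (ConditionSpec.control(),)
    images_per_run_brightfield: int = 2
    images_per_run_fluorescence: int = 3
    field_size: Tuple[int, int] = (1024, 1360)  # rows × cols (1360 × 1024 CCD)
    pixel_size: float = 0.2  # µm / pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.donors < 1 or not self.conditions or not self.microspots:
            raise DesignError("design needs ≥1 donor, ≥1 condition, ≥1 microspot")
        if self.donors < 3:
            warnings.warn(
                "fewer than 3 donors: paired statistics will be weak",
                stacklevel=2,
            )
        if self.donors < 2:
            warnings.warn("paired tests need at least 2 donors", stacklevel=2)
        for n in (
            self.duplicate_runs_per_condition,
            self.images_per_run_brightfield,
            self.images_per_run_fluorescence,
        ):
            if n < 1:
                raise DesignError("all image/run counts must be positive")
        if min(self.field_size) < 32:
            raise DesignError("field smaller than 32 px is not meaningful")
        if self.pixel_size <= 0:
            raise DesignError("pixel_size must be positive")
        for cond in self.conditions:
            for shear in cond.effect_multipliers:
                if shear not in self.shear_rates:
                    raise DesignError(
                        f"condition {cond.name!r} references shear "
                        f"{shear} s⁻¹ absent from the design"
                    )


@dataclass(frozen=True)
class RunMetadata:
    donor: str
    condition: str
    microspot: str
    shear_rate: float
    run_id: str

    def key(self) -> Tuple[str, str, str, float, str]:
        return (self.donor, self.condition, self.microspot, self.shear_rate, self.run_id)


@dataclass
class GroundTruth:
    """Exact per-field truth; fractions are pixel-counted on the masks."""

    true_platelet_fraction: float
    true_aggregate_fraction: float
    true_multilayer_fraction_of_platelet: float
    true_channel_fraction: Dict[str, float]
    object_table: pd.DataFrame
    intended_scores: Tuple[int, int, int]
    platelet_mask: np.ndarray
    aggregate_mask: np.ndarray
    multilayer_mask: np.ndarray
    channel_masks: Dict[str, np.ndarray]
    pixel_size: float

    def validate(self) -> None:
        f = self.true_platelet_fraction
        if not (0.0 <= f <= 1.0):
            raise GenerationError("platelet fraction outside [0, 1]")
        if self.true_aggregate_fraction > f + 1e-12:
            raise GenerationError("aggregate fraction exceeds platelet fraction")
        for ch, cf in self.true_channel_fraction.items():
            if cf > f + 1e-12:
                raise GenerationError(f"channel {ch} fraction exceeds platelet fraction")


@dataclass
class FieldImages:
    """Images of one microscope field plus its generating truth."""

    role: str  # "brightfield" | "fluorescence"
    index: int
    images: Dict[str, IntensityImage]  # channel name -> image
    truth: GroundTruth


@dataclass
class FlowRun:
    metadata: RunMetadata
    fields: List[FieldImages]


# ---------------------------------------------------------------------------
# Baseline generative intensities
#
# Per microspot and shear regime: field fraction covered by platelets, share
# of platelet area in aggregates, share of aggregate area with a multilayer
# core, positive share of platelet area per fluorescence channel, and a
# compactness (0–1) controlling how contracted aggregates are.  Collagen I is
# the strongest surface, collagen IV the weakest; high shear gives denser,
# more contracted, more activated thrombi.  Values are generator defaults in
# the mid-range of the assay's reported parameter ranges.

_HIGH = {
    "collagen-I": dict(platelet=0.38, agg_share=0.55, multi_share=0.55,
                       PS=0.12, **{"P-selectin": 0.55}, fibrinogen=0.40,
                       compactness=0.80),
    "collagen-III": dict(platelet=0.28, agg_share=0.45, multi_share=0.50,
                         PS=0.10, **{"P-selectin": 0.45}, fibrinogen=0.32,
                         compactness=0.65),
    "collagen-IV": dict(platelet=0.20, agg_share=0.40, multi_share=0.45,
                        PS=0.08, **{"P-selectin": 0.40}, fibrinogen=0.26,
                        compactness=0.50),
}
_LOW = {
    "collagen-I": dict(platelet=0.24, agg_share=0.40, multi_share=0.40,
                       PS=0.08, **{"P-selectin": 0.40}, fibrinogen=0.28,
                       compactness=0.45),
    "collagen-III": dict(platelet=0.17, agg_share=0.32, multi_share=0.38,
                         PS=0.06, **{"P-selectin": 0.32}, fibrinogen=0.22,
                         compactness=0.35),
    "collagen-IV": dict(platelet=0.12, agg_share=0.28, multi_share=0.35,
                        PS=0.05, **{"P-selectin": 0.28}, fibrinogen=0.18,
                        compactness=0.30),
}

BASELINES = {"high": _HIGH, "low": _LOW}
_SHEAR_HIGH_CUTOFF = 500.0  # s⁻¹: ≥500 treated as the arterial regime
_IMAGE_JITTER_SD = 0.08     # lognormal sd of per-field target jitter
_GENERIC_BASE = dict(platelet=0.20, agg_share=0.40, multi_share=0.45,
                     PS=0.08, **{"P-selectin": 0.40}, fibrinogen=0.26,
                     compactness=0.5)


def _baseline(microspot: str, shear_rate: float) -> Dict[str, float]:
    regime = "high" if shear_rate >= _SHEAR_HIGH_CUTOFF else "low"
    return dict(BASELINES[regime].get(microspot, _GENERIC_BASE))


def field_targets(
    microspot: str,
    shear_rate: float,
    condition: ConditionSpec,
    donor_factor: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    jitter_sd: float = _IMAGE_JITTER_SD,
) -> Dict[str, float]:
    """Target generative fractions for one field, after condition/donor effects."""
    base = _baseline(microspot, shear_rate)
    t = dict(base)
    t["platelet"] *= condition.multiplier(shear_rate, "seeding") * donor_factor
    t["agg_share"] *= condition.multiplier(shear_rate, "aggregate")
    t["multi_share"] *= condition.multiplier(shear_rate, "multilayer")
    for ch in FLUOR_CHANNELS:
        t[ch] *= condition.multiplier(shear_rate, ch)
    if rng is not None and jitter_sd > 0:
        for key in ("platelet", "agg_share", "multi_share", *FLUOR_CHANNELS):
            t[key] *= float(rng.lognormal(0.0, jitter_sd))
    t["platelet"] = min(t["platelet"], 0.90)
    for key in ("agg_share", "multi_share", *FLUOR_CHANNELS):
        t[key] = min(t[key], 0.95)
    return t


# ---------------------------------------------------------------------------
# Geometry


def _paint_disc(mask: np.ndarray, r: float, cy: float, cx: float) -> int:
    """Rasterize a disc into ``mask``; returns the count of newly set pixels."""
    h, w = mask.shape
    y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    if y0 >= y1 or x0 >= x1:
        return 0
    yy, xx = np.ogrid[y0:y1, x0:x1]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    window = mask[y0:y1, x0:x1]
    added = int((disc & ~window).sum())
    window |= disc
    return added


def _place_aggregates(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    target_fraction: float,
    pixel_size: float,
    compactness: float,
) -> np.ndarray:
    """Clustered disc groups merged into blobs, up to a field fraction.

    Each blob is rasterized and morphologically closed inside a local window
    around its center, so cost scales with blob size, not field size.
    """
    mask = np.zeros(shape, dtype=bool)
    if target_fraction <= 0:
        return mask
    total = mask.size
    # contracted thrombi scatter their platelets less and close up more
    scatter_px = (7.0 - 5.5 * compactness) / pixel_size
    close_r = max(1, int(round((0.3 + 3.2 * compactness) / pixel_size)))
    r_max = 2.0 / pixel_size
    half = int(np.ceil(3.5 * scatter_px + r_max + 2 * close_r + 2))
    structure = _disk_structure(close_r)
    covered = 0
    guard = 0
    while covered / total < target_fraction and guard < 10_000:
        guard += 1
        cy = rng.uniform(0, shape[0])
        cx = rng.uniform(0, shape[1])
        n_discs = int(rng.integers(8, 40))
        y0, y1 = int(cy) - half, int(cy) + half + 1
        x0, x1 = int(cx) - half, int(cx) + half + 1
        win = np.zeros((y1 - y0, x1 - x0), dtype=bool)
        for _ in range(n_discs):
            dy = rng.normal(0, scatter_px)
            dx = rng.normal(0, scatter_px)
            r = rng.uniform(1.0, 2.0) / pixel_size
            _paint_disc(win, r, cy + dy - y0, cx + dx - x0)
        win = ndimage.binary_closing(win, structure=structure)
        wy0, wx0 = max(0, y0), max(0, x0)
        wy1, wx1 = min(shape[0], y1), min(shape[1], x1)
        if wy0 >= wy1 or wx0 >= wx1:
            continue
        dest = mask[wy0:wy1, wx0:wx1]
        src = win[wy0 - y0 : wy1 - y0, wx0 - x0 : wx1 - x0]
        covered += int((src & ~dest).sum())
        dest |= src
    return mask


def _disk_structure(radius: int) -> np.ndarray:
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return yy**2 + xx**2 <= radius**2


def _multilayer_core(agg_mask: np.ndarray, share: float) -> np.ndarray:
    """Inner core of each aggregate holding ~``share`` of its area.

    The core is the set of pixels deepest inside each connected component,
    selected per component at the (1 − share) quantile of the Euclidean
    distance-to-edge transform; always non-empty for share > 0.
    """
    core = np.zeros_like(agg_mask)
    if share <= 0 or not agg_mask.any():
        return core
    dist = ndimage.distance_transform_edt(agg_mask)
    labels, n = ndimage.label(agg_mask)
    for lbl, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        sel = labels[sl] == lbl
        d = dist[sl][sel]
        if d.size == 0:
            continue
        cut = np.quantile(d, max(0.0, 1.0 - share))
        comp_core = sel & (dist[sl] >= cut)
        if not comp_core.any():  # degenerate quantile: keep the deepest pixel
            comp_core = sel & (dist[sl] >= d.max())
        core[sl] |= comp_core
    return core


SINGLE_MARGIN_UM = 1.0  # clearance kept between single platelets and aggregates


def _fill_singles(
    rng: np.random.Generator,
    mask: np.ndarray,
    target_fraction: float,
    pixel_size: float,
    forbidden: Optional[np.ndarray] = None,
) -> None:
    """Scatter single platelet discs until the union reaches the target.

    Discs overlapping ``forbidden`` (the aggregate neighborhood) are
    rejected, so isolated platelets stay resolvable from aggregates.
    """
    total = mask.size
    covered = int(mask.sum())
    guard = 0
    limit = int(4 * target_fraction * total / max(1.0, np.pi * (1.5 / pixel_size) ** 2))
    while covered / total < target_fraction and guard < max(1000, limit * 6):
        guard += 1
        r = rng.uniform(1.0, 2.0) / pixel_size
        cy = rng.uniform(0, mask.shape[0])
        cx = rng.uniform(0, mask.shape[1])
        if forbidden is not None:
            y0, y1 = max(0, int(cy - r - 1)), min(mask.shape[0], int(cy + r + 2))
            x0, x1 = max(0, int(cx - r - 1)), min(mask.shape[1], int(cx + r + 2))
            if y0 >= y1 or x0 >= x1 or forbidden[y0:y1, x0:x1].any():
                continue
        covered += _paint_disc(mask, r, cy, cx)


def _channel_subset(
    rng: np.random.Generator, platelet_mask: np.ndarray, target_count: int
) -> np.ndarray:
    """Blobby subset of the platelet mask with an exact pixel count.

    Pixels are ranked by a smoothed random field so positives form spatially
    coherent patches, as staining does, rather than salt-and-pepper pixels.
    """
    out = np.zeros_like(platelet_mask)
    n_avail = int(platelet_mask.sum())
    if target_count <= 0 or n_avail == 0:
        return out
    target_count = min(target_count, n_avail)
    score = ndimage.gaussian_filter(rng.standard_normal(platelet_mask.shape), 8.0)
    vals = score[platelet_mask]
    cut = np.partition(vals, n_avail - target_count)[n_avail - target_count]
    chosen = platelet_mask & (score >= cut)
    # ties at the cut can overshoot by a handful of pixels; trim arbitrarily
    excess = int(chosen.sum()) - target_count
    if excess > 0:
        idx = np.flatnonzero(chosen.ravel() & (score.ravel() == cut))[:excess]
        chosen.ravel()[idx] = False
    out |= chosen
    return out


def sample_ground_truth(
    rng: np.random.Generator,
    targets: Mapping[str, float],
    field_size: Tuple[int, int] = (1024, 1360),
    pixel_size: float = 0.2,
    rubric=None,
) -> GroundTruth:
    """Synthesize one field's masks from target fractions.

    Realized (pixel-counted) fractions are stored as the truth; they land
    within one percentage point of the requested targets because coverage is
    grown one object at a time.
    """
    if targets["platelet"] > 1.0:
        raise GenerationError("requested platelet coverage exceeds 100%")
    shape = tuple(field_size)
    platelet_target = float(targets["platelet"])
    agg_target = platelet_target * float(targets["agg_share"])

    agg_mask = _place_aggregates(
        rng, shape, agg_target, pixel_size, float(targets.get("compactness", 0.5))
    )
    multilayer_mask = _multilayer_core(agg_mask, float(targets["multi_share"]))
    platelet_mask = agg_mask.copy()
    margin_px = max(1, int(round(SINGLE_MARGIN_UM / pixel_size)))
    forbidden = (
        ndimage.binary_dilation(agg_mask, _disk_structure(margin_px))
        if agg_mask.any()
        else None
    )
    _fill_singles(rng, platelet_mask, platelet_target, pixel_size, forbidden)

    n_platelet_px = int(platelet_mask.sum())
    channel_masks = {}
    for ch in FLUOR_CHANNELS:
        want = int(round(float(targets[ch]) * n_platelet_px))
        channel_masks[ch] = _channel_subset(rng, platelet_mask, want)

    total = platelet_mask.size
    object_table = _object_table(platelet_mask, multilayer_mask, pixel_size)
    truth = GroundTruth(
        true_platelet_fraction=n_platelet_px / total,
        true_aggregate_fraction=float(agg_mask.sum()) / total,
        true_multilayer_fraction_of_platelet=(
            float(multilayer_mask.sum()) / n_platelet_px if n_platelet_px else 0.0
        ),
        true_channel_fraction={
            ch: float(m.sum()) / total for ch, m in channel_masks.items()
        },
        object_table=object_table,
        intended_scores=(0, 0, 0),
        platelet_mask=platelet_mask,
        aggregate_mask=agg_mask,
        multilayer_mask=multilayer_mask,
        channel_masks=channel_masks,
        pixel_size=pixel_size,
    )
    truth.validate()
    truth.intended_scores = _intended_scores(truth, rubric)
    return truth


def _object_table(
    platelet_mask: np.ndarray, multilayer_mask: np.ndarray, pixel_size: float
) -> pd.DataFrame:
    from skimage import measure

    labels = measure.label(platelet_mask, connectivity=2)
    n = int(labels.max())
    ml_counts = ndimage.sum_labels(
        multilayer_mask.astype(np.int64), labels, index=np.arange(1, n + 1)
    ) if n else np.zeros(0)
    rows = []
    for prop in measure.regionprops(labels):
        rows.append(
            dict(
                centroid_row=prop.centroid[0],
                centroid_col=prop.centroid[1],
                equivalent_radius_um=prop.equivalent_diameter_area / 2 * pixel_size,
                layer_count=2 if ml_counts[prop.label - 1] > 0 else 1,
                solidity=prop.solidity,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "centroid_row",
            "centroid_col",
            "equivalent_radius_um",
            "layer_count",
            "solidity",
        ],
    )


def _intended_scores(truth: GroundTruth, rubric=None) -> Tuple[int, int, int]:
    """Score tiers implied by the true masks, via the default scoring rubric."""
    from .scoring import extract_features, score_image, RubricConfig

    rubric = rubric or RubricConfig()
    feats = extract_features(
        truth.platelet_mask,
        truth.aggregate_mask,
        truth.multilayer_mask,
        truth.pixel_size,
    )
    triple = score_image(feats, 100.0 * truth.true_platelet_fraction, rubric)
    return (triple.morphology, triple.multilayer, triple.contraction)


# ---------------------------------------------------------------------------
# Rendering


def _illumination(shape: Tuple[int, int]) -> np.ndarray:
    w = shape[1]
    ramp = np.linspace(-ILLUMINATION_AMPLITUDE, ILLUMINATION_AMPLITUDE, w)
    return 1.0 + np.broadcast_to(ramp, shape)


def render_brightfield(
    truth: GroundTruth,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> IntensityImage:
    """Brightfield image: bright background, darker platelets, darkest multilayer."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    level = (
        MONOLAYER_DEPTH * truth.platelet_mask.astype(np.float64)
        + MULTILAYER_EXTRA_DEPTH * truth.multilayer_mask.astype(np.float64)
    )
    level = ndimage.gaussian_filter(level, EDGE_SIGMA_PX)
    img = BRIGHTFIELD_BACKGROUND * _illumination(level.shape) - level
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    np.clip(img, 0.0, 65535.0, out=img)
    return IntensityImage(pixels=img, channel=BRIGHTFIELD, pixel_size=truth.pixel_size)


def render_fluorescence(
    truth: GroundTruth,
    channel: str,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> IntensityImage:
    """Fluorescence image: dark background, bright channel-positive regions."""
    if channel not in FLUOR_CHANNELS:
        raise ValueError(f"unknown fluorescence channel {channel!r}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    level = FLUOR_POSITIVE * truth.channel_masks[channel].astype(np.float64)
    level = ndimage.gaussian_filter(level, EDGE_SIGMA_PX)
    img = FLUOR_BACKGROUND * _illumination(level.shape) + level
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    np.clip(img, 0.0, 65535.0, out=img)
    return IntensityImage(pixels=img, channel=channel, pixel_size=truth.pixel_size)


# ---------------------------------------------------------------------------
# Whole experiments


def generate_experiment(design: ExperimentDesign) -> List[FlowRun]:
    """Generate every (donor, condition, microspot, shear, run) image set.

    Deterministic in ``design.seed``; the donor lognormal effect is drawn once
    per (donor, condition) and shared across that donor's runs, microspots
    and shear rates.
    """
    root = np.random.SeedSequence(design.seed)
    donor_names = [f"donor{d + 1}" for d in range(design.donors)]
    donor_rng = np.random.default_rng(root.spawn(1)[0])
    # one blood sample per donor: the donor effect is shared across all of
    # that donor's conditions/runs, so it cancels in paired comparisons
    donor_sd = design.conditions[0].donor_sd
    donor_factors = {
        donor: float(donor_rng.lognormal(0.0, donor_sd)) for donor in donor_names
    }

    runs: List[FlowRun] = []
    unit_seeds = iter(root.spawn(
        design.donors
        * len(design.conditions)
        * len(design.microspots)
        * len(design.shear_rates)
        * design.duplicate_runs_per_condition
    ))
    for donor in donor_names:
        for cond in design.conditions:
            for microspot in design.microspots:
                for shear in design.shear_rates:
                    for run_idx in range(design.duplicate_runs_per_condition):
                        rng = np.random.default_rng(next(unit_seeds))
                        meta = RunMetadata(
                            donor=donor,
                            condition=cond.name,
                            microspot=microspot,
                            shear_rate=float(shear),
                            run_id=f"run{run_idx + 1}",
                        )
                        runs.append(
                            _generate_run(design, meta, cond, donor_factors, rng)
                        )
    return runs


def _generate_run(
    design: ExperimentDesign,
    meta: RunMetadata,
    cond: ConditionSpec,
    donor_factors: Mapping[str, float],
    rng: np.random.Generator,
) -> FlowRun:
    donor_factor = donor_factors[meta.donor]
    fields: List[FieldImages] = []
    for i in range(design.images_per_run_brightfield):
        targets = field_targets(
            meta.microspot, meta.shear_rate, cond, donor_factor, rng
        )
        truth = sample_ground_truth(
            rng, targets, design.field_size, design.pixel_size
        )
        img = render_brightfield(truth, noise_sd=cond.noise_sd, rng=rng)
        fields.append(
            FieldImages(role="brightfield", index=i, images={BRIGHTFIELD: img}, truth=truth)
        )
    for i in range(design.images_per_run_fluorescence):
        targets = field_targets(
            meta.microspot, meta.shear_rate, cond, donor_factor, rng
        )
        truth = sample_ground_truth(
            rng, targets, design.field_size, design.pixel_size
        )
        images = {
            ch: render_fluorescence(truth, ch, noise_sd=cond.noise_sd, rng=rng)
            for ch in FLUOR_CHANNELS
        }
        fields.append(
            FieldImages(role="fluorescence", index=i, images=images, truth=truth)
        )
    return FlowRun(metadata=meta, fields=fields)


def write_experiment(runs: Iterable[FlowRun], outdir: Path | str) -> pd.DataFrame:
    """Write TIFFs plus metadata and ground-truth CSVs; returns the metadata table."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    meta_rows = []
    truth_rows = []
    for run in runs:
        m = run.metadata
        stem = "_".join(
            [m.donor, m.condition, m.microspot, f"{m.shear_rate:g}s", m.run_id]
        ).replace(" ", "-")
        for fi in run.fields:
            for ch, img in fi.images.items():
                fname = f"{stem}_{fi.role}{fi.index + 1}_{ch}.tif".replace(" ", "-")
                path = outdir / "images" / fname
                tifffile.imwrite(
                    path, np.round(img.pixels).astype(np.uint16)
                )
                meta_rows.append(
                    dict(
                        donor=m.donor,
                        condition=m.condition,
                        microspot=m.microspot,
                        **{"shear_s-1": m.shear_rate},
                        run=m.run_id,
                        image_role=fi.role,
                        image_index=fi.index + 1,
                        channel=ch,
                        path=str(Path("images") / fname),
                    )
                )
            t = fi.truth
            truth_rows.append(
                dict(
                    donor=m.donor,
                    condition=m.condition,
                    microspot=m.microspot,
                    **{"shear_s-1": m.shear_rate},
                    run=m.run_id,
                    image_role=fi.role,
                    image_index=fi.index + 1,
                    true_platelet_fraction=t.true_platelet_fraction,
                    true_aggregate_fraction=t.true_aggregate_fraction,
                    true_multilayer_fraction_of_platelet=t.true_multilayer_fraction_of_platelet,
                    **{
                        f"true_fraction_{ch}": t.true_channel_fraction[ch]
                        for ch in FLUOR_CHANNELS
                    },
                    intended_morphology=t.intended_scores[0],
                    intended_multilayer=t.intended_scores[1],
                    intended_contraction=t.intended_scores[2],
                )
            )
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(outdir / "metadata.csv", index=False, quoting=csv.QUOTE_MINIMAL)
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
    return meta
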