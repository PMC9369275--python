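"""Discrete thrombus phenotype scores from measurable image features.

The assay scores each brightfield field on three ordinal scales — thrombus
morphology P3 (0–5), multilayer P4 (0–3) and contraction P5 (0–3), from
0,0,0 (essential absence of platelets) to 5,3,3 (large contracted,
multilayered aggregates).  The original procedure compares fields visually
against a preset of reference images; here the comparison is replaced by a
deterministic rubric over morphological features, so a score depends only on
pixels.  All cut-points live in :class:`RubricConfig` and are exposed in the
pipeline configuration; the defaults are calibrated against the synthetic
generator's intended score tiers.

Tier assignment uses half-open intervals: a feature exactly at a cut-point
takes the higher tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .metrics import BinaryMask

__all__ = [
    "MorphologyFeatures",
    "ScoreTriple",
    "RubricConfig",
    "RubricError",
    "extract_features",
    "score_image",
]


class RubricError(ValueError):
    """Invalid rubric configuration (e.g. non-monotone cut-points)."""


@dataclass(frozen=True)
class MorphologyFeatures:
    """Feature basis for the scoring rubric, from one brightfield field."""

    n_objects: int                       # connected platelet components
    largest_object_area: float           # µm², over all platelet components
    aggregate_area_fraction: float       # aggregate area / platelet area
    multilayer_area_fraction: float      # multilayer-tier area / platelet area
    mean_solidity_large: Optional[float] # mean solidity of aggregate
                                         # components; None when there are none

    def __post_init__(self) -> None:
        for name in ("aggregate_area_fraction", "multilayer_area_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 + 1e-9):
                raise ValueError(f"{name}={v} outside [0, 1]")
        s = self.mean_solidity_large
        if s is not None and not (0.0 < s <= 1.0 + 1e-9):
            raise ValueError(f"mean_solidity_large={s} outside (0, 1]")


@dataclass(frozen=True)
class ScoreTriple:
    morphology: int   # P3, 0–5
    multilayer: int   # P4, 0–3
    contraction: int  # P5, 0–3

    def __post_init__(self) -> None:
        if not (0 <= self.morphology <= 5):
            raise ValueError("morphology score outside 0–5")
        if not (0 <= self.multilayer <= 3 and 0 <= self.contraction <= 3):
            raise ValueError("multilayer/contraction score outside 0–3")

    def as_tuple(self) -> Tuple[int, int, int]:
        return (self.morphology, self.multilayer, self.contraction)


@dataclass(frozen=True)
class RubricConfig:
    """Cut-points of the deterministic scoring rubric.

    ``p1_floor`` (% SAC) defines "essential absence of platelets": below it
    the triple is 0,0,0.  Morphology climbs one tier for each satisfied
    condition — aggregates present, large aggregates, substantial multilayer,
    contracted aggregates.  Multilayer and contraction tiers come from
    cut-point ladders on the multilayer area fraction and on the mean
    solidity of aggregate components.
    """

    p1_floor: float = 0.5                 # % SAC
    small_aggregate_area: float = 50.0    # µm²; morphology tier 2
    large_aggregate_area: float = 400.0   # µm²; morphology tier 3
    morphology_multilayer_cut: float = 0.15  # tier 4
    morphology_solidity_cut: float = 0.80    # tier 5
    multilayer_cuts: Tuple[float, float, float] = (0.04, 0.15, 0.25)
    contraction_cuts: Tuple[float, float, float] = (0.60, 0.70, 0.80)

    def __post_init__(self) -> None:
        if self.p1_floor < 0:
            raise RubricError("p1_floor must be non-negative")
        if not self.small_aggregate_area < self.large_aggregate_area:
            raise RubricError("aggregate area cut-points must increase")
        for name in ("multilayer_cuts", "contraction_cuts"):
            cuts = getattr(self, name)
            if len(cuts) != 3 or any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise RubricError(f"{name} must be three strictly increasing values")
        if not all(0 < c <= 1 for c in self.contraction_cuts):
            raise RubricError("contraction cuts are solidities in (0, 1]")


def _as_bool(mask: BinaryMask | np.ndarray) -> np.ndarray:
    return mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)


def extract_features(
    platelet_mask: BinaryMask | np.ndarray,
    aggregate_mask: BinaryMask | np.ndarray,
    multilayer_mask: BinaryMask | np.ndarray,
    pixel_size: float,
    min_aggregate_area: float = 20.0,
) -> MorphologyFeatures:
    """Morphological feature set from the segmentation masks of one field.

    Aggregate-derived features (area fraction, solidity) consider only
    connected aggregate components above ``min_aggregate_area`` (µm²), and
    the solidity average is area-weighted; both choices keep the feature
    stable against populations of tiny fragments.
    """
    platelets = _as_bool(platelet_mask)
    aggregates = _as_bool(aggregate_mask)
    multilayer = _as_bool(multilayer_mask)
    if platelets.shape != aggregates.shape or platelets.shape != multilayer.shape:
        raise ValueError("mask shapes differ")

    px_area = pixel_size**2
    n_platelet = int(platelets.sum())
    if n_platelet == 0:
        return MorphologyFeatures(0, 0.0, 0.0, 0.0, None)

    labels, n_obj = ndimage.label(platelets)
    areas = ndimage.sum_labels(platelets, labels, index=np.arange(1, n_obj + 1))
    largest = float(areas.max()) * px_area if n_obj else 0.0

    min_area_px = min_aggregate_area / px_area
    solidity: Optional[float] = None
    agg_px_large = 0
    if aggregates.any():
        props = [
            p
            for p in measure.regionprops(measure.label(aggregates, connectivity=2))
            if p.area >= min_area_px
        ]
        if props:
            agg_px_large = int(sum(p.area for p in props))
            solidity = float(
                np.average(
                    [p.solidity for p in props], weights=[p.area for p in props]
                )
            )
    agg_fraction = agg_px_large / n_platelet
    ml_fraction = float((multilayer & platelets).sum()) / n_platelet

    return MorphologyFeatures(
        n_objects=int(n_obj),
        largest_object_area=largest,
        aggregate_area_fraction=agg_fraction,
        multilayer_area_fraction=ml_fraction,
        mean_solidity_large=solidity,
    )


def _tier(value: float, cuts: Sequence[float]) -> int:
    return int(sum(value >= c for c in cuts))


def score_image(
    features: MorphologyFeatures, p1: float, rubric: RubricConfig = RubricConfig()
) -> ScoreTriple:
    """Assign the P3/P4/P5 score triple for one field.

    Every rule is monotone non-decreasing in each feature, so improving any
    single feature can never lower a score.
    """
    if p1 < rubric.p1_floor:
        return ScoreTriple(0, 0, 0)

    has_aggregates = features.aggregate_area_fraction > 0
    solidity = features.mean_solidity_large

    morphology = 1
    morphology += int(
        has_aggregates and features.largest_object_area >= rubric.small_aggregate_area
    )
    morphology += int(
        has_aggregates and features.largest_object_area >= rubric.large_aggregate_area
    )
    morphology += int(
        features.multilayer_area_fraction >= rubric.morphology_multilayer_cut
    )
    morphology += int(
        has_aggregates
        and solidity is not None
        and solidity >= rubric.morphology_solidity_cut
    )

    multilayer = (
        _tier(features.multilayer_area_fraction, rubric.multilayer_cuts)
        if has_aggregates
        else 0
    )
    contraction = (
        _tier(solidity, rubric.contraction_cuts)
        if has_aggregates and solidity is not None
        else 0
    )
    return ScoreTriple(min(morphology, 5), multilayer, contraction)
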