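"""End-to-end pipeline: images + metadata in, tables and figures out.

Ties segmentation, scoring and statistics together behind one configuration
object.  Every output CSV is accompanied by a provenance record (config hash,
seed, library versions) so results can be traced to the exact settings that
produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .metrics import (
    BRIGHTFIELD,
    CHANNEL_PARAMETER,
    IntensityImage,
    PARAMETERS,
    SegmentationConfig,
    measure_brightfield,
    sac_percent,
    segment_fluor_positive,
)
from .scoring import RubricConfig, extract_features, score_image
from .stats import (
    average_images_to_run,
    average_runs_to_donor,
    plot_cumulative,
    plot_heatmap,
    scaled_matrix,
    subtraction_heatmap,
)

logger = logging.getLogger("thromboquant")

__all__ = [
    "PipelineConfig",
    "InputError",
    "ConfigurationError",
    "run_pipeline",
    "measure_images",
    "load_config",
    "config_hash",
]


class InputError(ValueError):
    """Bad or missing input data (exit code 1 at the CLI)."""


class ConfigurationError(ValueError):
    """Invalid configuration (exit code 2 at the CLI)."""


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    rubric: RubricConfig = field(default_factory=RubricConfig)
    scaling_mode: str = "dataset"        # "dataset" | "fixed"
    pooled_scaling: bool = False
    significance_threshold: float = 0.05
    p_adjust: Optional[str] = None       # None | "bh"
    control_condition: str = "control"
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0.0 < self.significance_threshold < 1.0):
            raise ConfigurationError("significance threshold must lie in (0, 1)")
        if self.scaling_mode not in ("dataset", "fixed"):
            raise ConfigurationError(f"unknown scaling mode {self.scaling_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        try:
            if "segmentation" in d:
                d["segmentation"] = SegmentationConfig(**d["segmentation"])
            if "rubric" in d:
                rub = dict(d["rubric"])
                for key in ("multilayer_cuts", "contraction_cuts"):
                    if key in rub:
                        rub[key] = tuple(rub[key])
                d["rubric"] = RubricConfig(**rub)
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(str(exc)) from exc


def load_config(path: Path | str) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)


def config_hash(config: PipelineConfig) -> str:
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _read_image(path: Path, channel: str, pixel_size: float) -> IntensityImage:
    return IntensityImage(
        pixels=tifffile.imread(path).astype(np.float64),
        channel=channel,
        pixel_size=pixel_size,
    )


def measure_images(
    metadata: pd.DataFrame,
    image_dir: Path | str,
    config: PipelineConfig,
    pixel_size: float = 0.2,
) -> pd.DataFrame:
    """Measure P1–P8 for every image referenced by the metadata table.

    Brightfield rows yield P1, P2 and the score triple P3–P5; fluorescence
    rows yield the channel's coverage parameter.  Returns one row per
    (run, image_role, image_index) with the run key, parameters, and the
    thresholds/settings used.
    """
    image_dir = Path(image_dir)
    required = {"donor", "condition", "microspot", "shear_s-1", "run",
                "image_role", "image_index", "channel", "path"}
    missing_cols = required - set(metadata.columns)
    if missing_cols:
        raise InputError(f"metadata lacks columns: {sorted(missing_cols)}")
    if metadata.empty:
        raise InputError("metadata table is empty")
    missing = [
        str(p) for p in metadata["path"] if not (image_dir / str(p)).is_file()
    ]
    if missing:
        raise InputError("missing image files:\n" + "\n".join(sorted(missing)))

    seg = config.segmentation
    rows: List[dict] = []
    group_cols = ["donor", "condition", "microspot", "shear_s-1", "run",
                  "image_role", "image_index"]
    for key, grp in metadata.groupby(group_cols, sort=True):
        donor, condition, microspot, shear, run, role, idx = key
        row = dict(
            donor=donor,
            condition=condition,
            microspot=microspot,
            shear_rate=float(shear),
            run_id=run,
            image_role=role,
            image_index=idx,
            **{p: np.nan for p in PARAMETERS},
        )
        if role == "brightfield":
            (rec,) = grp.to_dict("records")
            img = _read_image(image_dir / rec["path"], BRIGHTFIELD, pixel_size)
            ps, platelets, aggregates = measure_brightfield(img, seg)
            feats = extract_features(
                platelets, aggregates.aggregate_mask,
                aggregates.multilayer_mask, pixel_size,
                min_aggregate_area=seg.min_aggregate_area,
            )
            triple = score_image(feats, ps.P1, config.rubric)
            row.update(
                P1=ps.P1, P2=ps.P2,
                P3=float(triple.morphology),
                P4=float(triple.multilayer),
                P5=float(triple.contraction),
                multilayer_threshold=aggregates.multilayer_threshold,
            )
        elif role == "fluorescence":
            for rec in grp.to_dict("records"):
                ch = rec["channel"]
                if ch not in CHANNEL_PARAMETER:
                    raise InputError(f"unknown fluorescence channel {ch!r}")
                img = _read_image(image_dir / rec["path"], ch, pixel_size)
                row[CHANNEL_PARAMETER[ch]] = sac_percent(
                    segment_fluor_positive(img, seg)
                )
        else:
            raise InputError(f"unknown image_role {role!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def measure_runs(runs, config: PipelineConfig) -> pd.DataFrame:
    """Measure P1–P8 for in-memory synthetic runs (no TIFF round-trip).

    Same output schema as :func:`measure_images`; used by simulation studies
    and tests where writing images to disk is pointless.
    """
    seg = config.segmentation
    rows: List[dict] = []
    for run in runs:
        m = run.metadata
        for fi in run.fields:
            row = dict(
                donor=m.donor,
                condition=m.condition,
                microspot=m.microspot,
                shear_rate=m.shear_rate,
                run_id=m.run_id,
                image_role=fi.role,
                image_index=fi.index + 1,
                **{p: np.nan for p in PARAMETERS},
            )
            if fi.role == "brightfield":
                img = fi.images[BRIGHTFIELD]
                ps, platelets, aggregates = measure_brightfield(img, seg)
                feats = extract_features(
                    platelets, aggregates.aggregate_mask,
                    aggregates.multilayer_mask, img.pixel_size,
                    min_aggregate_area=seg.min_aggregate_area,
                )
                triple = score_image(feats, ps.P1, config.rubric)
                row.update(
                    P1=ps.P1, P2=ps.P2,
                    P3=float(triple.morphology),
                    P4=float(triple.multilayer),
                    P5=float(triple.contraction),
                )
            else:
                for ch, img in fi.images.items():
                    row[CHANNEL_PARAMETER[ch]] = sac_percent(
                        segment_fluor_positive(img, seg)
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    metadata: pd.DataFrame | Path | str,
    image_dir: Path | str,
    config: PipelineConfig,
    outdir: Path | str,
    pixel_size: float = 0.2,
) -> Dict[str, pd.DataFrame]:
    """Full analysis: per-image measurement → donor summaries → heatmaps.

    Writes per_image.csv, per_run.csv, donor_summary.csv, scaled_matrix.csv,
    heatmap.csv, figures, and provenance.json under ``outdir``.  Fails before
    writing anything if inputs are invalid (missing images, absent control).
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata)
    if metadata.empty:
        raise InputError("metadata table is empty")
    if config.control_condition not in set(metadata["condition"]):
        raise InputError(
            f"control condition {config.control_condition!r} absent from metadata"
        )

    per_image = measure_images(metadata, image_dir, config, pixel_size)
    per_run = average_images_to_run(per_image)
    donor_summary = average_runs_to_donor(per_run)
    sm = scaled_matrix(
        donor_summary, mode=config.scaling_mode, pooled=config.pooled_scaling
    )
    heatmap = subtraction_heatmap(
        donor_summary,
        control=config.control_condition,
        mode=config.scaling_mode,
        alpha=config.significance_threshold,
        adjust=config.p_adjust,
        pooled=config.pooled_scaling,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    tables = {
        "per_image": per_image,
        "per_run": per_run,
        "donor_summary": donor_summary,
        "scaled_matrix": sm.entries,
        "scaling_frames": sm.frames,
        "heatmap": heatmap,
    }
    for name, df in tables.items():
        df = df.copy()
        df.insert(0, "config_hash", chash)
        df.to_csv(outdir / f"{name}.csv", index=False)
    plot_heatmap(heatmap, outdir / "heatmap.png")
    plot_cumulative(sm, outdir / "cumulative.png")

    provenance = dict(
        config_hash=chash,
        config=config.to_dict(),
        seed=config.seed,
        package_version=__version__,
        versions={
            mod.__name__: mod.__version__
            for mod in _version_modules()
        },
    )
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return tables


def _version_modules():
    import numpy, pandas, scipy, skimage

    return (numpy, scipy, pandas, skimage)
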