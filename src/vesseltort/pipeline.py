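"""End-to-end orchestration: mask file(s) -> feature tables -> grading.

The :class:`PipelineConfig` gathers every tunable of the preprocessing,
metric and classification stages so a whole run is reproducible from one
serializable object; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classify import ClassifierConfig
from .features import aggregate_image_features, image_table, segment_table
from .metrics import MetricConfig, compute_record
from .preprocess import (EmptyMaskError, VesselMask, VesselSegment,
                         prune_spurs, segment_skeleton, skeletonize)

__all__ = ["PipelineConfig", "load_mask", "process_mask", "process_masks",
           "segments_from_csv", "segments_to_csv", "process_segment_table"]

log = logging.getLogger("vesseltort")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of a full run (logged with every run)."""

    min_segment_points: int = 5
    max_spur_length: int = 5
    junction_radius: float = 2.0
    pixel_spacing: float = 1.0
    metrics: MetricConfig = field(default_factory=MetricConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "metrics" in d and isinstance(d["metrics"], dict):
            d["metrics"] = MetricConfig(**d["metrics"])
        if "classifier" in d and isinstance(d["classifier"], dict):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_mask(path, pixel_spacing: float = 1.0) -> VesselMask:
    """Read a PNG/TIFF raster; any nonzero pixel is vessel."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:                       # collapse color/alpha channels
        arr = arr[..., :3].max(axis=-1)
    return VesselMask(pixels=arr > 0, pixel_spacing=pixel_spacing)


def process_mask(mask: VesselMask, image_id: str,
                 config: PipelineConfig = PipelineConfig()):
    """Mask -> (segment records, image feature record, extraction result)."""
    skel = skeletonize(mask)
    skel = prune_spurs(skel, config.max_spur_length)
    result = segment_skeleton(skel, min_segment_points=config.min_segment_points,
                              junction_radius=config.junction_radius,
                              image_id=image_id)
    log.info("image %s: %d segments kept, %d junction px, %d discarded px",
             image_id, len(result.segments), len(result.junction_pixels),
             len(result.discarded_pixels))
    records = [compute_record(seg, config.metrics, image_id=image_id,
                              segment_id=seg.segment_id)
               for seg in result.segments]
    seg_df = pd.DataFrame([r.as_dict() for r in records])
    image_rec = aggregate_image_features(seg_df, image_id) if records else None
    return records, image_rec, result


def process_masks(paths, config: PipelineConfig = PipelineConfig()):
    """Batch mask processing; per-file failures are collected, not fatal.

    Returns (segment_features, image_features, errors) where errors maps
    the failing path to the exception message.
    """
    all_records, image_rows, errors = [], [], {}
    for path in paths:
        image_id = Path(path).stem
        try:
            mask = load_mask(path, config.pixel_spacing)
            records, image_rec, _ = process_mask(mask, image_id, config)
            if image_rec is None:
                raise EmptyMaskError("no segments survived extraction")
        except Exception as exc:            # noqa: BLE001 — batch keeps going
            log.error("image %s failed: %s", image_id, exc)
            errors[str(path)] = str(exc)
            continue
        all_records.extend(records)
        image_rows.append(image_rec)
    seg_df = segment_table(all_records) if all_records else pd.DataFrame(
        columns=["image_id", "segment_id"])
    img_df = image_table(image_rows) if image_rows else pd.DataFrame(
        columns=["image_id", "n_segments"])
    return seg_df, img_df, errors


def segments_to_csv(segments: list[VesselSegment], path) -> None:
    """Ordered centerline points as CSV (image_id, segment_id, point_index, row, col)."""
    rows = []
    for seg in segments:
        for i, (r, c) in enumerate(seg.points):
            rows.append((seg.image_id, seg.segment_id, i, int(r), int(c)))
    pd.DataFrame(rows, columns=["image_id", "segment_id", "point_index",
                                "row", "col"]).to_csv(path, index=False)


def segments_from_csv(path, pixel_spacing: float = 1.0) -> list[VesselSegment]:
    df = pd.read_csv(path)
    need = {"image_id", "segment_id", "point_index", "row", "col"}
    if not need <= set(df.columns):
        raise ValueError(f"segment CSV needs columns {sorted(need)}")
    out = []
    for (img, sid), grp in df.groupby(["image_id", "segment_id"], sort=True):
        grp = grp.sort_values("point_index")
        out.append(VesselSegment(segment_id=int(sid), image_id=str(img),
                                 points=grp[["row", "col"]].to_numpy(),
                                 pixel_spacing=pixel_spacing))
    return out


def process_segment_table(segments: list[VesselSegment],
                          config: PipelineConfig = PipelineConfig()):
    """Point-list segments -> (segment_features, image_features)."""
    records = [compute_record(seg, config.metrics) for seg in segments]
    seg_df = segment_table(records)
    image_rows = [aggregate_image_features(seg_df, img)
                  for img in seg_df["image_id"].unique()]
    return seg_df, image_table(image_rows)
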