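"""Two-level tortuosity feature tables and their CSV interfaces.

Segment level: one row per vessel fragment with the fourteen tortuosity
measures and the curvature summaries, laid out in the conventional
column order (image, segment, A/V flag, Arc, Chord, DM, SOAM, ICMn,
ICMb, SDavc, Navc, tau1..tau7) plus the supporting td/df/inflection
columns.  Image level: per image, the number of segments and the
average / minimum / maximum of each measure.  Severity labels are a
separate (image_id, grade) table with ordinal grades 1..4
(normal, mild, moderate, severe).

Degenerate metric values are explicit (NaN in memory, empty CSV field)
and are excluded from the image-level aggregates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES, TortuosityRecord

__all__ = [
    "SEGMENT_COLUMNS",
    "GRADE_NAMES",
    "segment_table",
    "image_table",
    "aggregate_image_features",
    "join_labels",
    "write_segment_csv",
    "read_segment_csv",
    "write_image_csv",
    "read_image_csv",
    "write_labels_csv",
    "read_labels_csv",
]

#: Table-1-style column order; icm_n is the ICM of Eq.-14 form and icm_b
#: duplicates it (no A/V-specific variant is configured by default)
SEGMENT_COLUMNS = [
    "image_id", "segment_id", "av_class", "arc", "chord", "dm", "soam",
    "icm_n", "icm_b", "sd_avc", "n_avc",
    "tau1", "tau2", "tau3", "tau4", "tau5", "tau6", "tau7",
    "td", "df", "inflection_count", "flags",
]

GRADE_NAMES = {1: "normal", 2: "mild", 3: "moderate", 4: "severe"}


def segment_table(records: list[TortuosityRecord] | pd.DataFrame) -> pd.DataFrame:
    """Segment-level feature table; (image_id, segment_id) must be unique."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.as_dict() for r in records])
    if "icm_n" not in df.columns:
        df["icm_n"] = df["icm"]
        df["icm_b"] = df["icm"]
    if df.duplicated(subset=["image_id", "segment_id"]).any():
        dupes = df[df.duplicated(subset=["image_id", "segment_id"])]
        raise ValueError("duplicate (image_id, segment_id) keys: "
                         f"{dupes[['image_id', 'segment_id']].values.tolist()}")
    return df[SEGMENT_COLUMNS]


def aggregate_image_features(segments: pd.DataFrame, image_id: str) -> dict:
    """Image-level record: n_segments + avg/min/max per metric.

    Degenerate (flagged NaN) values are excluded metric-by-metric; a
    metric whose every value is flagged aggregates to NaN.  Raises on an
    image with no segment rows.
    """
    rows = segments[segments["image_id"] == image_id]
    if len(rows) == 0:
        raise ValueError(f"image {image_id!r} has no segment rows")
    out = {"image_id": image_id, "n_segments": int(len(rows))}
    for name in METRIC_NAMES:
        col = "icm_n" if (name == "icm" and "icm" not in rows) else name
        vals = pd.to_numeric(rows[col], errors="coerce").dropna().to_numpy()
        if len(vals):
            vals = np.sort(vals)    # canonical order: exactly permutation-invariant
            out[f"{name}_avg"] = float(vals.mean())
            out[f"{name}_min"] = float(vals[0])
            out[f"{name}_max"] = float(vals[-1])
        else:
            out[f"{name}_avg"] = out[f"{name}_min"] = out[f"{name}_max"] = np.nan
    return out


def image_table(records: list[dict]) -> pd.DataFrame:
    """Stack image-level records into the image feature table."""
    df = pd.DataFrame(records)
    cols = ["image_id", "n_segments"] + [
        f"{m}_{s}" for m in METRIC_NAMES for s in ("avg", "min", "max")]
    return df[cols]


def join_labels(images: pd.DataFrame, labels: pd.DataFrame,
                strict: bool = True) -> pd.DataFrame:
    """Inner-join image features with severity labels on image_id.

    With ``strict`` every image must be labeled; duplicate labels are
    always an error naming the offending image.
    """
    if labels.duplicated(subset=["image_id"]).any():
        bad = labels[labels.duplicated(subset=["image_id"])]["image_id"].tolist()
        raise ValueError(f"duplicate severity labels for image(s): {bad}")
    if not labels["grade"].isin([1, 2, 3, 4]).all():
        bad = sorted(set(labels["grade"]) - {1, 2, 3, 4})
        raise ValueError(f"severity grades must be in 1..4, got {bad}")
    missing = sorted(set(images["image_id"]) - set(labels["image_id"]))
    if missing and strict:
        raise ValueError(f"unlabeled image(s): {missing}")
    merged = images.merge(labels[["image_id", "grade"]], on="image_id",
                          how="inner")
    return merged.sort_values("image_id", kind="stable").reset_index(drop=True)


def write_segment_csv(df: pd.DataFrame, path) -> None:
    segment_table(df).to_csv(path, index=False, float_format="%.17g")


def read_segment_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True, float_precision="round_trip")
    df["flags"] = df.get("flags", pd.Series(dtype=str)).fillna("")
    return df


def write_image_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_image_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_labels_csv(df: pd.DataFrame, path) -> None:
    df[["image_id", "grade"]].to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"image_id", "grade"} <= set(df.columns):
        raise ValueError("labels CSV needs image_id and grade columns")
    return df
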