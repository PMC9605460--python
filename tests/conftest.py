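"""Shared fixtures: analytic curves, raster fixtures, labeled datasets."""

import math

import numpy as np
import pytest
import scipy.integrate as si

from vesseltort.metrics import MetricConfig, compute_record
from vesseltort.preprocess import extract_segments, prune_spurs, skeletonize
from vesseltort.synthetic import CurveSpec, rasterize, sample_curve


def sine_quadrature_truth(a: float, w: float, span: float) -> dict:
    """Independent quadrature oracle for a sine curve (no metrics code)."""
    ds = lambda u: math.hypot(1.0, a * w * math.cos(w * u))
    curv = lambda u: (-a * w * w * math.sin(w * u)
                      / (1 + (a * w * math.cos(w * u)) ** 2) ** 1.5)
    arc = si.quad(ds, 0, span, limit=400)[0]
    tau2 = si.quad(lambda u: curv(u) * ds(u), 0, span, limit=400)[0]
    tau3 = si.quad(lambda u: curv(u) ** 2 * ds(u), 0, span, limit=400)[0]
    soam = math.degrees(
        si.quad(lambda u: abs(curv(u)) * ds(u), 0, span, limit=400)[0]) / arc
    chord = math.hypot(span, a * math.sin(w * span))
    return {"arc": arc, "chord": chord, "dm": arc / chord, "tau2": tau2,
            "tau3": tau3, "soam": soam}


def raster_segment(points, shape, offset, thickness=3, max_spur_length=5):
    """Rasterize a polyline and recover its longest centerline segment."""
    mask = rasterize(points, shape=shape, offset=offset, thickness=thickness)
    skel = prune_spurs(skeletonize(mask), max_spur_length)
    segs = extract_segments(skel)
    assert segs, "raster fixture produced no segments"
    return max(segs, key=len)


def raster_segment_auto(points, phase=(0.0, 0.0), thickness=3):
    """As raster_segment, with the canvas sized to the curve's extent.

    ``phase`` shifts the curve by a sub-pixel offset to control where it
    lands relative to the pixel grid.
    """
    pts = np.asarray(points, dtype=float)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    offset = (-lo[0] + 15 + phase[0], -lo[1] + 15 + phase[1])
    shape = (int(hi[1] - lo[1]) + 32, int(hi[0] - lo[0]) + 32)
    return raster_segment(pts, shape, offset, thickness=thickness)


@pytest.fixture(scope="session")
def point_list_config():
    return MetricConfig.for_point_lists(resample_step=0.2)


@pytest.fixture(scope="session")
def s_curve_record():
    """Hand-example: 'S' of two unit semicircles on a step-0.01 point list."""
    pts, oracle = sample_curve(CurveSpec("composite_S", {"radius": 1.0},
                                         step=0.01))
    rec = compute_record(pts, MetricConfig.for_point_lists(0.01))
    return rec, oracle


@pytest.fixture(scope="session")
def labeled_dataset_small():
    """120-image labeled synthetic set (30 per grade) for classifier tests."""
    from vesseltort.synthetic import generate_labeled_dataset
    from vesseltort.features import join_labels

    feats, labels = generate_labeled_dataset(n_per_grade=30, seed=11)
    return join_labels(feats, labels)
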