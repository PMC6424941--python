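"""Evaluation layer: ROI accuracy/precision, Bland-Altman, AHA segments.

Accuracy is proxied by the ROI mean T1 (against a reference or ground
truth), precision by the ROI standard deviation — the standard convention
for comparing quantitative T1 mapping techniques.  Sample (n-1) standard
deviations are used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import T1MapResult
from .phantom import GroundTruth

__all__ = [
    "RoiReport",
    "BlandAltman",
    "AhaSummary",
    "roi_stats",
    "bland_altman",
    "aha_segments",
]


@dataclass
class RoiReport:
    """Per-ROI mean (accuracy proxy) and SD (precision proxy) of fitted T1.

    ``table`` columns: label, n_voxels, mean_t1_ms, sd_t1_ms, and (when a
    ground truth was supplied) true_t1_ms and bias_ms = mean - truth.
    """

    table: pd.DataFrame

    def row(self, label: int) -> pd.Series:
        return self.table.set_index("label").loc[label]


@dataclass
class BlandAltman:
    """Paired-difference agreement summary: bias and 95% limits of agreement."""

    means: np.ndarray
    differences: np.ndarray
    bias: float
    sd_differences: float
    loa_lower: float
    loa_upper: float


@dataclass
class AhaSummary:
    """Simplified AHA 17-segment summary (segment 17 = blood pool).

    ``table`` has one row per segment (1..17) with mean, SD and voxel count;
    ``segment_labels`` is a volume with the per-voxel segment id (0 where a
    voxel belongs to no segment).
    """

    table: pd.DataFrame
    segment_labels: np.ndarray


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def roi_stats(
    t1_result: T1MapResult | np.ndarray,
    labels: np.ndarray,
    truth: GroundTruth | None = None,
) -> RoiReport:
    """Mean/SD of fitted T1 per ROI label, over valid voxels only.

    Labels with no valid voxel are excluded with a warning.  When ``truth``
    is given, the per-ROI true T1 (mode over the ROI) and the bias
    (mean - truth) are added.
    """
    if isinstance(t1_result, T1MapResult):
        t1 = t1_result.t1_map
        valid = t1_result.valid_mask
    else:
        t1 = np.asarray(t1_result, dtype=np.float64)
        valid = np.isfinite(t1)
    labels = np.asarray(labels)
    if labels.shape != t1.shape:
        raise ValueError(f"label shape {labels.shape} != map shape {t1.shape}")
    if labels.min() < 0:
        raise ValueError("ROI labels must be non-negative integers")

    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = (labels == lab) & valid
        vals = t1[sel]
        if vals.size == 0:
            warnings.warn(f"ROI label {lab}: no valid voxels; excluded",
                          stacklevel=2)
            continue
        row = {
            "label": int(lab),
            "n_voxels": int(vals.size),
            "mean_t1_ms": float(np.mean(vals)),
            "sd_t1_ms": _sample_sd(vals),
        }
        if truth is not None:
            in_roi = truth.t1_map[labels == lab]
            true_t1 = float(np.median(in_roi[in_roi > 0])) if (in_roi > 0).any() else np.nan
            row["true_t1_ms"] = true_t1
            row["bias_ms"] = row["mean_t1_ms"] - true_t1
        rows.append(row)
    return RoiReport(pd.DataFrame(rows))


def bland_altman(values_a: np.ndarray, values_b: np.ndarray) -> BlandAltman:
    """Bland-Altman agreement of two paired per-ROI measurement vectors.

    Differences are ``a - b``; bias is their mean and the 95% limits of
    agreement are ``bias +/- 1.96 * SD`` (sample SD).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 paired values")
    diff = a - b
    bias = float(np.mean(diff))
    sd = _sample_sd(diff)
    return BlandAltman(
        means=(a + b) / 2.0,
        differences=diff,
        bias=bias,
        sd_differences=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
    )


def aha_segments(
    t1_result: T1MapResult | np.ndarray,
    myocardium_mask: np.ndarray,
    blood_mask: np.ndarray,
    lv_center: tuple[float, float],
    rv_insertion_angle_deg: float,
    slice_partition: dict[str, tuple[int, int]],
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> AhaSummary:
    """Simplified AHA 16-segment myocardial summary plus blood pool.

    Basal and mid short-axis rings are split into 6 segments of 60 degrees,
    the apical ring into 4 segments of 90 degrees; angles are measured from
    the anterior RV insertion reference, proceeding counterclockwise
    (anterior -> anteroseptal -> inferoseptal -> ...).  Segment numbering is
    basal 1-6, mid 7-12, apical 13-16, and segment 17 reports the blood
    pool.  ``slice_partition`` maps ``"base"``, ``"mid"``, ``"apex"`` to
    half-open z index ranges ``(z0, z1)``.
    """
    if isinstance(t1_result, T1MapResult):
        t1 = t1_result.t1_map
        valid = t1_result.valid_mask
    else:
        t1 = np.asarray(t1_result, dtype=np.float64)
        valid = np.isfinite(t1)
    myocardium_mask = np.asarray(myocardium_mask, dtype=bool)
    blood_mask = np.asarray(blood_mask, dtype=bool)
    for name, msk in (("myocardium", myocardium_mask), ("blood", blood_mask)):
        if msk.shape != t1.shape:
            raise ValueError(f"{name} mask shape {msk.shape} != map {t1.shape}")

    required = {"base", "mid", "apex"}
    if set(slice_partition) != required:
        raise ValueError(f"slice_partition must have keys {sorted(required)}")
    covered: set[int] = set()
    for name, (z0, z1) in slice_partition.items():
        rng = set(range(z0, z1))
        if rng & covered:
            raise ValueError("apex/mid/base slice ranges must be disjoint")
        covered |= rng

    nx, ny, nz = t1.shape
    dx, dy, _ = voxel_spacing_mm
    x = (np.arange(nx) * dx)[:, None] - lv_center[0]
    y = (np.arange(ny) * dy)[None, :] - lv_center[1]
    theta = np.degrees(np.arctan2(y, x))  # CCW in the (x, y) plane
    rel = np.mod(theta - rv_insertion_angle_deg, 360.0)

    seg_labels = np.zeros(t1.shape, dtype=np.int32)
    ring_offsets = {"base": (0, 6, 60.0), "mid": (6, 6, 60.0), "apex": (12, 4, 90.0)}
    for ring, (z0, z1) in slice_partition.items():
        offset, nseg, span = ring_offsets[ring]
        ring_myo = myocardium_mask[:, :, z0:z1]
        if not ring_myo.any():
            raise ValueError(
                f"myocardium mask is empty in the {ring} slice range ({z0}, {z1})"
            )
        sector = np.minimum((rel / span).astype(np.int32), nseg - 1)
        for z in range(z0, z1):
            sl = myocardium_mask[:, :, z]
            seg_labels[:, :, z][sl] = offset + 1 + sector[sl]
    seg_labels[blood_mask] = 17

    rows = []
    for seg in range(1, 18):
        sel = (seg_labels == seg) & valid
        vals = t1[sel]
        rows.append({
            "segment": seg,
            "n_voxels": int(vals.size),
            "mean_t1_ms": float(np.mean(vals)) if vals.size else np.nan,
            "sd_t1_ms": _sample_sd(vals),
        })
    return AhaSummary(pd.DataFrame(rows), seg_labels)
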