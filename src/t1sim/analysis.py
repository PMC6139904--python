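"""ROI, AHA-segment, and method-comparison statistics for T1 maps.

The segmentation follows the American Heart Association (AHA) left-
ventricular model applied slice-wise to short-axis data: slices are evenly
categorized into basal, mid-ventricular and apical slabs; basal and mid
slices are divided into six 60-degree segments and apical slices into four
90-degree segments, measured from the anterior right-ventricular (RV)
insertion point (clockwise when viewed from the apex, configurable).  Only
the 16 short-axis segments are scored — the apical-cap segment 17 has no
short-axis extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import T1Map

__all__ = [
    "ROIStats",
    "ComparisonReport",
    "AHA_SEGMENT_NAMES",
    "roi_stats",
    "assign_aha_segments",
    "bullseye_table",
    "bullseye_json",
    "compare_methods",
]

#: 16 scored AHA segment ids -> names (1-6 basal, 7-12 mid, 13-16 apical)
AHA_SEGMENT_NAMES: Dict[int, str] = {
    1: "basal_anterior", 2: "basal_anteroseptal", 3: "basal_inferoseptal",
    4: "basal_inferior", 5: "basal_inferolateral", 6: "basal_anterolateral",
    7: "mid_anterior", 8: "mid_anteroseptal", 9: "mid_inferoseptal",
    10: "mid_inferior", 11: "mid_inferolateral", 12: "mid_anterolateral",
    13: "apical_anterior", 14: "apical_septal", 15: "apical_inferior",
    16: "apical_lateral",
}

_SLAB_OFFSET = {"base": 0, "mid": 6, "apex": 12}
_SLAB_NSEG = {"base": 6, "mid": 6, "apex": 4}


@dataclass
class ROIStats:
    mean: float
    sd: float
    cv_pct: float
    n_voxels: int


@dataclass
class ComparisonReport:
    """Linear regression + Bland-Altman + paired t-test between two methods."""

    slope: float
    intercept: float
    r_squared: float
    bias: float
    loa_low: float
    loa_high: float
    t_statistic: float
    p_value: float
    relative_errors_pct: np.ndarray


def _map_values(t1map: Union[T1Map, np.ndarray]) -> np.ndarray:
    return t1map.t1 if isinstance(t1map, T1Map) else np.asarray(t1map, dtype=float)


def roi_stats(
    t1map: Union[T1Map, np.ndarray],
    roi_mask: np.ndarray,
    name: str = "ROI",
) -> ROIStats:
    """Mean, SD (n-1 denominator) and CV of map values inside the ROI."""
    values = _map_values(t1map)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != values.shape:
        raise ValueError(f"{name}: mask shape does not match the map grid")
    vals = values[roi_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"{name}: empty ROI (no finite voxels inside mask)")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return ROIStats(mean=mean, sd=sd, cv_pct=cv, n_voxels=int(vals.size))


def assign_aha_segments(
    mask: np.ndarray,
    slice_slabs: Sequence[str],
    rv_angle_deg: float = 0.0,
    clockwise: bool = True,
) -> np.ndarray:
    """Label every myocardial voxel with its AHA segment id (1-16).

    ``mask`` is a 3D annular myocardium mask; ``slice_slabs`` gives the slab
    ("base"/"mid"/"apex") of each slice.  Angles are measured from the RV
    insertion reference, clockwise as viewed from the apex by default.
    Returns an int array with 0 outside the myocardium.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D (x, y, slice)")
    if len(slice_slabs) != mask.shape[2]:
        raise ValueError("one slab label per slice required")
    bad = set(slice_slabs) - set(_SLAB_NSEG)
    if bad:
        raise ValueError(f"unknown slab labels: {sorted(bad)}")

    out = np.zeros(mask.shape, dtype=np.int16)
    for z, slab in enumerate(slice_slabs):
        sl = mask[:, :, z]
        if not sl.any():
            continue
        xs, ys = np.nonzero(sl)
        cx, cy = xs.mean(), ys.mean()
        if sl[int(round(cx)), int(round(cy))]:
            raise ValueError(
                f"slice {z}: mask is not annular (centroid falls on the "
                f"myocardium class, so the angular origin is ambiguous)"
            )
        ang = np.degrees(np.arctan2(ys - cy, xs - cx))
        if clockwise:
            ang = -ang
        rel = np.mod(ang - rv_angle_deg, 360.0)
        nseg = _SLAB_NSEG[slab]
        seg = np.minimum((rel / (360.0 / nseg)).astype(int), nseg - 1)
        out[xs, ys, z] = seg + 1 + _SLAB_OFFSET[slab]
    return out


def bullseye_table(
    t1map: Union[T1Map, np.ndarray],
    segments: np.ndarray,
    subject: Optional[str] = None,
) -> pd.DataFrame:
    """Per-segment mean/SD/CV table (one row per populated segment)."""
    values = _map_values(t1map)
    segments = np.asarray(segments)
    rows = []
    for seg_id in sorted(np.unique(segments[segments > 0])):
        st = roi_stats(values, segments == seg_id, name=AHA_SEGMENT_NAMES.get(int(seg_id), str(seg_id)))
        slab = "base" if seg_id <= 6 else ("mid" if seg_id <= 12 else "apex")
        rows.append(
            (subject, int(seg_id), AHA_SEGMENT_NAMES[int(seg_id)], slab,
             st.mean, st.sd, st.cv_pct, st.n_voxels)
        )
    return pd.DataFrame(
        rows,
        columns=["subject", "segment_id", "segment", "slab", "mean", "sd",
                 "cv_pct", "n_voxels"],
    )


def bullseye_json(table: pd.DataFrame) -> Dict[str, Dict[str, dict]]:
    """Aggregate a (possibly multi-subject) segment table into the nested
    ``{slab: {segment: {mean, sd, cv}}}`` bull's-eye structure.

    Aggregation across subjects is an unweighted mean of per-subject values.
    """
    out: Dict[str, Dict[str, dict]] = {}
    grouped = table.groupby(["slab", "segment"], sort=False)[["mean", "sd", "cv_pct"]].mean()
    for (slab, segment), row in grouped.iterrows():
        out.setdefault(slab, {})[segment] = {
            "mean": float(row["mean"]),
            "sd": float(row["sd"]),
            "cv": float(row["cv_pct"]),
        }
    return out


def compare_methods(x: Sequence[float], y: Sequence[float]) -> ComparisonReport:
    """Method comparison of paired T1 measurements (y against reference x).

    Ordinary least-squares regression of y on x, Bland-Altman statistics of
    the differences y - x (bias and 95% limits of agreement), and a
    two-tailed paired t-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    reg = stats.linregress(x, y)
    diffs = y - x
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    tt = stats.ttest_rel(y, x)
    return ComparisonReport(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        t_statistic=float(tt.statistic),
        p_value=float(tt.pvalue),
        relative_errors_pct=100.0 * diffs / x,
    )
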