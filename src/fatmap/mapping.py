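"""Radial fat-mapping: segmented fat-fraction slices -> distance-normalized
fat-distribution curves and depth-windowed scalar metrics.

The muscle cross-section is partitioned into non-overlapping regions of
interest (ROIs) radiating outward from the vertebral center of rotation (CoR)
at two-pixel increments. The per-ROI mean fat fraction, plotted against depth
normalized to 0-100% of the radial muscle width (0% = deepest pixel, 100% =
most superficial), is the subject's fat-distribution curve. Curves from the
left and right muscle at two axial slices per lumbar level are averaged
node-wise into one curve per level. Two scalars summarize each level:
``overall FI%`` (pixel-weighted mean over the whole cross-section) and
``deep15 FI%`` (mean of the curve over the deepest 15% of radial width).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID = np.arange(101.0)  # integer-percent depth grid, 0 = deepest
ROI_STEP_PX = 2.0  # radial ROI width in pixels


@dataclass
class FatFractionSlice:
    """One axial fat-fraction raster with its muscle masks.

    fat: 2D array of fat fraction in [0,100] percent.
    masks: side name ('left'/'right') -> boolean raster.
    cor: continuous (row, col) coordinate of the center of rotation.
    """

    fat: np.ndarray
    masks: dict[str, np.ndarray]
    cor: tuple[float, float]
    level: str
    slice_index: int
    pixel_spacing: float = 1.0
    subject: str = ""

    def __post_init__(self):
        self.fat = np.asarray(self.fat, dtype=float)
        r, c = self.cor
        if not (0 <= r <= self.fat.shape[0] - 1 and 0 <= c <= self.fat.shape[1] - 1):
            raise ValueError(f"CoR {self.cor} outside raster bounds {self.fat.shape}")
        for side, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.fat.shape:
                raise ValueError(f"mask shape {m.shape} != fat shape {self.fat.shape}")
            if not m.any():
                raise ValueError(f"empty {side} mask")
            if not np.isfinite(self.fat[m]).all():
                raise ValueError(f"non-finite fat values inside {side} mask")
            self.masks[side] = m

    def distances(self, side: str) -> np.ndarray:
        """Euclidean distance of each in-mask pixel from the CoR, in length units."""
        rr, cc = np.nonzero(self.masks[side])
        return np.hypot(rr - self.cor[0], cc - self.cor[1]) * self.pixel_spacing


@dataclass
class RadialFatCurve:
    """Distance-normalized 1D fat profile on the 101-node percent grid."""

    fi: np.ndarray  # FI% at each node of GRID
    n_pixels_per_roi: np.ndarray = field(default_factory=lambda: np.array([]))
    subject: str = ""
    level: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fi = np.asarray(self.fi, dtype=float)
        if self.fi.shape != GRID.shape:
            raise ValueError(f"curve must have {GRID.size} nodes, got {self.fi.shape}")


def radial_rois(slc: FatFractionSlice, side: str) -> list[np.ndarray]:
    """Partition a side's mask into radial ROIs of two-pixel width.

    ROI k holds the in-mask pixel indices whose CoR distance d satisfies
    r_min + 2k <= d < r_min + 2(k+1), with r_min the minimum in-mask distance.
    Returns a list of (n_k, 2) integer index arrays ordered deep to superficial;
    empty shells are kept as zero-length entries so callers can detect gaps.
    """
    mask = slc.masks[side]
    rr, cc = np.nonzero(mask)
    d = np.hypot(rr - slc.cor[0], cc - slc.cor[1]) * slc.pixel_spacing
    step = ROI_STEP_PX * slc.pixel_spacing
    r_min = d.min()
    k = np.floor((d - r_min) / step).astype(int)
    n_rois = int(k.max()) + 1
    if n_rois == 1:
        warnings.warn("all mask pixels fall in a single radial shell", stacklevel=2)
    rois = []
    for j in range(n_rois):
        sel = k == j
        rois.append(np.column_stack([rr[sel], cc[sel]]))
    return rois


def roi_curve(slc: FatFractionSlice, side: str) -> RadialFatCurve:
    """Per-ROI mean FI% interpolated onto the 101-node depth grid.

    Each ROI's mean is placed at the ROI's mid-depth (the mean distance of its
    member pixels), depths are normalized to 0-100% of (max - min in-mask
    distance), and values are linearly interpolated onto integer percent
    nodes. The grid does not extrapolate: nodes deeper than the first ROI
    mid-depth (or more superficial than the last) take the nearest ROI's value.
    """
    rois = radial_rois(slc, side)
    d_all = slc.distances(side)
    r_min, r_max = d_all.min(), d_all.max()
    span = r_max - r_min

    mids, means, counts = [], [], []
    gap = False
    for j, idx in enumerate(rois):
        counts.append(len(idx))
        if len(idx) == 0:
            gap = True
            continue
        d_roi = np.hypot(idx[:, 0] - slc.cor[0], idx[:, 1] - slc.cor[1]) * slc.pixel_spacing
        mids.append(d_roi.mean())
        means.append(slc.fat[idx[:, 0], idx[:, 1]].mean())
    if gap:
        warnings.warn("empty radial shell(s): interpolating across the gap", stacklevel=2)
    if len(means) < 2:
        raise ValueError("need at least 2 occupied ROIs to build a curve")

    if span == 0:
        pct = np.array([0.0])
        fi = np.interp(GRID, pct, np.array(means[:1]))
    else:
        pct = (np.asarray(mids) - r_min) / span * 100.0
        fi = np.interp(GRID, pct, np.asarray(means))
    return RadialFatCurve(
        fi=fi,
        n_pixels_per_roi=np.asarray(counts),
        subject=slc.subject,
        level=slc.level,
        meta={"side": side, "slice_index": slc.slice_index, "r_min": r_min, "r_max": r_max},
    )


def average_curves(curves: list[RadialFatCurve]) -> RadialFatCurve:
    """Node-wise unweighted mean of curves on the common grid (normally the
    four left/right x slice-1/slice-2 curves of one subject+level)."""
    if not curves:
        raise ValueError("no curves to average")
    levels = {c.level for c in curves}
    meta = {"n_curves": len(curves)}
    if len(curves) < 4:
        meta["incomplete"] = True
    fi = np.mean([c.fi for c in curves], axis=0)
    return RadialFatCurve(fi=fi, subject=curves[0].subject, level=levels.pop() if len(levels) == 1 else "", meta=meta)


def subject_level_curve(slices: list[FatFractionSlice]) -> RadialFatCurve:
    """One fat-map for a subject+level: average of left & right over all slices."""
    curves = [roi_curve(s, side) for s in slices for side in sorted(s.masks)]
    return average_curves(curves)


def overall_fi(slices: list[FatFractionSlice]) -> float:
    """Pixel-weighted mean FI% pooled over both sides of every slice supplied."""
    vals = np.concatenate([s.fat[m] for s in slices for m in s.masks.values()])
    return float(vals.mean())


def deep15_fi(curve: RadialFatCurve) -> float:
    """Mean FI% over the deepest 15% of radial width (grid nodes 0..15)."""
    return float(curve.fi[:16].mean())


def cohort_curves_and_metrics(
    subjects_slices: dict[str, dict[str, list[FatFractionSlice]]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run fat-mapping for a whole cohort.

    subjects_slices: subject id -> level -> list of FatFractionSlice.
    Returns (curves, metrics): curves in long format (subject, level, node_pct,
    fi); metrics one row per subject+level with overall_fi and deep15_fi.
    """
    curve_rows, metric_rows = [], []
    for sid, by_level in subjects_slices.items():
        for level, slices in by_level.items():
            curve = subject_level_curve(slices)
            curve_rows.append(
                pd.DataFrame({"subject": sid, "level": level, "node_pct": GRID, "fi": curve.fi})
            )
            metric_rows.append(
                {
                    "subject": sid,
                    "level": level,
                    "overall_fi": overall_fi(slices),
                    "deep15_fi": deep15_fi(curve),
                }
            )
    return pd.concat(curve_rows, ignore_index=True), pd.DataFrame(metric_rows)


def curves_wide(curves_long: pd.DataFrame, level: str) -> tuple[list[str], np.ndarray]:
    """Pivot long-format curves for one level into (subject ids, subject x node)."""
    sub = curves_long[curves_long["level"] == level]
    wide = sub.pivot(index="subject", columns="node_pct", values="fi").sort_index()
    return list(wide.index), wide.to_numpy(dtype=float)
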