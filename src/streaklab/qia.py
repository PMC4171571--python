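"""Quantitative image analysis (QIA) of nuclear-stained stacks.

Nuclei are segmented on the DNA-stain (Hoechst) channel by Gaussian
smoothing, a global Otsu threshold and 8-connected labelling with a
minimum-area filter; the mean pixel intensity of every other channel is
then measured per nucleus. On top of the per-nucleus records the module
builds distribution timecourses (shared-range histograms with means) and
pairwise Pearson-correlation timecourses against a baseline condition,
plus a circular region-of-interest readout along a cell track for live
reporter quantification.

Pixel convention: 0-based coordinates, origin at the top-left, x along
columns, y along rows increasing downward; pixel centres at integer
coordinates. Centroid and ROI semantics depend on this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters, measure

from .synth import ImageScene, Track

__all__ = [
    "segment_nuclei",
    "extract_nuclear_intensities",
    "intensity_distribution_timecourse",
    "pairwise_correlation_timecourse",
    "track_roi_intensity",
    "CorrelationPoint",
    "ROISeries",
    "DEFAULT_MIN_AREA_PX",
    "DEFAULT_SMOOTH_SIGMA_PX",
]

DEFAULT_MIN_AREA_PX = 50
DEFAULT_SMOOTH_SIGMA_PX = 2.0


def segment_nuclei(hoechst_image: np.ndarray,
                   smooth_sigma: float = DEFAULT_SMOOTH_SIGMA_PX,
                   min_area: int = DEFAULT_MIN_AREA_PX) -> np.ndarray:
    """Label nuclei on the DNA-stain channel.

    Gaussian smoothing (σ = ``smooth_sigma``), global Otsu threshold,
    8-connected components, components smaller than ``min_area`` removed.
    Returns an integer label map (background 0). A constant image yields
    zero labels with a warning (Otsu is undefined there).
    """
    img = np.asarray(hoechst_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("hoechst_image must be 2-D")
    if (img < 0).any():
        raise ValueError("hoechst_image must be non-negative")
    smoothed = filters.gaussian(img, sigma=smooth_sigma, preserve_range=True) \
        if smooth_sigma > 0 else img
    if np.ptp(smoothed) == 0:
        warnings.warn("constant image: Otsu threshold undefined, no nuclei")
        return np.zeros(img.shape, dtype=int)
    thr = filters.threshold_otsu(smoothed)
    mask = smoothed > thr
    labels = measure.label(mask, connectivity=2)
    # drop components below the area floor and relabel sequentially
    areas = np.bincount(labels.ravel())
    keep = np.nonzero(areas >= min_area)[0]
    keep = keep[keep != 0]
    remap = np.zeros(areas.size, dtype=int)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def extract_nuclear_intensities(labels: np.ndarray,
                                channel_images: dict[str, np.ndarray],
                                timepoint: float = 0.0,
                                condition: str = "") -> pd.DataFrame:
    """Per-nucleus mean intensity of every channel over the label's pixels.

    Returns one row per nucleus with columns ``label, timepoint_h,
    condition, cx_px, cy_px, area_px`` and ``mean_<channel>``.
    """
    labels = np.asarray(labels)
    for name, img in channel_images.items():
        if np.asarray(img).shape != labels.shape:
            raise ValueError(
                f"channel {name!r} shape {np.asarray(img).shape} does not "
                f"match label map shape {labels.shape}")
    props = measure.regionprops(labels)
    rows = []
    for p in props:
        rr, cc = p.coords[:, 0], p.coords[:, 1]
        row = {"label": int(p.label), "timepoint_h": float(timepoint),
               "condition": condition,
               # centroid as (x, y) in the top-left/y-down convention
               "cx_px": float(p.centroid[1]), "cy_px": float(p.centroid[0]),
               "area_px": int(p.area)}
        for name, img in channel_images.items():
            row[f"mean_{name}"] = float(np.asarray(img, dtype=float)[rr, cc].mean())
        rows.append(row)
    cols = ["label", "timepoint_h", "condition", "cx_px", "cy_px", "area_px"] \
        + [f"mean_{n}" for n in channel_images]
    return pd.DataFrame(rows, columns=cols)


def intensity_distribution_timecourse(records: pd.DataFrame,
                                      channels: list[str] | None = None,
                                      bins: int = 50):
    """Per-channel, per-timepoint histograms and means.

    Histogram bins share one range per channel across all timepoints so
    that the distribution timecourse is comparable; the mean of each
    distribution is reported alongside. Returns ``(means, histograms)``
    where ``means`` is a tidy DataFrame (channel, timepoint_h, mean, n)
    and ``histograms`` maps (channel, timepoint) to (counts, bin_edges).
    """
    if channels is None:
        channels = [c[len("mean_"):] for c in records.columns
                    if c.startswith("mean_")]
    timepoints = sorted(records["timepoint_h"].unique())
    means_rows = []
    hists = {}
    for ch in channels:
        col = f"mean_{ch}"
        allvals = records[col].to_numpy(dtype=float)
        lo, hi = (float(allvals.min()), float(allvals.max())) if allvals.size \
            else (0.0, 1.0)
        if lo == hi:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, bins + 1)
        for tp in timepoints:
            vals = records.loc[records["timepoint_h"] == tp, col].to_numpy(dtype=float)
            if vals.size == 0:
                means_rows.append({"channel": ch, "timepoint_h": tp,
                                   "mean": float("nan"), "n": 0})
                continue
            counts, _ = np.histogram(vals, bins=edges)
            hists[(ch, tp)] = (counts, edges)
            means_rows.append({"channel": ch, "timepoint_h": tp,
                               "mean": float(vals.mean()), "n": int(vals.size)})
    return pd.DataFrame(means_rows), hists


@dataclass
class CorrelationPoint:
    """Pearson correlation of one channel pair at one timepoint."""

    channel_a: str
    channel_b: str
    timepoint_h: float
    r: float
    n: int
    baseline_r: float = float("nan")
    defined: bool = True


def pairwise_correlation_timecourse(records: pd.DataFrame,
                                    pairs: list[tuple[str, str]],
                                    baseline_records: pd.DataFrame | None = None
                                    ) -> list[CorrelationPoint]:
    """Pearson r of per-nucleus means for each channel pair and timepoint.

    ``baseline_r`` is computed once per pair from the pooled baseline
    condition's records (the reference line of the correlation plot).
    A zero-variance channel yields an entry flagged ``defined=False``.
    """
    def _corr(df, a, b):
        xa = df[f"mean_{a}"].to_numpy(dtype=float)
        xb = df[f"mean_{b}"].to_numpy(dtype=float)
        if xa.size < 3:
            return float("nan"), int(xa.size), False
        if np.std(xa) == 0 or np.std(xb) == 0:
            return float("nan"), int(xa.size), False
        r, _ = stats.pearsonr(xa, xb)
        return float(r), int(xa.size), True

    out = []
    for a, b in pairs:
        base_r = float("nan")
        if baseline_records is not None and len(baseline_records) >= 3:
            base_r, _, _ = _corr(baseline_records, a, b)
        for tp in sorted(records["timepoint_h"].unique()):
            sub = records[records["timepoint_h"] == tp]
            r, n, defined = _corr(sub, a, b)
            out.append(CorrelationPoint(a, b, float(tp), r, n,
                                        baseline_r=base_r, defined=defined))
    return out


@dataclass
class ROISeries:
    """Mean circular-ROI intensity along a track, one value per frame."""

    values: np.ndarray
    clipped: np.ndarray  # True where the ROI ran off the image edge


def track_roi_intensity(scene: ImageScene, track: Track, channel: str,
                        radius_um: float = 10.0) -> ROISeries:
    """Mean intensity in a circular ROI around each track position.

    A disk of the given physical radius (converted to pixels through the
    scene's pixel size) is centred on the cell position at every frame;
    pixels whose centres fall inside contribute to the mean. ROIs that
    run off the image edge are clipped and flagged; a position fully
    outside the image yields NaN. Track sample *i* reads frame *i*.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    t_frames = scene.stack.shape[0]
    if track.n > t_frames:
        raise ValueError(
            f"track has {track.n} samples but the stack has {t_frames} frames")
    ci = scene.channels.index(channel)
    h, w = scene.stack.shape[2:]
    r_px = radius_um / scene.pixel_size
    yy, xx = np.mgrid[0:h, 0:w]
    values = np.full(track.n, np.nan)
    clipped = np.zeros(track.n, dtype=bool)
    for i in range(track.n):
        cx = track.x[i] / scene.pixel_size
        cy = track.y[i] / scene.pixel_size
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2
        n_in = int(disk.sum())
        if n_in == 0:
            clipped[i] = True
            continue
        # flag ROIs whose bounding disk touches the image border
        touches = (cx - r_px < -0.5 or cy - r_px < -0.5
                   or cx + r_px > w - 0.5 or cy + r_px > h - 0.5)
        clipped[i] = bool(touches)
        values[i] = float(scene.stack[i, ci][disk].mean())
    return ROISeries(values=values, clipped=clipped)
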