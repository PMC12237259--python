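"""STED-scale analyses around single active zones.

Two families of measurements are implemented:

* **K-neighbor distances** -- within a 53 x 53-px (1.06 x 1.06 um at 20-nm
  pitch) region of interest, the BRP scaffold ring's center of mass marks the
  AZ center; ranked Euclidean distances from partner-channel local maxima to
  that center give k1..k5, and AZs are binned small / middle / big by
  scaffold pixel area.

* **Radial intensity profiles** -- cluster centers are found by
  moments-preserving (Tsai) auto-thresholding followed by prominence-based
  maxima detection; annulus-mean intensity versus radius is computed per
  cluster in both channels, reduced to a per-image median, and aggregated
  across images as mean with Student-t 95% confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .spots import find_maxima

logger = logging.getLogger("nmjquant")

__all__ = [
    "AZNeighborResult",
    "RadialProfile",
    "extract_az_rois",
    "ring_center",
    "partner_maxima",
    "kneighbor",
    "bin_by_area",
    "count_within_radius",
    "analyze_az",
    "kneighbor_table",
    "moments_threshold",
    "cluster_centers",
    "radial_profile",
    "aggregate_radial_profiles",
]

SIZE_BIN_EDGES_PX2 = (159, 215)  # small: [1, 159], middle: [160, 215], big: > 215


# ---------------------------------------------------------------------------
# K-neighbor analysis
# ---------------------------------------------------------------------------

@dataclass
class AZNeighborResult:
    """Per-AZ ring center, partner coordinates and ranked distances (nm)."""

    az_id: int
    roi_origin: tuple[int, int]
    ring_center: tuple[float, float]          # (xm, ym), subpixel, ROI coords
    az_area_px2: float
    size_bin: str
    partner_points: list[tuple[int, int]]     # (y, x) integer pixels
    ranked_distances_nm: np.ndarray           # length k, NaN-padded
    count_within_400nm: int
    flagged_no_points: bool = False


def extract_az_rois(
    frame_channels: dict[str, np.ndarray],
    az_centers: list[tuple[int, int]],
    roi_px: int = 53,
) -> list[dict]:
    """Crop ``roi_px`` x ``roi_px`` regions of every channel per AZ center.

    Centers whose ROI would exceed the frame are skipped with a log entry.
    Returns one dict per kept AZ: ``{"origin": (y0, x0), <channel>: crop}``.
    """
    half = roi_px // 2
    any_chan = next(iter(frame_channels.values()))
    ny, nx = any_chan.shape
    out = []
    for cy, cx in az_centers:
        y0, x0 = int(round(cy)) - half, int(round(cx)) - half
        if y0 < 0 or x0 < 0 or y0 + roi_px > ny or x0 + roi_px > nx:
            logger.info("extract_az_rois: ROI at (%s, %s) exceeds frame, skipped", cy, cx)
            continue
        crops = {"origin": (y0, x0)}
        for name, chan in frame_channels.items():
            crops[name] = chan[y0:y0 + roi_px, x0:x0 + roi_px]
        out.append(crops)
    return out


def ring_center(brp_roi: np.ndarray) -> tuple[float, float]:
    """Subpixel (xm, ym) intensity-weighted centroid after minimum subtraction.

    Exact invariance under an added pedestal holds only when the pedestal
    equals the ROI minimum that is subtracted; a partial pedestal shifts the
    weighting slightly (documented behaviour of the minimum-subtraction
    convention).
    """
    roi = np.asarray(brp_roi, dtype=float)
    mn, mx = roi.min(), roi.max()
    if mx == mn:
        raise ValueError("constant ROI: ring center undefined")
    w = roi - mn
    cy, cx = ndimage.center_of_mass(w)
    return float(cx), float(cy)


def partner_maxima(partner_roi: np.ndarray, prominence: float) -> list[tuple[int, int]]:
    """Local maxima of the partner channel inside the ROI (delegated)."""
    roi = np.asarray(partner_roi, dtype=float)
    if roi.size == 0 or np.all(roi == roi.flat[0]):
        return []
    return find_maxima(roi, prominence)


def kneighbor(
    center_xy: tuple[float, float],
    points_yx: list[tuple[int, int]],
    k: int = 5,
    pitch_nm: float = 20.0,
) -> np.ndarray:
    """Ranked Euclidean distances (nm) from partner points to the AZ center.

    The minimum is k1.  With fewer than ``k`` points the absent ranks are
    NaN; with no points at all every rank is NaN (caller flags the AZ).
    """
    xm, ym = center_xy
    out = np.full(k, np.nan)
    if points_yx:
        d = np.sort(
            [np.hypot(x - xm, y - ym) * pitch_nm for (y, x) in points_yx]
        )
        out[: min(k, d.size)] = d[:k]
    return out


def bin_by_area(az_area_px2: float) -> str:
    """Size bin of an AZ scaffold: small [1, 159], middle [160, 215], big > 215 px^2."""
    if az_area_px2 < 1:
        raise ValueError("AZ area below 1 px^2")
    lo, hi = SIZE_BIN_EDGES_PX2
    if az_area_px2 <= lo:
        return "small"
    if az_area_px2 <= hi:
        return "middle"
    return "big"


def count_within_radius(distances_nm: np.ndarray, r_nm: float = 400.0) -> int:
    """Number of distances <= ``r_nm`` (NaN ranks ignored)."""
    d = np.asarray(distances_nm, dtype=float)
    return int(np.count_nonzero(d[~np.isnan(d)] <= r_nm))


def analyze_az(
    az_id: int,
    brp_roi: np.ndarray,
    partner_roi: np.ndarray,
    prominence: float,
    pitch_nm: float = 20.0,
    roi_origin: tuple[int, int] = (0, 0),
    area_threshold: float | None = None,
    k: int = 5,
) -> AZNeighborResult:
    """Full per-AZ K-neighbor analysis of one ROI pair.

    AZ scaffold area is the supra-threshold pixel count of the BRP ROI;
    ``area_threshold`` defaults to the ROI's moments threshold.
    """
    if area_threshold is None:
        area_threshold = moments_threshold(brp_roi)
    area_px2 = float(np.count_nonzero(np.asarray(brp_roi) > area_threshold))
    center = ring_center(brp_roi)
    pts = partner_maxima(partner_roi, prominence)
    dists = kneighbor(center, pts, k=k, pitch_nm=pitch_nm)
    return AZNeighborResult(
        az_id=az_id,
        roi_origin=roi_origin,
        ring_center=center,
        az_area_px2=area_px2,
        size_bin=bin_by_area(max(area_px2, 1.0)),
        partner_points=pts,
        ranked_distances_nm=dists,
        count_within_400nm=count_within_radius(dists),
        flagged_no_points=not pts,
    )


def kneighbor_table(
    results: list[AZNeighborResult],
    animal_ids: list | None = None,
    per_animal: bool = False,
) -> pd.DataFrame:
    """Long-format table of K-neighbor results; optional per-animal means."""
    rows = []
    for i, r in enumerate(results):
        row = {
            "az_id": r.az_id,
            "size_bin": r.size_bin,
            "az_area_px2": r.az_area_px2,
            "count_within_400nm": r.count_within_400nm,
        }
        for j, d in enumerate(r.ranked_distances_nm, start=1):
            row[f"k{j}_nm"] = d
        if animal_ids is not None:
            row["animal"] = animal_ids[i]
        rows.append(row)
    df = pd.DataFrame(rows)
    if per_animal:
        if animal_ids is None:
            raise ValueError("per-animal averaging requires animal_ids")
        num = df.select_dtypes("number").columns
        df = df.groupby("animal", as_index=False)[list(num)].mean()
    return df


# ---------------------------------------------------------------------------
# Moments (Tsai) threshold and radial profiles
# ---------------------------------------------------------------------------

def moments_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Moment-preserving (Tsai) gray-level threshold.

    Chooses the binarization that preserves the image's first three gray-level
    moments: from the histogram moments m1..m3 the two representative levels
    z0 < z1 and the below-threshold fraction p0 are solved in closed form,
    and the threshold is the p0-tile of the histogram.  Raises on a constant
    image or a histogram with a single populated bin.
    """
    img = np.asarray(image, dtype=float).ravel()
    lo, hi = img.min(), img.max()
    if hi == lo:
        raise ValueError("constant image: moments threshold undefined")
    hist, edges = np.histogram(img, bins=nbins, range=(lo, hi))
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: single populated bin")
    p = hist / hist.sum()
    lev = np.arange(nbins, dtype=float)
    m1 = float((p * lev).sum())
    m2 = float((p * lev**2).sum())
    m3 = float((p * lev**3).sum())
    cd = m2 - m1 * m1
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)
    csum = np.cumsum(p)
    idx = int(np.searchsorted(csum, p0))
    idx = min(idx, nbins - 1)
    return float(edges[idx + 1])


def cluster_centers(
    image: np.ndarray,
    prominence: float,
    threshold: float | None = None,
) -> list[tuple[int, int]]:
    """Cluster centers: background removed by the moments threshold, then
    prominence-filtered local maxima on the supra-threshold signal."""
    img = np.asarray(image, dtype=float)
    if threshold is None:
        threshold = moments_threshold(img)
    masked = np.where(img > threshold, img, 0.0)
    if np.all(masked == 0):
        return []
    return [pt for pt in find_maxima(masked, prominence) if img[pt] > threshold]


@dataclass
class RadialProfile:
    """Radial (annulus-mean) intensity versus distance from cluster centers.

    ``level`` is ``"cluster"`` (one profile per center), ``"image-median"``
    (median across the image's clusters) or ``"group-mean"`` (mean across
    images, with ``ci95``).  Radii are bin centers in nm, strictly
    increasing; bin k covers [k*bin - bin/2, k*bin + bin/2).
    """

    radii_nm: np.ndarray
    intensity_by_radius: dict[str, np.ndarray]
    n_centers: int
    level: str
    ci95: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
    truncated_centers: int = 0


def radial_profile(
    channels: dict[str, np.ndarray],
    centers: list[tuple[float, float]],
    max_radius_nm: float,
    bin_nm: float,
    pitch_nm: float = 20.0,
) -> RadialProfile:
    """Per-image median radial profile around ``centers`` in every channel.

    For each center the mean intensity in annuli of width ``bin_nm`` is
    computed out to ``max_radius_nm``; centers closer than the maximum radius
    to the frame border are still profiled over the available pixels and
    counted as truncated.
    """
    if not centers:
        raise ValueError("no cluster centers to profile")
    names = list(channels)
    ny, nx = channels[names[0]].shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    n_bins = int(np.floor(max_radius_nm / bin_nm)) + 1
    radii = np.arange(n_bins) * bin_nm
    margin_px = max_radius_nm / pitch_nm
    profiles = {name: [] for name in names}
    truncated = 0
    for cy, cx in centers:
        if (
            cy < margin_px or cx < margin_px
            or cy > ny - 1 - margin_px or cx > nx - 1 - margin_px
        ):
            truncated += 1
        d_nm = np.hypot(yy - cy, xx - cx) * pitch_nm
        bin_idx = np.floor(d_nm / bin_nm + 0.5).astype(int)
        valid = bin_idx < n_bins
        counts = np.bincount(bin_idx[valid], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            for name in names:
                sums = np.bincount(
                    bin_idx[valid],
                    weights=np.asarray(channels[name], float)[valid],
                    minlength=n_bins,
                )
                profiles[name].append(sums / np.where(counts > 0, counts, np.nan))
    med = {name: np.nanmedian(np.array(p), axis=0) for name, p in profiles.items()}
    return RadialProfile(
        radii_nm=radii,
        intensity_by_radius=med,
        n_centers=len(centers),
        level="image-median",
        truncated_centers=truncated,
    )


def aggregate_radial_profiles(
    image_profiles: list[RadialProfile],
    normalize: bool = False,
) -> RadialProfile:
    """Group mean of per-image median profiles with Student-t 95% CIs.

    With ``normalize=True`` each channel of the aggregated profile is divided
    by its maximum bin (the "normalized" presentation).
    """
    if not image_profiles:
        raise ValueError("no image profiles to aggregate")
    radii = image_profiles[0].radii_nm
    names = list(image_profiles[0].intensity_by_radius)
    n = len(image_profiles)
    mean = {}
    ci = {}
    for name in names:
        arr = np.array([p.intensity_by_radius[name] for p in image_profiles])
        m = np.nanmean(arr, axis=0)
        if n > 1:
            sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.975, df=n - 1)
            lo, hi = m - tcrit * sem, m + tcrit * sem
        else:
            lo, hi = m.copy(), m.copy()
        if normalize:
            peak = np.nanmax(m)
            m, lo, hi = m / peak, lo / peak, hi / peak
        mean[name] = m
        ci[name] = (lo, hi)
    return RadialProfile(
        radii_nm=radii,
        intensity_by_radius=mean,
        n_centers=sum(p.n_centers for p in image_profiles),
        level="group-mean",
        ci95=ci,
    )


def radial_profile_table(profile: RadialProfile) -> pd.DataFrame:
    """Long-format (radius, channel, level, value[, ci]) table of a profile."""
    rows = []
    for name, vals in profile.intensity_by_radius.items():
        for i, r in enumerate(profile.radii_nm):
            row = {"radius_nm": r, "channel": name, "level": profile.level,
                   "value": vals[i]}
            if profile.ci95 is not None:
                row["ci_low"] = profile.ci95[name][0][i]
                row["ci_high"] = profile.ci95[name][1][i]
            rows.append(row)
    return pd.DataFrame(rows)
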