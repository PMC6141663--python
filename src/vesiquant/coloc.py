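"""Colocalization and synapse-mapping analyses for multi-channel images.

Covers Manders overlap coefficients on neurite regions, synapse selection by
a dual-channel intensity criterion, width-averaged line profiles across
synapses with maximum-aligned averaging, enrichment folds, and synapse
density / distance-to-soma maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import Point, Polygon as _ShapelyPolygon

from .core_io import RegionOfInterest


@dataclass
class MandersResult:
    M1: float | None  # fraction of channel-A intensity on channel-B-positive pixels
    M2: float | None
    threshold_a: float
    threshold_b: float
    n_pixels: int


@dataclass
class LineProfile:
    """Sampled intensity vs arclength for one channel along one path."""

    positions_um: np.ndarray
    intensities: np.ndarray


@dataclass
class SynapseMap:
    centroids: np.ndarray        # (N, 2) px, (row, col)
    image_area_um2: float
    density_per_um2: float
    distances_um: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Manders


def manders_coefficients(channel_a: np.ndarray, channel_b: np.ndarray,
                         roi: RegionOfInterest | None = None,
                         thr_a: float = 0.0, thr_b: float = 0.0,
                         ) -> MandersResult:
    """Manders overlap coefficients restricted to an ROI.

    ``M1`` is the summed channel-A intensity on pixels where channel B
    exceeds its threshold, divided by the summed channel-A intensity on
    pixels where A exceeds its own threshold (and symmetrically for ``M2``).
    A coefficient whose denominator is empty is undefined and returned as
    ``None``.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must have the same shape")
    if thr_a < 0 or thr_b < 0:
        raise ValueError("thresholds must be >= 0")
    if roi is not None:
        sel = roi.to_mask(a.shape)
    else:
        sel = np.ones(a.shape, dtype=bool)

    pos_a = sel & (a > thr_a)
    pos_b = sel & (b > thr_b)
    den_a = a[pos_a].sum()
    den_b = b[pos_b].sum()
    m1 = float(a[pos_b].sum() / den_a) if den_a > 0 else None
    m2 = float(b[pos_a].sum() / den_b) if den_b > 0 else None
    return MandersResult(M1=m1, M2=m2, threshold_a=thr_a, threshold_b=thr_b,
                         n_pixels=int(sel.sum()))


# ---------------------------------------------------------------------------
# Synapse selection (dual-channel punctum criterion)


def select_synapses(channel_a: np.ndarray, channel_b: np.ndarray,
                    candidates: np.ndarray,
                    neurite_rois: list[RegionOfInterest],
                    delta: float = 1000.0,
                    coloc_tol: float = 2.0,
                    exclusion_radius: float = 3.0,
                    ) -> np.ndarray:
    """Keep candidate puncta bright in BOTH channels over the local neurite.

    A candidate (row, col) is a synapse when, in each channel, its intensity
    exceeds the median of the surrounding neurite ROI (excluding a disk of
    ``exclusion_radius`` px around the punctum itself) by at least ``delta``
    AU.  ``candidates`` holds per-channel punctum positions interleaved or a
    single shared set; positions from the two channels must agree within
    ``coloc_tol`` px — with a shared candidate set this is automatic.
    Returns the retained (row, col) centroids.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if not neurite_rois:
        raise ValueError("need at least one neurite ROI")
    masks = [roi.to_mask(a.shape) for roi in neurite_rois]

    H, W = a.shape
    rr, cc = np.mgrid[0:H, 0:W]
    kept = []
    for (r, c) in candidates:
        containing = [m for m in masks if m[int(round(r)), int(round(c))]]
        if not containing:
            continue
        neurite = containing[0] & ((rr - r) ** 2 + (cc - c) ** 2
                                   > exclusion_radius ** 2)
        if not neurite.any():
            raise ValueError("no neurite baseline pixels around punctum")
        base_a = float(np.median(a[neurite]))
        base_b = float(np.median(b[neurite]))
        peak_a = _local_max(a, r, c, coloc_tol)
        peak_b = _local_max(b, r, c, coloc_tol)
        if peak_a - base_a >= delta and peak_b - base_b >= delta:
            kept.append((r, c))
    return np.array(kept).reshape(-1, 2)


def _local_max(image: np.ndarray, row: float, col: float, radius: float) -> float:
    H, W = image.shape
    r0, r1 = max(0, int(row - radius)), min(H, int(row + radius) + 1)
    c0, c1 = max(0, int(col - radius)), min(W, int(col + radius) + 1)
    return float(image[r0:r1, c0:c1].max())


# ---------------------------------------------------------------------------
# Line profiles


def extract_line_profile(image: np.ndarray, path: np.ndarray,
                         width: int = 3, pixel_size: float = 1.0,
                         ) -> LineProfile:
    """Width-averaged intensity profile along a polyline.

    The path (``(row, col)`` vertices, px) is resampled at 1-px arclength
    spacing; at each sample the profile value is the mean of ``width``
    bilinear samples spread 1 px apart along the local normal — the ImageJ
    wide-line convention.
    """
    image = np.asarray(image, dtype=float)
    path = np.atleast_2d(np.asarray(path, dtype=float))
    if len(path) < 2:
        raise ValueError("path needs at least two vertices")
    if width < 1:
        raise ValueError("width must be >= 1")

    # resample the polyline at 1-px arclength spacing
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arclen[-1]
    if total <= 0:
        raise ValueError("degenerate path")
    s = np.arange(0.0, total + 1e-9, 1.0)
    rows = np.interp(s, arclen, path[:, 0])
    cols = np.interp(s, arclen, path[:, 1])

    # local tangent (central differences) and unit normal
    t_r = np.gradient(rows)
    t_c = np.gradient(cols)
    norm = np.hypot(t_r, t_c)
    norm[norm == 0] = 1.0
    n_r, n_c = -t_c / norm, t_r / norm

    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    samples = np.empty((len(s), width))
    H, W = image.shape
    for j, off in enumerate(offsets):
        rr = rows + off * n_r
        cc = cols + off * n_c
        if (rr.min() < -0.5 or rr.max() > H - 0.5 or
                cc.min() < -0.5 or cc.max() > W - 0.5):
            raise ValueError("profile path (with width) exits the image")
        samples[:, j] = map_coordinates(image, [rr, cc], order=1, mode="nearest")
    return LineProfile(positions_um=s * pixel_size,
                       intensities=samples.mean(axis=1))


def align_and_average_profiles(profiles: dict[str, list[LineProfile]],
                               reference: str,
                               ) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Align per-synapse multi-channel profiles on the reference maximum, then average.

    Each synapse contributes one profile per channel, all sampled on the same
    grid.  Profiles are shifted (integer samples) so the reference-channel
    maximum sits at the grid centre; samples shifted out of range are
    dropped from the average.  Returns, per channel, ``(positions_um, mean,
    sem)`` centred on the reference peak (position 0 = synapse centre).
    """
    if reference not in profiles:
        raise ValueError(f"reference channel {reference!r} missing")
    n_syn = len(profiles[reference])
    if n_syn == 0:
        raise ValueError("no profiles to average")
    for ch, plist in profiles.items():
        if len(plist) != n_syn:
            raise ValueError(f"channel {ch!r} has {len(plist)} profiles, "
                             f"expected {n_syn}")

    length = len(profiles[reference][0].intensities)
    ref_pos = profiles[reference][0].positions_um
    spacing = float(ref_pos[1] - ref_pos[0]) if length > 1 else 1.0
    center = length // 2
    shifts = [center - int(np.argmax(p.intensities)) for p in profiles[reference]]

    out = {}
    for ch, plist in profiles.items():
        stack = np.full((n_syn, length), np.nan)
        for i, (p, sh) in enumerate(zip(plist, shifts)):
            if len(p.intensities) != length:
                raise ValueError("profiles must share a common grid")
            src_lo, src_hi = max(0, -sh), min(length, length - sh)
            stack[i, src_lo + sh:src_hi + sh] = p.intensities[src_lo:src_hi]
        n_ok = np.sum(~np.isnan(stack), axis=0)
        mean = np.full(length, np.nan)
        any_ok = n_ok > 0
        mean[any_ok] = np.nanmean(stack[:, any_ok], axis=0)
        sem = np.full(length, np.nan)
        multi = n_ok > 1
        if multi.any():
            sem[multi] = (np.nanstd(stack[:, multi], axis=0, ddof=1)
                          / np.sqrt(n_ok[multi]))
        positions = (np.arange(length) - center) * spacing
        out[ch] = (positions, mean, sem)
    return out


def enrichment_fold(positions_um: np.ndarray, profile: np.ndarray,
                    center_halfwidth: float = 0.5,
                    flank_window: tuple[float, float] = (0.5, 1.5),
                    ) -> float:
    """Mean intensity at the profile centre over the mean in the two flanks.

    ``center_halfwidth`` sets the central window (±hw µm around position 0);
    ``flank_window`` is the absolute-position band (µm) of the two flanking
    neurite segments.  Invariant to scaling the whole profile.
    """
    positions_um = np.asarray(positions_um, dtype=float)
    profile = np.asarray(profile, dtype=float)
    lo, hi = flank_window
    if lo < center_halfwidth:
        raise ValueError("flank window must lie outside the center window")
    center = np.abs(positions_um) <= center_halfwidth
    flank = (np.abs(positions_um) > lo) & (np.abs(positions_um) <= hi)
    if not center.any() or not flank.any():
        raise ValueError("empty center or flank window")
    flank_mean = np.nanmean(profile[flank])
    if flank_mean == 0:
        raise ValueError("flank mean is zero; fold undefined")
    return float(np.nanmean(profile[center]) / flank_mean)


# ---------------------------------------------------------------------------
# Synapse density and distances


def synapse_density(centroids: np.ndarray, image_area_um2: float) -> float:
    """Synapse count normalized to the image surface area (per µm²)."""
    if image_area_um2 <= 0:
        raise ValueError("image area must be > 0")
    n = len(np.atleast_2d(centroids)) if np.size(centroids) else 0
    return n / image_area_um2


def nearest_soma_distance(centroid: tuple[float, float],
                          soma_outlines: list[np.ndarray],
                          pixel_size: float) -> float:
    """Distance (µm) from a synapse to the nearest soma outline.

    Outlines are (N, 2) polygons of (row, col) vertices — the plasma
    membrane.  A synapse inside a soma is at distance 0.
    """
    if not soma_outlines:
        raise ValueError("need at least one soma outline")
    r, c = centroid
    point = Point(c, r)
    best = np.inf
    for outline in soma_outlines:
        outline = np.asarray(outline, dtype=float)
        if len(outline) < 3:
            raise ValueError("soma outline needs at least 3 vertices")
        poly = _ShapelyPolygon([(cc, rr) for rr, cc in outline])
        d = 0.0 if poly.covers(point) else point.distance(poly.exterior)
        best = min(best, d)
    return float(best * pixel_size)


def build_synapse_map(centroids: np.ndarray, image_shape: tuple[int, int],
                      pixel_size: float,
                      soma_outlines: list[np.ndarray] | None = None,
                      ) -> SynapseMap:
    """Density and per-synapse nearest-soma distances for one field of view."""
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float)) \
        if np.size(centroids) else np.empty((0, 2))
    area = image_shape[0] * image_shape[1] * pixel_size ** 2
    dists = None
    if soma_outlines:
        dists = np.array([nearest_soma_distance(tuple(c), soma_outlines, pixel_size)
                          for c in centroids])
    return SynapseMap(centroids=centroids, image_area_um2=area,
                      density_per_um2=len(centroids) / area, distances_um=dists)
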