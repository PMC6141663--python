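"""Calibrated containers, TIFF I/O, ROIs and background subtraction.

Conventions used throughout the package:

* pixel coordinates are 0-based, pixel-centered, ``(row, col)`` order;
* time is expressed relative to stimulus onset (``t = clock - stim_onset``),
  so "before stimulation" means ``t < 0``;
* intensities are arbitrary units ("AU") and are never rescaled implicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class MovieStack:
    """A T x H x W fluorescence time series with acquisition calibration.

    Parameters
    ----------
    frames
        Non-negative intensity array, shape ``(T, H, W)``.
    pixel_size
        Lateral calibration in micrometres per pixel.
    frame_interval
        Seconds per frame.
    stim_onset
        Stimulus start on the movie clock, in seconds.
    channel_label
        Free-text channel description.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    stim_onset: float = 0.0
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or min(self.frames.shape) < 1:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def times(self) -> np.ndarray:
        """Frame times in seconds relative to stimulus onset."""
        return np.arange(self.n_frames) * self.frame_interval - self.stim_onset

    def frame_at(self, t_rel: float) -> int:
        """Index of the frame whose start time is nearest to ``t_rel`` (stimulus-relative)."""
        idx = int(round((t_rel + self.stim_onset) / self.frame_interval))
        return int(np.clip(idx, 0, self.n_frames - 1))


@dataclass
class RegionOfInterest:
    """Polygon or label-mask region, 0-based (row, col) pixel coordinates."""

    kind: str  # "polygon" | "label_mask"
    vertices: np.ndarray | None = None  # (N, 2) array of (row, col)
    mask: np.ndarray | None = None  # boolean H x W

    def __post_init__(self) -> None:
        if self.kind == "polygon":
            if self.vertices is None:
                raise ValueError("polygon ROI requires vertices")
            self.vertices = np.asarray(self.vertices, dtype=float)
            if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
                raise ValueError("vertices must be an (N, 2) array")
            if len(self.vertices) < 3:
                raise ValueError("polygon needs at least 3 vertices")
            poly = self._shapely()
            if not poly.is_valid:
                raise ValueError("polygon is self-intersecting or degenerate")
        elif self.kind == "label_mask":
            if self.mask is None:
                raise ValueError("label_mask ROI requires a mask")
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.ndim != 2:
                raise ValueError("mask must be 2-D")
            if not self.mask.any():
                raise ValueError("mask is empty")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    def _shapely(self) -> _ShapelyPolygon:
        # shapely takes (x, y); we store (row, col) and map col->x, row->y.
        return _ShapelyPolygon([(c, r) for r, c in self.vertices])

    def pixel_area(self) -> float:
        """Area in pixel^2 (shoelace for polygons, pixel count for masks)."""
        if self.kind == "polygon":
            return float(self._shapely().area)
        return float(self.mask.sum())

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize to a boolean mask of the given (H, W) shape, pixel-centre test."""
        if self.kind == "label_mask":
            if self.mask.shape != shape:
                raise ValueError("mask shape does not match image shape")
            return self.mask
        from skimage.draw import polygon as _draw_polygon

        rr, cc = _draw_polygon(self.vertices[:, 0], self.vertices[:, 1], shape)
        out = np.zeros(shape, dtype=bool)
        out[rr, cc] = True
        return out

    def contains(self, row: float, col: float) -> bool:
        if self.kind == "polygon":
            from shapely.geometry import Point

            return bool(self._shapely().buffer(1e-9).contains(Point(col, row)))
        r, c = int(round(row)), int(round(col))
        if 0 <= r < self.mask.shape[0] and 0 <= c < self.mask.shape[1]:
            return bool(self.mask[r, c])
        return False


@dataclass
class AnalysisConfig:
    """Tunable constants of the analysis pipeline.

    Defaults are the operational values used by the study protocol: a
    full-fusion event must complete within 200 ms, a synapse is
    "synchronized" when it responds within 1 s of stimulus onset, a response
    is the first sustained 2-standard-deviation excursion of the trace, and
    synapse puncta must exceed their local neurite by 1,000 AU in both
    channels.
    """

    full_fusion_max_duration: float = 0.2  # s
    sync_window: float = 1.0  # s
    response_sd_factor: float = 2.0
    synapse_intensity_delta: float = 1000.0  # AU
    profile_width: int = 3  # px
    profile_length: float = 4.0  # µm
    # detection
    psf_sigma: float = 1.3  # px
    detect_threshold: float = 5.0  # AU, on the band-passed image
    # fusion-event operationalization (tunable; the source criteria are visual)
    full_fusion_drop_high: float = 0.5  # trace must start >= this x running median
    full_fusion_drop_low: float = 0.1  # ... and fall to <= this x running median
    full_fusion_no_recovery: float = 1.0  # s the trace must stay down
    kr_rise_factor: float = 1.5  # kiss-and-run brightening vs running median
    kr_max_duration: float = 0.5  # s
    kr_width_factor: float = 1.3  # concurrent widening ("cloud")
    # response detection
    baseline_window: tuple[float, float] = (-10.0, -1.0)  # s, stimulus-relative
    response_sustain_frames: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("full_fusion_max_duration", "sync_window", "response_sd_factor",
                     "profile_length", "psf_sigma", "kr_max_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.profile_width < 1:
            raise ValueError("profile_width must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        data = json.loads(Path(path).read_text())
        data.pop("coordinate_convention", None)
        if "baseline_window" in data:
            data["baseline_window"] = tuple(data["baseline_window"])
        return cls(**data)


# ---------------------------------------------------------------------------
# TIFF I/O


def read_movie(path: str | Path, *, pixel_size: float, frame_interval: float,
               stim_onset: float = 0.0, channel_label: str = "") -> MovieStack:
    """Read a single- or multi-page grayscale TIFF as a :class:`MovieStack`.

    Frames are loaded in acquisition (page) order and intensities are kept
    as stored — no rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import logging

    class _Capture(logging.Handler):
        def __init__(self):
            super().__init__(level=logging.ERROR)
            self.records: list[str] = []

        def emit(self, record):
            self.records.append(record.getMessage())

    capture = _Capture()
    tiff_logger = logging.getLogger("tifffile")
    tiff_logger.addHandler(capture)
    try:
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
    except Exception as exc:  # tifffile raises assorted types on truncation
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    finally:
        tiff_logger.removeHandler(capture)
    if capture.records:
        # tifffile logs (rather than raises) on truncated page chains
        raise FormatError(f"corrupt TIFF {path}: {capture.records[0]}")
    if not pages:
        raise FormatError(f"{path} contains no pages")
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise FormatError(f"page {i} of {path} is not grayscale (shape {page.shape})")
        if page.shape != pages[0].shape:
            raise FormatError(
                f"page {i} of {path} has shape {page.shape}, expected {pages[0].shape}")
    frames = np.stack(pages).astype(np.float64)
    return MovieStack(frames, pixel_size=pixel_size, frame_interval=frame_interval,
                      stim_onset=stim_onset, channel_label=channel_label)


def write_movie(movie: MovieStack, path: str | Path, dtype=np.uint16) -> None:
    """Write a movie as a multi-page grayscale TIFF (integer stacks round-trip bit-exactly)."""
    frames = movie.frames
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        frames = np.clip(np.round(frames), info.min, info.max)
    tifffile.imwrite(Path(path), frames.astype(dtype))


# ---------------------------------------------------------------------------
# Background subtraction and ROI geometry


def _frame_mode(frame: np.ndarray) -> float:
    """Mode of the intensity histogram (1-AU bins) — robust floor estimate."""
    finite = frame[np.isfinite(frame)]
    if finite.size == 0:
        return 0.0
    lo = np.floor(finite.min())
    hi = np.ceil(finite.max())
    if hi == lo:
        return float(lo)
    # 1-AU bins centred on integers, so integer-valued data maps to itself
    edges = np.arange(lo - 0.5, hi + 1.5)
    counts, edges = np.histogram(finite, bins=edges)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def subtract_background(movie: MovieStack,
                        bg_roi: RegionOfInterest | None = None) -> MovieStack:
    """Subtract a per-frame scalar background; negatives clamp to 0.

    The scalar is the mean inside ``bg_roi`` when given (the ROI should lie
    outside any cell footprint), otherwise the per-frame intensity mode.
    """
    H, W = movie.shape[1:]
    if bg_roi is not None:
        mask = bg_roi.to_mask((H, W))
        if not mask.any():
            raise ValueError("background ROI is empty or out of bounds")
        bg = movie.frames[:, mask].mean(axis=1)
    else:
        bg = np.array([_frame_mode(f) for f in movie.frames])
    out = np.clip(movie.frames - bg[:, None, None], 0.0, None)
    return MovieStack(out, pixel_size=movie.pixel_size,
                      frame_interval=movie.frame_interval,
                      stim_onset=movie.stim_onset, channel_label=movie.channel_label)


def roi_area(roi: RegionOfInterest, pixel_size: float) -> float:
    """ROI area in µm² (shoelace or pixel count, times ``pixel_size**2``)."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return roi.pixel_area() * pixel_size ** 2


# ---------------------------------------------------------------------------
# ROI (de)serialization — JSON with an explicit coordinate-convention header


def save_rois(rois: Sequence[RegionOfInterest], path: str | Path) -> None:
    payload = {
        "coordinate_convention": "0-based, pixel-centered, (row, col)",
        "rois": [],
    }
    for roi in rois:
        if roi.kind == "polygon":
            payload["rois"].append({"kind": "polygon",
                                    "vertices": roi.vertices.tolist()})
        else:
            rows, cols = np.nonzero(roi.mask)
            payload["rois"].append({"kind": "label_mask",
                                    "shape": list(roi.mask.shape),
                                    "pixels": np.stack([rows, cols], axis=1).tolist()})
    Path(path).write_text(json.dumps(payload))


def load_rois(path: str | Path) -> list[RegionOfInterest]:
    payload = json.loads(Path(path).read_text())
    out = []
    for entry in payload["rois"]:
        if entry["kind"] == "polygon":
            out.append(RegionOfInterest("polygon", vertices=np.asarray(entry["vertices"])))
        else:
            mask = np.zeros(tuple(entry["shape"]), dtype=bool)
            px = np.asarray(entry["pixels"], dtype=int)
            mask[px[:, 0], px[:, 1]] = True
            out.append(RegionOfInterest("label_mask", mask=mask))
    return out
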