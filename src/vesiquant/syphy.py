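"""Synaptic pHluorin (SypHy) trace analysis.

SypHy is quenched inside acidic synaptic vesicles and lights up on
exocytosis or on NH4Cl deprotonation.  Because expression level varies
between cells, every synapse trace is normalized to its own maximum during
NH4Cl application (the total vesicle pool), making responses comparable
across synapses.  A response is the first sustained excursion of the
normalized trace two baseline standard deviations above the baseline mean,
and a synapse is *synchronized* when that response falls within 1 s of
stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import AnalysisConfig, MovieStack, RegionOfInterest
from .ldcv import detect_spots, _disk_mean

RESPONSE_CLASSES = ("pre_stimulus", "synchronized", "delayed", "nonresponsive")


@dataclass
class SynapseTrace:
    roi_id: int
    times: np.ndarray              # s, stimulus-relative
    raw: np.ndarray                # AU, background-subtracted ROI mean
    normalized: np.ndarray | None = None  # fraction of the NH4 plateau
    baseline_mean: float | None = None    # on the normalized trace
    baseline_sd: float | None = None
    response_time: float | None = None    # s, stimulus-relative
    peak: float | None = None             # normalized units above baseline

    def values(self) -> np.ndarray:
        return self.raw if self.normalized is None else self.normalized


# ---------------------------------------------------------------------------


def identify_synapses(movie: MovieStack, nh4_window: tuple[float, float],
                      immobility_tol: float = 1.0, plateau_factor: float = 2.0,
                      config: AnalysisConfig = AnalysisConfig(),
                      ) -> list[RegionOfInterest]:
    """Find synapse ROIs: immobile puncta with a sharp NH4Cl plateau.

    Candidate puncta come from the mean image over ``nh4_window`` (where the
    whole pool fluoresces); a punctum is kept when (a) its centroid drifts at
    most ``immobility_tol`` px across the movie and (b) its NH4-window mean
    intensity is at least ``plateau_factor`` times its pre-NH4 mean.
    Returns one small disk label-mask ROI per synapse.
    """
    times = movie.times()
    in_nh4 = (times >= nh4_window[0]) & (times <= nh4_window[1])
    if not in_nh4.any():
        raise ValueError("nh4_window lies outside the movie span")
    nh4_img = movie.frames[in_nh4].mean(axis=0)
    positions = detect_spots(nh4_img, config.psf_sigma, config.detect_threshold)

    H, W = movie.shape[1:]
    radius = 2.0 * config.psf_sigma
    rois = []
    pre_frames = movie.frames[~in_nh4 & (times < nh4_window[0])]
    for (r, c) in positions:
        # (b) plateau criterion on the local disk mean
        nh4_mean = np.mean([_disk_mean(f, r, c, radius)
                            for f in movie.frames[in_nh4]])
        pre_mean = (np.mean([_disk_mean(f, r, c, radius) for f in pre_frames])
                    if len(pre_frames) else 0.0)
        if pre_mean <= 0 or nh4_mean < plateau_factor * pre_mean:
            continue
        # (a) immobility: centroid drift across the movie
        if _centroid_drift(movie.frames, r, c, radius) > immobility_tol:
            continue
        rr, cc = np.mgrid[0:H, 0:W]
        mask = (rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2
        rois.append(RegionOfInterest("label_mask", mask=mask))
    return rois


def _centroid_drift(frames: np.ndarray, row: float, col: float,
                    radius: float, n_segments: int = 5) -> float:
    """Centroid drift across the movie, from segment-averaged images.

    Splitting the movie into a few segments and taking the centroid of each
    segment's mean image averages out frame noise while still exposing slow
    drift; the result is the maximum distance of any segment centroid from
    the overall mean position.
    """
    H, W = frames.shape[1:]
    r0, r1 = max(0, int(row - 2 * radius)), min(H, int(row + 2 * radius) + 1)
    c0, c1 = max(0, int(col - 2 * radius)), min(W, int(col + 2 * radius) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1].astype(float)
    cents = []
    for segment in np.array_split(frames, min(n_segments, len(frames))):
        patch = segment.mean(axis=0)[r0:r1, c0:c1]
        w = np.clip(patch - np.median(patch), 0.0, None)
        total = w.sum()
        if total <= 0:
            continue
        cents.append(((w * rr).sum() / total, (w * cc).sum() / total))
    if len(cents) < 2:
        return 0.0
    cents = np.asarray(cents)
    center = cents.mean(axis=0)
    return float(np.max(np.hypot(*(cents - center).T)))


def extract_traces(movie: MovieStack, rois: list[RegionOfInterest],
                   ) -> list[SynapseTrace]:
    """ROI-mean raw trace per synapse (movie already background-subtracted)."""
    times = movie.times()
    out = []
    for i, roi in enumerate(rois):
        mask = roi.to_mask(movie.shape[1:])
        raw = movie.frames[:, mask].mean(axis=1)
        out.append(SynapseTrace(roi_id=i, times=times, raw=raw))
    return out


def normalize_to_nh4(trace: SynapseTrace, nh4_window: tuple[float, float],
                     ) -> SynapseTrace:
    """Normalize the raw trace to its maximum inside the NH4Cl window.

    The plateau maximum is the total SypHy pool of the synapse; dividing by
    it removes expression-level differences (the normalized trace is
    invariant to scaling the raw trace by any positive constant).
    """
    in_win = (trace.times >= nh4_window[0]) & (trace.times <= nh4_window[1])
    if not in_win.any():
        raise ValueError("nh4_window lies outside the trace")
    plateau = float(trace.raw[in_win].max())
    if plateau <= 0:
        raise ValueError("non-positive NH4 plateau maximum")
    return replace(trace, normalized=trace.raw / plateau)


def detect_response_time(trace: SynapseTrace,
                         baseline_window: tuple[float, float] = (-10.0, -1.0),
                         sd_factor: float = 2.0,
                         sustain_frames: int = 2,
                         search_end: float | None = None) -> float | None:
    """First sustained crossing of baseline_mean + sd_factor * baseline_sd.

    The crossing must hold for ``sustain_frames`` consecutive frames (single-
    frame noise spikes do not count).  Returns the stimulus-relative time of
    the first crossing frame, or ``None``.  Candidate frames start after the
    baseline window and end at ``search_end`` (which must precede the NH4Cl
    window — the deprotonation plateau is not a stimulus response).
    """
    values = trace.values()
    in_base = (trace.times >= baseline_window[0]) & (trace.times < baseline_window[1])
    if in_base.sum() < 5:
        raise ValueError("baseline window must contain at least 5 samples")
    base_mean = float(values[in_base].mean())
    base_sd = float(values[in_base].std(ddof=1))
    trace.baseline_mean, trace.baseline_sd = base_mean, base_sd
    span = float(values.max() - values.min())
    if base_sd < 1e-9 * span:
        # degenerate (noise-free) baseline: floor the SD at a tiny fraction
        # of the trace's dynamic range so that numerically negligible
        # crosstalk from neighbouring puncta cannot cross the threshold
        base_sd = max(1e-9 * span, 1e-30)

    threshold = base_mean + sd_factor * base_sd
    in_search = trace.times >= baseline_window[1]
    if search_end is not None:
        in_search &= trace.times < search_end
    candidates = np.flatnonzero(in_search & (values >= threshold))
    n = len(values)
    for k in candidates:
        if k + sustain_frames <= n and np.all(values[k:k + sustain_frames] >= threshold):
            return float(trace.times[k])
    return None


def classify_synchronization(response_time: float | None,
                             sync_window: float = 1.0) -> str:
    """Partition a response time into the four synchrony classes."""
    if response_time is None:
        return "nonresponsive"
    if response_time < 0:
        return "pre_stimulus"
    if response_time <= sync_window:
        return "synchronized"
    return "delayed"


def peak_response(trace: SynapseTrace, stim_window: tuple[float, float],
                  ) -> float:
    """Maximum normalized rise above baseline within the stimulation window."""
    if trace.normalized is None:
        raise ValueError("normalize the trace first")
    in_win = (trace.times >= stim_window[0]) & (trace.times <= stim_window[1])
    if not in_win.any():
        raise ValueError("empty stimulation window")
    base = trace.baseline_mean
    if base is None:
        base = float(trace.normalized[trace.times < 0].mean())
    return float(trace.normalized[in_win].max() - base)


def summarize_synchrony(classes: list[str]) -> dict[str, float]:
    """Fractions per class among responders; nonresponders reported separately.

    Returns ``{"pre_stimulus": .., "synchronized": .., "delayed": ..,
    "nonresponsive_fraction": ..}`` where the first three sum to 1 over the
    responding synapses.
    """
    if not classes:
        raise ValueError("empty class list")
    for c in classes:
        if c not in RESPONSE_CLASSES:
            raise ValueError(f"unknown class {c!r}")
    n = len(classes)
    n_nonresp = classes.count("nonresponsive")
    n_resp = n - n_nonresp
    if n_resp == 0:
        raise ValueError("no responding synapses: responder fractions undefined")
    return {
        "pre_stimulus": classes.count("pre_stimulus") / n_resp,
        "synchronized": classes.count("synchronized") / n_resp,
        "delayed": classes.count("delayed") / n_resp,
        "nonresponsive_fraction": n_nonresp / n,
    }


def analyze_syphy_movie(movie: MovieStack, nh4_window: tuple[float, float],
                        config: AnalysisConfig = AnalysisConfig(),
                        stim_window: tuple[float, float] | None = None,
                        ) -> list[SynapseTrace]:
    """Full pipeline: identify synapses, normalize, time and classify responses."""
    rois = identify_synapses(movie, nh4_window, config=config)
    traces = extract_traces(movie, rois)
    out = []
    for tr in traces:
        tr = normalize_to_nh4(tr, nh4_window)
        tr.response_time = detect_response_time(
            tr, config.baseline_window, config.response_sd_factor,
            config.response_sustain_frames, search_end=nh4_window[0])
        if stim_window is not None:
            tr.peak = peak_response(tr, stim_window)
        out.append(tr)
    return out
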