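"""Ground-truthed synthetic scenes for every analysis stage.

Each generator renders an input with known truth (spot positions, fusion
events, Gaussian parameters, calcium maps, colocalization coefficients) so
the corresponding analysis stage can be verified exactly in the noiseless
case.  All randomness flows from a single integer seed; a fixed seed yields
bit-identical output.

The default TIRF protocol mirrors the study design: immobile neuropeptide-
labelled vesicles imaged at 10 Hz, a 30-s 10-Hz pre-stimulus phase, then a
100-Hz stimulus phase during which most fusion occurs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .calcium import FuraCalibration
from .core_io import MovieStack
from .sted import EllipticalGaussianParams, eval_gaussian2d

EVENT_CLASSES = ("full_fusion", "kiss_and_run")

# Default phase layout: label, start s, end s (stimulus-relative).
DEFAULT_PROTOCOL = (("pre_stimulus_10hz", -30.0, 0.0), ("stimulus_100hz", 0.0, 180.0))


@dataclass
class SimulationConfig:
    """Knobs of the TIRF/epifluorescence movie generators.

    Times in ``event_schedule`` are stimulus-relative seconds (stimulus onset
    is t = 0).  ``read_noise_sd`` sets the Gaussian camera noise; with spot
    amplitude ``a`` the per-spot SNR is ``a / read_noise_sd``.
    """

    n_spots: int = 10
    image_shape: tuple[int, int] = (64, 64)
    n_frames: int = 2100          # 30 s pre-stimulus + 180 s stimulus at 10 Hz
    frame_interval: float = 0.1   # s (10 Hz acquisition)
    pixel_size: float = 0.16      # µm
    stim_onset: float = 30.0      # s on the movie clock
    psf_sigma: float = 1.3        # px
    spot_amplitude: float = 200.0  # AU
    amplitude_jitter: float = 0.25  # spots drawn uniform in ±jitter around amplitude
    background: float = 20.0      # AU
    read_noise_sd: float = 0.0    # AU; 0 = noiseless
    poisson_noise: bool = False
    bleach_tau: float = 300.0     # s
    protocol: tuple = DEFAULT_PROTOCOL
    event_schedule: tuple = ()    # ((time_s, spot_id, class), ...)
    # kiss-and-run rendering: transient brightening + widening ("cloud")
    kr_amplitude_factor: float = 2.0
    kr_width_factor: float = 1.5
    kr_duration: float = 0.3      # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spot_amplitude <= 0 or self.background < 0:
            raise ValueError("amplitudes must be positive, background non-negative")
        duration = self.n_frames * self.frame_interval
        for t, spot_id, cls in self.event_schedule:
            if cls not in EVENT_CLASSES:
                raise ValueError(f"unknown event class {cls!r}")
            if not 0 <= spot_id < self.n_spots:
                raise ValueError(f"event scheduled for nonexistent spot {spot_id}")
            clock = t + self.stim_onset
            if not 0.0 <= clock < duration:
                raise ValueError(f"event at t={t} s falls outside the movie")


@dataclass
class SceneGroundTruth:
    """Complete truth record of a generated scene; serializes to JSON."""

    spots: list = field(default_factory=list)      # dicts: row, col, amplitude, ...
    events: list = field(default_factory=list)     # dicts: time_s, spot_id, class
    vesicle_params: list = field(default_factory=list)  # Eq-style parameter dicts
    ca_map: list | None = None                     # nested list, nM
    manders: dict | None = None                    # {"M1": .., "M2": ..}
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self)))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneGroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _render_gaussian_spot(frame: np.ndarray, row: float, col: float,
                          amplitude: float, sigma: float) -> None:
    """Add an isotropic Gaussian spot in place (3.5-sigma support)."""
    H, W = frame.shape
    half = int(np.ceil(3.5 * sigma))
    r0, r1 = max(0, int(row) - half), min(H, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(W, int(col) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1].astype(float)
    frame[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma ** 2))


def _place_spots(rng: np.random.Generator, n: int, shape: tuple[int, int],
                 sigma: float, min_separation: float) -> np.ndarray:
    """Random immobile spot positions with a minimum pairwise separation."""
    margin = 4.0 * sigma
    positions: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(positions) == n:
            break
        r = rng.uniform(margin, shape[0] - 1 - margin)
        c = rng.uniform(margin, shape[1] - 1 - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_separation ** 2
               for pr, pc in positions):
            positions.append((r, c))
    if len(positions) < n:
        raise ValueError(f"cannot place {n} spots with separation "
                         f"{min_separation:.1f} px in a {shape} image")
    return np.array(positions)


def _apply_noise(frames: np.ndarray, rng: np.random.Generator,
                 read_sd: float, poisson: bool) -> np.ndarray:
    if poisson:
        frames = rng.poisson(np.clip(frames, 0.0, None)).astype(float)
    if read_sd > 0:
        frames = frames + rng.normal(0.0, read_sd, size=frames.shape)
    return np.clip(frames, 0.0, None)


def simulate_ldcv_movie(config: SimulationConfig) -> tuple[MovieStack, SceneGroundTruth]:
    """TIRF movie of immobile vesicle puncta with scheduled fusion events.

    A ``full_fusion`` event removes its spot at the scheduled time — the
    punctum disappears within one frame.  A ``kiss_and_run`` event doubles
    the spot amplitude and widens it by 1.5x for 0.3 s (the released cargo
    cloud), after which the spot is lost.  Exponential bleaching acts on all
    amplitudes; noise is added last.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.image_shape
    positions = _place_spots(rng, config.n_spots, (H, W), config.psf_sigma,
                             min_separation=6.0 * config.psf_sigma)
    amplitudes = config.spot_amplitude * rng.uniform(
        1.0 - config.amplitude_jitter, 1.0 + config.amplitude_jitter,
        size=config.n_spots)

    events_by_spot = {spot_id: (t, cls) for t, spot_id, cls in config.event_schedule}
    if len(events_by_spot) < len(config.event_schedule):
        raise ValueError("at most one event per spot is supported")

    frames = np.full((config.n_frames, H, W), float(config.background))
    times = np.arange(config.n_frames) * config.frame_interval - config.stim_onset
    for k, t in enumerate(times):
        bleach = np.exp(-(k * config.frame_interval) / config.bleach_tau)
        for s in range(config.n_spots):
            amp = amplitudes[s] * bleach
            sigma = config.psf_sigma
            if s in events_by_spot:
                t_ev, cls = events_by_spot[s]
                if cls == "full_fusion":
                    if t >= t_ev:
                        continue  # vesicle gone
                else:  # kiss_and_run
                    if t_ev <= t < t_ev + config.kr_duration:
                        amp *= config.kr_amplitude_factor
                        sigma *= config.kr_width_factor
                    elif t >= t_ev + config.kr_duration:
                        continue  # lost after the transient
            _render_gaussian_spot(frames[k], positions[s, 0], positions[s, 1],
                                  amp, sigma)
    frames = _apply_noise(frames, rng, config.read_noise_sd, config.poisson_noise)

    truth = SceneGroundTruth(
        spots=[{"spot_id": s, "row": float(positions[s, 0]),
                "col": float(positions[s, 1]), "amplitude": float(amplitudes[s])}
               for s in range(config.n_spots)],
        events=[{"time_s": float(t), "spot_id": int(s), "class": cls}
                for t, s, cls in config.event_schedule],
        extra={"protocol": [list(p) for p in config.protocol]},
    )
    movie = MovieStack(frames, pixel_size=config.pixel_size,
                       frame_interval=config.frame_interval,
                       stim_onset=config.stim_onset, channel_label="NPY-Venus")
    return movie, truth


def simulate_syphy_movie(config: SimulationConfig, surface_fraction: float,
                         nh4_window: tuple[float, float],
                         response_times: Sequence[float | None] | None = None,
                         response_step_fraction: float | None = None,
                         ) -> tuple[MovieStack, SceneGroundTruth]:
    """Epifluorescence movie of synaptic pHluorin puncta.

    Each synapse carries a total pool ``P`` (its amplitude after NH4Cl
    deprotonation).  The resting punctum shows ``surface_fraction * P``; at
    its programmed response time the trace steps up by
    ``response_step_fraction * P`` (default: another ``surface_fraction``,
    i.e. a doubling); inside ``nh4_window`` (stimulus-relative seconds) the
    punctum shows the full pool.

    ``response_times`` gives one stimulus-relative time (or ``None``) per
    synapse; omitted entirely means no synapse responds.
    """
    if not 0.0 <= surface_fraction <= 1.0:
        raise ValueError("surface_fraction must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    H, W = config.image_shape
    # synapses are sparse puncta on distinct neurites: keep them well apart
    positions = _place_spots(rng, config.n_spots, (H, W), config.psf_sigma,
                             min_separation=10.0 * config.psf_sigma)
    pools = config.spot_amplitude * rng.uniform(
        1.0 - config.amplitude_jitter, 1.0 + config.amplitude_jitter,
        size=config.n_spots)
    if response_times is None:
        response_times = [None] * config.n_spots
    if len(response_times) != config.n_spots:
        raise ValueError("need one response time (or None) per synapse")
    step = surface_fraction if response_step_fraction is None else response_step_fraction

    frames = np.full((config.n_frames, H, W), float(config.background))
    times = np.arange(config.n_frames) * config.frame_interval - config.stim_onset
    for k, t in enumerate(times):
        in_nh4 = nh4_window[0] <= t <= nh4_window[1]
        for s in range(config.n_spots):
            if in_nh4:
                amp = pools[s]
            else:
                amp = surface_fraction * pools[s]
                t_r = response_times[s]
                if t_r is not None and t >= t_r:
                    amp += step * pools[s]
            _render_gaussian_spot(frames[k], positions[s, 0], positions[s, 1],
                                  amp, config.psf_sigma)
    frames = _apply_noise(frames, rng, config.read_noise_sd, config.poisson_noise)

    truth = SceneGroundTruth(
        spots=[{"spot_id": s, "row": float(positions[s, 0]),
                "col": float(positions[s, 1]), "pool": float(pools[s]),
                "response_time_s": (None if response_times[s] is None
                                    else float(response_times[s]))}
               for s in range(config.n_spots)],
        extra={"surface_fraction": surface_fraction,
               "nh4_window": list(nh4_window),
               "response_step_fraction": step},
    )
    movie = MovieStack(frames, pixel_size=config.pixel_size,
                       frame_interval=config.frame_interval,
                       stim_onset=config.stim_onset, channel_label="SypHy")
    return movie, truth


def render_sted_vesicles(params: Sequence[EllipticalGaussianParams],
                         image_shape: tuple[int, int],
                         noise_sd: float = 0.0, seed: int = 0,
                         ) -> tuple[np.ndarray, SceneGroundTruth]:
    """Sum of correlated-Gaussian vesicle surfaces plus optional noise."""
    H, W = image_shape
    for p in params:
        half = 3.0 * max(p.x_width, p.y_width)
        if not (half <= p.x0 <= W - 1 - half and half <= p.y0 <= H - 1 - half):
            raise ValueError(f"vesicle at ({p.x0}, {p.y0}) too close to the border")
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    image = np.zeros((H, W))
    for p in params:
        image += eval_gaussian2d(p, xx, yy)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    truth = SceneGroundTruth(vesicle_params=[
        {"A": p.A, "x0": p.x0, "y0": p.y0, "x_width": p.x_width,
         "y_width": p.y_width, "cor": p.cor, "offset": p.offset}
        for p in params])
    return image, truth


def simulate_fura_pair(true_ca: np.ndarray, calib: FuraCalibration,
                       f380_level: float = 1000.0, noise_sd: float = 0.0,
                       seed: int = 0,
                       ) -> tuple[np.ndarray, np.ndarray, SceneGroundTruth]:
    """Fura-2 350/380 image pair whose ratio encodes a known calcium map.

    Inverts [Ca2+] = Kd * beta * (R - Rmin) / (Rmax - R) pixelwise:
    ``R = (Kd*beta*Rmin + ca*Rmax) / (Kd*beta + ca)``, which is < Rmax for
    every finite non-negative concentration, so the noiseless round trip
    through ``ratio_image`` and ``calcium_from_ratio`` is exact.
    """
    true_ca = np.asarray(true_ca, dtype=float)
    if not np.all(np.isfinite(true_ca)) or np.any(true_ca < 0):
        raise ValueError("true_ca must be finite and non-negative")
    kb = calib.K_d * calib.beta
    ratio = (kb * calib.R_min + true_ca * calib.R_max) / (kb + true_ca)
    f380 = np.full_like(true_ca, float(f380_level))
    f350 = ratio * f380
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f350 = np.clip(f350 + rng.normal(0.0, noise_sd, f350.shape), 0.0, None)
        f380 = np.clip(f380 + rng.normal(0.0, noise_sd, f380.shape), 0.0, None)
    truth = SceneGroundTruth(ca_map=true_ca.tolist(),
                             extra={"f380_level": float(f380_level)})
    return f350, f380, truth


def simulate_coloc_pair(n_pixels: int, overlap_fraction: float, seed: int = 0,
                        image_shape: tuple[int, int] = (32, 32),
                        intensity: float = 100.0,
                        ) -> tuple[np.ndarray, np.ndarray, SceneGroundTruth]:
    """Two-channel binary-support pair with a controllable co-occurrence.

    Each channel occupies ``n_pixels`` uniform-intensity pixels; a fraction
    ``overlap_fraction`` (rounded to whole pixels) of them is shared.  The
    true Manders coefficients are computed from the constructed supports and
    stored in the ground truth.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    H, W = image_shape
    if 2 * n_pixels > H * W:
        raise ValueError("supports would not fit in the image")
    rng = np.random.default_rng(seed)
    n_shared = int(round(overlap_fraction * n_pixels))
    order = rng.permutation(H * W)
    shared = order[:n_shared]
    only_a = order[n_shared:n_pixels]
    only_b = order[n_pixels:2 * n_pixels - n_shared]

    a = np.zeros(H * W)
    b = np.zeros(H * W)
    a[shared] = a[only_a] = intensity
    b[shared] = b[only_b] = intensity
    a = a.reshape(H, W)
    b = b.reshape(H, W)

    sup_a, sup_b = a > 0, b > 0
    m1 = float(a[sup_b].sum() / a[sup_a].sum()) if sup_a.any() else np.nan
    m2 = float(b[sup_a].sum() / b[sup_b].sum()) if sup_b.any() else np.nan
    truth = SceneGroundTruth(manders={"M1": m1, "M2": m2},
                             extra={"n_pixels": n_pixels,
                                    "overlap_fraction": overlap_fraction})
    return a, b, truth
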