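"""Ratiometric Fura-2 calcium: background-subtracted 350/380 ratio images
converted to concentration with an in-situ calibration.

The conversion is the classic ratiometric relation

    [Ca2+] = K_d * beta * (R - R_min) / (R_max - R)

with R = F350/F380, the dissociation constant ``K_d`` (nM), the limiting
ratios ``R_min`` (calcium-free) and ``R_max`` (saturating), and
``beta = F380_min / F380_max``.  Default constants come from a whole-cell
patch-clamp calibration: R_max 3.73, R_min 0.64, K_d 350 nM, beta 6.73.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FuraCalibration:
    R_max: float = 3.73
    R_min: float = 0.64
    K_d: float = 350.0  # nM
    beta: float = 6.73  # F380_min / F380_max

    def __post_init__(self) -> None:
        if not self.R_max > self.R_min > 0:
            raise ValueError("need R_max > R_min > 0")
        if self.K_d <= 0 or self.beta <= 0:
            raise ValueError("K_d and beta must be > 0")


def ratio_image(f350: np.ndarray, f380: np.ndarray, bg350: float = 0.0,
                bg380: float = 0.0, min_f380: float = 1.0,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted F350/F380 ratio with a validity mask.

    Pixels whose background-subtracted F380 falls below ``min_f380`` carry
    no usable signal and are masked out (ratio set to NaN, mask False).
    """
    f350 = np.asarray(f350, dtype=float)
    f380 = np.asarray(f380, dtype=float)
    if f350.shape != f380.shape:
        raise ValueError(f"shape mismatch: {f350.shape} vs {f380.shape}")
    if min_f380 <= 0:
        raise ValueError("min_f380 must be > 0")
    num = f350 - bg350
    den = f380 - bg380
    valid = den >= min_f380
    ratio = np.full(f350.shape, np.nan)
    ratio[valid] = num[valid] / den[valid]
    return ratio, valid


def calcium_from_ratio(R, calib: FuraCalibration = FuraCalibration(),
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Convert ratio values to [Ca2+] in nM.

    Returns ``(ca, flags)`` of the input shape.  Flags: 0 = in range,
    1 = below R_min (clamped to 0 nM — sub-floor ratios are noise),
    2 = at/above R_max (masked NaN — the relation diverges at R_max and a
    capped value would be fabricated), 3 = input NaN (propagated).
    """
    R = np.asarray(R, dtype=float)
    ca = np.empty(R.shape)
    flags = np.zeros(R.shape, dtype=np.uint8)

    nan_in = np.isnan(R)
    low = ~nan_in & (R < calib.R_min)
    high = ~nan_in & (R >= calib.R_max)
    ok = ~(nan_in | low | high)

    ca[ok] = calib.K_d * calib.beta * (R[ok] - calib.R_min) / (calib.R_max - R[ok])
    ca[low] = 0.0
    ca[high] = np.nan
    ca[nan_in] = np.nan
    flags[low] = 1
    flags[high] = 2
    flags[nan_in] = 3
    if R.ndim == 0:
        return float(ca), int(flags)
    return ca, flags


def calcium_map(f350: np.ndarray, f380: np.ndarray,
                calib: FuraCalibration = FuraCalibration(), *,
                bg350: float = 0.0, bg380: float = 0.0, min_f380: float = 1.0,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline: ratio then conversion; returns (ca nM, flags)."""
    ratio, valid = ratio_image(f350, f380, bg350, bg380, min_f380)
    ca, flags = calcium_from_ratio(ratio, calib)
    return ca, flags
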