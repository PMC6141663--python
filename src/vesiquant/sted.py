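"""Vesicle morphometry from STED patches: correlated elliptical Gaussian fits.

The intensity model of a single vesicle is

    f(x, y) = A * exp[ -1/(2*(1-cor^2)) * ( ((x-x0)/x_width)^2
              + ((y-y0)/y_width)^2
              - 2*cor*(x-x0)*(y-y0)/(x_width*y_width) ) ] + offset

with amplitude ``A``, center ``(x0, y0)``, per-axis widths and a
cross-correlation term ``cor`` in (-1, 1) that tilts the elliptical
iso-intensity contours.  Note that with this parameterization the intensity
at ``x0 ± x_width`` (cor = 0) is ``A·e^(-1/2)``, i.e. the width parameters
play the role of Gaussian sigmas even though they are conventionally named
half widths; reported FWHM values follow the formula, not the name (see the
methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares


@dataclass
class EllipticalGaussianParams:
    A: float
    x0: float
    y0: float
    x_width: float
    y_width: float
    cor: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("amplitude A must be > 0")
        if self.x_width <= 0 or self.y_width <= 0:
            raise ValueError("widths must be > 0")
        if not -1.0 < self.cor < 1.0:
            raise ValueError("cor must lie strictly between -1 and 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.x0, self.y0, self.x_width, self.y_width,
                         self.cor, self.offset])

    @classmethod
    def from_array(cls, arr) -> "EllipticalGaussianParams":
        return cls(*[float(v) for v in arr])


@dataclass
class FitDiagnostics:
    rss: float
    converged: bool
    n_iterations: int
    param_stderr: np.ndarray | None = None


def eval_gaussian2d(params: EllipticalGaussianParams, x, y):
    """Evaluate the correlated 2-D Gaussian at coordinates ``(x, y)`` (array-ok)."""
    if not -1.0 < params.cor < 1.0:
        raise ValueError("cor must lie strictly between -1 and 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = (x - params.x0) / params.x_width
    dy = (y - params.y0) / params.y_width
    q = dx * dx + dy * dy - 2.0 * params.cor * dx * dy
    return params.A * np.exp(-q / (2.0 * (1.0 - params.cor ** 2))) + params.offset


def render_patch(params: EllipticalGaussianParams, shape: tuple[int, int]) -> np.ndarray:
    """Render the model on an (H, W) pixel grid; x ≡ column, y ≡ row."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return eval_gaussian2d(params, xx, yy)


def moments_init(patch: np.ndarray) -> EllipticalGaussianParams:
    """Moment-based initial guess: centroid, second central moments, mixed moment."""
    patch = np.asarray(patch, dtype=float)
    floor = float(np.median(patch))
    amp = float(patch.max()) - floor
    if amp <= 0:
        raise ValueError("flat patch: max does not exceed median")
    w = np.clip(patch - floor, 0.0, None)
    total = w.sum()
    yy, xx = np.mgrid[0:patch.shape[0], 0:patch.shape[1]].astype(float)
    x0 = float((w * xx).sum() / total)
    y0 = float((w * yy).sum() / total)
    vx = float((w * (xx - x0) ** 2).sum() / total)
    vy = float((w * (yy - y0) ** 2).sum() / total)
    vxy = float((w * (xx - x0) * (yy - y0)).sum() / total)
    sx = max(np.sqrt(max(vx, 1e-6)), 0.3)
    sy = max(np.sqrt(max(vy, 1e-6)), 0.3)
    cor = float(np.clip(vxy / (sx * sy), -0.95, 0.95))
    return EllipticalGaussianParams(A=amp, x0=x0, y0=y0, x_width=sx, y_width=sy,
                                    cor=cor, offset=max(floor, 0.0))


def fit_vesicle(patch: np.ndarray,
                init: EllipticalGaussianParams | None = None,
                *, fit_offset: bool = True,
                max_iterations: int = 200,
                ) -> tuple[EllipticalGaussianParams, FitDiagnostics]:
    """Bounded nonlinear least-squares fit of the correlated Gaussian to a patch.

    Parameters
    ----------
    patch
        Image patch, at least 7 x 7 pixels.
    init
        Starting parameters; a moments-based guess when omitted.
    fit_offset
        Include an additive baseline. Pin to 0 (``False``) to match the bare
        six-parameter model.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 7:
        raise ValueError("patch must be at least 7 x 7 pixels")
    if np.allclose(patch, patch.flat[0]):
        raise ValueError("all-equal patch cannot be fitted")
    if init is None:
        init = moments_init(patch)
    if not fit_offset:
        init = replace(init, offset=0.0)

    yy, xx = np.mgrid[0:patch.shape[0], 0:patch.shape[1]].astype(float)
    flat = patch.ravel()

    def unpack(v):
        if fit_offset:
            a, x0, y0, sx, sy, cor, off = v
        else:
            a, x0, y0, sx, sy, cor = v
            off = 0.0
        return EllipticalGaussianParams(a, x0, y0, sx, sy, cor, off)

    def residuals(v):
        p = unpack(v)
        return eval_gaussian2d(p, xx, yy).ravel() - flat

    H, W = patch.shape
    lo = [1e-9, -2.0, -2.0, 0.3, 0.3, -0.99]
    hi = [np.inf, W + 1.0, H + 1.0, float(max(H, W)), float(max(H, W)), 0.99]
    v0 = [init.A, init.x0, init.y0,
          np.clip(init.x_width, 0.31, max(H, W) - 1e-6),
          np.clip(init.y_width, 0.31, max(H, W) - 1e-6),
          np.clip(init.cor, -0.95, 0.95)]
    if fit_offset:
        lo.append(-np.inf)
        hi.append(np.inf)
        v0.append(init.offset)

    result = least_squares(residuals, v0, bounds=(lo, hi),
                           max_nfev=max_iterations * (len(v0) + 1),
                           xtol=1e-12, ftol=1e-12, gtol=1e-12)
    params = unpack(result.x)
    rss = float(2.0 * result.cost)

    stderr = None
    dof = flat.size - len(result.x)
    if result.success and dof > 0:
        try:
            jtj = result.jac.T @ result.jac
            cov = np.linalg.pinv(jtj) * (rss / dof)
            stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            stderr = None
    diag = FitDiagnostics(rss=rss, converged=bool(result.success),
                          n_iterations=int(result.nfev), param_stderr=stderr)
    return params, diag


def vesicle_size(params: EllipticalGaussianParams, pixel_size_um: float,
                 *, converged: bool = True) -> dict[str, float]:
    """Vesicle size in nanometres from fitted widths.

    Returns mean half width (``(x_width + y_width)/2 * pixel``), and per-axis
    full widths (``2 * width * pixel``).
    """
    if not converged:
        raise ValueError("refusing to report sizes from an unconverged fit")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size must be > 0")
    nm = pixel_size_um * 1000.0
    return {
        "mean_hwhm_nm": 0.5 * (params.x_width + params.y_width) * nm,
        "fwhm_x_nm": 2.0 * params.x_width * nm,
        "fwhm_y_nm": 2.0 * params.y_width * nm,
    }
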