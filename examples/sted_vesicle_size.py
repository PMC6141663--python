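"""Measure vesicle sizes from a STED patch with a correlated Gaussian fit.

A vesicle is rendered as a tilted elliptical Gaussian at 25 nm pixels with
shot-to-shot noise, refit from a moments-based initial guess, and its full
widths converted to nanometres.
"""

from vesiquant import (EllipticalGaussianParams, fit_vesicle,
                       render_sted_vesicles, vesicle_size)

true = EllipticalGaussianParams(A=180.0, x0=15.3, y0=14.6,
                                x_width=2.4, y_width=1.8, cor=0.35)
patch, truth = render_sted_vesicles([true], (31, 31), noise_sd=9.0, seed=5)

fit, diag = fit_vesicle(patch, fit_offset=False)
size = vesicle_size(fit, pixel_size_um=0.025, converged=diag.converged)

print(f"converged: {diag.converged} (RSS {diag.rss:.1f})")
print(f"amplitude : {fit.A:7.1f} AU   (true {true.A})")
print(f"center    : ({fit.x0:.2f}, {fit.y0:.2f}) px  "
      f"(true ({true.x0}, {true.y0}))")
print(f"widths    : {fit.x_width:.2f} x {fit.y_width:.2f} px  "
      f"(true {true.x_width} x {true.y_width})")
print(f"cor       : {fit.cor:+.2f}          (true {true.cor:+.2f})")
print(f"FWHM      : {size['fwhm_x_nm']:.0f} x {size['fwhm_y_nm']:.0f} nm, "
      f"mean half width {size['mean_hwhm_nm']:.0f} nm")
# At SNR 20 the fitted widths land within a few percent of the rendered
# truth; FWHM = 2 * width * 25 nm places this vesicle near 120 x 90 nm.
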