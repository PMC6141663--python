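"""Manders colocalization and synapse enrichment from line profiles.

Part 1 measures Manders coefficients on a synthetic two-channel pair with a
known 60% co-occurrence.  Part 2 builds three-pixel-wide line profiles
across synthetic synapses on a neurite, aligns them on the reference-channel
maximum, and computes the enrichment fold of a second marker at the synapse
relative to the flanking neurite.
"""

import numpy as np

from vesiquant import (align_and_average_profiles, enrichment_fold,
                       extract_line_profile, manders_coefficients,
                       simulate_coloc_pair)

# --- Manders on a constructed pair -------------------------------------
a, b, truth = simulate_coloc_pair(n_pixels=300, overlap_fraction=0.6, seed=2)
res = manders_coefficients(a, b)
print(f"Manders M1 = {res.M1:.3f}, M2 = {res.M2:.3f} "
      f"(constructed truth {truth.manders['M1']:.3f})")

# --- aligned line profiles and enrichment ------------------------------
pixel_size = 0.1  # um
rng = np.random.default_rng(4)
profiles = {"syb2": [], "caps": []}
for _ in range(30):
    img_ref = np.full((60, 60), 20.0)   # neurite baseline, reference marker
    img_sec = np.full((60, 60), 50.0)   # second marker along the neurite
    offset = rng.integers(-5, 6)        # synapse is not always path-centred
    row, col = 30, 30 + offset
    yy, xx = np.mgrid[0:60, 0:60]
    bump = np.exp(-((yy - row) ** 2 + (xx - col) ** 2) / (2 * 2.0 ** 2))
    img_ref = img_ref + 500.0 * bump
    img_sec = img_sec + 180.0 * bump    # enriched at the synapse
    path = [(30.0, 10.0), (30.0, 50.0)]  # 4 um at 0.1 um/px
    profiles["syb2"].append(
        extract_line_profile(img_ref, path, width=3, pixel_size=pixel_size))
    profiles["caps"].append(
        extract_line_profile(img_sec, path, width=3, pixel_size=pixel_size))

avg = align_and_average_profiles(profiles, reference="syb2")
pos, mean_caps, sem = avg["caps"]
fold = enrichment_fold(pos, mean_caps, center_halfwidth=0.2,
                       flank_window=(1.0, 1.8))
print(f"second-marker enrichment at synapses: {fold:.2f}-fold over the "
      f"adjacent neurite")
# Aligning on the reference maximum before averaging keeps the synaptic
# peak sharp despite the random offsets; the fold compares the central
# +-0.2 um of the averaged profile to the 1.0-1.8 um flanks.
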