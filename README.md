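# vesiquant

Quantitative analysis of vesicle-exocytosis fluorescence imaging, built for
studies of regulated secretion in neurons: large dense-core vesicle (LDCV)
fusion at the TIRF footprint, synaptic-vesicle transmission reported by
pHluorin probes, super-resolution vesicle morphometry, two-channel
colocalization at synapses, and ratiometric calcium imaging.  Every
analysis stage ships with a ground-truthed synthetic-scene generator, so
the whole pipeline is verifiable end to end without any raw recordings.

## What it computes

**LDCV exocytosis (TIRF).**  Immobile NPY-labelled vesicle puncta are
detected at the cell footprint and their fixed-position traces classified
into fusion events: *full fusion* (disappearance of the punctum within
200 ms, no recovery) or *kiss and run* (brief brightening with a widening
cloud of released cargo, then loss).  Summary statistics follow the
field's conventions — cumulative exocytosis normalized as
`n(t) · A_cohort / A_footprint`, vesicle density per footprint area, and
release probability `P_r = n_events / n_vesicles`.

**Synaptic pHluorin (SypHy).**  Synapses are immobile puncta with a sharp
NH4Cl response; each trace is normalized to its NH4-revealed total pool
(`F/F_NH4`), making results independent of expression level.  The response
time is the first sustained crossing of `mean + 2·SD` of the baseline
fluctuation, and synapses are classified as pre-stimulus, synchronized
(within 1 s of stimulus onset), delayed, or nonresponsive.

**Vesicle morphometry (STED).**  Vesicle patches are fitted with a
correlated elliptical Gaussian

    f(x,y) = A·exp[−1/(2(1−cor²)) (((x−x0)/x_w)² + ((y−y0)/y_w)²
             − 2·cor·(x−x0)(y−y0)/(x_w·y_w))]

and sizes reported as FWHM per axis (`2·w·pixel`) and mean half width.

**Colocalization & mapping.**  Manders coefficients (M1, M2) on neurite
ROIs; synapse selection by a dual-channel ≥ 1,000 AU-over-neurite rule;
3-px-wide, ~4-µm line profiles across synapses, aligned on the
reference-channel maximum before averaging; enrichment folds
(synapse / flanking neurite); synapse density and distance-to-soma maps.

**Ratiometric calcium (Fura-2).**  Background-subtracted 350/380 ratios
converted with `[Ca²⁺] = K_d·β·(R−R_min)/(R_max−R)` using an in-situ
calibration (defaults R_max 3.73, R_min 0.64, K_d 350 nM, β 6.73);
saturated ratios are masked, sub-floor ratios clamp to 0 nM with a flag.

## Worked example

`examples/ldcv_fusion_events.py` simulates a 20-s TIRF movie of ten
vesicles with three scheduled fusion events at SNR 10, then analyzes it
blind to the schedule:

```
vesicles at the footprint : 10
footprint area            : 104.9 um^2
vesicle density           : 0.0954 /um^2
  kiss_and_run  at t = +6.5 s (row 24.7, col 54.0)
  full_fusion   at t = +9.0 s (row 56.2, col 52.2)
  full_fusion   at t = +2.0 s (row 50.4, col 41.9)
release probability       : 0.30
scheduled ground truth    : [('full_fusion', 2.0), ('kiss_and_run', 6.5), ('full_fusion', 9.0)]
```

All three events are recovered with the correct class, time and position;
the release probability is events/vesicles = 3/10.  The other scripts in
`examples/` walk through the SypHy classifier, the STED fit, the
colocalization/profile analysis and the calcium conversion the same way.

A thin CLI wraps the same library calls for batch use:
`vesiquant simulate | ldcv | syphy | sted-fit | coloc | calcium`
(see `vesiquant <subcommand> --help`).

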