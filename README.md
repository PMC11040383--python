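# strobomech

Stroboscopic optical mechanotyping of adherent cells: recover per-pixel
complex dynamic shear modulus maps, `G = G' + iG''`, of a whole field of
live adherent cells from their micro-oscillations under acoustic shear.

## Who this is for, and what it does

Cell viscoelasticity tracks cell type, cycle, differentiation and disease
state, but the standard tools (AFM, micropipettes, optical tweezers) probe
one position on one cell at a time.  This package implements the analysis
side of a high-content alternative: an ultrasonic transducer shears the
fluid above an adherent culture with Gaussian-windowed bursts at a carrier
frequency `f0` (~30 kHz), a fast camera images the resulting micro-motions
*stroboscopically* — one frame per burst at a frame rate detuned by
`N/(N+1)` so that N frames sweep one full oscillation — and homodyne
(lock-in) detection extracts, per 5 x 5 px DIC box, the complex displacement
phasor at `f0`.

The chain from images to mechanics:

1. **Stress.**  Tracer beads (radius `R_b`) resting on the dish are tracked
   (PTV), their per-sub-FOV homodyne velocity phasors `u_k` interpolated into
   a flow field, and the wall shear stress obtained from the vertical
   velocity gradient, `sigma_k = mu * u_k / R_b`.
2. **Strain.**  Digital image correlation against an averaged rest reference
   gives per-box displacements; homodyne detection gives phasor maps
   `delta_k`; spatial derivatives give the two shear strains
   `gamma_p = d(dx)/dx + d(dy)/dy` and `gamma_s = d(dx)/dy + d(dy)/dx`.
3. **Modulus.**  Per box, `1/G_p = (1/sigma_x) d(dx)/dx + (1/sigma_y) d(dy)/dy`
   (and the analogous `1/G_s`), with `G = (G_p + G_s)/2`; the storage modulus
   `G'` is its real part, the loss modulus `G''` its imaginary part.
4. **Statistics.**  Fluorescence channels are segmented (background
   subtraction + Otsu, overlap removal); each DIC box fully inside a mask is
   labelled and populations are compared with Mann–Whitney U tests, edge
   profiles and loss-versus-storage distributions; the run report carries a
   measured error budget.

A synthetic-experiment generator renders stroboscopic stacks, bead frames
and fluorescence channels from scenes with *known* complex moduli, so the
entire chain is verifiable by parameter recovery.

## Worked example

`examples/` holds one short script per capability.  The end-to-end recovery
example renders a reduced co-culture (256 x 256 px, six cells from two
populations with median |G| of 4.4 and 6.3 kPa, 250 strobe frames) and runs
the full analysis:

```text
$ python examples/03_parameter_recovery.py
  reference_image  ok          0.0 s
  bead_tracking    ok          5.6 s
  dic              ok         19.1 s
  mechanics        ok          0.0 s
  segmentation     ok          0.7 s
  statistics       ok          0.0 s
  blank_noise      ok          0.0 s

labelled DIC boxes: 180 (of 2209 valid boxes)
  green   median |G| =  4.55 kPa (truth  4.40 kPa, error  +3.4%), loss angle 0.77 rad
  orange  median |G| =  6.63 kPa (truth  6.30 kPa, error  +5.2%), loss angle 0.81 rad
Mann-Whitney green vs orange: p = 2.75e-28
```

The recovered medians sit within a few percent of the generated truth — far
inside the method's ~30% error budget — and the two mechanotypes separate
decisively.  `examples/01_pulse_and_strobe.py` shows the drive and the
stroboscopic time base, `02_homodyne_lockin.py` the ~22x lock-in SNR gain,
and `04_error_budget.py` the error propagation.

A thin CLI wraps the same library for shell use:

```bash
strobomech simulate --out data/ --seed 0        # render + write a run manifest
strobomech run --config data/run.yaml --out out/
strobomech stats --table out/boxes.csv
```

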