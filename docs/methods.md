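# Methods

## The measurement model

An adherent cell layer in a petri dish is sheared by an oscillating radial
fluid flow at an ultrasonic carrier frequency `f0` (30–45 kHz here), driven
by Gaussian-windowed sine bursts

    f(t) = exp(-alpha^2 (t - t0)^2) * sin(2 pi f0 t),

repeated `N` times at `f_repet` (1 kHz), with the envelope centred in each
repetition period, `t0 = 1/(2 f_repet)`.  Bursts rather than a continuous
tone prevent acoustic standing waves.  (The burst spectrum is implemented
exactly as the time-domain formula above; no constraint is placed on its
nominal spectral width.)

A fast camera triggered at `f_strob = N/(N+1) * f_repet` takes one frame per
pulse.  Because the frame rate is slightly detuned from the repetition rate,
frame `n` samples the oscillation at effective time `n * dt` with
`dt = 1/f_strob - 1/f_repet = 1/(N f_repet)` — for N = 1000 pulses a 1 MHz
effective sampling rate, comfortably above the 2·f0 Nyquist requirement,
obtained at a ~1 kHz real frame rate over a full field of view.  `N_aq = 3N/2`
frames are acquired; the trailing N/2 frames see the sample at rest and are
averaged into the DIC reference image.

### Homodyne (lock-in) detection

Every time series in the chain — per-box DIC displacements, per-sub-FOV bead
displacements — is reduced to the complex coefficient of the Fourier bin
nearest `f0` on the reconstructed time base, normalised as
`(2/N) * sum_n x_n exp(-i 2 pi f0 t_n)`.  Under this convention a signal
`Re[X exp(+i 2 pi f0 t)]` returns its phasor `X`; a cosine of amplitude A
returns A at phase 0.  All downstream phases share the convention, so the
complex modulus is convention-independent, and a strain that lags the stress
produces a positive loss modulus.  With N = 1000 and `f_repet` = 1 kHz the
frequency grid spacing is exactly 1 kHz, so 30 and 45 kHz carriers fall on a
bin and no windowing is applied (the bursts are already Gaussian-windowed).
The projection integrates over the whole record, so any echo folded back by
the stroboscopic sampling is treated as signal.  Single-bin detection rejects
all off-carrier noise: the amplitude-estimate SNR improves by `sqrt(N/2)`
(~22x at N = 1000) over per-sample readout.

### Stress from tracer beads

Non-fluorescent beads of radius `R_b = 1.5 um` rest on the dish bottom and
follow the gap flow (Stokes number ~1e-2; no inertia or Faxén corrections).
Detection inverts each frame around its median, smooths at half the bead
radius, finds thresholded local maxima, and refines centroids by an iterated
intensity-weighted mean.  Linking is frame-to-frame nearest-neighbour with a
gate of half the median inter-particle distance (PTV is only valid when
displacements stay below inter-distances); ambiguous links are dropped and
counted, and only tracks complete over all frames enter the flow estimate.

The field of view is divided into the largest `n x n` grid for which every
sub-FOV holds at least five complete tracks.  Per sub-FOV and direction, bead
displacements are averaged over particles, homodyne-detected, and converted
to a *velocity* phasor by `i 2 pi f0` — the quantity in the wall-stress law

    sigma_k = mu * u_k(z = R_b) / R_b ,    k in {x, y},

with `mu` the medium viscosity (water at room temperature, 1.0e-3 Pa s).
The velocity reading is what makes the stress dimensionally a pressure and an
in-phase elastic response a real modulus; a configuration switch
(`velocity=False` in `homodyne_flow`) exposes the literal displacement-based
reading for sensitivity checks.  The per-pixel field is an order-2 tensor
spline through the sub-FOV centres (order reduced when n < 3), with constant
extrapolation outside the centre hull.  The flow-field error is the RMS
residual between each complete track's own homodyne phasor and the
interpolated field at its mean position, relative to the RMS field value.

### Cell motion, strains and moduli

Cell motion is measured by block-matching DIC against the rest reference:
non-overlapping 5 x 5 px comparison boxes (2.57 um at the 0.514 um/px fast
camera pitch — the DIC box, the statistical unit of all population
statistics), normalized cross-correlation over an integer search window
(default radius 10 px in the operator, 4 px in the pipeline configuration
since displacements are at most a few pixels), then sub-pixel refinement by
two Gauss–Newton steps against the reference patch: the first uses
spectrally exact reference gradients and a free intensity offset at the
integer peak, the second re-evaluates the residual against the cubic-spline
resampled reference at the refined position.  Two steps remove the
linearization bias that appears when noise makes the integer peak jitter by
one pixel; at a perfect match the correction is identically zero, so
noise-free integer shifts are recovered exactly.  Boxes with reference-patch
standard deviation under 1 gray level, or whose search window leaves the
image, are invalid; frames whose correlation peak falls below 0.2 are NaN and
a box with more than 5% such frames is dropped.  Invalid boxes are excluded
downstream, never interpolated.

Strains are central differences (one-sided at borders) of the homodyne
displacement phasor maps on the box grid:

    gamma_p = d(dx)/dx + d(dy)/dy        gamma_s = d(dx)/dy + d(dy)/dx .

The first combination is named "pure shear" for continuity with the
compliance inversion below, although in standard continuum nomenclature it is
the planar divergence (conventional pure shear is `d(dx)/dx - d(dy)/dy`).
A strain box is valid only when every displacement box its stencil touches is
valid.  The compliances

    1/G_p = (1/sigma_x) d(dx)/dx + (1/sigma_y) d(dy)/dy
    1/G_s = (1/sigma_x) d(dx)/dy + (1/sigma_y) d(dy)/dx

are summed over the directions whose stress amplitude exceeds 0.1x the larger
of the two (with one direction excluded the remaining term alone defines the
compliance — the single-component limit G = sigma/gamma, with no factor-2
rescaling); the reported dynamic modulus is `G = (G_p + G_s)/2`, degrading to
whichever of the two is valid (the `source` map records which), with
`G' = Re G` (storage) and `G'' = Im G` (loss).  How the compliance sum should
be weighted when both stress components are comparable is an open modelling
choice; the plain sum is used.  Strains and moduli are computed on the native
DIC-box grid; warping into fluorescence coordinates (known 2x3 affine,
bilinear on real and imaginary parts) is used for labelling boxes against
masks and for exporting aligned maps, which avoids differentiating resampled
data.

### Segmentation and statistics

Per fluorescence channel, >= 10 images are averaged, the long-range
illumination background (Gaussian blur with sigma of a quarter of the smaller
image dimension, i.e. a +-2-sigma support spanning half the image — the blur
parameterization is a declared convention) is subtracted, and the result is
Otsu-thresholded with a noise floor of 4 robust standard deviations so a
cell-free image yields an essentially empty mask.  Pixels claimed by several
channels (cell lines in contact) are removed from every mask and the overlap
fraction reported.  A DIC box is labelled with a channel only if its entire
5 x 5 px footprint maps inside that channel's mask; boundary boxes stay
unassigned so mask edges never dilute a population.  Distance-to-edge is the
Euclidean distance transform inside each mask (boundary pixels at zero),
in um.

Modulus populations are non-normal (Shapiro–Wilk is reported per group;
samples beyond 5000 values use the leading 5000), so groups are compared
with the two-sided Mann–Whitney U test, validated against exact enumeration
for tiny samples in the test-suite.  No multiple-testing correction is
applied (one pairwise comparison per experiment); the 1.5 IQR outlier rule
affects boxplot whiskers only, never test samples.  Cell-based statistics
(per-cell box means, given an instance segmentation — deliberately not
automated) are provided for comparison with box-based statistics; only the
cell-based SEM is biologically meaningful.

### Error budget

Three numbers summarize the validation chain: (i) the measured flow-field
residual error, which enters the stress linearly; (ii) the blank-area strain
noise — the median homodyne strain amplitude over boxes far from every cell
mask, relative to the median over labelled boxes, measuring the whole
imaging-plus-analysis noise floor on the static dish; and (iii) their
quadrature propagation `sqrt(a^2 + b^2)` into the modulus.  The default blank
margin is 15 um from any mask, chosen to exceed the reach of cell-driven
motion (the synthetic taper zone plus a strain stencil, ~11 um).  A separate
systematic bound, depth-of-field / R_b, covers the assumption that every
tracer sits at `z = R_b` (0.87/1.5 ~ 58%, mitigated in practice by tracer
sedimentation).

## The synthetic-experiment generator

The generator is the package's ground truth and its test bench; it emulates
the statistical structure the analysis assumes, not the optics.

* **Displacement field.** Per cell, `delta_k = sigma_k * psi` with a scalar
  complex potential obeying `d(psi)/dx + d(psi)/dy = 1/G`.  Both strain
  combinations then recover G identically — including under discrete central
  differences, because the cross-diagonal component of psi cancels between
  the x- and y-stencils.  Uniform-G cells use the affine psi; radially
  varying cells (`soft_center`, for edge-profile studies) integrate 1/G
  along image diagonals.  The field extends unchanged 8 px beyond the mask
  and cosine-tapers to zero by 14 px, so the strain stencils of every
  labelled box see the exact field; this is a deliberate departure from a
  hard cut at the mask edge, which would corrupt all boundary-adjacent
  boxes.  Far from cells the field is exactly zero.
* **Rendering.** Frame n shows a band-passed speckle texture (cells at
  contrast 25 gray levels, dish at 12 — DIC needs local contrast everywhere,
  and blank boxes must stay matchable) warped by
  `Re[delta exp(i 2 pi f0 t_n)] * envelope(t_n)` with cubic sub-pixel
  interpolation, plus Gaussian camera noise (2 gray RMS on the 8-bit
  rendering, the regime in which the blank-area strain noise sits at the
  few-percent level the validation procedure reports) — frames whose
  envelope is below 1e-3 are rendered at rest.  The Gaussian envelope
  multiplies the homodyne amplitude of *both* the cell and the bead records
  by the same mean-envelope factor, so it cancels exactly in the modulus.
* **Beads.** Tracers follow the prescribed flow exactly (no inertia), are
  rendered as dark super-Gaussian discs on a separate synchronized stack,
  and their exact trajectories are emitted as ground truth.  Keeping beads
  off the cell stack keeps the blank-area estimate well-defined; it is a
  simplification relative to a real field of view where tracers share the
  image.
* **Fluorescence.** Channel masks are rendered on their own grid (0.3 um/px)
  through a known affine transform (scale + small rotation + offset), under
  a broad Gaussian illumination background and per-image noise; overlapping
  cells are bright in every channel that owns them.
* **Study conditions.** The default scene is a 512 x 512 px co-culture of 72
  equal-sized cells (radius ~16 px / 8 um) on a jittered grid, populations
  interleaved checkerboard-fashion with median |G| of exactly 4.4 and
  6.3 kPa (per-cell magnitudes lognormal with sigma_ln = 0.35, rescaled so
  the realized median hits the target; loss tangent ~1, so storage and loss
  moduli are comparable), driven at 30 kHz with flow phasors (0.40, 0.28)
  m/s — peak displacements ~2 px, consistent with bead speeds of order
  1 m/s.  Equal cell sizes make box- and cell-based statistics directly
  comparable; the grid spacing keeps each cell's tapered field out of every
  neighbour's strain stencils.  Geometry/texture and camera noise use
  separate seeds, so noise can be varied at fixed ground truth.

What the generator does **not** model — optical PSFs, 3-D cell geometry and
depth-dependent focus, transducer acoustics, tracers sharing the cell image,
temperature effects — bounds what passing tests show: recovery on this
generator demonstrates the correctness and noise behaviour of the analysis
chain, not the absolute accuracy of the physical stress calibration on real
data.

## Numerical choices and problem sizes

* Exactness guards: compliances below 1e-12 1/Pa, stress directions below
  the 0.1 relative threshold, and non-positive components in the log-ratio
  map are masked rather than propagated.
* The kernel-density estimate in the loss-versus-storage view falls back to
  a uniform density for degenerate tiny samples.
* Determinism: the analysis chain contains no randomness; the generator is
  bit-reproducible given (seed, noise_seed).
* The acceptance script runs the full default scene (512 x 512, N = 1000,
  72 cells, ~6 minutes on one CPU); the test-suite exercises the same chain
  on reduced scenes (256 x 256, N = 250) plus one full-scale run, keeping
  the complete suite within a half hour.

## Known limitations

* The sub-pixel DIC retains a ~2–4% displacement-scale bias from the
  interpolation asymmetry between warped frames and the unwarped reference;
  it propagates into recovered |G| well inside the method's error budget.
* Quadratic interpolation of the flow is only as good as the tracer
  coverage; outside the sub-FOV centre hull the field is held constant.
* Cell-instance segmentation is not automated; cell-based statistics require
  an externally supplied (or synthetic ground-truth) instance-label image.
* Frequency sweeps and rheological model fits (power-law exponents) are out
  of scope; the pipeline measures single-frequency moduli.
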