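# Methods

## Optical model

The imaging path is treated with geometric optics only. A sample sits at the
focal plane of a plano-convex objective (focal length *f*ʟ), whose collimated
output is refocused by a parabolic mirror (focal length *f*ₘ) onto a camera at
the mirror's focus. For an objective displaced laterally by *y* ≥ 0 from the
mirror axis:

* chief-ray incidence angle θ(*y*) = 2 tan⁻¹(*y*/2*f*ₘ) — the factor 2 is the
  reflection doubling of the surface-normal tilt of the parabola;
* stretch *S* = 1/cos θ: the image forms normal to the chief ray, so its
  projection onto the detector is elongated along the displacement axis;
* mirror-to-focus distance *V* = √(*y*² + (*f*ₘ − *y*²/4*f*ₘ)²), using the
  parabola sag *y*²/4*f*ₘ; magnification *M* = *V*/*f*ʟ is isotropic;
* combined magnification (*M·S*, *M*) along the image axes (y′ ∥ displacement,
  x′ ⊥); defocus span across the sensor *D*f = *D*ₛ sin θ.

Scalar auxiliary formulas: DOF = 2*u*²*N·c*/*f*² with the subject at focus
(*u* = *f*, so DOF = 2*N·c*), NA = sin tan⁻¹(*D*/2*f*ʟ), lateral resolution
0.6 λ/NA. The circle of confusion is set to 36 µm, twice the 18 µm lateral
resolution of the well-plate objective; that is the reading under which the
quoted 0.9 mm alignment tolerance follows from the formula. The 0.6
prefactor with NA(6 mm, 72 mm) = 0.0416 gives 8.97 µm where 9.1 µm is
usually quoted — a ≈2% difference attributable to rounding of the prefactor
(0.61 would give 9.12 µm); the package computes with 0.6 and does not adjust
the result. The defocus span at the mirror edge (*y* = 110 mm,
θ = 57.6°) evaluates to 2.03 mm for a 2.4 mm sensor; the often-stated
"under 2 mm" bound is approximate and is not enforced.

Design choices: angles are radians internally (degrees only at
presentation); units are fixed per field (mm / µm / nm) and converted at
construction; *y* is unsigned because every formula is even in it.

## Warp and rectification

`forward_project` applies an anisotropic scale about the geometric image
centre — factors (*M·S*, *M*) normalized by the on-axis magnification
*f*ₘ/*f*ʟ, so *y* = 0 is the identity — with bilinear interpolation and
constant fill; `rectify` applies the exact inverse. Bilinear interpolation
is matched to the low-frequency content of 8-bit bright-field images;
higher-order kernels gain nothing measurable on such data. The y′ axis is
mapped to the image row axis by convention (sensor orientation is carried in
frame metadata). The transform centre is the image centre, not the intensity
centroid, because the chief ray passes near the sensor centre by alignment.
Round-trip accuracy on a band-limited image is <2% RMS of range for
displacements up to 80 mm (limited by interpolation, not geometry); grid-cell
centroids on a 200 µm calibration grid return to within ~0.05 px.

Stack normalization is a single min–max affine map to [0, 255] fitted over
the *whole* stack — per-frame rescaling would distort the temporal signals
every downstream metric depends on. A zero-contrast stack normalizes to
zeros with a warning. Centered crops put any odd remainder on the
high-index side.

## Multiplexing

Frame *k* of a stream is timestamped *k*/base_fps; LED switching and
exposure are treated as instantaneous (sub-millisecond switch times are
negligible at 120–500 fps base rates). Disk-throughput arithmetic uses
binary MB (2²⁰ B), the convention under which a 1280×1024 single-byte frame
is exactly 1.25 MB and a 150 MB/s disk sustains 120 fps. Schedules are
either round-robin (each sample once per cycle) or block mode (each
consecutive group of *k* wells interleaved for a fixed number of cycles; a
trailing smaller block is allowed). Demultiplexed stacks inherit stream
timestamps, and their effective rate is derived from the median timestamp
spacing, which equals base_fps/*n* in round-robin mode and base_fps/block
size inside a block. Camera/TTL synchronization and dropped-frame recovery
are not modelled: the schedule is assumed perfectly honoured.

## Cardiac pipeline

Motion is |*P*ₜ − *P*ₜ₋ₙ| per pixel with lag *n* = 6 frames by default,
computed in float to avoid 8-bit wraparound. The activation-time definition
is the standard optical-mapping convention: each pixel activates when its
smoothed motion signal first crosses 50% of its own temporal maximum,
linearly interpolated between frames. Smoothing defaults: Gaussian σ = 1 px
spatially and a 3-frame moving mean; pixels whose maximum stays below 5% of
the stack's global maximum are marked unactivated. All four parameters are
exposed. Conduction velocity comes from a least-squares affine fit of
activation time against pixel position; speed is pixel pitch divided by the
gradient magnitude, direction is the gradient orientation, and gradients
below 10⁻⁶ s/px are reported as quasi-simultaneous activation rather than as
an (unstable) huge speed.

## Worm pipeline

Activity is the number of pixels whose intensity changes by **more than 65
units** (strict inequality; ≈25% of the normalized 0–255 range) between
sequential frames (lag 1, unlike the cardiac lag 6), summed over all pairs
and divided by the number of pairs. Both the raw per-frame count (primary)
and the per-pixel fraction are reported; a stack of *F* frames contributes
*F* − 1 pairs. The threshold default is the conventional 65 rather than the
exact 25% value of 63.75; both are one flag away. Group comparison uses
Welch's two-tailed t-test by default (pooled variance available); identical
zero-variance groups return p = 1 by convention.

## PSF estimation from grid contrast

The forward model renders the transmission profile of the grid (area-weighted
sampling at ≤ period/400 so edges are anti-aliased and the discretization is
identical across an inversion sweep), convolves it with a normalized
isotropic Gaussian of the given FWHM (periodic boundary, kernel truncated at
8σ because the line-centre minima are set by far tails), and returns the
gap-centre/line-centre intensity ratio. Contrast is defined bright/dark
(> 1, larger = sharper); measured values quoted dark/bright are reciprocals.
The relation is strictly decreasing and continuous in FWHM, so the inverse
is a well-posed bisection (Brent), accurate to 0.05 µm. The default target
is a 1-D profile across a line far from crossings; the crossed 2-D variant
(separable, so its contrast is the square of the 1-D value) is available
because the physical target is a grid and the choice changes the numbers.
With a Gaussian shape assumption the model reproduces the *ordering* and
range of measured (contrast, FWHM) calibration pairs; exact pairs depend on
unknowable details of the real system (PSF shape, illumination coherence),
so the shipped calibration CSV is used for ordering/range checks only.
Estimating contrast from raw images (segmenting line/gap regions) is out of
scope; the input is the already-measured ratio.

## Synthetic data generator

The generator is the fixture source for the whole package: ground truth is
always emitted beside the pixels, and every accuracy test reads truth from
there.

**Monolayers.** Each pixel's intensity is baseline + amplitude × a biphasic
pulse evaluated at *t* − (delay along the propagation direction)/*v*: an erf
contraction edge (width 40 ms), a plateau of 0.3 of the beat period, and an
erf relaxation edge (width 60 ms), repeating each cycle. The |ΔI| motion
signal therefore shows exactly two peaks per beat — contraction then
relaxation — matching the observed phenomenology. Defaults: 2×2 mm field on
an 80×80 grid (25 µm/px), 40 fps (the rate cardiac imaging requires), 2 s,
1 s period, 20 mm/s planar wave, additive Gaussian noise σ = 2 intensity
units. The generator returns the exact per-pixel activation-time plane, so
conduction-velocity recovery is tested against truth (<5% speed error is
comfortably met; typical recovery is within 0.4%).

**Worms.** Each worm is a sinusoidally bent centreline (1.5 body waves,
lateral amplitude 0.2 × body length) whose phase advances 2π·f/fps per frame,
with a seeded bounded random walk of the centroid (0.5 px/frame). Bodies are
rendered dark-on-bright via a rasterized centreline, a Euclidean distance
transform and a Gaussian radial profile (width 3 px), which anti-aliases
edges cheaply and makes overlapping bodies take the darker value. Defaults
emulate one well of the plate assay: 2×2 mm field scaled to 48×48 px
(42 µm/px), 15 fps, 100 frames, five ~1 mm worms. Wild-type thrashing is
5 Hz, the slow mitochondrial-mutant condition 2 Hz. Note that at the 15 fps
per-well rate a 10 Hz thrash aliases onto 5 Hz, so monotonicity sweeps over
2–10 Hz are run at 30 fps; the strain-discrimination experiment itself stays
at the assay's 15 fps.

**Plate rendering.** Each scheduled frame is forward projected at its well's
displacement, attenuated by exp(−0.005·*y*/mm) (empirical brightness falloff
with off-axis distance), blurred with a Gaussian whose FWHM grows linearly
with *y* (9.1 µm + 0.19 µm/mm, the trend of the measured calibration range
13.4–21.6 µm), optionally defocus-blurred per LED colour (blur diameter
≈ 2·NA × the 981 µm red→blue chromatic focal shift of the single-element
objective), noised (σ = 2) and clipped to 8 bits. Well displacements follow
the 9 mm well pitch of a 96-well plate centred under the mirror.

**Scaling.** Plate scenes are rendered at 48×48 px per well rather than the
640×512 sensor ROI; the schedule arithmetic (80 wells, 100 frames per well,
blocks of eight at a 120 fps base rate, 8000 frames, 67 s) is kept exact.
This preserves everything the package's claims depend on — counts, timing,
warp geometry, metric behaviour — while keeping full-plate simulations in
the seconds range. What the generator does **not** emulate: real worm
biomechanics and posture repertoire, electrophysiological wave dynamics
(re-entry, wavebreak), photon/shot noise, vignetting structure beyond the
radial falloff, and meniscus artefacts. Passing tests therefore demonstrate
correctness of the *computational* pipeline on data with known truth, not
biological fidelity.

## Determinism and numerics

Every stochastic component draws from `numpy.random.default_rng` seeded from
a single `SeedSequence`; identical seeds give bit-identical streams
end-to-end. Degenerate inputs have defined behaviour throughout: constant
stacks (warning + zeros), all-quiet motion (warning + empty map), uniform
activation (quasi-simultaneous), zero-variance group comparisons (p = 1),
saturated or sub-unity contrast (errors with the attainable interval).

## Known limitations

* No off-axis aberration or blur correction (rectification is purely
  geometric); no deconvolution, vignetting model, or subpixel registration.
* No worm path tracking or thrash-frequency spectral estimation — the
  activity metric is deliberately a pixel-change statistic.
* The chromatic focus offset is modelled as an equivalent Gaussian blur, not
  wave-optical defocus.
* The PSF calibration model assumes an isotropic Gaussian PSF and incoherent
  illumination; estimates are model-conditional.
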