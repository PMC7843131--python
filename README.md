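# rapmicro

Computational toolkit for **random-access parallel (RAP) microscopy** — an
imaging scheme in which a single fast camera sits at the focal point of a
large parabolic mirror and images whichever of many spatially separated
samples currently has its LED lit. Because LED switching is sub-millisecond,
dozens of petri dishes or multiwell-plate wells can be recorded
near-simultaneously by interleaving them frame-by-frame, trading camera frame
rate for sample count (a 500 fps camera images 50 dishes at 10 fps each, or
two at 250 fps).

The package implements everything downstream of the camera:

* **`rapmicro.optics`** — closed-form geometry of the parabolic imaging path.
  An objective displaced laterally by *y* from the mirror axis sends its
  chief ray onto the detector at angle θ = 2 tan⁻¹(*y*/2*f*ₘ), stretching the
  image by *S* = 1/cos θ along the displacement direction, while the
  mirror-to-focus distance *V*(*y*) = √(*y*² + (*f*ₘ − *y*²/4*f*ₘ)²) sets the
  isotropic magnification *M* = *V*/*f*ʟ. Also: defocus span *D*f = *D*ₛ sin θ,
  depth of field 2*N·c*, NA and the 0.6 λ/NA diffraction limit.
* **`rapmicro.warp`** — forward simulation of that anisotropic distortion and
  its exact inverse (rectification), plus whole-stack min–max normalization
  and centered cropping.
* **`rapmicro.mux`** — LED schedules (round-robin and block mode), frame-rate
  and disk-bandwidth arithmetic, and lossless demultiplexing/remultiplexing
  of interleaved streams.
* **`rapmicro.activity`** — the two analysis pipelines: dye-free cardiac
  motion (running background subtraction |*P*ₜ − *P*ₜ₋ₙ|, ROI traces,
  activation maps, conduction velocity) and *C. elegans* activity
  (supra-threshold pixel-change counts with a two-sample t-test).
* **`rapmicro.psfcal`** — estimates the lateral PSF FWHM from the measured
  contrast of a periodic grid target by inverting a Gaussian-convolution
  forward model.
* **`rapmicro.synth`** — a fully seeded synthetic-data generator (beating
  monolayers as traveling biphasic waves, thrashing worms as undulating dark
  curves) rendered through the optical distortion and interleaved per an LED
  schedule, with ground truth emitted beside the pixels.

## Worked example

Derived optics of the four-dish instrument (`config1`: 25 mm/100 mm
objectives, 640×480 sensor) at a 70 mm off-axis displacement:

```
$ rapmicro optics --preset config1 --y 70
y_mm                         70.0000
theta_deg                    38.5801
stretch                      1.2792
focus_distance_mm            112.2500
magnification_parallel       1.4359
magnification_orthogonal     1.1225
...
numerical_aperture           0.1240
```

The chief ray lands at 38.6°, so this dish's movie is stretched 1.28× along
the displacement axis (1.4359/1.1225); `rapmicro rectify --y 70` undoes
exactly that factor. Planning the 80-well worm assay:

```
$ rapmicro schedule --wells 80 --frames-per-well 100 --fps 120
wells                 80
frames per well       100
per-well fps          15
total frames          8000
duration              67 s
```

End-to-end on synthetic data, the analysis pipelines recover the generator's
ground truth. A simulated planar contraction wave (20 mm/s) analysed with
the cardiac pipeline prints

```
conduction velocity 20.03 mm/s at 0.00 deg  (truth: 20 mm/s, 0 deg)
```

and a simulated plate of wild-type (5 Hz thrashing) versus slow-mutant
(2 Hz) wells, eight per group at 15 fps × 100 frames, gives

```
WT mean 505.8 px/frame, mutant mean 412.5 px/frame, p = 0.0062
```

i.e. the activity metric (pixels changing by >65 intensity units per frame
pair) separates the strains well below the 0.05 significance level.

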