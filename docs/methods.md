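# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical decisions a maintainer would want to know.

## Device cycle and stretch geometry

**Pressure waveform.** The device produces a smooth cyclic air-chamber
pressure; no functional form is published, so each cycle is modelled as a
raised-cosine rise from baseline to peak over the diastolic fraction
(default 60 % of a 1/1.2 s period) followed by a raised-cosine fall over
the systolic fraction (40 %). The two half-cosines join with zero slope,
so the trace is C¹ with exactly one maximum per cycle — which keeps peak
detection and threshold triggering unambiguous. Defaults: peak 80 mmHg
(140 mmHg overstretch), baseline 0, 1 kHz sampling.

**Stimulus scheduling.** Stimulation is triggered when the rising pressure
crosses a threshold. The threshold is derived from the programmed lead
time: it equals the waveform value on the rising limb one lead (default
100 ms) before the systolic onset, and onsets are detected by sample-wise
below→above comparison. At 1 kHz the onset-to-systole lead is correct to
one sample (±1 ms, matching the device's stated timing precision). A zero
lead degenerates to triggering at the pressure maximum.

**Membrane geometry.** The deflected membrane is modelled as a spherical
cap over the ring aperture — the simplest axisymmetric shape for a thin
clamped membrane under uniform pressure. For ring radius *a* and apex
height *h*: R = (a² + h²)/(2h), θ = asin(a/R), and percent stretch is the
arc-over-chord excess 100(θ/sinθ − 1). This is 0 in the flat limit,
strictly increasing in *h*, and reaches ~57.1 % at the hemisphere, which
bounds the invertible range of `height_for_stretch` (bracketed root
finding, 1e-12 tolerance). The closed form is cross-checked in the tests
against numeric arc-length integration to 1e-6 relative.

**Pressure→height calibration.** The device's published characterisation
fixes two working points (80 mmHg → 25 % stretch, 140 mmHg → 32 %); the
corresponding apex heights anchor a monotone piecewise-cubic (PCHIP)
interpolation through (0, 0). Pressures outside the anchored range are
refused rather than extrapolated — the calibration is measurement-backed
only inside it.

**Oversizing.** A slice cut with `area_fraction` excess area over the ring
has diameter d·√(1+f); the default 25 % excess gives 7.826 mm for the 7-mm
ring.

## Synthetic recordings

The generator renders the membrane cap top-down (orthographic): height
field z(x,y) = √(R²−r²) − (R−h) inside the aperture, Lambertian shading
I = albedo · max(0, n·L) with normals from central-difference gradients,
seeded band-limited albedo texture inside the ring (mean 0.85, ±0.05)
over a dark background (0.05), additive Gaussian sensor noise expressed
as a fraction of the [0,1] range, and optional polynomial baseline drift
in the 1-D trace fixture. Identical parameters and seed give bit-identical
output; ground truth (per-frame apex height and stretch, cycle timing,
stimulus frames) is recorded from the generator state.

Default light direction: 20° zenith along +x. The cap's rim normals reach
64.7° zenith, so any light more oblique than ~25° puts part of the rim in
attached shadow while any light creates a photometric singular point where
the normal parallels the light; 20° keeps the whole surface lit at the
cost of a singular region on the lit flank. For real recordings made with
an obliquely mounted camera the strain stage defaults to a 51° zenith
light instead (configurable).

What the generator does **not** emulate: perspective/oblique projection
(a shear approximation exists but is off by default), lens distortion,
rolling shutter, specularity, tissue texture dynamics, or non-membrane
tissue mechanics. Passing tests therefore demonstrate correctness of the
algorithms under the stated image-formation model, not robustness to
every property of real DSLR footage.

## Movement trace and cycle metrics

The trace is the masked mean absolute intensity difference against a
reference frame (frame 0 by default) — sign-free movement in arbitrary
units. Processing order is fixed and logged: zero-phase first-order
Butterworth low-pass (default cutoff 5 Hz ≈ 4× the pacing rate; applied
forward and backward with reflection padding, so gain is the squared
magnitude — exactly ½ at the cutoff — and phase is zero), then 6th-order
least-squares polynomial detrend, then peak/valley detection
(`scipy.signal.find_peaks`, prominence ≥ 0.3 of the global peak-to-peak,
separation ≥ 0.4 s, alternation enforced by keeping the more extreme of
consecutive same-type detections).

**Cycle metrics.** Naively averaging discrete peak→valley intervals is
biased at 30 fps: the low-pass genuinely shifts the extrema of an
asymmetric waveform (~27 ms for the default cycle), and picking the
noisiest dip in a flat valley adds a further systematic late bias.
`compute_cycle_metrics` therefore estimates the same quantities from an
ensemble-average cycle: the beat period is refined by minimising the
residual of a harmonic regression (8 harmonics), each harmonic is shrunk
against a noise floor measured at off-harmonic probe frequencies, and —
because the filter is zero-phase with a known magnitude response — the
filtfilt gain at each harmonic is divided out exactly. Contraction time is
the max→min phase interval of the reconstructed cycle (the downstroke:
pressure release/systole), relaxation the complement; amplitude is the
cycle's peak-to-valley span; speeds are the extreme rates of its
derivative. Noiseless recovery of the default cycle's timing is accurate
to ~2 ms; at 10 % noise the contraction estimate scatters with sd ≈ 0.5
frame, so single 20-s recordings can occasionally be off by slightly more
than one frame period — a frame-rate limit, not an estimator bias (the
mean error across recordings is well under one frame).

## Regional strain

Pipeline per recording: segment the tissue (Otsu threshold, largest
component, holes filled) unless a mask is supplied; movement trace →
peaks; Up = peak with the globally largest trace value, Down = deepest
valley. By default the reconstruction uses beat averages — the mean of
the frames at all detected peaks (Up) and valleys (Down) — which leaves
noiseless input untouched and suppresses sensor noise by √n_cycles. The
Down frame (membrane near rest, nearly flat) doubles as a reflectance
reference: both images are divided by albedo ≈ I_down / L_z before
reconstruction. This assumes the Down state is close to flat; for
recordings where it is not, disable `albedo_from_down`.

**Shape from shading.** Single-image Lambertian SFS with known light is
solved as regularized nonlinear least squares on the height field:
photometric residual I − R(∇z) with central-difference gradients
(matching the renderer), a curvature-variation penalty ‖Δz − mean(Δz)‖²
(a pressurized membrane has near-constant curvature, so unlike a
Dirichlet penalty this does not flatten domes) built on the 5-point
Laplacian (which, unlike central differences, suppresses checkerboard
modes), background pinned at zero, damped Gauss–Newton steps with
conjugate-gradient solves and backtracking line search, and an annealed
regularization weight (0.3 → 1e-6 over 60 iterations by default).
Single-image SFS has a concave/convex ambiguity; it is resolved with the
physical prior that the tissue distends upward as a clamped membrane:
the solver starts from the linear membrane mode (−Δz = const, z = 0
outside the mask) at the amplitude that best explains the image
photometrically — amplitude 0, hence a flat start, for featureless
frames. On noiseless renders of the 25 % cap the recovered heights
correlate with truth at r ≈ 0.996 (r ≈ 0.95 is the regression floor
asserted in tests). Heights are relative, in pixel units; both frames of
a pair share one reconstruction configuration so the unknown global
scale cancels in the strain ratio to leading order.

**Regions and distances.** The mask is split into ten equal-width bands
along its principal axis (image-moment orientation; an isotropic mask
falls back to the image x-axis). A region's surface distance S is the
mean over its pixel rows of the 3-D polyline length Σ√(Δxy² + Δz²) along
the axis; a flat surface returns the in-plane width, and the polyline
matches analytic arcs to ≲0.1 % at ≥200 px resolution. Strain per region
is (S_up − S_down)/S_down. Note that S is a mean of row lengths, so the
whole-mask strain of a cap is the length-weighted arc excess (~19 % for
the 25 % cap), smaller than the central transect's 25 % — the central
transect alone carries the full calibrated stretch.

**Stimulated vs unstimulated.** `compare_stim` reports per-region percent
difference of mean strains and a paired two-tailed t-test across slices
(t = 0, p = 1 for exactly identical groups; NaN with a single pair).
"Moving regions" are defined data-driven as regions whose strain reaches
25 % of the maximum regional strain: for a centrally clamped dome these
are the outer bands (the flattest bands sit over the apex and barely
elongate along a transect), while for an asymmetric tissue the same rule
selects whichever side beats. On a synthetic pair built with peak
stretches 25 % and 20.833 % (true ratio 1.2) the full pipeline reports a
~20–21 % mean difference over the moving regions, both noiseless and at
5 % sensor noise.

## Problem sizes and determinism

Synthetic tests use 64–128 px frames and 5–20 s traces; the full-pipeline
strain contrast runs at 256×256 px and 10 s of 30 fps video, which keeps
a complete verification run within a few minutes on one core. All
randomness flows through explicit `numpy.random.default_rng(seed)`
generators; every stage is deterministic given its inputs.

## Known limitations

* The stretch model is geometric (spherical cap, arc-over-chord); it does
  not model tissue constitutive behaviour, preload/afterload, or
  fluid–structure coupling.
* SFS assumes Lambertian reflectance, a known light direction, and the
  membrane prior for ambiguity resolution; strongly non-Lambertian or
  multi-lobed surfaces are out of scope.
* Cycle-timing precision is bounded by the 30 fps frame rate (see above).
* The 51° camera obliquity of real rigs is approximated, not modelled;
  quantitative strain from real oblique footage would need a projection
  correction upstream.
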