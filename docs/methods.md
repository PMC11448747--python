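# Methods

## The forward model

Each imaging channel is a sequence sample → objective → tube lens → camera,
described in the paraxial approximation by 2×2 ray-transfer (ABCD) matrices
for free space and thin lenses, composed in optical order (object-side
element rightmost). Only these two element types are needed for a
single-medium (air) infinite-conjugate channel, and every matrix they
generate has unit determinant — a property the test suite checks on random
element sequences, with the tolerance scaled by the magnitude of the entry
products (the determinant is a difference of large, nearly equal terms).

The channel matrix is

    M = FS(d_cam) · TL(f_t) · FS(d_interlens) · TL(f_o) · FS(d_sample)

with the closure constraint d_interlens = d_total − d_sample − d_cam: the
sample stage and camera are fixed, so the total path is a constant of the
optomechanics and only the objective and tube lens move. The sensor holds a
real image of the sample iff the B entry of M vanishes; A is then the signed
lateral magnification (negative: inverted image), and D = 1/A by the unit
determinant.

The objective is a single thin lens at its principal plane. ``d_sample`` is
therefore the *principal-plane* distance, not the mechanical working
distance engraved on the barrel; the two differ by a fixed offset for a
given objective, which cancels in the error estimate because only
d_sample − f_o is ever used. (For coverslip-corrected objectives the focal
plane sits working-distance + coverslip-thickness from the front surface;
`focal_plane_from_front` does this bookkeeping.)

## Solving the imaging condition

For fixed d_sample, B(d_cam) is *exactly* quadratic: d_cam enters only
through the two free-space factors, each linear in it. The solver exploits
this: three evaluations of the matrix model reconstruct the quadratic's
coefficients exactly, its real roots follow from the numerically stable
(citardauq) quadratic formula with one Newton polish, and each root is
verified to give |B| < 1e−9 mm. Roots are filtered for physical feasibility
— d_cam and d_interlens both at least 1 mm — and when two survive, the one
nearest f_t is chosen: the aligned solution is d_cam = f_t and the alignment
loop operates in its neighbourhood. This closed-form-within-the-matrix-model
approach was preferred over a bracketed scalar root search because near the
edges of the solvable region the two roots coalesce and a coarse bracket
scan can miss the sign change entirely; the test suite still cross-checks
every solution against an independent sequential thin-lens-conjugate oracle
(agreement: 1e−6 mm in d_cam, 1e−9 relative in |M|).

### Where no image exists — and why it matters

With d_total fixed, the tube lens needs a throw of at least 4·f_t between a
real object and its real image. Just above d_sample = f_o the objective's
intermediate image recedes toward (and past) the sensor, and there is a band
of d_sample in which neither a real-object nor a virtual-object tube-lens
configuration fits the remaining path: the quadratic has no real root. For
the reference design (f_o = 4.5 mm, f_t = 45 mm) the bands are roughly
4.552–4.596 mm (400 mm path), 4.559–4.626 mm (350 mm) and 4.570–4.683 mm
(300 mm). Beyond the band a second, disconnected solution branch appears in
which the magnification ordering between channels reverses. Consequences
for the implementation:

* curve scans retain no-solution grid points as explicit NaN gaps and warn
  once per channel, never interpolating across them;
* curve inversion is restricted to the contiguous solved branch containing
  f_o, which is strictly monotonic there; measured ratios outside that
  branch's value range raise an out-of-range error rather than extrapolating
  or silently picking the wrong branch;
* the virtual microscope refuses to synthesize measurements at a true
  d_sample inside a band (the physical camera would show no focusable
  image there either — in practice an operator would notice the tube lens
  hitting its travel limit without finding focus).

On the too-close side (d_sample < f_o) the intermediate image is virtual and
a solution always exists, so the whole lower scan range is usable.

## Magnification curves and normalization

The default scan covers f_o ± 0.25 mm in 1 μm steps, anchored so that f_o is
always a grid point. Curves store |A|; the signed value is kept alongside
but excluded from normalization because pixel-distance measurements cannot
see image inversion. Normalized curves divide each channel's |M| by the
reference channel's at the same grid point — the shortest path by
convention, so normalized values quantify "how much more (or less) this
channel magnifies than the shortest one". With identical tube lenses all
curves meet at exactly 1 at d_sample = f_o; with differing tube lenses they
meet at f_t,i / f_t,ref, and the same pixel-pitch-compensated normalization
of measurements keeps the estimate valid.

## The estimator

Measured per-channel distances (pixels × pixel pitch) are normalized to the
reference channel and the estimation channel's ratio is inverted through its
normalized curve by piecewise-linear interpolation. The estimation channel
defaults to the longest path: its normalized curve is the steepest, so a
given measurement error maps to the smallest d_sample error. Linear (not
spline) interpolation is monotone by construction and its error on a 1 μm
grid is orders of magnitude below the convergence threshold. The remaining
non-reference channels are inverted too as a cross-check; a spread above 10
grid steps triggers a warning, since consistent per-channel estimates are
evidence the model matches the hardware while large discrepancies point to
field distortion or tube-lens focal-length tolerances (the latter being
invisible to a purely image-based calibration).

The signed working-distance error is d_sample_interpolated − f_o, positive
meaning the objective is too far from the sample. Convergence compares
|error| against the Abbe axial resolution dz = 2λ/NA² — both converted to
micrometres before comparison; a unit-confusion test guards this, because a
mm/μm slip here would declare convergence three orders of magnitude early.
dz is the natural threshold (positioning finer than the axial resolution is
not optically meaningful) but can be overridden.

## The virtual microscope

`synthetic` generates what the cameras would record at a chosen *true*
d_sample: per-channel pixel distances spanning n periods of a grid of known
pitch (default 10 μm, a standard stage-graticule ruling), and optionally
full 1024×1024 8-bit images with the rulings rendered as Gaussian-profile
dark lines (width tied to the period) on a bright background — a
diffraction-blurred appearance that exercises the subpixel detector
honestly, rather than ideal step edges it could localize trivially.

Noise models, both seeded: multiplicative Gaussian on distances (standing in
for feature-localization error; 0.5 % is used in the simulation studies) and
additive Gaussian on image pixels. Shot noise and an NA-derived PSF are not
modelled — there is no photon-budget model to calibrate them against — and
neither are vignetting or field distortion. Passing tests therefore
demonstrate correctness of the inference given the geometric-optics forward
model, not robustness to every real-camera artefact; on hardware, the
central-region measurement advice and the cross-check warning are the
defences against the unmodelled effects.

The simulated alignment loop is measure → estimate → move the objective by
−error → refocus tube lenses (exact refocus via the imaging-condition
solve; real hardware refocuses by eye, an error source the simulation does
not emulate) → repeat until |error| < dz. Noiseless, one correction lands
within the interpolation error; with 0.5 % distance noise the median run
converges in ≤ 3 iterations from ±0.1 mm-scale starting offsets (the
positive start is +0.045 mm, the largest offset at which every channel of
the reference design still images).

## Line-profile measurement

The graticule measurement takes a horizontal profile (central row by
default, averaged over ±halfwidth rows perpendicular to the profile to
suppress noise without biasing line centres), finds local extrema of the
requested polarity (dark rulings by default) separated by at least a minimum
spacing with a small prominence guard, refines each to subpixel by a
three-point parabolic fit, and reports the span of the first to the
(n_periods+1)-th line. Spanning many periods divides the per-line
localization error by n_periods; the number of periods is an explicit
argument so every channel measures the *same physical feature span*.
Distances are invariant to global intensity scaling and offset. On
noiseless rendered images the pipeline recovers the programmed on-sensor
period to ~0.01 px per period, well inside the 0.5 px bound asserted in
tests.

## Parameter defaults

| parameter | default | why |
|---|---|---|
| scan range | f_o ± 0.25 mm | generous bracket of realistic misalignment; gaps are handled explicitly |
| scan step | 1 μm | interpolation error ≪ dz = 2.5 μm for the reference design |
| feasibility margin | 1 mm | lens/sensor housings cannot overlap |
| |B| tolerance | 1e−9 mm | far below any mechanical tolerance |
| graticule pitch | 10 μm | standard calibration-slide ruling |
| n_periods | 10 | amortizes subpixel localization error |
| image | 1024×1024, 8-bit | consumer-camera scale used in compact builds |
| noise_sd (simulations) | 0.005 | ~0.5 % distance error, conservative for a 10-period span |

## Known limitations

Paraxial model only (useful guidance even at NA > 0.6, but aberrations are
outside the model); chromatic effects, field distortion and vignetting not
modelled; tube-lens focal-length manufacturing tolerance is detectable only
as a cross-check discrepancy, not correctable; channels with *equal* path
lengths carry no alignment information (introduce a temporary path
difference, align, then remove it); absolute magnification calibration needs
a feature of known physical size — relative alignment does not.
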