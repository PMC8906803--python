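# Methods

This note documents the models, numerical choices, and limitations behind
`oroflow`. Units throughout: positions in mm, time in s, velocities in
cm/s (the conventions of the X-ray kinematics literature); the physics
module (`oroflow.physics`) works in SI.

## Coordinate systems and rigid poses

Per-frame neurocranium poses are least-squares rigid fits (Kabsch/SVD with
the determinant correction, so reflections are impossible) of ≥3 visible
bone markers to their bone-model (CT) coordinates. Frames with fewer than
three visible markers, or a collinear configuration, are *pose-missing*
and excluded downstream rather than extrapolated — the package never
invents a pose. The anatomical coordinate system (ACS) is a fixed rigid
offset from the neurocranium defined by three user-supplied landmarks in
bone-model space: an origin (caudal tip of the chewing pad, midsagittal —
a surrogate for the esophagus entrance, treating the pharyngeal jaws as
static), a two-point line parallel to the pharyngeal-process plate
(anterior-positive x), and a dorsal midsagittal hint point
(Gram–Schmidt-orthogonalised y); z = x × y (right-positive). The exact
landmark coordinates are inputs, not constants: they differ per individual
and are supplied in the analysis configuration. The synthetic worlds ship
landmark values that are synthetic by construction.

## Velocities and smoothing

Velocities are central finite differences of zero-phase (forward-backward)
4th-order Butterworth-filtered positions, default cutoff 25 Hz. The
behavioural dynamics of interest live below ~3 Hz (the fastest printed
phase, a ~0.26 s intake), so 25 Hz retains an order-of-magnitude margin
while suppressing the ±0.1 mm tracking noise. Filtering is applied per
contiguous valid run with odd (point-symmetric) edge padding over roughly
three filter time constants, which continues linear trends exactly —
constant-velocity segments come through transient-free. Frames adjacent to
tracking gaps are flagged invalid because their central differences
straddle missing data.

Gap filling (`fill_gaps`) linearly interpolates interior missing runs up
to a caller-chosen `max_gap` and logs every filled span; leading/trailing
gaps are never filled. How occluded frames should be treated is genuinely
an analysis choice, so the policy is exposed rather than hard-wired.

## Phase segmentation

Segmentation operates on the cross-tracer mean anteroposterior velocity
(per-tracer mode is available; the mean is the default because single
tracers drop out of view). Frames are classified by the asymmetric dead
band (−4.5, +2) cm/s — posterior drift at the ~3–4 cm/s approach speed
must not register as flow, while weak anterior flow is meaningful — and a
phase boundary is a dead-band crossing. Dead-band-exceeding runs shorter
than `min_phase_duration` (default 0.02 s = 15 frames at 750 fps; the
shortest real phase is an order of magnitude longer) are discarded;
same-direction runs separated by shorter stagnant slivers are merged. The
first posterior run whose peak reaches `intake_fraction` (default 0.5) of
the global posterior maximum is the intake — backflows repeat the intake
pattern at roughly a third of the speed, so relative peak speed separates
them robustly. The pre-intake span is the approach when its mean velocity
is posterior. Anterior runs after the intake are rf, posterior runs bf.
rf/bf periodicity is the mean spacing of rf/bf phase onsets.

Two numerical refinements matter at the printed noise level. First,
boundary *detection* runs on an additionally filtered velocity
(`boundary_cutoff`, default 15 Hz; `None` disables): noise in a 25
Hz-bandwidth velocity is correlated over ~half the filter period, so it
cannot be averaged away by any local estimator and must be filtered out
before thresholding. Candidate runs are validated against the unfiltered
velocity so that filter ringing at step-like inputs cannot fabricate
phases. Second, each crossing is refined to sub-frame precision by an
iterated local quadratic fit (±8 frames, re-centred on its own solution);
solutions farther than 2.5 frames from the raw edge are rejected in favour
of the raw crossing, which protects discontinuous (hand-constructed)
inputs. Measured on the synthetic presets, ground-truth boundaries are
recovered within ±2 frames for 98–99% of boundaries over 20 seeds per
species; the one systematic residual is the intake onset (~1.5 frames),
where the detection filter reacts to the plateau-to-pulse kink only
0.6 cm/s above threshold.

## Path-line geometry

Curvature of a tracer path is the Menger curvature — the reciprocal
circumradius of three consecutive samples — projected to the dorsoventral
(x, z) plane: κ = 4A/(|ab||bc||ca|), dimensionally 1/mm. Per tracer, the
anteroposterior position during the intake is standardized to 0–100% of
its own excursion and the maximum κ per 10% interval is reported
(`n_bins` configurable; the interval width is an analysis choice). The
water-vs-food comparison pools all interval maxima into one two-group
Kruskal–Wallis test by default; a per-interval mode exists because the
pooling convention is ambiguous in practice.

Curvature uses its own smoothing bandwidth (`curvature_cutoff`, default
8 Hz), deliberately heavier than the velocity filter: three-point
circumcircle noise scales as σ/chord², so residual noise at velocity-grade
bandwidth is *larger for slower tracks* and would invert the water–food
contrast; the lateral excursions being measured evolve over the ~0.3 s
intake, far inside the retained band.

Kendall correlations use tau-b (robust to ties from quantized
coordinates). Flow-pattern labels are explicit heuristics, not published
thresholds: `anterior_return` requires a sustained (≥0.02 s) anterior
velocity segment after 20% of the tracer's posterior excursion;
`posteromedial` requires the final |z| to fall below half (configurable)
of the intake maximum while the net motion is posterior; everything else
is `posterior`.

## Skeletal kinematics

Gape is the 3D distance between the jaw-tip locators (a projection-based
definition would differ by <2% at these gape angles). Hyoid depression is
rest-mean y minus y(t); opercula abduction is |z(t)| minus rest-mean |z|;
the rest posture is the mean over the approach phase by default, since no
rest posture is ever printed. Peaks are in-window global maxima without
sub-frame interpolation (±1 frame = ±1.33 ms at 750 fps, negligible
against the phase scales). A phase's peak order is classified
`intake_like` (gape → hyoid → opercula), `rf_like` (inverted), or `other`
(any trace missing in the window also forces `other`).

## Tracer physics

`stokes_density` inverts the Stokes terminal-velocity balance
ρ = 18µv/(gd²) + ρ_w with v positive when settling (the drop-test
extractor reports velocity positive-up, matching the "rising is positive"
plotting convention; the sign is converted at the interface). At the
~5 cm/s settling speed of the densest tracers the particle Reynolds number
is ≫1, where Stokes drag underestimates the true drag; the function warns
but proceeds, because the same closed form is what the density estimates
it reproduces were computed with. `terminal_velocity` fits the final 50%
of a drop record and rejects records whose tail slope still drifts
(non-terminal).

The suction simulation replaces a moving-mesh finite-volume CFD with a
desk-scale reduced-order model. The flow is separable, u(x, t) =
u_ap(t)·F(x): suction pressure follows a raised-cosine ramp to −2 kPa over
20 ms and is then held; the aperture speed is the quasi-steady orifice
estimate u_ap = √(2|p|/ρ) (an analytic sine peaking at 2 m/s — the order
of measured intake flows). The spatial shape F is C¹ everywhere: a point
sink displaced one cavity radius *behind* the aperture outside the mouth
(so off-axis pathlines enter the cavity off-axis instead of collapsing
onto a singular sink point), a radially tapered plug flow inside the
40 × 10 mm cylindrical cavity, blended over an entrance region of one
radius. Smoothness is load-bearing: a density-matched particle follows the
fluid pathline exactly only when the field has no velocity jumps, and that
identity is the simulation's primary self-check (agreement ≤1 µm at a
halved time step).

The particle obeys a reduced Maxey–Riley balance — Stokes drag,
weight/buoyancy, added mass (coefficient ½), and the fluid
pressure-gradient force; Basset history and Faxén corrections are
neglected (the main fidelity caveat; an optional Schiller–Naumann drag
correction is available for slip Reynolds >1). Time integration is RK4 at
0.125 ms over 100 ms (800 steps), with Du/Dt evaluated semi-analytically
(analytic ∂/∂t via u_ap′, spatial gradient by central differences).
Integration stops when a path reaches the cavity base or leaves the
domain; fidelity metrics (velocity lag during forcing acceleration,
overshoot during deceleration, gravity-direction deviation, total path
separation) are computed over the common time prefix, excluding the
termination sample and near-stagnant frames. Release points default to
5 mm ahead of the aperture, on-axis and 5 mm off-axis; both are
configurable since no coordinates are printed for them.

## Synthetic data: what it emulates, and what it does not

The generator produces world-frame recordings with the statistical
structure the pipeline assumes: a raised-cosine velocity program (approach
plateau → intake pulse → stasis → alternating rf/bf pulses), ~15 water
tracers sharing that program with per-tracer side-preserving lateral
S-curves that progress with *intracavity position* (lateral divergence is
an intraoral phenomenon), one midsagittal, more dorsal food tracer with
attenuated displacement, four rigid cranium markers advancing at the
approach speed, and jaw/hyoid/operculum locators following the canonical
peak waves (forward in intake/bf, inverted in rf). Isotropic Gaussian
noise (SD 0.1 mm, the device resolution) is added to every sample; all
ground truth is recorded pre-noise.

Phase-boundary ground truth is the analytic dead-band crossing of the
pre-noise program, and each pulse is widened so that the
crossing-to-crossing time equals the preset phase duration — the program's
knots coincide with the boundaries by construction. Preset means are the
published carp/tilapia trial statistics; the printed between-trial SDs are
stored with the presets and applied only when `between_trial_sd_scale` >
0, so that a default run is exactly reproducible against the preset
values.

What passing tests on this generator do *not* show about real recordings:
real tracers drop out of view (the generator only simulates missing frames
when asked), the real velocity field is shared only approximately across
tracers, real pulses are not raised cosines, cranium motion includes
rotation and is not purely translational during approach, and real noise
is not isotropic white. The generator is a correctness and power harness,
not a flow model.

## Degenerate inputs and tie-breaks

Empty or all-stagnant sequences segment to a single stasis interval with a
warning flag instead of raising. Tracers with zero anteroposterior span,
phases with <2 valid frames, and traces fully missing in a phase are
omitted with that fact recorded in the result rather than raised. Ties in
peak detection resolve to the earliest frame (argmax convention); ties in
ranks use average ranks (Kruskal–Wallis) and tau-b corrections (Kendall).

## Known limitations

- The reduced-order flow model has no gill-slit outflow, no moving
  boundaries, and one-way coupling only; its fidelity conclusions are
  qualitative (orderings, bounds), not field-accurate velocities.
- Stokes-law densities inherit the Re ≫ 1 bias discussed above.
- The intake-onset boundary carries a ~1.5-frame systematic at the default
  detection bandwidth (inside the ±2-frame tolerance used throughout).
- Flow-pattern classification thresholds are heuristics; they recover the
  generator's constructed sub-populations (≥80% agreement) but are not
  validated against measured flow fields.
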