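# Methods

This note records the models, parameter choices and numerical decisions
behind `povar`, and what the synthetic test bed does and does not establish
about real recordings.

## Stimulus kinematics

A dual-axis turntable spins the animal about an Earth-vertical main axis
(velocity V_M, radius r) while counter-rotating it about its own eccentric
axis (velocity V_E). The centrifugal acceleration ω²r (ω = |V_M| in rad/s)
adds to gravity, so the gravito-inertial acceleration (GIA) tilts from the
head's dorso-ventral axis by θ = arctan(ω²r/g) — the tilt a conventional
OVAR test would need — while the eccentric rotation sweeps the GIA around
the head at f = |V_E|/360 Hz. In the head frame the GIA keeps a constant
dorso-ventral component g and a horizontal component ω²r rotating at f, so
its magnitude is constant at g/cos θ.

Two deliberate choices. First, the tilt is defined by the **tangent** of
the centrifugal-to-gravity ratio (the direction of the resultant force);
the protocol's round labels (10–40°) come from `nominal_tilt_angle`, which
rounds the exact value (10.35°, 20.21°, 30.80°, 41.32° at r = 0.17 m) to
the nearest 10°. The labels are robust to using g = 9.8, 9.81 or standard
gravity 9.80665 m/s² (the default). Second, a single sign convention is
fixed package-wide: CW viewed from above is positive; head axes are
naso-occipital (+nose), interaural (+left), dorso-ventral (+up); radians
internally, degrees at every public boundary. Platform start-up transients
and Coriolis cross-coupling are out of scope (analyses discard the first
minute anyway).

## Synthetic recordings

`generate_trace` emulates the structure the analysis assumes rather than
retinal images: horizontal position = SMC sinusoid at the stimulus
frequency + slow-phase drift at the bias velocity + resetting quick phases
+ white Gaussian position noise; vertical position = SMC + noise. Quick
phases use a half-cosine displacement profile (default 40 ms) — smooth,
differentiable, with a realistic peak-velocity-to-amplitude ratio — and are
triggered two ways: a Poisson process (the FPN-rate control) and a
deterministic reset whenever the eye exceeds the orbital limit (so large
biases produce resetting nystagmus even at zero Poisson rate). Quick phases
beat opposite to the drift; orbital resets always re-center. All
randomness comes from one integer seed; identical seeds are bit-identical.

Scenario presets encode the phenotypes of interest: `canal_null` (SMC
intact, no bias/quick phases), `otolith_null` (no SMC, no bias),
`uvl_left`/`uvl_right` (rate **and** bias multiplied by the asymmetry
ratio, default 0.6, when the stimulus direction matches the lesioned side —
left lesions suppress CCW), `storage_attenuated` (bias and rate halved, SMC
untouched). The control defaults — vertical SMC 3°, horizontal SMC 1°,
bias 8 deg/s under CW stimulation (sign flips with direction), quick-phase
rate 0.8 Hz, amplitude 10 ± 2°, orbital limit 15°, noise SD 0.1°, sampling
rate 60 Hz — are chosen as representative murine rotational-nystagmus
magnitudes; the camera rate resolves 40 ms quick phases at ≥ 2 samples.
TAV recordings place a velocity step at a configurable time and decay the
slow-phase velocity as v₀·e^(−t/τ) with v₀ = 0.8 × plateau (compensatory
sign); the plateau default is 100 deg/s.

What the generator does **not** emulate: colored measurement noise, blinks
and lid artifacts beyond quality flags, torsion, saccadic-amplitude/rate
correlations, gain nonlinearity at large eccentricities, or any
image-level confound beyond Gaussian pixel noise and a specular highlight
in the rendered frames. Passing tests therefore certify the algorithms
against the assumed trace structure, not against video idiosyncrasies of a
specific rig.

## Pupil tracking

Frames are binarized (Otsu by default, or a fixed level), the largest dark
connected component above 0.1% of the frame is kept, and an ellipse is
fitted by least squares to the **sub-pixel iso-intensity contour** at the
threshold level (`skimage.measure.find_contours` + `EllipseModel`), which
preserves sub-pixel centers that a binary-mask fit would quantize; the
component's moment ellipse is the fallback. Ambiguity — a second dark
component within 20% of the largest — fails the frame explicitly rather
than guessing, as do empty masks and degenerate fits; a center is never
fabricated. Tracking converts centers to degrees with a user-supplied
linear scale (default 0.2 deg/px) and origin, flipping y so up is positive;
failed frames are linearly interpolated when gaps are ≤ 3 samples and
flagged as artifacts otherwise. Deep-learning region proposals, corneal
reflection compensation and geometric eyeball calibration are intentionally
absent: with whole-frame synthetic/benchtop images the classical stage is
the measurement content.

## Phase segmentation and metrics

The horizontal trace is low-pass filtered (zero-phase 4th-order Butterworth,
10 Hz cutoff) and differentiated twice by central differences. Quick-phase
candidates are seeded where |acceleration| > 1000 deg/s² and grown over
contiguous samples where the velocity deviates from a **running-median
baseline** (0.6 s window) by more than 30 deg/s — the baseline makes the
thresholds excursion-relative, so large compensatory velocities (early TAV
decay) are not mislabelled fast. Candidates closer than the 50 ms
refractory gap merge; merged runs containing several distinct speed peaks
(quick phases packed tighter than the filter can separate) are split at
inter-peak minima; events shorter than 15 ms are dropped; labels are padded
35 ms on each side. The specific threshold values are design defaults —
justified by murine quick phases being an order of magnitude faster than
the 0.1–0.4 Hz slow components — and all are exposed in
`SegmentationConfig`.

FPN frequency is the count of events with onsets inside the analysis window
(default: 60 s after start to the end, the customary discard of the
spin-up minute) divided by the window duration. Bias velocity fits
`dc + A sin + B cos` at the stimulus frequency to slow-labelled velocity
samples and reports the dc term; the fit runs twice, dropping residuals
beyond 2.5 robust SDs before refitting, because the zero-phase filter's
ringing lobes flanking each quick phase otherwise bias the mean by a few
percent. Events straddling the window boundary count if their onset is
inside.

## SMC fitting

The stimulus frequency is set by the apparatus, so the SMC fit is linear.
Vertical traces (no quick phases) are fitted in the position domain:
`dc + drift·t + A sin + B cos`, the drift column absorbing residual bias so
it cannot inflate the amplitude. Desaccaded horizontal traces are fitted in
the **velocity domain** on slow-labelled samples (`bias + Aω cos(ωt + φ)`),
with the same trimmed second pass: the quick-phase sawtooth in position has
broadband power that leaks into a position-domain sinusoid fit, whereas
slow-phase velocity contains no steps. Amplitude is the fitted peak
amplitude (not peak-to-peak); phase is reported relative to the profile's
phase reference but is not used diagnostically (absolute-phase hardware
chains are out of scope). Gain divides the amplitude by the equivalent
tilt angle (pOVAR/OVAR) or by the oscillation amplitude (aVOR). The
asymmetry statistic is the ratio of FPN frequencies with the suppressed
direction in the numerator (control CW/CCW; left lesion CCW/CW; right
lesion CW/CCW), so lesions give ratios < 1.

## Time constant

The post-step slow-phase envelope takes one point per slow-labelled run
(median velocity — robust to residual quick-phase tails; midpoint time),
starting 0.5 s after the step to skip platform transients, skipping runs
shorter than 4 samples (slivers between dense early quick phases carry
mostly filter ringing) and chopping runs longer than 1 s so quick-phase-free
decays still yield a usable envelope. `v₀·e^(−t/τ)` is fitted by nonlinear
least squares initialized from the log-linear regression; points below 10%
of the initial magnitude are excluded (log-of-noise protection), with
truncation only at a *sustained* (two-point) drop so an isolated outlier
cannot end the window. Non-decaying or sign-flipping envelopes fail loudly.
Recovery accuracy on the synthetic bed: median |Δτ|/τ ≈ 3–8% at τ = 2, 5,
10 s with 0.2° noise.

## Velocity-storage internal model

The simulator is a minimal dynamical system consistent with the canal and
otolith pathways of the velocity-storage account of OVAR nystagmus. State:
a canal low-pass x (so V_SCC = Ω − x is the high-passed head velocity,
time constant 4 s), an internal gravity estimate Ĝ, and a storage vector s
(leak time constant 15 s). Dynamics:

    x' = (Ω − x)/τ_c                         V_SCC = Ω − x
    Ĝ' = −ω_est × Ĝ + k_g·s_oto·(g·GIA/|GIA| − Ĝ)
    s' = −s/τ_s + k_sc·C + gate(f)·k_F·s_oto·f,   C = gate(V_SCC)·V_SCC,
                                                  f = GIA × Ĝ
    ω_est = C + s
    eye velocity = −G_vor·ω_est(yaw) + k_smc·s_oto·GIA(interaural)

`gate(·)` applies the right-side canal gain to CW yaw signals and the
left-side gain to CCW ones (each canal is excited by rotation toward its
side). Gating **both** the canal signal and the rotation-feedback term is
the model's central commitment: it encodes the finding that reconstructing
angular velocity from otolith signals requires canal participation, so
bilateral canal loss silences the bias (and the fast phases) while the
direct otolith SMC drive survives, and a unilateral lesion suppresses only
the direction whose excitatory side is lesioned. During steady rotation Ĝ
tracks the rotating GIA with a lag, so GIA × Ĝ has a constant yaw
component whose sign matches the head rotation; the leaky integrator turns
it into a sustained bias opposite the head movement in eye coordinates.

Defaults: τ_c = 4 s, τ_s = 15 s, VOR gain 0.8, orbital limit 15°, reset
fraction 0.9, k_g = 2 s⁻¹, k_sc = 0.07 s⁻¹ (storage DC gain ≈ 1 so the
onset transient does not overcharge the integrator), k_F = 0.04
(deg/s)/(m²/s⁴) and k_smc = 0.5 (deg/s)/(m/s²), the latter two set to give
a steady-state bias of a few deg/s and an SMC of ~1.5° at tilt 30° —
plausible murine magnitudes; no quantitative fitting to recorded data is
attempted or claimed. Quick phases are deterministic orbital resets spread
over a 40 ms half-cosine (so simulated traces are analyzable by the same
segmentation used for recordings), making the simulated FPN rate a
reproducible function of the bias. Integration is fixed-step RK4 at
dt = 1 ms (numba-compiled); steady-state claims are evaluated after ≥ 5
storage time constants. Divergence (non-finite state, or the Ĝ norm
leaving 0.4–1.6 × g) raises an explicit instability error.

## Pipeline

`analyze_recording` composes tracking (optional) → segmentation → metrics →
SMC/τ fits into a JSON-serializable report embedding a hash of the full
configuration, so every number is traceable to the exact thresholds that
produced it; unreliable-estimate conditions are reported as warnings, never
silently dropped. Paired CW/CCW analysis checks profile compatibility
before delegating to the asymmetry ratio.

## Problem sizes

Test and acceptance runs use 3-minute recordings at 60 Hz for the
statistical suites (50 seeds for detection, 20 seeds or pairs for recovery
and symmetry), 60 s TAV recordings, and 100 s simulator runs at dt = 1 ms
with the steady state read from the final 20–40 s. These sizes give
comfortably converged statistics for the properties asserted.

## Known limitations

Torsional eye movements are not analyzed; the simulator's coefficients are
plausibility choices, not fits; the generator's white position noise
understates low-frequency drift in real video-oculography; calibration is a
fixed linear scale (no eyeball geometry); aVOR support is limited to
analysis of supplied traces (the simulator handles rotational and TAV
paradigms); and single-eye analysis only — binocular comparisons are run as
two independent pipelines.
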