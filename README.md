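# povar

Analysis of mouse eye movements during off-vertical axis rotation (OVAR) and
related vestibular tests, plus an executable internal model of the velocity
storage mechanism (VSM).

## The problem

Rotating a mouse about an axis tilted from gravity sweeps the
gravito-inertial acceleration (GIA) around its head and evokes two
eye-movement components: a **sinusoidal modulation component (SMC)** locked
to the stimulus frequency (an otolith readout) and a steady **bias**
slow-phase velocity, interrupted by resetting quick phases — horizontal
fast-phase nystagmus (**H-FPN**). On a dual-axis turntable the tilt is
produced centrifugally ("pseudo-OVAR", pOVAR): a main-axis rotation at
angular speed ω and radius r tilts the GIA by

    θ = arctan(ω² r / g),

while the eccentric-axis velocity V_E sets the otolith modulation frequency
f = |V_E| / 360. The scientifically interesting dissociation: the SMC needs
only otoliths, but the bias/H-FPN needs **both** continuous otolith input
and semicircular-canal (SCC) participation — canal-deficient animals keep a
normal SMC yet lose the fast phases, and a unilateral canal lesion
suppresses the fast phases of one rotation direction only, which makes the
CW/CCW fast-phase ratio a lateralizing diagnostic.

`povar` provides, for researchers running such tests (or modelling them):

- **stimulus kinematics** — tilt/frequency equivalents and head-frame GIA
  time courses for a dual-axis profile;
- **synthetic data** — ground-truthed eye traces (SMC + bias + quick phases
  + noise, per lesion scenario) and rendered pupil-video frames, so every
  stage is testable without recordings;
- **pupil tracking** — threshold segmentation + sub-pixel ellipse fitting,
  calibrated traces with explicit failure/interpolation flags;
- **nystagmus segmentation** — zero-phase low-pass filtering, double
  differentiation, acceleration-seeded / velocity-grown quick-phase events;
  FPN frequency and bias velocity (stimulus-frequency component removed by
  a robust trimmed fit);
- **SMC analysis** — linear sinusoid fits at the known stimulus frequency
  (velocity-domain on desaccaded horizontal traces), gains, CW/CCW
  asymmetry ratios;
- **time constant** — exponential fit of the post-step slow-phase velocity
  envelope in the trapezoidal-velocity (TAV) paradigm;
- **VSM simulator** — canal high-pass, gravity (tilt) estimator and leaky
  storage integrator recharged by the rotation feedback k_F (GIA × Ĝ),
  gated by per-side canal gains; reproduces the canal-null, otolith-null,
  unilateral-lesion and storage-attenuation phenotypes.

## Worked example

`examples/02_synthesize_and_segment.py` builds a 3-minute control recording
(tilt 30°, 0.3 Hz, CW) with known ground truth and analyzes it:

```
analysis window: 60-180 s (first minute discarded)
quick phases injected/detected: 125/125
fast-phase nystagmus frequency: 1.042 Hz
bias velocity: -8.00 deg/s (truth -8.00)
```

Every injected quick phase is recovered; the FPN frequency is the event
count over the window, and the bias comes out at the generated −8 deg/s
(negative = slow phase opposing the CW rotation). The other examples cover
kinematics, pupil tracking, lesion asymmetry, the TAV time constant and the
simulator; `examples/06_velocity_storage_model.py` prints the steady-state
phenotype table:

```
scenario              FPN (Hz)  bias (deg/s)
control                  0.500         -7.14
canal_null               0.000         -0.00
otolith_null             0.000         -0.09
storage_attenuated       0.150         -1.77
uvl_left                 0.500         -7.14
uvl_right                0.100         -1.42
```

A `povar` CLI mirrors the library (`kinematics`, `synth`, `track`,
`segment`, `smc`, `tau`, `simulate`, `analyze`, `paired`); run
`povar --help`.

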