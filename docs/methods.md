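# Methods

`echogaze` emulates a benchtop study of ultrasound gaze sensing end to end:
an acoustic model of a benchtop rig produces digitized receiver traces, a
signal pipeline reduces them to time-of-flight/amplitude features, and
boosted-tree regressors recover the gaze angles. This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Scene model

The model eye is the standard sphere-on-sphere approximation: a scleral
sphere (radius 11.925 mm, fixed at the origin) and a corneal sphere (radius
7.8 mm) whose center sits 5.6 mm from the sclera center along the gaze
axis. The corneal cap — the part of the corneal sphere outside the scleral
ball — protrudes 1.475 mm beyond the sclera, which is what makes echo
timing gaze-dependent. Gaze (θ, ϕ) rotates the corneal center rigidly about
the sclera center (θ about +y, ϕ about +x; +z toward the transducer ring,
+x nasal, +y up; mm and degrees everywhere). The limbus discontinuity in
surface normals inherent to the two-sphere model is accepted.

Transducers sit on a ring facing the eye. The ring radius (20 mm) and the
standoff of the ring plane from the rest corneal apex (25 mm) are package
choices on a glasses-frame scale; no canonical values exist for a benchtop
arc. All transducers aim at the rest apex. The gaze protocol uses a fixed
receiver at ring position 180° (temporal side) and a transmitter stepped
over −90°…+90° in 10° steps through the nasal side.

The occluder is a parametric proxy for the printed face that a physical
bench would mount around the eye: a reflective plane shell 2 mm in front of
the apex with an elliptical aperture (half-width 5.5 mm, half-height
4.5 mm, center raised 1 mm — the palpebral opening sits slightly above the
optical axis, so downward gaze loses paths before upward gaze does), plus a
small tilted "nose-pad" patch near ring azimuth 20° protruding 2.5 mm out
of the shell, oriented to couple nasal transmitter positions to the
receiver. The proxy's free parameters were fixed once so that it produces
the two qualitative occlusion signatures a face imposes on this geometry —
an asymmetric amplitude profile peaking near transmitter position +20°, and
degraded accuracy for downward gaze — and are all exposed in the config.
Disabling the occluder gives the open-eye control condition.

## Acoustics

* **Reflection.** The power reflection fraction at a boundary is
  R = ((Z₂−Z₁)/(Z₂+Z₁))² with Z = ρc. For air (Z ≈ 343 kg m⁻² s⁻¹) against
  any of the solids involved (tear film to glass) R exceeds 99.87%, so all
  solid surfaces reflect with unit amplitude by default (per-bounce
  reflectance is a config hook).
* **Attenuation.** Absorption in air at 1.7 MHz is modeled as a fixed
  470 dB/m: amplitude factor 10^(−470·d/20) per metre of path. Speed of
  sound is fixed at 343 m/s; no temperature or humidity dependence.
* **Directivity.** Both emission and reception apply the native-curve
  weight w(α) = cos(min(α·90/15, 90°)) with a hard cutoff at α = 15°; a
  detected ray carries the product of its emission weight, reception
  weight, and path attenuation. The cutoff is a parameter: a measured
  emission cone can be narrower (≈10°) than the 15° weight model, and the
  two are not reconciled here.

Two propagation engines share this physics:

1. **Monte-Carlo tracer** (`acoustics.trace`): rays uniform on the emission
   hemisphere (counter-based Philox seeding, deterministic), specular
   reflections, analytic ray–quadric intersections (no fixed-step
   marching), detection on finite receiver discs (default radius 0.5 mm;
   sensors block rays they intercept), up to 3 bounces by default — deeper
   recursion is negligible after attenuation and directivity. This engine
   serves the modeling-style questions (directional vs omnidirectional
   comparisons, where signal appears around a frame) with generous
   millimetre-scale sensor apertures of the kind finite-element modeling
   studies use.
2. **Deterministic specular solver** (`specular.specular_arrivals`): the
   bench emulator's engine. Forward Monte Carlo cannot populate a 0.5 mm
   aperture (detection probability ~10⁻⁶/ray off a convex mirror), so
   protocol arrivals are computed analytically: 1-bounce sphere paths from
   Fermat's stationary-path condition (Alhazen's problem, solved by 1-D
   bounded minimisation in the coplanar frame), 1-bounce plane paths by the
   image method, 2-bounce plane+sphere paths by composing the two. Each
   path is weighted by directivity, attenuation, occlusion transmission,
   and a divergence Jacobian |∂(emission direction)/∂(receiver position)|
   estimated by finite differences (δ = 0.05 mm), times the aperture area
   over 2π — which makes the deterministic weights agree with the expected
   per-ray Monte-Carlo detection (verified in the tests to within
   aperture-averaging error). For a plane mirror the Jacobian reduces to
   cos θ/L²; for the convex eye it correctly penalises beam divergence.
* **Soft shadowing.** Occluder plane edges shade with an error-function
  ramp of 1 mm width rather than a geometric step. The scale is the first
  Fresnel zone (√(λL/2) ≈ 1–1.5 mm at λ = 0.197 mm and bench distances):
  hard shadows at these wavelengths are unphysical, and binary path
  blocking would turn single feature columns into blocked/unblocked
  indicator variables. Solid spheres and the flat plate block hard.

## Bench emulation

The transmit burst is 7 cycles at 1.74 MHz (rectangular electrical drive),
repeated at 2 kHz; receiver traces are digitized at 80 MHz for 300 µs
(covers every configured round trip plus the 45 µs analysis window).
Rendered echoes use the drive shaped by a raised-cosine envelope — a
band-limited transducer pair rings up and down, so received packets have a
dominant central crest; an ideal rectangular packet would make "the peak"
an n-way tie between identical crests and inject ±cycle timing noise that
no real bench shows.

The gaze protocol: 36 poses ({−5,−3,−1,+1,+3,+5}² degrees; the 1°-step
11×11 grid is available via `gaze_step_deg`), 19 transmitter positions, 50
repeats per position, 9 sessions. Noise has three configurable parts, none
with a canonical value, all chosen once: per-sample additive Gaussian noise
(std 0.35 trace units, putting the strongest corneal echo near 6 dB peak
SNR on a single shot — too noisy for direct peak picking, clean after
10-trace averaging), per-session multiplicative gain jitter (5%), and
per-session timing offset (0.2 µs) for day-to-day drift. Everything derives
from counter-based seeds keyed by (seed, session, pose, transmitter,
group), so any trace can be re-rendered independently and a dataset is
bitwise reproducible from (config, seed).

The dataset object is lazy: arrivals (one specular solve per pose ×
transmitter) and the manifest are eager; traces render on demand. The
default **fast mode** synthesises each 10-trace group average directly as
one render with additive noise std divided by √10 — statistically identical
for i.i.d. Gaussian noise (the tests verify fast and full modes agree
exactly when noise is off, and that counting is mode-invariant). Full mode
renders all 307,800 single-shot traces.

Benches 1 and 2 (attenuation vs distance; directivity vs angle) are
closed-form: round-trip amplitude 10^(−2·470·d/20·1000) against a flat
plate, and w(|α|) for a rotating facing pair.

What the generator does **not** emulate: diffraction beyond the soft-edge
ramp, interference between overlapping echoes (amplitudes add coherently
only through waveform summation), electronic crosstalk, amplifier
time-gain correction, temperature-dependent sound speed, eyelashes, and
any eye or face geometry beyond the parametric proxies. Passing tests
therefore show that the pipeline recovers gaze from echo timing/amplitude
structure under this idealised bench — not that a physical rig would reach
the same numbers.

## Feature extraction

Per (pose, session): the 50 repeats are averaged in consecutive disjoint
blocks of 10 (k = 0…4), each average band-pass filtered at [1.6, 1.9] MHz
with an order-4 Butterworth. Filtering is zero-phase (forward–backward,
`sosfiltfilt`) by default so the filter's group delay does not bias τ; a
single-pass mode exists. The squared filtered trace locates the echo; a
45 µs window (total width, clipped at trace edges) is centred on its global
maximum; τ is the time of the **first** occurrence of the maximum of the
averaged *raw* trace inside the window (ties break to the earliest sample)
and a is that maximum. No sub-sample interpolation.

A feature vector stacks τ_r then a_r over the 19 transmitter positions —
38 columns (`tof_us_m90 … tof_us_p90, amp_m90 … amp_p90`), 1620 rows
(36 poses × 9 sessions × 5 groups) for the default protocol.

## Regression and reports

Two independent regressors (one per axis) minimise squared error:
gradient-boosted regression trees (xgboost; learning rate 0.0825, depth 5,
750 trees, min child weight 23, α = 0.01, λ = 1 — taken as given, no
search harness) and an ordinary-least-squares baseline. `tree_method=hist`
with one thread keeps fits bit-reproducible across hosts.

Metrics come from shuffled row-level 5-fold CV (a group-by-session splitter
exists for leakage-sensitive runs but is off by default): per-axis RMSE,
pooled RMSE √(mean((e_θ²+e_ϕ²)/2)), and adjusted R² = 1−(1−R²)(n−1)/(n−p−1)
in percent with p = 38, the full feature-column count — also for
feature-family ablations (tof-only / amp-only), so the penalty is identical
across families and their goodness-of-fit numbers are directly comparable.
Further analyses: epsilon-ball sensitivity (fraction of estimates whose
Euclidean gaze error is within a radius), gain-based feature importances
normalised per axis, a 20-shuffle label-permutation null, and a per-pose
mean-error map.

## Numerical choices and degenerate inputs

Geometry tolerance is 1e−9 relative; tangent ray–sphere hits resolve to
"hit". The specular solver refines a 512-point grid bracket with bounded
scalar minimisation (xatol 1e−12), giving path lengths accurate to well
below 1e−6 mm (stationarity makes the length error quadratic in the
parameter error); solutions pinned at visibility boundaries are rejected.
Arrival times are path/343 m/s exactly. Echo insertion rounds to the
nearest sample at 80 MHz. A trace whose analysis window is identically
zero raises a degenerate-trace error; constant regression labels, missing
protocol cells, sub-Nyquist sampling, arrivals beyond the trace duration,
and fold sizes too small for the adjusted-R² denominator all raise typed
errors rather than returning numbers.

## Known limitations

* The deterministic solver enumerates up to 2 bounces (1-bounce plus
  plane↔sphere compositions); sphere↔sphere double bounces and 3-bounce
  paths exist only in the Monte-Carlo engine, where they contribute
  negligible detected weight.
* Amplitudes are arbitrary units; only ratios and decay shapes are
  meaningful, matching how such benches report them.
* The occluder is a proxy; its parameters reproduce qualitative occlusion
  signatures, not any particular face.
* Default test-suite problem sizes: the study-level checks run the full
  default protocol (1620 feature vectors) once per session; Monte-Carlo
  property tests use 8,192–120,000 rays with correspondingly loose
  tolerances, while ray-heavy demos default to 131,072 rays.
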