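# Methods

This note documents the models inside `pcflow`: what is simulated, how the
measurement chain works, which knobs matter, and what the synthetic design
can and cannot say about real data.

## 1. The flow phantom

Each acquisition plane is a 2D pixel grid (default 96×96 at 1.95 mm — a
typical phase-contrast matrix — with 20 frames of 40 ms) carrying a
three-component velocity field `[frame, y, x]` in cm/s, a circular lumen
mask (default radius 15 mm, an aortic root), and a relative
signal-magnitude image (1 in the lumen, 0.05 outside).  Velocities are
identically zero outside the lumen.  Grid coordinates put the origin on a
pixel center so that a jet at (0, 0) attains its nominal peak exactly on
the grid.

**Baseline flow** is a body-force profile `1 − (r/R)^m` scaled by a
half-sine systolic waveform; `m = 2` (Poiseuille) for aortic planes.  The
LVOT plane uses `m = 8`, a blunt plug-like profile, which is what
pulsed-wave Doppler actually samples in the outflow tract; its centerline
speed is set so the LVOT carries the same peak flux as the valve plane.

**Jets.** A stenotic jet has a Gaussian in-plane core of radius σ, a peak
speed, a polar tilt θ against the plane normal and an azimuth φ.  Its
velocity vector at every pixel is the jet-axis unit vector times
`s(t)·g(x, y)`, so the through-plane component scales as cos θ, the
in-plane components as sin θ·(cos φ, sin φ), and the pixel *speed* at the
core equals `s(t)` for any tilt — the invariance that motivates
multi-directional encoding.  Several jets may coexist (bicuspid-type
geometries).

**Waveform.**  Half-sine over systole (default onset 0, duration 320 ms),
zero in diastole; the defaults place the waveform maximum exactly on a
sampled frame (t = 160 ms).  An optional regurgitant fraction adds a
negative diastolic half-sine.

**Cohort severities** follow the conventional peak-velocity bands: none
< 2, mild 2–3, moderate 3–4, severe > 4 m/s.  A subject draws its target
total peak inside the band; because overlapping jets and the baseline flow
shift the realised maximum, jet speeds are rescaled (≤ 3 iterations) until
the multi-plane peak lands on the target, guaranteeing band membership by
construction.  Tilt is uniform in [0°, 30°], azimuth uniform; a secondary
jet (half speed) appears with probability 0.2.  The jet decays across the
three contiguous aortic planes (peak factors 1.0, 1.0, 0.85 for planes
0/1/2) and broadens with distance above the valve (+2% σ per mm), so
planes 0/1 carry the highest peaks.  The decay factors model a reported
phenomenon whose magnitude is not published; they are configuration, not
physics.

**Ground truth** is obtained by direct integration of the generated
fields: per-plane peak-speed curves, per-plane through-plane flux
(rectangle rule over frames, matching the stroke-volume integrator), and
the effective orifice area EOA = flux / ∫v<sub>peak</sub> dt evaluated at
the plane with the highest peak, so continuity-equation estimates computed
at the selected plane have a self-consistent reference.  Note the phantom
does **not** conserve flux across planes: broadening without decay mimics
entrainment, so each plane has its own true flux, and stroke-volume
accuracy must be judged against the flux of the plane actually analysed.

## 2. Simulated Doppler TTE

Continuous-wave Doppler measures, frame by frame, the largest projection
`|v·b|` of any lumen voxel (any aortic plane) onto the acoustic beam
`b`.  A sonographer's window search is emulated by evaluating several
candidate beams — the plane normal plus beams scattered around the true
jet axis with misalignments drawn uniformly in [0°, 15°] — and keeping the
window with the highest envelope.  V<sub>peak</sub>, V<sub>mean</sub>,
MG, PG and VTI then follow from the same operations as the CMR arm.  The
LVOT VTI comes from pulsed-wave style interrogation of the LVOT plane
along its normal, and AVA from the continuity equation with a circular
LVOT of the subject's drawn diameter (2.0–2.4 cm).  Simulated TTE thus
slightly underestimates the true peak (residual beam misalignment), while
1Dir PC-CMR underestimates by the full cos θ — which is exactly the
mechanism that creates the negative 1Dir bias and the 3Dir advantage in
the cohort tables.

## 3. Balanced four-point encoding and decoding

Encoding `i` of four carries phase
`φ_i = (π / (4·Venc)) · (h_i · v) + φ_bg` with Hadamard rows
`h₁ = (−1,−1,−1), h₂ = (+1,+1,−1), h₃ = (+1,−1,+1), h₄ = (−1,+1,+1)`;
the complex image is `M·exp(jφ_i)` plus independent complex Gaussian noise
(σ per channel, in magnitude units; default 0.03).  The 1/4 moment
normalisation is chosen so that each *decoded* component wraps exactly at
±Venc — matching the operational meaning of a scanner's Venc — while
individual encoding phases stay unwrapped up to 4·Venc.  The four-point
moment table itself is the conventional balanced set; the source study
names the scheme but not its normalisation.

Decoding forms, per direction `d`, the argument of the conjugate product
`Π_i z_i^{c_{d,i}}` with `c_d` the d-th Hadamard column, times Venc/π.
Because each column sums to zero, any phase common to the four encodings —
constant or spatially varying background — cancels identically, and using
a single complex argument (rather than differences of individually wrapped
phases) removes order-of-wrapping ambiguity.  No further background-offset
correction is applied anywhere downstream.  The magnitude image is the
pixel-wise minimum over the four encodings.  Zero-magnitude pixels have
undefined phase; they decode to 0 and are counted.  The same Venc applies
to all three directions.

k-space simulation, undersampling and iterative recovery are deliberately
out of scope: noise enters in image space.

## 4. Aliasing detection, Venc scout, unwrapping

A decoded value is a wrap suspect when (a) it opposes the local spatial
median (7×7) while |median| > 0.2·Venc *and* the gap to the median exceeds
Venc — a genuine wrap jumps by ≈ 2·Venc, and this gap condition carries
the specificity against noise — or (b) consecutive frames jump by more
than Venc.  A direction is flagged at ≥ 4 suspect pixels (1 during the
noise-free Venc scout).  The median window must exceed the wrapped-core
diameter, else the median itself wraps.

The Venc scout encodes and decodes the field noise-free at 200, 300 and
400 cm/s, picks the smallest alias-free setting, and escalates in
100 cm/s steps when all scouts alias.

Unwrapping is attempted only for flagged directions.  The temporal pass
anchors each pixel on its lowest-|v| frame (jets are transient, so a
near-zero diastolic anchor exists) and adds multiples of 2·Venc wherever
consecutive frames jump by more than Venc; pixels whose minimum |v|
exceeds 0.9·Venc cannot be anchored.  The spatial pass region-grows from
the lowest-velocity seed in the lumen, shifting neighbours into the same
2·Venc branch; `hybrid` runs temporal then one spatial pass.  Temporal
unwrapping is exact for |v| < 2·Venc with frame-to-frame true change
below Venc (no noise).  If wrap signatures persist afterwards — e.g. a
core aliased in every frame — the salvage is declared failed, the maps
are returned unchanged, and cohort drivers exclude the subject with a
logged reason.

## 5. Quantification

* **Thresholding**: a pixel is retained when its time-minimum magnitude is
  ≥ 0.15 of the maximum *and* its temporal-mean flow speed (|vz| in 1Dir,
  speed in 3Dir) is ≥ 0.05·Venc.  The cut-offs are configuration; the
  flow criterion reads the "temporal phase accumulation" idea as mean flow
  magnitude (a signed-average variant would cancel regurgitant frames).
  The retained mask is static across frames.
* **Peak-velocity curve**: per frame, the maximum of |vz| (1Dir) or speed
  (3Dir) over retained pixels; the plane with the highest curve maximum is
  selected, ties toward the lowest plane.
* **V<sub>mean</sub> and MG** average v and 4v² over the ejection window —
  frames above 1% of the curve maximum.  The floor exists to drop
  diastolic frames; 1% keeps the dense-sampling bias of the window below
  0.7% for a half-sine (a floor at fraction ε biases the mean by
  ≈ 2·arcsin(ε)/π), while still functioning as a noise gate.  Full-cycle
  averaging is available as a config option.  Note MG is the average of
  4v², not 4·V<sub>mean</sub>².
* **VTI** integrates the curve over the full cycle (trapezoid; at default
  frame counts the rectangle-rule difference is below test tolerances).
  With image noise the diastolic curve sits at the noise-envelope floor,
  which inflates VTI and deflates V<sub>mean</sub>/MG relative to the
  noise-free Doppler envelope — visible in the cohort tables as a negative
  V<sub>mean</sub>/MG bias and positive VTI bias for both CMR modes, and
  stronger in 3Dir whose 3-component speed floor is higher.
* **Stroke volume** is Σ vz·pixel-area·Δt over the vessel ROI (manual
  contour analog), using the through-plane component in both modes: flux
  through a plane is the normal component by definition.  The ROI is the
  lumen mask, not the thresholded mask, so slow near-wall flow is kept.
* **Valve areas**: AVA_Cine = SV_cine/VTI_AV, AVA_Flow = SV_PC/VTI_AV,
  and the Doppler-style AVA = π(D/2)²·VTI_LVOT/VTI_AV.  The phantom
  supplies the ground-truth flux as "cine" SV.

## 6. Statistics

Pearson r with Fisher-z 95% CI (SE = 1/√(n−3)) and the two-sided t-test
p; Bland–Altman bias = mean(method − reference) with sample SD and
± 1.96·SD limits; Kolmogorov–Smirnov normality against the fitted normal
(a Lilliefors situation — the asymptotic p is conservative and the caveat
is logged, not table-corrected).  Comparison of the two CMR-vs-reference
correlations defaults to Steiger's Z for dependent overlapping
correlations (both share the reference arm within subjects), with the
independent-samples Fisher z available; identical observed correlations
return p = 1 directly, which also covers degenerate |r| = 1 cohorts.  SV
is compared against the cine stroke volume; AVA variants against the
Doppler continuity AVA; everything else against the TTE reading.  The
moderate+severe subgroup re-analysis is a row filter requiring ≥ 4
subjects.

## 7. Reproducibility and problem sizes

Every random draw in a cohort run descends from one master seed
(subject seeds, encoding noise, TTE windows), so identical (config, seed)
pairs give byte-identical CSVs.  The default cohort is 23 subjects with
the 13/30/39/17% severity mix; validation exercises use 21 subjects for
the comparison tables, 50 for the speed-dominance sweep, 6 at a 48² grid
for byte-level determinism checks, and 4000-point curves for the
closed-form integrals — sizes chosen to make every mechanism measurable
at interactive runtimes.

## 8. Limitations

The phantom is a geometric stand-in, not CFD: no turbulence, no intravoxel
dephasing, no eddy-current or Maxwell phase, no k-space/undersampling
model, no 3D volume.  The true spatial structure of patient jets is
unknown; Gaussian cores are a modelling convenience.  Passing tests
demonstrate that the measurement chain is correct under these assumptions
— projection geometry, wrap arithmetic, integrators, statistics — not that
the phantom reproduces clinical effect sizes.  The plane-decay factors and
TTE misalignment ranges, in particular, set the magnitudes of the
1Dir-vs-3Dir differences and are configuration choices.
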