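# Methods

`aneupiv` is a self-contained virtual counterpart of a stereoscopic-PIV
study of flow-diverter treatment efficacy in an idealized intracranial
aneurysm. Every stage of the real measurement chain — pulsatile phantom
flow, tracer imaging by a stereo camera pair, multi-pass cross-correlation,
three-component reconstruction, phase averaging and hemodynamic metrics —
has a synthetic, seed-reproducible equivalent, so the whole chain can be
validated against closed-form ground truth.

## Flow phantom

**Geometry.** A spherical side-wall aneurysm sac (diameter 20 mm) sits on a
straight parent vessel (diameter 4 mm) and communicates with it through an
ostium of width 8 mm (the sac circle is placed so it cuts the vessel wall at
±4 mm). The physical vessel is bent by 120°; in the sagittal measurement
plane the vessel is treated as locally straight near the ostium, and the
bend angle is carried as a documentation parameter only. Coordinates: x
along the vessel (flow in +x), y into the sac, z out of plane; lengths in
mm, velocities in m/s.

**Fluid.** The blood-analogue liquid has ρ = 1221 kg·m⁻³ and
μ = 5·10⁻³ Pa·s, hence ν = μ/ρ ≈ 4.1·10⁻⁶ m²·s⁻¹. Reference blood values
(μ = 3.9·10⁻³ Pa·s at ρ = 1060 kg·m⁻³) are kept as documentation constants.

**Waveform.** The inflow shape is a constant plus two periodically wrapped
Gaussians in cycle phase (systolic peak at 20 % of the cycle, diastolic
shoulder at 42 %), normalised to unit maximum. Defaults give a
physiological peak/mean flow ratio near two. The peak centreline velocity
is set from the target peak Reynolds number Re = U_peak·D/ν = 1025, giving
U_peak ≈ 1.049 m/s. The cycle duration is **not** uniquely determined by
the printed dimensionless numbers: with T = 1.0 s (the default) the implied
Womersley number is Wo = (D/2)·√(2π/(Tν)) ≈ 2.48 rather than the printed
2.54; T ≈ 0.951 s would reproduce both, while the acquisition arithmetic
(36 000 double frames / 36 cycles at 0.5 kHz) implies T = 2 s. The three
constraints are mutually inconsistent, so T = 1.0 s is declared an
assumption (recorded in every run manifest) and
`WaveformConfig.from_womersley` constructs the exactly-consistent variant.

**Velocity field.** The parent vessel carries a Poiseuille profile
modulated by the waveform. The sac field is built from a stream function in
sac-centred polar coordinates (s = r/R):

- rotating cell: ψ ∝ (1−s²)²(½+s²), giving u_θ ∝ s³(1−s²) — no-slip at the
  wall, a stagnation point at the sac centre, and peak swirl at s ≈ 0.77
  (the near-wall alignment band);
- inflow jet: ψ ∝ s²(1−s²)²·g(θ) with g a Gaussian in azimuth (width 35°)
  centred on the distal ostium edge, strengthening the through-flow where
  the jet enters and impinges on the dome.

Both terms are exactly divergence-free and vanish with zero gradient on the
wall. The in-plane field factorises as U_peak·shape(t)·V(x), so cycle means
have closed form. Peak in-sac speed defaults to 0.3·U_peak, which puts the
ROI-mean speeds in the 0.1 m/s range of the real measurements.

**Treatment scenarios.** A deployment is an effective-medium modification
of the sac flow with four parameters: attenuation α of the in-sac in-plane
velocity; a shift of the jet entry along the wall (used for the
strut-compression case, which enters more proximally); a normalized
out-of-plane fluctuation σ_z; and an extra peak-systolic attenuation
constructed so the flow-weighted cycle mean stays exactly (1−α) while the
peak value scales by (1−α)(1−e). Presets for the five configurations
(untreated + four malposition cases) are calibrated once from the reported
treated/untreated velocity table: α = 0, 0.78, 0.82, 0.89, 0.64 and
σ_z = 0.036 (baseline), 0.052, 0.045, 0.364, 0.368.

**Out-of-plane disturbance.** The physical picture is coherent lateral
sloshing around the malpositioned device, so w is a sum of K = 12
travelling modes with sac-scale wavelengths (10–20 mm), temporal harmonics
2–13 per cycle, and amplitude σ_z times the local cycle-mean in-plane
speed. Cycle-to-cycle stochasticity enters through per-mode phase offsets
that follow low-discrepancy strides (frac(√p) for primes p) across the
cycle index: the ensemble mean of w over recorded cycles is then ~0 and the
realised cycle-to-cycle spread equals the configured level up to the
deterministic √(N/(N−1)) ddof factor, instead of carrying the large
realization noise of iid phases at desk-scale cycle counts (N = 6, where
iid sampling noise would dominate the comparison the generator exists to
emulate). Each cycle still looks like an independent random field. This is
the main idealisation of the generator: real cycle-to-cycle variability is
not variance-controlled, so green tests establish estimator correctness at
the configured fluctuation level, not robustness to ensemble-sampling
noise.

**Tracers and imaging.** Tracers are ideal (Stokes number ≪ 1 for 10 µm
spheres) and are re-seeded uniformly in the lumen light-sheet slab (1 mm)
for every double frame, then advected through the flow map with RK4;
particles leaving the lumen respawn at the inlet. Each camera is telecentric
with viewing directions at ±35° about the in-plane vertical axis, so z
leaks into the sensor u coordinate with sensitivity sin 35°. Particles
render as Gaussian spots (e⁻² diameter 2.5 px, floored at 2 px against peak
locking) with additive Gaussian sensor noise on a constant background.
Because the cameras are virtual, the mapping and its Jacobian are exact;
no calibration-target stage exists, by design.

## PIV engine

Multi-pass FFT cross-correlation (64 → 32 px windows, 50 % overlap, final
vector every 16 px ↔ 141 µm at the reference magnification of
8.8125 µm/px), with:

- **Hann window weighting** with the correlation plane divided by the
  weight autocorrelation (floored at half its maximum). Plain top-hat
  windows suffer a loss-of-pairs bias from particle images truncated at
  window edges (~0.05 px on synthetic uniform shifts); weighting reduces
  bias and random error by roughly an order of magnitude. Top-hat remains
  selectable.
- **Three-point Gaussian sub-pixel fit** per axis with a parabolic
  fallback when a neighbour is non-positive. Residual random error is the
  textbook 0.02–0.05 px from cross-particle correlation noise.
- **Normalized-median validation** (3×3 neighbourhood, noise floor 0.1 px,
  threshold 2) with neighbourhood-median replacement; the replacement
  fraction is logged and warned above 10 %.
- **Stereo reconstruction** by per-point least squares of the four
  projected-displacement equations using the exact camera Jacobians; the
  conversion px → m/s happens only here. The out-of-plane component
  optionally passes a Gaussian low-pass (default 1.5 mm): w carries the
  geometrically amplified share (cot 35° ≈ 1.4×) of the correlation noise
  while the modelled physical w is sac-scale coherent.

**Interframe time.** The acquisition presets (200 µs untreated to 900 µs
for the strongest flow reduction) are quoted at the reference magnification
and scaled proportionally to the pixel pitch, preserving the
pixel-displacement dynamic range when the virtual sensor is coarser than
the real one (desk scale: 512×512 px at 48 µm/px).

## Cycle statistics and metrics

Phase averaging is the pointwise mean and (N−1)-denominator standard
deviation over trigger-locked cycles; masked points stay NaN. Cycle
averages use the periodic trapezoid rule, which on the uniform phase grid
is the plain mean. The scenario's U_mean is magnitude-first (time average
of the ROI spatial-mean speed), because the reported quantities are
strictly positive scalars; the vector average is retained for the OVI.

- **Velocity reduction**: 100·(1 − treated/untreated), reported unrounded
  and rounded to integer percent.
- **Normalized out-of-plane fluctuation** U_z_STD/U_mean: ROI-and-cycle
  mean of the z-component cycle-to-cycle standard deviation divided by the
  scenario's cyclic-mean ROI speed (average-then-normalize; the pointwise
  alternative is available). An optional noise-floor correction subtracts,
  in quadrature, the measurement noise of the U_z channel. The floor is
  estimated from the data alone: with a trigger-locked pump the in-plane
  cycle-to-cycle residual is pure correlation noise, and for a symmetric
  stereo pair the U_z noise equals the u-channel noise times cot(half
  angle) with the same spatial correlation, so passing the u-residuals
  through the same w low-pass reproduces the filtered U_z noise statistics.
  Without the correction the untreated (near-floor) fluctuation is inflated
  by reconstruction noise and treated/untreated contrasts are biased low.
  The assumption (no physical in-plane cycle variability) is exact in the
  phantom and approximate for real data; both raw and corrected values are
  reported.
- **Oscillatory velocity index**: OVI = ½(1 − ‖∫v dt‖ / ∫‖v‖ dt) over one
  cycle with the Euclidean norm over all three components (a 2-component
  variant exists for sensitivity checks); points whose path integral falls
  below 10⁻⁹ m return 0 — no transport supports no oscillation claim —
  keeping the map total and bounded in [0, ½].
- **Probes**: bilinear speed-vs-phase series at three geometric landmarks —
  P1 just inside the distal ostium on the jet path, P2 two millimetres
  below the dome apex, P3 just inside the proximal ostium edge. The exact
  coordinates are declared assumptions.

## Numerical choices and degenerate inputs

- Constant interrogation windows raise (no peak); displacements at the
  circular-correlation boundary are flagged out of range.
- Stereo systems with condition number above 10⁶ raise with the number.
- ROI = sac interior eroded by 1 mm (vectors straddling the wall are not
  meaningful at the final window footprint).
- The reconstruction world grid is the camera-1 vector grid back-projected
  at z = 0 with the frontal pixel scale on both axes; for the symmetric
  telecentric pair both cameras sample this grid exactly at their vector
  nodes, so no interpolation error enters the reconstruction.
- All randomness descends from one root seed via named child seed
  sequences per (cycle, phase) and purpose; reruns with equal manifests are
  bit-identical on disk (float32 storage).

## Known limitations

- Effective-medium treatment: no strut-resolved stent geometry, no wall
  compliance, no non-Newtonian rheology, no refraction modelling.
- The vessel is straight in-plane; the 120° bend is not geometrically
  modelled.
- The in-sac field, while topologically faithful (distal jet entry,
  near-wall alignment, central stagnation), is a two-term stream function,
  not a Navier–Stokes solution.
- Absolute sac velocities are phantom-scale choices; only relative
  treatment contrasts are calibrated to the reported table. The absolute
  reported velocities are reproducible only from the experiment's deposited
  EnSight datasets, which the reader supports but which are not bundled.
- Desk-scale runs (6 cycles × 64 phases, 512² px) trade ensemble size and
  resolution for runtime relative to the full experiment (36 cycles × 1000
  phases, 2560×2160 px).
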