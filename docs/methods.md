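# Methods

## Physical model

The excitation beam is linearly polarized along a lab axis x, passes a
rotatable quarter-wave plate (fast axis at physical angle φ to x) and a
half-wave plate (at θ), and then the microscope train, which is modelled
as a diagonal Jones operator diag(γe^{iδ}, 1): a relative phase shift δ
and amplitude attenuation γ acting on the **x** component of the field.
Only the relative change between components is observable, and the model
places it on x; this is a convention, stated here because it fixes the
sign/axis meaning of the fitted γ and δ. The model assumes a plane wave
(no objective in the beam during calibration) and fully polarized light;
depolarization and high-NA focal-field effects are out of scope.

The field at the image plane has the closed form
Ex = d₁ + i d₂, Ey = d₃ + i d₄ with

```
d1 = -γ [cos δ sin φ sin(2θ-φ) + sin δ cos φ cos(2θ-φ)]
d2 = -γ [sin δ sin φ sin(2θ-φ) - cos δ cos φ cos(2θ-φ)]
d3 =  sin φ cos(2θ-φ)
d4 =  cos φ sin(2θ-φ)
```

equal (verified to 1e-12 against an explicit 2×2 Jones product in the
test suite) to i·M·H(θ)·Q(φ)·(1,0)ᵀ with Q = R(φ)diag(1,−i)R(−φ),
H = R(θ)diag(1,−1)R(−θ). Motor angles are related to physical angles by
fixed mount offsets: φ = φ′ − φ₀, θ = θ′ − θ₀, and α = α′ − α₀ for the
analyzer. All interfaces use degrees; radians are internal.

A linear analyzer at angle α transmits
I(α) = I₀[|Ex|²cos²α + |Ey|²sin²α + 2Re(Ex Ey*) sin α cos α], which in
Stokes form is I₀(S₀ + S₁cos 2α + S₂sin 2α)/2. The ellipse summary is
closed-form: I_max/min = I₀(S₀ ± √(S₁²+S₂²))/2, α_max = ½ atan2(S₂, S₁),
ρ = E_min/E_max. Numerically, ρ is computed as |S₃|/(S₀ + √(S₁²+S₂²)):
for a pure state S₀² = S₁²+S₂²+S₃² exactly, and this form avoids the
catastrophic cancellation that otherwise floors ρ near 1e-9 for nearly
linear light. Handedness is labelled from the sign of
S₃ = −2 Im(Ex Ey*): positive is "right" (fixed, arbitrary convention).
For ρ > 0.999 the ellipse orientation is physically meaningless and
α_max is reported as 0 with a `degenerate_orientation` flag.

`fit_malus` recovers (I_max, I_min, α_max) from an analyzer sweep by the
exact Fourier identity (cos²/sin² → DC + cos 2α + sin 2α), an ordinary
linear solve: no initialization, no iteration, exact on noiseless data.
It requires ≥ 4 distinct angles spanning ≥ 90°.

## Calibration fit

The calibration protocol is a full factorial grid — QWP 0–180° and HWP
0–90° in 10° steps, analyzer 0–180° in 30° steps, 1330 rows, each
intensity an average of 10 readings — fitted by nonlinear least squares
for (δ, γ, φ₀, θ₀, α₀, I₀). The cost surface is multimodal in the angle
offsets, so the fit is multi-started: residual costs are pre-screened on
a coarse offset lattice (4 δ × 8 φ₀ × 4 θ₀ × 6 α₀ values, γ = 1,
I₀ = max I; a cheap vectorized pass) and trust-region refinement
(`scipy.optimize.least_squares`, ftol 1e-10) runs from the 10 best
lattice points; the lowest final cost wins, with early exit on
numerically exact fits. Fifty-draw random-parameter recovery in the test
suite confirms the global optimum is found.

**Identifiability.** The intensity model is invariant under a discrete
group, enumerated empirically on the simulator: the periodicities φ₀ mod
180°, θ₀ mod 90°, α₀ mod 180°, and two nontrivial generators —
(δ, φ₀) → (−δ, φ₀+90°), and the x/y relabelling (γ, I₀, φ₀, θ₀, α₀) →
(1/γ, γ²I₀, φ₀+90°, θ₀+45°, α₀+90°). The canonical cell δ ∈ (−90°, 90°],
φ₀ ∈ [0°, 180°), θ₀ ∈ [0°, 90°), α₀ ∈ [0°, 180°) therefore still contains
four equivalent representatives; the fit reports the one with
lexicographically smallest (γ, φ₀, δ, θ₀, α₀). For instruments on a group
boundary (γ exactly 1) the chosen representative can switch under noise;
all representatives predict identical intensities, and
`canonical_difference` compares two calibrations modulo the group.

**Covariance.** σ̂² = RSS/(n−6); covariance σ̂²(JᵀJ)⁻¹ with the model
Jacobian evaluated by central finite differences at the canonical
optimum (an equally exact minimum, so this is valid and avoids
transforming the covariance through the canonicalization map). A
rank-deficient Jacobian (e.g. an ideal instrument, where offsets are
degenerate) produces an identifiability warning and a pseudoinverse
covariance. Monte-Carlo coverage at 1% noise (100 replicates, 3-std
intervals ≥ 97% hit rate) validates the calibration of these stds.

## Setting solvers

**Linear.** The field is linear iff Im(Ex Ey*) = 0, which reduces to
tan 2φ = −tan δ · sin 2x with x = 2θ − φ. For each x the principal
branch φ ∈ (−45°, 45°] and its 90°-shifted partner both satisfy the
condition but yield different output orientations — this is why every
linear polarization angle is realized by exactly two motor settings.
Target orientations are inverted along each branch by bracketed root
finding (brentq on the wrapped α_max(x) − target difference over a 0.25°
scan grid, wrap-aware), validated on the forward model to < 0.01° in
orientation, and the pair is labelled A/B by ascending θ′ so set
identities are stable across runs.

**Circular.** Requiring Ey = ±i Ex gives two coupled tangent conditions
with paired signs s. Equating them and clearing denominators collapses,
with t = tan φ, to (γ²+1)t + sγ cos δ (1+t²) = 0, i.e.
sin 2φ = −2sγ cos δ/(1+γ²) — a closed form (the right-hand side never
exceeds 1 in magnitude since 2γ/(1+γ²) ≤ 1). x then follows from
tan x = −γ sin δ cos φ/(γ cos δ sin φ + s cos φ). The closed form was
preferred over iterative root bracketing because it is exact across all
sign branches; a Nelder-Mead polish step runs only if the forward-model
ellipticity of a candidate falls below 1 − 1e-12 (it normally does not).
Every returned solution is verified on the forward model (ρ > 1 − 1e-9)
and solutions come in opposite-handed pairs; flipping s flips the
handedness. For an ideal instrument (δ = 0, γ = 1) the conditions
degenerate (0/0): any HWP angle gives circular light once the QWP is at
45° to the input. The representative with x = 2θ − φ = 0 is returned,
matching the textbook QWP-at-45° setting.

**Power calibration.** γ ≠ 1 modulates the peak excitation power across
linear settings. r = I_max(setting)/I_max(reference) is computed from
the model-predicted ellipse maxima. `apply_power_calibration` defaults
to the plain multiplication I′ = r·I; `inverse` and `inverse-squared`
modes are provided because SHG scales quadratically with excitation
intensity, making division by r² the variant that removes the ratio-map
bias — demonstrated end-to-end on the simulator, where an uncompensated
γ = 0.8 stack yields biased (or model-inconsistent) pixels and the
r²-compensated stack recovers the ground truth exactly.

## Uncertainty propagation

First-order (delta-method) propagation: var(f) = gᵀCg, with gradients by
central finite differences (relative step 1e-6, floor 1e-8°; the
functions are smooth and no analytic derivatives are needed). Two
estimands mirror how settings are used:

* circular: φ′(φ₀, δ, γ) from the closed form; then θ′(θ₀, φ₀, δ, γ)
  with φ′ held fixed at its nominal value — the QWP is parked before the
  HWP is solved, so its realized angle contributes no uncertainty to the
  HWP equation;
* linear: the band around φ′(x) with x = 2θ′ − φ′ treated as exact, and
  its image in the (φ′, θ′) plane through θ′ = (x + φ′)/2.

The Monte-Carlo oracle in the tests samples parameters from the fitted
covariance and re-solves the same functionals; agreement is within 15%
at 10,000 draws. Reported intervals default to ±3 std (configurable).
Note the delta method quantifies only statistical uncertainty from the
fit; a systematic mount misalignment moves the truly best setting outside
the interval and can only be caught by fine-grained verification maps.

## P-SHG pixel analysis

Preprocessing: 3×3 mean filter per frame with reflect (edge-including)
padding, chosen because it preserves the local mean at borders and is
deterministic. A pixel is masked `saturated` if any **raw** frame reaches
the saturation value (dtype max for integer stacks, e.g. 255/65535,
overridable), evaluated before smoothing; and `low_intensity` if the
across-frame mean of the smoothed stack is below the gray-value
threshold (default 10). "Average gray value" is interpreted as the
across-frame mean (frame-wise masking would be the alternative reading);
raising the threshold never unmasks a pixel.

Each unmasked pixel's response is fitted by **linear** least squares on
the basis {1, cos 2α, sin 2α, cos 4α, sin 4α}; the design depends only on
the shared angle list, so one pseudoinverse serves the whole image
(512×512 fits in seconds). With c = (χ₃₃+χ₃₁)/2, d = (χ₃₃−χ₃₁)/2,
e = χ₁₅ (× a common brightness factor), the C6v intensity model
I ∝ (χ₃₁sin²α′ + χ₃₃cos²α′)² + (χ₁₅ sin 2α′)² has a₀ = c² + d²/2 + e²/2,
second-harmonic amplitude 2cd at phase 2φ, and fourth-harmonic amplitude
d²/2 − e²/2 at phase 4φ. Inversion: φ from the second-harmonic phase
(from the fourth when the second vanishes, i.e. χ₃₃ ≈ χ₃₁); then
{c², d²} are the two roots of v² − (a₀+S₄)v + S₂²/4 = 0 and
e² = d² − 2S₄. A negative discriminant or negative squared amplitude
means the profile is inconsistent with the model and the pixel is masked
`fit_failed`, as are isotropic pixels (both harmonics below 1e-9 of a₀).

The model cannot distinguish (R₃₃, R₁₅, φ) from (1/R₃₃, R₁₅/R₃₃,
φ+90°); the fit reports the branch with χ₃₃/χ₃₁ ≥ 1 (the collagen case).
χ₁₅ enters only squared, so the reported χ₁₅/χ₃₁ is an absolute value.
Difference maps between the two setting sets subtract on jointly
unmasked pixels, with fiber-angle differences wrapped to (−90°, 90°].

## Virtual instrument and tissue

The virtual microscope evaluates the same forward model with known true
parameters; each tabulated calibration intensity is the mean of 10 noisy
readings (default additive Gaussian, σ as a fraction of I₀ — power-meter
sample averaging makes near-Gaussian noise the natural default; a
multiplicative jitter term is available). The virtual tissue holds
ground-truth maps of R₃₃ ∈ [1.2, 2.2], R₁₅ ∈ [0.5, 1.5] and φ (uniform),
values in the range reported for collagen; rendered pixel intensity is
brightness · (I_max/I₀)² · C6v-response + background, the squared factor
encoding the two-photon dependence on excitation power so that γ ≠ 1
produces exactly the bias the power calibration corrects. Optional
Poisson noise and 8-bit quantization (which creates genuine saturation)
are available. All generators are deterministic under their seed.

What the simulator does **not** emulate: objective/NA polarization
distortions, scan-mirror blanking artifacts, detector nonlinearity,
spatially varying background, out-of-plane fiber tilt, and partial
polarization. Passing tests therefore demonstrate the correctness of the
estimation chain under the stated model, not robustness to every
real-tissue effect.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path: the full 1330-row calibration grid, 100-replicate coverage
runs, 10,000-draw Monte-Carlo oracles, and image sizes of 8–32 px per
side (a 512×512 frame differs only in runtime). Key tolerances: 1e-12
for Jones-oracle agreement, 1e-6 for noiseless parameter recovery, 1e-9
for forward-model linearity/circularity of solved settings, 0.01° for
linear-target orientation, 15% for delta-method vs Monte-Carlo, and
1e-7–1e-9 for noiseless P-SHG round trips.
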