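# Methods notes

This note records the scientific conventions, default parameters, and the
open design choices made in `vsdmask`, in the spirit of a model-description
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic VSDI sessions

The generator produces the three recording blocks of a similarity-masking
experiment day: a *fixation* block (target and full-field gratings flashed
at 5 Hz, 60 ms ON / 140 ms OFF, 1.0 s) used to build decoding templates, a
*detection* block (oriented backgrounds at 0°, ±15°, ±30°, ±45°, ±60°, 90°
with a 50% chance of an additive target), and a *reference* block
(target-only trials across contrasts) for cross-day amplitude pooling.

**Signal model.**  A trial stack is
`F(x,t) = F0(x)·(1 + dff(x,t) + noise) + α(x)·v(t)` with

- `dff(x,t) = s(t)·g·[C_T·env(x)·(1 + κ·A·cos2(θ−θ_T)) + C_B·(1 + κ·A·cos2(θ−θ_B))]`
  — a retinotopic envelope response for the target, a spatially uniform
  drive for the full-field background, and a columnar-band ripple
  `A(x)cos 2(θ(x)−θ_stim)` on both, all linear in Michelson contrast;
- `s(t)` a gamma-CDF rise/decay (latency 40 ms, shape 4, scale 15 ms,
  peak-normalized) chosen to mimic target responses that begin ~40 ms after
  onset and peak around 100 ms;
- `env(x)` a 2-D Gaussian (default σ = 1 mm on an 8×8 mm², 128×128 grid);
- `θ(x), A(x)` the half-angle and modulus of a random complex field
  band-limited to 0.8–3.0 cyc/mm (hard spectral annulus, so ≥99% of the
  columnar power is in-band by construction);
- `F0(x)` a two-scale static fluorescence pattern: coarse staining
  inhomogeneity (Gaussian-filtered noise, σ = 8 px, 10%) times fine
  vessel-like texture (σ = 2 px, 8%).  The fine scale is what makes global
  motion estimable by image registration, as vasculature does in real
  recordings;
- motion planted through the separable model itself:
  `α(x) = −∇F0(x)`, `v(t)` a 3 Hz sinusoid — i.e. first-order sub-pixel
  translation, exactly the structure the stabilization stage assumes.

**Defaults real data do not pin down.**  VSDI noise statistics vary
strongly between preparations, so the defaults (white per-pixel dF/F noise
σ = 1·10⁻³ per frame, spatially correlated noise σ = 5·10⁻⁴ with 5-px
correlation length, response gain 0.01 ΔF/F per unit contrast, columnar
modulation 0.3) were chosen once as a realistic VSDI signal-to-noise regime
— single-trial ΔF/F responses of a few 10⁻³ against comparable noise — and
are configurable.  A ~2 Hz global heartbeat sinusoid is available but off
by default.  Reaction times are shifted log-normal (median 180 ms, floor
75 ms); the measurement convention, not the generative form, is what the
behavioral analysis depends on.

Passing closed-loop tests on this generator demonstrates internal
consistency of the estimators — templates, variances, decoders, d′ — at a
realistic SNR.  It does not demonstrate robustness to real-data features
the generator omits: non-rigid motion beyond the separable model, dye
bleaching, heartbeat/respiration artifacts locked to irregular rhythms, eye
movements, or neural response nonlinearity (trial stacks are linear in
contrast; masking is injected only into behavior).

## Preprocessing

Stabilization follows the separable motion model
`I(x,t) = I0(x,t) + α(x)·v(t)`: one global translation per frame is
estimated from the central quarter of each image by phase cross-correlation
(upsampling factor 50) against the mean pre-onset frame, then per-pixel
coupling coefficients α(x) are fit by least squares and the motion term
subtracted.  Two numerical details matter: the correlation inputs are
mean-subtracted and Hann-windowed (otherwise the DC pedestal and window
edges bias sub-pixel shifts toward zero on smooth images), and v(t) is
mean-centered before the α fit because the model is only identified up to a
constant image.

ΔF/F uses the per-pixel mean over −80..0 ms before onset as F0.  The
columnar bandpass is a frequency-domain annulus at 0.8–3.0 cyc/mm with
raised-cosine edges of 0.1 cyc/mm (hard edges ring; the transition zone
means the filter is exactly idempotent only for content clear of the
edges).  Flash responses are the single-bin Fourier amplitude/phase at 5 Hz
over the 1.0-s stimulation window, scaled so a pixel following
`a·sin(2π·5t)` reports amplitude `a`.

## Decoding

Templates: elliptical 2-D Gaussian with offset (moment-initialized
nonlinear least squares) for the retinotopic map; per-pixel orientation
tuning from the vector sum `Σ_k resp_k·e^{2iθ_k}` of bandpassed grating
amplitude maps for the columnar map.  Reliability weights divide each
template pixel by the variance of condition-mean-subtracted residuals
(columnar-scale residuals bandpassed first), floored at the 1st percentile
of positive values so quiet pixels cannot dominate.  Columnar decoding is
restricted to pixels within the 2-SD retinotopic ellipse; norms are
Euclidean over included pixels.  Orientation bins are (−75°…90°, 15° steps,
half-width ±7.5°]; a pixel exactly on a bin edge joins the lower bin.
Empty bins propagate as missing (NaN) channels rather than zeros.

## Population vectors

`z = Σ_k r_k e^{2iθ_k}`; angle = arg(z)/2 mapped to [−90°, 90°), magnitude
= |z|, and *coherence* = |z| / Σ_k|r_k| ∈ [0, 1].  The coherence is the
normalization used for the 0.2 display threshold on trajectory headings —
this 0–1 form was chosen because it makes the threshold scale-free.  Negative channel
values stay in the sum (they rotate the vector by 90°).  Clockwise/
anticlockwise backgrounds of equal disparity can be pooled by mirroring the
channel axis of the negative-orientation member before averaging.

## Statistics

The pooled estimators are deliberately literal even where they are not
the conventional forms: the weighted mean/SD place the weight inside
both sums and divide by n, and the weighted covariance multiplies each
deviation by its weight (so weights enter quadratically).  The correlation
ρ built from these covariances is nevertheless invariant to affine
transforms of either variable and to rescaling of the weights, and reduces
to Pearson r at equal weights.  Significance uses
`t = ρ√((n_eff−2)/(1−ρ²))` with the entropy-based effective sample size
`n_eff = exp(−Σ w̃ ln w̃)` and a t distribution with (possibly non-integer)
`n_eff − 2` degrees of freedom.

Trend selection compares a line `mθ + c` with a Gaussian
`A·e^{−θ²/2σ²} + c` by a nested F test,
`F = (SS_flat − SS_gau) / (SS_gau/(n−3))`, Gaussian chosen at α = 0.05.
Because the Gaussian's width is free (and the two models are not strictly
nested), the test is mildly anti-conservative: under flat-truth noise the
Gaussian is selected at ~7–8% rather than 5%.  This is a property of the
procedure itself and is asserted as such in the tests.

SVD pooling stacks each experiment's (frames × contrast) target-only
response — linearly interpolated to the union contrast grid, edges clamped
— and takes the first singular component; an experiment's loading is the
norm of its SVD1 coefficients, scales match everything to the
largest-loading experiment, and reliability weights are 1/scale².
Per-frame p-values in correlation time courses are reported raw, without
multiple-comparison correction, and flagged as such.

## Normalization model

Per channel: `r = r_e^p/(r_n^p + r0^p)` with p = 2, r0 = 0.03125, and
drives `(c^e ∗ h)(x₀, t)` evaluated at the stimulus center; kernels are
unit-mass 2-D Gaussians (s = 0.28°) times unit-mass gamma densities
(excitation a = 9, b = 8 ms; normalization a = 9, b = 10.64 ms);
orientation tuning Gaussians σ_e = 15°, σ_n = 20° act on differences
wrapped to [−90°, 90°] (the raw difference would break 180° periodicity).

Conventions the equations alone do not fix:

- **Contrast units.**  Drives are linear in *rms* contrast
  (Michelson/√2).  In these units r0 = 1/32 behaves as a semisaturation
  contrast (≈3%, a typical V1 value), and the 24%-target-only response
  peaks ≈105 ms after onset, matching the described target dynamics.  The
  24%-target normalization is applied to the *output* (responses are
  expressed in units of the 24% target-only response averaged over
  50–200 ms); rescaling the drives themselves by that reference instead
  would make r0 negligible and collapse the dynamics into an early
  transient.
- **λ(x).**  The target+background effective contrast is
  `λ(x)·√(c_B² + c_T²)` with `λ = C_TB/√(C_B² + C_T²)` computed from local
  rms contrasts of the rendered luminance patterns (both cosine-centered,
  4 cyc/deg) in a Gaussian window of SD s_e.  In-phase parallel pairs then
  sum coherently (λ > 1) and oblique/orthogonal pairs combine in quadrature
  (λ ≈ 1).  Because the target envelope (σ = 0.14°) is narrower than the
  rms window (0.28°), the coherent center value is recovered only to ~10%;
  this bias is small relative to the model's qualitative behavior and is
  covered by the tests at that tolerance.
- **Discretization.**  dt = 1 ms, 400-ms horizon, spatial grid 0.02° over
  ±3°, stimulus pulse a unit box of width D (250 ms default).  Outputs are
  box-averaged into 10-ms frames labeled at bin centers to mirror the
  100-Hz imaging frame rate; the background-only population-vector peak
  frame is insensitive to dt between 1 and 10 ms.

Known limitations: the model's per-channel responses are not sublinear
(TB ≤ T + B) at literally every instant — during the early transient the
in-phase λ boost produces the similarity *enhancement* that is the point of
the biphasic dynamic, and small late violations persist at weakly driven
flank channels.  Sublinearity holds, and is asserted, for the 0–90
projected population response throughout the sustained window (100 ms to
stimulus offset).  Setting σ_n = σ_e (or even removing normalization tuning
entirely) weakens but does not abolish the late positive behavior
correlation in this implementation, because contrast saturation at the
background-matched channels also suppresses similar-background target
responses; the tests record this as an open discrepancy with the qualitative
claim that tuned normalization is required for the late phase.

## Pipeline

`run_pipeline(config, outdir)` is reproducible from config + seed alone
(the summary embeds a config hash), persists per-stage CSV tables, and at
test scale uses a 64×64 grid with a handful of trials per orientation; the
full 128×128 (or 512×512) geometry is a config change, not a code path.
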