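# vsdmask

Analysis toolkit for **orientation similarity masking** in primary visual
cortex as measured with voltage-sensitive dye imaging (VSDI).  In a
similarity-masking detection task, a small oriented Gabor target is added to
a larger oriented grating background; detectability collapses as the
background orientation approaches the target orientation — the neural basis
of camouflage.  `vsdmask` re-implements the complete desk-scale analysis of
such an experiment on synthetic data: stimulus-locked VSDI trial stacks,
motion-stabilized ΔF/F preprocessing, reliability-weighted retinotopic and
columnar template decoding, orientation population-vector dynamics,
signal-detection behavioral summaries, reliability-weighted pooled statistics,
and a delayed, orientation-tuned divisive-normalization model that
reproduces the biphasic masking dynamics.

It is aimed at systems/computational neuroscientists who want a tested,
reusable reference implementation of these methods, or a synthetic testbed
for developing widefield-imaging decoders.

## The core quantities

**Decoding.**  Each 10-ms ΔF/F frame `R(x,t)` is projected onto
reliability-weighted templates built from a separate fixation block:

- retinotopic: `r_ret(t) = R(x,t)·Ĥ_ret / ‖Ĥ_ret‖`, with
  `Ĥ_ret = H_ret/σ²_ret(x)` a 2-D Gaussian fit to the flashed-target
  response, down-weighted by per-pixel residual variance;
- columnar 0–90 axis: `r_0−90(t) = R_col(x,t)·Ĥ_0−90 / ‖Ĥ_0−90‖` with
  `Ĥ_0−90 = Re(H_ori)/σ²_col(x)` and `H_ori = H_ret·A·e^{2iθ}` the complex
  orientation-column map (0.8–3.0 cyc/mm band);
- population: 12 channels at −75°…90° in 15° steps, each the normalized
  response of pixels preferring that orientation bin.  The channels sum to
  a complex population vector `z = Σ_k r_k e^{2iθ_k}` whose half-angle is
  the decoded orientation and whose modulus the tuning magnitude.

**Behavior.**  Equal-variance Gaussian observer:
`d′ = Φ⁻¹(P̂_hit) − Φ⁻¹(P̂_FA)` with proportions rescaled to
`P̂ = 0.005 + 0.99·P`; the masking profile is an inverted, dc-shifted
Gaussian `d′(θ) = c − A·e^{−θ²/2σ²}`.

**Model.**  Twelve orientation channels each compute

    r(t) = r_e(t)^p / (r_n(t)^p + r0^p)

where `r_e`, `r_n` are excitatory and normalization drives obtained by
convolving the channel's effective stimulus contrast with separable
Gaussian × gamma spatiotemporal kernels.  The normalization pool is more
broadly tuned (σ_n = 20° > σ_e = 15°) and slower (gamma scale 10.64 vs
8 ms); the delayed, tuned denominator produces a biphasic target-evoked
response — early enhancement by target–background similarity, late
suppression — and a behavior correlation that flips from negative to
positive over the trial.

## Worked example

Simulate the model and a behavioral session:

```bash
$ vsdmask model
background-only population-vector peak: 85 ms
target-evoked 0-vs-90 background crossing: 82 ms
```

The first line is the delayed-normalization signature: the background-only
population vector grows, peaks (here 85 ms after onset), then drops as the
slower normalization signal catches up.  The second line is the biphasic
crossing: the 0°-channel target-evoked response on a similar (0°) background
starts above the orthogonal (90°) background trace and crosses below it.

```python
from vsdmask import synth, behavior

maps = synth.make_ground_truth(seed=11)
design = synth.BlockDesign(trials_per_orientation=500, render_stacks=False)
session = synth.simulate_session(design, maps, seed=21)
print(behavior.summarize_session(session.detection_block).masking_fit)
# (1.626, 29.54, 2.444)
```

The generator drew outcomes from the masking profile (A, σ, c) =
(1.5, 30°, 2.5); at 500 trials per orientation the fitted parameters come
back within sampling error — depth A ≈ 1.63, width σ ≈ 29.5°, asymptote
c ≈ 2.44 d′ units.

The full pipeline (synthetic session → templates → decoding → statistics →
model) runs from a config and writes CSV tables, a JSON summary, and
overview figures:

```bash
vsdmask run --seed 7 --out results/run7
```

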