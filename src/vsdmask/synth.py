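"""Synthetic VSDI session generator.

Generates everything a desk-scale run of the analysis needs: ground-truth
retinotopic and columnar orientation maps, raw fluorescence trial stacks with
stimulus-locked responses, spatially correlated noise and planted camera/
cortex motion, and signal-detection behavioral outcomes.  All outputs are
pure functions of their parameters and an integer seed.

The signal model mirrors the decoding assumptions downstream: a target
drives a retinotopic (mm-scale) Gaussian envelope response, any oriented
stimulus additionally drives a columnar-band ripple
``A(x) * cos(2*(theta(x) - theta_stim))`` scaled by stimulus contrast, and
the whole response rides multiplicatively on a static baseline fluorescence
image.  Motion enters through the separable model ``I = I0 + alpha(x).v(t)``
with ``alpha = -grad(I0)``, i.e. first-order sub-pixel translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage, stats

from .utils import (
    gaussian_2d,
    orientation_difference,
    spawn_rngs,
    wrap_orientation,
)

MIN_REACTION_TIME_MS = 75.0

OUTCOMES = ("hit", "miss", "correct_reject", "false_alarm")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of one detection-task stimulus.

    Contrasts are Michelson fractions in [0, 1]; orientations are degrees
    with 180-deg periodicity (0 deg = horizontal target orientation).  The
    target is a Gabor (4 cyc/deg, Gaussian envelope sigma 0.14 deg); the
    background a 4-deg raised-cosine windowed grating.  Both are
    cosine-centered so a 0-deg background is fully in phase with the target.
    """

    target_contrast: float = 0.0
    target_orientation: float = 0.0
    target_sigma: float = 0.14
    spatial_frequency: float = 4.0
    background_contrast: float = 0.0
    background_orientation: float = 0.0
    background_diameter: float = 4.0
    duration_ms: float = 250.0
    phase_alignment: bool = True

    def __post_init__(self):
        for name in ("target_contrast", "background_contrast"):
            c = getattr(self, name)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"{name}={c} outside [0, 1]")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        object.__setattr__(self, "target_orientation",
                           float(wrap_orientation(self.target_orientation)))
        object.__setattr__(self, "background_orientation",
                           float(wrap_orientation(self.background_orientation)))

    @property
    def target_present(self) -> bool:
        return self.target_contrast > 0

    @property
    def envelope_fwhm_deg(self) -> float:
        """Full width at half maximum of the target's Gaussian envelope."""
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.target_sigma


@dataclass
class GroundTruthMaps:
    """Generative maps of one synthetic imaging field.

    ``orientation_preference`` is in [0, 180) degrees per pixel;
    ``columnar_magnitude`` is the non-negative ripple amplitude;
    ``retinotopic_envelope`` is the unitless mm-scale response gain of the
    target with a single interior maximum.  ``baseline_image`` is the static
    fluorescence pattern (camera units) the responses ride on.
    """

    retinotopic_envelope: np.ndarray
    orientation_preference: np.ndarray
    columnar_magnitude: np.ndarray
    mm_per_pixel: float
    baseline_image: np.ndarray
    envelope_center: tuple
    envelope_sigma_mm: float
    column_band: tuple

    @property
    def grid_shape(self):
        return self.retinotopic_envelope.shape

    @property
    def complex_field(self):
        """Band-limited columnar field ``A(x) * exp(2i*theta(x))``."""
        return self.columnar_magnitude * np.exp(
            2j * np.deg2rad(self.orientation_preference))


@dataclass
class ImageStack:
    """Time-ordered frames with acquisition metadata.

    ``frames`` is (T, H, W), either raw fluorescence (camera units,
    ``is_dff=False``) or dF/F (unitless, ``is_dff=True``).  ``onset_index``
    is the first frame at/after stimulus onset; ``baseline_window_ms`` is
    relative to onset.
    """

    frames: np.ndarray
    frame_rate: float = 100.0
    onset_index: int = 30
    is_dff: bool = False
    baseline_window_ms: tuple = (-80.0, 0.0)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if not 0 <= self.onset_index < self.frames.shape[0]:
            raise ValueError("onset_index outside stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    def times_ms(self) -> np.ndarray:
        """Frame times in ms relative to stimulus onset."""
        idx = np.arange(self.n_frames) - self.onset_index
        return idx * 1000.0 / self.frame_rate

    def copy_with(self, frames, **kw) -> "ImageStack":
        out = ImageStack(frames=frames, frame_rate=self.frame_rate,
                         onset_index=self.onset_index, is_dff=self.is_dff,
                         baseline_window_ms=self.baseline_window_ms)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class TrialRecord:
    """One behavioral trial with (optionally) its rendered image stack."""

    stimulus: StimulusSpec
    target_present: bool
    outcome: str
    reaction_time_ms: Optional[float] = None
    stack: Optional[ImageStack] = None
    block: str = "detection"

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        saccade = self.outcome in ("hit", "false_alarm")
        if saccade and self.reaction_time_ms is None:
            raise ValueError("saccade outcome requires a reaction time")
        if not saccade and self.reaction_time_ms is not None:
            raise ValueError("fixation outcome cannot carry a reaction time")
        if self.reaction_time_ms is not None and self.reaction_time_ms < MIN_REACTION_TIME_MS:
            raise ValueError("reaction time below the 75 ms minimum")


@dataclass
class Session:
    """One synthetic experiment day: fixation, detection, reference blocks."""

    fixation_block: list
    detection_block: list
    reference_block: list
    ground_truth: GroundTruthMaps
    seed: int


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise in dF/F units.

    White per-pixel noise plus a low-spatial-frequency correlated field
    (Gaussian-filtered white noise rescaled to ``corr_sd``), plus an
    optional global heartbeat-locked sinusoid.
    """

    white_sd: float = 1.0e-3
    corr_sd: float = 5.0e-4
    corr_length_px: float = 5.0
    heartbeat_amp: float = 0.0
    heartbeat_hz: float = 2.0

    def __post_init__(self):
        if self.white_sd < 0 or self.corr_sd < 0:
            raise ValueError("noise SDs must be non-negative")


#: Noise-free spec, convenient in tests.
NO_NOISE = NoiseSpec(white_sd=0.0, corr_sd=0.0, heartbeat_amp=0.0)


@dataclass(frozen=True)
class MotionSpec:
    """Planted global translation v(t): a sinusoid in x and y (pixels)."""

    amplitude_px: float = 0.0
    frequency_hz: float = 3.0
    phase_offset: float = np.pi / 2.0

    def trace(self, n_frames: int, frame_rate: float) -> np.ndarray:
        t = np.arange(n_frames) / frame_rate
        vx = self.amplitude_px * np.sin(2 * np.pi * self.frequency_hz * t)
        vy = self.amplitude_px * np.sin(2 * np.pi * self.frequency_hz * t
                                        + self.phase_offset)
        return np.stack([vx, vy], axis=1)


NO_MOTION = MotionSpec(amplitude_px=0.0)


@dataclass(frozen=True)
class TemporalResponse:
    """Stimulus-locked dF/F time course: gamma-filtered pulse.

    The response is ``G(t - latency) - G(t - latency - duration)`` with G the
    gamma(shape, scale) CDF, peak-normalized to 1 for the trial's pulse.
    Defaults give ~40 ms onset latency and a peak around 100 ms, matching
    published VSDI target dynamics.
    """

    latency_ms: float = 40.0
    shape: float = 4.0
    scale_ms: float = 15.0

    def evaluate(self, t_ms: np.ndarray, duration_ms: float) -> np.ndarray:
        g = stats.gamma(self.shape, scale=self.scale_ms)
        resp = g.cdf(t_ms - self.latency_ms) - g.cdf(t_ms - self.latency_ms - duration_ms)
        peak = g.cdf(duration_ms) - 0.0  # max of the pulse response
        return resp / peak if peak > 0 else resp


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_ground_truth(grid_shape=(128, 128), mm_per_pixel=8.0 / 128.0,
                      envelope_center=None, envelope_sigma_mm=1.0,
                      column_band=(0.8, 3.0), seed=0,
                      baseline_level=1000.0,
                      baseline_pattern_sd=0.1) -> GroundTruthMaps:
    """Generate ground-truth retinotopic and columnar maps.

    The columnar orientation map is the half-angle of a random complex field
    whose spectrum is confined to the annulus ``column_band`` (cycles/mm);
    its magnitude map is the field modulus normalized to unit mean.  The
    retinotopic envelope is an isotropic 2D Gaussian of ``envelope_sigma_mm``
    with a single interior maximum at ``envelope_center`` (pixels, row/col;
    default grid center).
    """
    low, high = column_band
    if not 0 < low < high:
        raise ValueError("column band must satisfy 0 < low < high")
    nyquist = 1.0 / (2.0 * mm_per_pixel)
    if high > nyquist:
        raise ValueError(
            f"column band upper edge {high} cyc/mm exceeds the Nyquist "
            f"frequency {nyquist:.3f} cyc/mm at {mm_per_pixel} mm/px")
    if envelope_sigma_mm <= 0:
        raise ValueError("envelope_sigma_mm must be positive")

    h, w = grid_shape
    rng_field, rng_base = spawn_rngs(seed, 2)

    # band-limited complex field -> orientation preference + magnitude
    z = rng_field.standard_normal((h, w)) + 1j * rng_field.standard_normal((h, w))
    fy = np.fft.fftfreq(h, d=mm_per_pixel)
    fx = np.fft.fftfreq(w, d=mm_per_pixel)
    rad = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    mask = (rad >= low) & (rad <= high)
    field = np.fft.ifft2(np.fft.fft2(z) * mask)
    magnitude = np.abs(field)
    magnitude = magnitude / magnitude.mean()
    orientation = np.rad2deg(np.angle(field)) / 2.0 % 180.0

    if envelope_center is None:
        envelope_center = ((h - 1) / 2.0, (w - 1) / 2.0)
    envelope = gaussian_2d((h, w), envelope_center,
                           envelope_sigma_mm / mm_per_pixel)

    # two-scale baseline: coarse staining inhomogeneity plus fine vessel-like
    # texture (the texture is what makes motion estimable and what motion
    # artifacts accentuate)
    rough = ndimage.gaussian_filter(rng_base.standard_normal((h, w)), 8.0)
    rough = rough / max(rough.std(), 1e-12)
    fine = ndimage.gaussian_filter(rng_base.standard_normal((h, w)), 2.0)
    fine = fine / max(fine.std(), 1e-12)
    baseline = baseline_level * (1.0 + baseline_pattern_sd * rough) \
        * (1.0 + 0.8 * baseline_pattern_sd * fine)
    baseline = np.clip(baseline, 0.05 * baseline_level, None)

    return GroundTruthMaps(
        retinotopic_envelope=envelope,
        orientation_preference=orientation,
        columnar_magnitude=magnitude,
        mm_per_pixel=mm_per_pixel,
        baseline_image=baseline,
        envelope_center=tuple(envelope_center),
        envelope_sigma_mm=float(envelope_sigma_mm),
        column_band=(float(low), float(high)),
    )


def _stimulus_dff_pattern(stimulus: StimulusSpec, maps: GroundTruthMaps,
                          response_gain: float, columnar_gain: float) -> np.ndarray:
    """Peak spatial dF/F pattern evoked by a stimulus (before temporal shaping)."""
    pattern = np.zeros(maps.grid_shape)
    A = maps.columnar_magnitude
    theta = maps.orientation_preference
    if stimulus.target_contrast > 0:
        ripple = columnar_gain * A * np.cos(
            2 * np.deg2rad(orientation_difference(theta, stimulus.target_orientation)))
        pattern += response_gain * stimulus.target_contrast * \
            maps.retinotopic_envelope * (1.0 + ripple)
    if stimulus.background_contrast > 0:
        ripple = columnar_gain * A * np.cos(
            2 * np.deg2rad(orientation_difference(theta, stimulus.background_orientation)))
        pattern += response_gain * stimulus.background_contrast * (1.0 + ripple)
    return pattern


def render_trial_stack(stimulus: StimulusSpec, maps: GroundTruthMaps,
                       response_gain: float = 0.01,
                       columnar_gain: float = 0.3,
                       noise: NoiseSpec = NO_NOISE,
                       motion: MotionSpec = NO_MOTION,
                       seed: int = 0,
                       n_frames: int = 120,
                       frame_rate: float = 100.0,
                       onset_index: int = 30,
                       temporal: TemporalResponse = TemporalResponse(),
                       flash_hz: Optional[float] = None,
                       flash_on_ms: float = 60.0,
                       flash_train_ms: float = 1000.0) -> ImageStack:
    """Render one raw-fluorescence trial stack.

    The noiseless dF/F at the envelope center for a target-only stimulus
    peaks at ``response_gain * target_contrast`` (columnar ripple aside).
    ``flash_hz`` switches the temporal profile to a flashed train (fixation
    block): pulses of ``flash_on_ms`` at ``flash_hz`` for ``flash_train_ms``.

    Returns raw fluorescence: ``F = F0(x) * (1 + dff + noise) + alpha(x).v(t)``
    with ``alpha = -grad(F0)``, so motion is exactly the separable model the
    preprocessing stage assumes (first-order sub-pixel translation).
    """
    if noise.white_sd < 0:
        raise ValueError("noise variance must be non-negative")
    rng = np.random.default_rng(seed)
    t_ms = (np.arange(n_frames) - onset_index) * 1000.0 / frame_rate

    if flash_hz is None:
        tc = temporal.evaluate(t_ms, stimulus.duration_ms)
    else:
        period = 1000.0 / flash_hz
        onsets = np.arange(0.0, flash_train_ms - 1e-9, period)
        tc = np.zeros_like(t_ms)
        for t0 in onsets:
            tc += temporal.evaluate(t_ms - t0, flash_on_ms)

    pattern = _stimulus_dff_pattern(stimulus, maps, response_gain, columnar_gain)
    dff = tc[:, None, None] * pattern[None, :, :]

    if noise.white_sd > 0:
        dff = dff + noise.white_sd * rng.standard_normal(dff.shape)
    if noise.corr_sd > 0:
        corr = ndimage.gaussian_filter(
            rng.standard_normal(dff.shape),
            sigma=(0.0, noise.corr_length_px, noise.corr_length_px))
        sd = corr.std()
        if sd > 0:
            dff = dff + noise.corr_sd * corr / sd
    if noise.heartbeat_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        beat = noise.heartbeat_amp * np.sin(
            2 * np.pi * noise.heartbeat_hz * (t_ms / 1000.0) + phase)
        dff = dff + beat[:, None, None]

    frames = maps.baseline_image[None] * (1.0 + dff)

    if motion.amplitude_px != 0.0:
        v = motion.trace(n_frames, frame_rate)
        gy, gx = np.gradient(maps.baseline_image)
        frames = frames + (-gx)[None] * v[:, 0, None, None] \
                        + (-gy)[None] * v[:, 1, None, None]

    return ImageStack(frames=frames, frame_rate=frame_rate,
                      onset_index=onset_index, is_dff=False)


def simulate_behavior_outcome(dprime: float, criterion: float,
                              target_present: bool, seed=0,
                              rt_median_ms: float = 180.0,
                              rt_sigma: float = 0.25,
                              rng: Optional[np.random.Generator] = None):
    """Draw one trial outcome from the equal-variance Gaussian observer.

    ``P(hit) = Phi(d'/2 - criterion)``; ``P(FA) = Phi(-d'/2 - criterion)``.
    Reaction times (saccade outcomes only) are shifted log-normal with the
    given median above the 75 ms floor.

    Returns ``(outcome, reaction_time_ms_or_None)``.
    """
    if not (np.isfinite(dprime) and np.isfinite(criterion)):
        raise ValueError("dprime and criterion must be finite")
    if rng is None:
        rng = np.random.default_rng(seed)
    p_saccade = stats.norm.cdf(dprime / 2.0 - criterion) if target_present \
        else stats.norm.cdf(-dprime / 2.0 - criterion)
    saccade = rng.uniform() < p_saccade
    if target_present:
        outcome = "hit" if saccade else "miss"
    else:
        outcome = "false_alarm" if saccade else "correct_reject"
    rt = None
    if saccade:
        rt = MIN_REACTION_TIME_MS + (rt_median_ms - MIN_REACTION_TIME_MS) * \
            np.exp(rt_sigma * rng.standard_normal())
        rt = max(rt, MIN_REACTION_TIME_MS)
    return outcome, rt


@dataclass(frozen=True)
class BlockDesign:
    """Trial bookkeeping for one synthetic session.

    Detection block: ``trials_per_orientation`` trials per background
    orientation, exactly half with the additive target.  Fixation block:
    flashed target plus flashed full-field gratings at ``map_orientations``.
    Reference block: target-only detection trials at ``reference_contrasts``.
    """

    background_orientations: tuple = (0.0, 15.0, -15.0, 30.0, -30.0,
                                      45.0, -45.0, 60.0, -60.0, 90.0)
    trials_per_orientation: int = 20
    target_contrast: float = 0.24
    background_contrast: float = 0.12
    criterion: float = 0.2
    map_orientations: tuple = tuple(np.arange(0.0, 180.0, 22.5))
    fixation_reps: int = 4
    reference_contrasts: tuple = (0.06, 0.12, 0.24, 0.48)
    reference_reps: int = 4
    render_stacks: bool = True
    n_frames: int = 120
    frame_rate: float = 100.0
    onset_index: int = 30
    fixation_onset_index: int = 15   # leaves >=1.0 s for the 5 Hz flash train


@dataclass(frozen=True)
class MaskingProfile:
    """Inverted dc-shifted Gaussian sensitivity profile
    ``d'(theta) = c - A * exp(-theta^2 / (2 sigma^2))`` (minimum at 0 deg)."""

    A: float = 1.5
    sigma: float = 30.0
    c: float = 2.5

    def dprime(self, theta_deg):
        th = wrap_orientation(theta_deg)
        return self.c - self.A * np.exp(-(th ** 2) / (2.0 * self.sigma ** 2))


def simulate_session(design: BlockDesign, maps: GroundTruthMaps,
                     masking_profile: MaskingProfile = MaskingProfile(),
                     noise: NoiseSpec = NoiseSpec(),
                     motion: MotionSpec = NO_MOTION,
                     seed: int = 0,
                     response_gain: float = 0.01,
                     columnar_gain: float = 0.3) -> Session:
    """Simulate a full session (fixation, detection, reference blocks).

    All randomness derives from ``seed``.  Detection-block target presence
    is balanced exactly 50/50 within each background orientation (odd trial
    counts round the target-present half down).
    """
    rng_beh, rng_seeds, rng_order = spawn_rngs(seed, 3)

    def _render(stimulus, flash=False):
        if not design.render_stacks:
            return None
        s = int(rng_seeds.integers(0, 2 ** 31 - 1))
        onset = design.fixation_onset_index if flash else design.onset_index
        return render_trial_stack(
            stimulus, maps, response_gain=response_gain,
            columnar_gain=columnar_gain, noise=noise, motion=motion, seed=s,
            n_frames=design.n_frames, frame_rate=design.frame_rate,
            onset_index=onset,
            flash_hz=5.0 if flash else None)

    fixation = []
    for _ in range(design.fixation_reps):
        stim = StimulusSpec(target_contrast=design.target_contrast)
        fixation.append(TrialRecord(stim, True, "correct_reject", None,
                                    _render(stim, flash=True), block="fixation_target"))
    for ori in design.map_orientations:
        for _ in range(design.fixation_reps):
            stim = StimulusSpec(background_contrast=1.0,
                                background_orientation=ori)
            fixation.append(TrialRecord(stim, False, "correct_reject", None,
                                        _render(stim, flash=True),
                                        block="fixation_grating"))

    detection = []
    for ori in design.background_orientations:
        n = design.trials_per_orientation
        present = np.zeros(n, dtype=bool)
        present[: n // 2] = True
        rng_order.shuffle(present)
        d = float(masking_profile.dprime(ori))
        for tp in present:
            stim = StimulusSpec(
                target_contrast=design.target_contrast if tp else 0.0,
                background_contrast=design.background_contrast,
                background_orientation=ori)
            outcome, rt = simulate_behavior_outcome(
                d, design.criterion, bool(tp), rng=rng_beh)
            detection.append(TrialRecord(stim, bool(tp), outcome, rt,
                                         _render(stim), block="detection"))

    reference = []
    for c in design.reference_contrasts:
        for _ in range(design.reference_reps):
            stim = StimulusSpec(target_contrast=c)
            outcome, rt = simulate_behavior_outcome(
                masking_profile.dprime(90.0), design.criterion, True,
                rng=rng_beh)
            reference.append(TrialRecord(stim, True, outcome, rt,
                                         _render(stim), block="reference"))

    return Session(fixation_block=fixation, detection_block=detection,
                   reference_block=reference, ground_truth=maps, seed=seed)
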