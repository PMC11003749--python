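"""End-to-end orchestration: simulate -> preprocess -> decode -> analyze.

``run_pipeline`` executes the full synthetic study from one config + seed:
ground-truth maps, a session of fixation/detection/reference trials,
template construction from the fixation block, reliability-weighted decoding
of the detection block, population-vector trajectories, behavioral
summaries, orientation trend fits, neural-behavior correlations, and the
normalization-model panels.  Every stage's tables are persisted as CSV and a
machine-readable JSON summary collects the headline quantities.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import behavior as beh
from . import decode as dec
from . import model as mdl
from . import popvec as pv
from . import preprocess as pre
from . import stats as st
from . import synth
from .utils import wrap_orientation

log = logging.getLogger("vsdmask")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run (serializable, seed included)."""

    seed: int = 0
    # synthetic session
    grid_shape: tuple = (64, 64)
    field_mm: float = 8.0
    envelope_sigma_mm: float = 1.0
    column_band: tuple = (0.8, 3.0)
    background_orientations: tuple = (0.0, 15.0, -15.0, 30.0, -30.0, 45.0,
                                      -45.0, 60.0, -60.0, 90.0)
    trials_per_orientation: int = 4
    target_contrast: float = 0.24
    background_contrast: float = 0.12
    masking_A: float = 1.5
    masking_sigma: float = 30.0
    masking_c: float = 2.5
    response_gain: float = 0.01
    columnar_gain: float = 0.3
    noise_white_sd: float = 1.0e-3
    noise_corr_sd: float = 5.0e-4
    motion_amplitude_px: float = 0.0
    fixation_reps: int = 2
    # preprocessing / decoding
    include_sd: float = 2.0
    # statistics
    alpha: float = 0.05
    zscore_window_ms: tuple = (50.0, 250.0)
    integration_window_ms: tuple = (50.0, 200.0)
    coherence_threshold: float = 0.2
    # model
    run_model: bool = True

    @property
    def mm_per_pixel(self) -> float:
        return self.field_mm / self.grid_shape[0]

    def to_dict(self):
        d = asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    session: synth.Session
    template: dec.RetinotopicTemplate
    columnar_map: dec.ColumnarMap
    variance: dec.VarianceMaps
    behavior: beh.BehaviorSummary
    condition_means: dict          # (scale, target_present, ori) -> DecodedSeries
    target_evoked: dict            # (scale, ori) -> DecodedSeries
    trend: st.TrendFit
    correlation: st.CorrelationResult
    trajectories: dict             # ori -> PopulationTrajectory (bg-only)
    summary: dict


def _amplitude_maps_from_fixation(session, cfg):
    """Average flash-response amplitude maps for the target and each grating."""
    mm = cfg.mm_per_pixel
    target_maps, grating = [], {}
    for tr in session.fixation_block:
        dff = pre.delta_f_over_f(tr.stack)
        fmap = pre.extract_flash_response(dff, 5.0, mm_per_pixel=mm)
        if tr.block == "fixation_target":
            target_maps.append(fmap.amplitude)
        else:
            grating.setdefault(tr.stimulus.background_orientation, []).append(
                fmap.amplitude)
    target_amp = pre.FlashResponseMap(
        amplitude=np.mean(target_maps, axis=0), phase=np.zeros(cfg.grid_shape),
        flash_frequency=5.0, mm_per_pixel=mm)
    grating_amps = {
        ori: pre.FlashResponseMap(amplitude=np.mean(maps, axis=0),
                                  phase=np.zeros(cfg.grid_shape),
                                  flash_frequency=5.0, mm_per_pixel=mm)
        for ori, maps in grating.items()}
    return target_amp, grating_amps


def analyze_session(session: synth.Session, cfg: PipelineConfig) -> PipelineResult:
    """Run the full decoding + statistics analysis on one session."""
    mm = cfg.mm_per_pixel

    log.info("templates: fitting retinotopic and columnar maps")
    target_amp, grating_amps = _amplitude_maps_from_fixation(session, cfg)
    template = dec.fit_retinotopic_template(target_amp)
    cmap = dec.fit_columnar_map(grating_amps, template, band=cfg.column_band,
                                include_sd=cfg.include_sd)

    log.info("detection block: preprocessing %d trials",
             len(session.detection_block))
    dff_stacks, labels = [], []
    for tr in session.detection_block:
        stack = tr.stack
        if cfg.motion_amplitude_px > 0:
            stack = pre.stabilize(stack, pre.estimate_motion(stack))
        dff_stacks.append(pre.delta_f_over_f(stack))
        labels.append((tr.target_present,
                       float(tr.stimulus.background_orientation)))

    var_ret = dec.estimate_pixel_variance(dff_stacks, labels, "retinotopic",
                                          cfg.column_band, mm)
    var_col = dec.estimate_pixel_variance(dff_stacks, labels, "columnar",
                                          cfg.column_band, mm)
    var = dec.VarianceMaps(retinotopic=var_ret.retinotopic,
                           columnar=var_col.columnar)

    log.info("decoding %d trials", len(dff_stacks))
    per_trial = {"retinotopic": [], "0-90": [], "population": []}
    for stack in dff_stacks:
        band_stack = pre.bandpass_stack(stack, *cfg.column_band, mm_per_pixel=mm)
        per_trial["retinotopic"].append(dec.decode_retinotopic(stack, template, var))
        per_trial["0-90"].append(dec.decode_columnar_axis(band_stack, cmap, var))
        per_trial["population"].append(dec.decode_population(band_stack, cmap, var))

    # condition means and target-evoked series
    cond_means, evoked = {}, {}
    oris = sorted({lab[1] for lab in labels})
    for scale in per_trial:
        for tp in (True, False):
            for ori in oris:
                idx = [i for i, lab in enumerate(labels) if lab == (tp, ori)]
                if not idx:
                    continue
                vals = np.mean([per_trial[scale][i].values for i in idx], axis=0)
                cond_means[(scale, tp, ori)] = per_trial[scale][idx[0]].copy_with(vals)
        for ori in oris:
            tb = cond_means.get((scale, True, ori))
            b = cond_means.get((scale, False, ori))
            if tb is not None and b is not None:
                evoked[(scale, ori)] = pv.target_evoked_series(tb, b)

    behavior = beh.summarize_session(session.detection_block)

    # integrated columnar target-evoked response per orientation
    t = dff_stacks[0].times_ms()
    win = (t >= cfg.integration_window_ms[0]) & (t < cfg.integration_window_ms[1])
    integ, counts = [], []
    for o in behavior.orientations:
        key = ("0-90", float(o))
        if key not in evoked:
            continue
        integ.append(float(np.asarray(evoked[key].values)[win].mean()))
        row = behavior.per_orientation[list(behavior.orientations).index(o)]
        counts.append(row.n_hit + row.n_miss + row.n_cr + row.n_fa)
    integ = np.array(integ)
    counts = np.array(counts, dtype=float)

    trend = None
    if integ.size >= 5:
        trend = st.fit_orientation_trend(integ, behavior.orientations[:integ.size],
                                         alpha=cfg.alpha)
    correlation = st.weighted_correlation(integ, behavior.dprimes[:integ.size],
                                          counts)

    trajectories = {
        ori: pv.trajectory_summary(cond_means[("population", False, ori)],
                                   cfg.coherence_threshold)
        for ori in oris if ("population", False, ori) in cond_means}

    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_detection_trials": len(session.detection_block),
        "template_center": list(template.center),
        "behavior_masking_fit": list(behavior.masking_fit)
        if behavior.masking_fit else None,
        "integrated_columnar_by_orientation": {
            f"{o:+.0f}": v for o, v in
            zip(behavior.orientations[:integ.size], integ)},
        "neural_behavior_rho": correlation.rho,
        "neural_behavior_p": correlation.p_value,
        "trend_model": trend.model if trend is not None else None,
    }

    if cfg.run_model:
        peak = mdl.background_only_peak_time(
            background_contrast=cfg.background_contrast)
        mp = synth.MaskingProfile(cfg.masking_A, cfg.masking_sigma, cfg.masking_c)
        pool = sorted({abs(o) for o in cfg.background_orientations})
        _, mresp = mdl.target_evoked_response(
            target_contrast=cfg.target_contrast,
            background_contrast=cfg.background_contrast,
            background_orientations=tuple(pool))
        tms, rho, _ = mdl.model_behavior_correlation(
            mresp, {o: float(mp.dprime(o)) for o in pool})
        early = (tms >= 40) & (tms < 90)
        late = (tms >= 120) & (tms < 250)
        summary["model"] = {
            "bg_popvec_peak_ms": peak,
            "early_rho_mean": float(np.nanmean(rho[early])),
            "late_rho_mean": float(np.nanmean(rho[late])),
            "early_negative": bool(np.nanmean(rho[early]) < 0),
            "late_positive": bool(np.nanmean(rho[late]) > 0),
        }

    return PipelineResult(config=cfg, session=session, template=template,
                          columnar_map=cmap, variance=var, behavior=behavior,
                          condition_means=cond_means, target_evoked=evoked,
                          trend=trend, correlation=correlation,
                          trajectories=trajectories, summary=summary)


def run_pipeline(cfg: PipelineConfig, outdir, make_figures: bool = False) -> PipelineResult:
    """Simulate a session from the config, analyze it, and persist outputs."""
    if cfg.trials_per_orientation < 4:
        raise ValueError("need at least 4 trials per orientation "
                         "(2 per target condition for variance estimation)")
    os.makedirs(outdir, exist_ok=True)
    log.info("run %s seed=%d", cfg.config_hash(), cfg.seed)

    maps = synth.make_ground_truth(
        grid_shape=cfg.grid_shape, mm_per_pixel=cfg.mm_per_pixel,
        envelope_sigma_mm=cfg.envelope_sigma_mm, column_band=cfg.column_band,
        seed=cfg.seed)
    design = synth.BlockDesign(
        background_orientations=cfg.background_orientations,
        trials_per_orientation=cfg.trials_per_orientation,
        target_contrast=cfg.target_contrast,
        background_contrast=cfg.background_contrast,
        fixation_reps=cfg.fixation_reps, reference_reps=2)
    session = synth.simulate_session(
        design, maps,
        masking_profile=synth.MaskingProfile(cfg.masking_A, cfg.masking_sigma,
                                             cfg.masking_c),
        noise=synth.NoiseSpec(white_sd=cfg.noise_white_sd,
                              corr_sd=cfg.noise_corr_sd),
        motion=synth.MotionSpec(amplitude_px=cfg.motion_amplitude_px),
        seed=cfg.seed, response_gain=cfg.response_gain,
        columnar_gain=cfg.columnar_gain)

    result = analyze_session(session, cfg)

    from .io import save_trial_log, save_yaml
    save_trial_log(os.path.join(outdir, "trial_log.csv"),
                   session.detection_block)
    result.behavior.to_frame().to_csv(
        os.path.join(outdir, "behavior_by_orientation.csv"), index=False)
    rows = []
    for (scale, ori), s in result.target_evoked.items():
        if scale != "0-90":
            continue
        for tt, v in zip(s.times_ms, np.asarray(s.values)):
            rows.append({"orientation_deg": ori, "t_ms": tt, "value": v})
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "target_evoked_columnar.csv"), index=False)
    for ori, traj in result.trajectories.items():
        traj.to_frame().to_csv(
            os.path.join(outdir, f"trajectory_bg{ori:+.0f}.csv"), index=False)
    save_yaml(os.path.join(outdir, "config.yaml"), cfg.to_dict())
    with open(os.path.join(outdir, "summary.json"), "w") as f:
        json.dump(result.summary, f, indent=2, default=float)

    if make_figures:
        _render_figures(result, outdir)
    return result


def _render_figures(result: PipelineResult, outdir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    b = result.behavior
    axes[0].plot(b.orientations, b.dprimes, "o-")
    axes[0].set(xlabel="background orientation (deg)", ylabel="d'",
                title="behavioral masking")
    for (scale, ori), s in sorted(result.target_evoked.items()):
        if scale == "0-90" and ori >= 0:
            axes[1].plot(s.times_ms, s.values, label=f"{ori:+.0f}")
    axes[1].legend(fontsize=6)
    axes[1].set(xlabel="t (ms)", ylabel="target-evoked r(0-90)",
                title="columnar dynamics")
    ax = plt.subplot(1, 3, 3, projection="polar")
    for ori, traj in result.trajectories.items():
        ang = np.deg2rad(2 * np.nan_to_num(traj.angle_deg))
        ax.plot(ang, traj.magnitude, lw=1, label=f"{ori:+.0f}")
    ax.set_title("bg-only population trajectories")
    fig.tight_layout()
    fig.savefig(os.path.join(outdir, "overview.png"), dpi=120)
    plt.close(fig)
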