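"""Shared synthetic fixtures.

Heavy fixtures are session-scoped: one ground-truth map set, one noiseless
fixation block for template construction, and one default-noise detection
session reused across decoding and acceptance tests.
"""

import numpy as np
import pytest

from vsdmask import decode as dec
from vsdmask import preprocess as pre
from vsdmask import synth

GRID = (128, 128)
SEED = 11


@pytest.fixture(scope="session")
def gt_maps():
    return synth.make_ground_truth(grid_shape=GRID, seed=SEED)


@pytest.fixture(scope="session")
def mm_per_pixel(gt_maps):
    return gt_maps.mm_per_pixel


@pytest.fixture(scope="session")
def noiseless_templates(gt_maps):
    """Retinotopic template + columnar map from a noiseless fixation block."""
    mm = gt_maps.mm_per_pixel
    target = synth.render_trial_stack(
        synth.StimulusSpec(target_contrast=0.24), gt_maps,
        noise=synth.NO_NOISE, seed=0, onset_index=15, flash_hz=5.0)
    tmap = pre.extract_flash_response(pre.delta_f_over_f(target), 5.0,
                                      mm_per_pixel=mm)
    template = dec.fit_retinotopic_template(tmap)
    gratings = {}
    for ori in np.arange(0.0, 180.0, 22.5):
        s = synth.render_trial_stack(
            synth.StimulusSpec(background_contrast=1.0,
                               background_orientation=ori),
            gt_maps, noise=synth.NO_NOISE, seed=0, onset_index=15, flash_hz=5.0)
        gratings[ori] = pre.extract_flash_response(
            pre.delta_f_over_f(s), 5.0, mm_per_pixel=mm)
    cmap = dec.fit_columnar_map(gratings, template)
    return template, cmap


@pytest.fixture(scope="session")
def detection_session(gt_maps):
    """Default-SNR detection session: 6 background orientations, 4 trials each."""
    design = synth.BlockDesign(
        background_orientations=(0.0, 15.0, -30.0, 45.0, -60.0, 90.0),
        trials_per_orientation=4, fixation_reps=0, reference_reps=0)
    return synth.simulate_session(design, gt_maps, noise=synth.NoiseSpec(),
                                  seed=3)


@pytest.fixture(scope="session")
def decoded_population(detection_session, noiseless_templates, gt_maps):
    """Trial-mean population decoder outputs per background orientation."""
    template, cmap = noiseless_templates
    mm = gt_maps.mm_per_pixel
    stacks, labels = [], []
    for tr in detection_session.detection_block:
        stacks.append(pre.delta_f_over_f(tr.stack))
        labels.append((tr.target_present,
                       float(tr.stimulus.background_orientation)))
    var = dec.estimate_pixel_variance(stacks, labels, "columnar",
                                      mm_per_pixel=mm)
    out = {}
    for ori in sorted({lab[1] for lab in labels}):
        idx = [i for i, lab in enumerate(labels) if lab == (False, ori)]
        series = [dec.decode_population(
            pre.bandpass_stack(stacks[i], mm_per_pixel=mm), cmap, var)
            for i in idx]
        mean = series[0].copy_with(np.mean([s.values for s in series], axis=0))
        out[ori] = mean
    return out
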