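"""Shared fixtures: small atlases and the standard desk-scale training cohort.

The expensive session fixtures (a 32x32x32 cohort of 400 subjects and CNN
regressors trained on it with three seeds) are shared between the training
and region-importance recovery tests so the cohort is simulated and each
model fitted exactly once per session.
"""

import numpy as np
import pytest

from brainage import generate_atlas, generate_volumes, stack_volumes
from brainage.model import ModelConfig, build_model, train, predict

# the standard synthetic training cohort: 20 regions, two of which carry a
# strong linear age signal (1 intensity unit / year against unit voxel noise)
STANDARD_SHAPE = (32, 32, 32)
STANDARD_N_REGIONS = 20
STANDARD_SIGNAL_REGIONS = (3, 11)
STANDARD_N_SUBJECTS = 400
STANDARD_EFFECT = 1.0
STANDARD_NOISE_SD = 1.0


@pytest.fixture(scope="session")
def small_atlas():
    return generate_atlas((16, 16, 16), n_regions=6, seed=7)


@pytest.fixture(scope="session")
def standard_cohort():
    """(atlas, truth, ids, volumes, ages) for the standard training cohort."""
    atlas = generate_atlas(STANDARD_SHAPE, STANDARD_N_REGIONS, seed=1)
    samples, truth = generate_volumes(
        atlas, STANDARD_N_SUBJECTS, signal_regions=STANDARD_SIGNAL_REGIONS,
        effect_size=STANDARD_EFFECT, noise_sd=STANDARD_NOISE_SD, seed=2)
    ids, X, ages = stack_volumes(samples)
    return atlas, truth, ids, X, ages


@pytest.fixture(scope="session")
def trained_models(standard_cohort):
    """Age regressors trained on the standard cohort with three seeds.

    Returns a list of (model, heldout_mae, baseline_mae) triples, where the
    baseline is the constant mean-training-age predictor evaluated on the
    same held-out subjects.
    """
    _, _, _, X, ages = standard_cohort
    tr, va, te = slice(0, 280), slice(280, 340), slice(340, 400)
    out = []
    for seed in (0, 1, 2):
        cfg = ModelConfig(input_shape=STANDARD_SHAPE, seed=seed)
        model = build_model(cfg)
        model, _ = train(model, (X[tr], ages[tr]), (X[va], ages[va]), cfg)
        heldout_mae = float(np.mean(np.abs(predict(model, X[te]) - ages[te])))
        baseline_mae = float(np.mean(np.abs(ages[tr].mean() - ages[te])))
        out.append((model, heldout_mae, baseline_mae))
    return out
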