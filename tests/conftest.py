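import numpy as np
import pytest

from soundmvpa.geometry import CONDITIONS, build_speaker_array, condition_labels
from soundmvpa.glm import build_design_matrix, fit_run_glm
from soundmvpa.synth import make_pattern_spec, simulate_subject

SMALL_GRID = (12, 12, 6)
LARGE_GRID = (24, 24, 12)


@pytest.fixture(scope="session")
def speaker_array():
    return build_speaker_array()


@pytest.fixture(scope="session")
def labelings(speaker_array):
    return {c: condition_labels(speaker_array, c) for c in CONDITIONS}


def small_spec(amplitude: float, noise_sd: float = 1.0, seed: int = 1, **overrides):
    cfg = {
        "grid_shape": SMALL_GRID,
        "amplitudes": {c: amplitude for c in CONDITIONS},
        "n_informative": 10,
        "noise_sd": noise_sd,
    }
    cfg.update(overrides)
    return make_pattern_spec(cfg, seed=seed)


def fit_subject(spec, seed):
    """Simulate one subject and fit the per-run beta-series GLM."""
    ds = simulate_subject(spec, seed=seed)
    responses = []
    for r, (design, vol) in enumerate(ds.runs):
        dm = build_design_matrix(design, acquisition_times=vol.acquisition_times_s)
        responses.append(fit_run_glm(vol, dm, run_id=r))
    return ds, responses


@pytest.fixture(scope="session")
def null_subject():
    """Amplitude-0 subject: betas carry no label information."""
    spec = small_spec(0.0)
    ds, responses = fit_subject(spec, seed=11)
    return spec, ds, responses


@pytest.fixture(scope="session")
def signal_subject():
    """Subject with a clearly detectable planted pattern (large ROI)."""
    spec = make_pattern_spec(
        {
            "grid_shape": LARGE_GRID,
            "amplitudes": {c: 1.0 for c in CONDITIONS},
            "n_informative": 10,
            "noise_sd": 1.0,
        },
        seed=3,
    )
    ds, responses = fit_subject(spec, seed=12)
    return spec, ds, responses


def make_response_images(rng, labeling, grid_shape, roi_mask, amplitude, noise_sd, n_runs=8):
    """Craft ResponseImage objects directly (no simulation): planted class
    patterns plus i.i.d. noise on the betas themselves."""
    from soundmvpa.glm import ResponseImage

    n_vox = int(np.prod(grid_shape))
    roi_flat = np.flatnonzero(np.asarray(roi_mask).ravel())
    informative = roi_flat[: max(4, len(roi_flat) // 5)]
    responses = []
    for r in range(n_runs):
        betas = rng.normal(0.0, noise_sd, size=(16, n_vox))
        for lid in range(16):
            if lid in labeling.class_a:
                betas[lid, informative] += amplitude
            elif lid in labeling.class_b:
                betas[lid, informative] -= amplitude
        responses.append(
            ResponseImage(
                run_id=r,
                betas=betas.reshape(16, *grid_shape),
                residual_variance=np.ones(grid_shape),
            )
        )
    return responses, informative
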