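import numpy as np
import pytest
from hypothesis import settings

from mirsikit import pipeline, preprocess, synth
from mirsikit.model import ClassLabel

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_gen():
    return synth.default_config()


@pytest.fixture(scope="session")
def kidney_ff_cube(default_gen):
    return synth.simulate_cube(
        default_gen, ClassLabel("kidney", "FF"), "kidney-FF-fix", seed=42
    )


@pytest.fixture(scope="session")
def masked_kidney_ff(kidney_ff_cube):
    """Mask + noise stats + a 2,000-pixel baseline-corrected sample."""
    mask, _ = preprocess.tissue_mask(kidney_ff_cube)
    stats = preprocess.background_stats(kidney_ff_cube, mask)
    sset = preprocess.sample_pixels(kidney_ff_cube, mask, 2000, seed=7)
    return mask, stats, sset


@pytest.fixture(scope="session")
def study_metrics_by_seed():
    """Five independent replicates of the full synthetic study's quantitative
    arm (band counts, Amide I reductions, class mean spectra)."""
    return {seed: pipeline.study_band_metrics(seed) for seed in range(5)}
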