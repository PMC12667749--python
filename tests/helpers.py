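"""Shared builders for the test suite."""

import numpy as np

from mirsikit.model import ClassLabel, default_grid
from mirsikit.synth import BandSpec, BaselineSpec, GeneratorConfig

KFF = ClassLabel("kidney", "FF")


def single_band_config(center=1658.0, fwhm=20.0, amp=1.0, noise=0.0, cv=0.0,
                       baseline=BaselineSpec(0.0, 0.0, 0.0)):
    """Generator config with exactly one kidney-FF band and no confounders."""
    return GeneratorConfig(
        grid=default_grid(),
        band_tables={KFF: (BandSpec(center, fwhm, amp),)},
        baselines={KFF: baseline},
        amplitude_field_cv=cv,
        noise_sd=noise,
        cube_height=16,
        cube_width=16,
    )
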