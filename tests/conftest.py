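import numpy as np
import pytest

from spineglia.roi_profiles import IntensityProfile


def make_profile(values, step_um=0.05, pixel_size=0.1, normalized=True,
                 dendrite_segment=None):
    """Build an IntensityProfile directly from an array of (normalized) values."""
    values = np.asarray(values, dtype=float)
    positions = np.arange(len(values)) * step_um
    p = IntensityProfile(
        positions=positions,
        raw=values,
        pixel_size=pixel_size,
        step_px=step_um / pixel_size,
        dendrite_segment=dendrite_segment,
    )
    if normalized:
        p.background = 0.0
        p.corrected = values
        p.dendrite_reference = 1.0
        p.normalized = values
    return p


def gaussian_bump(apex, center_um, sigma_um, length_um=20.0, step_um=0.05,
                  baseline=1.0):
    """Baseline profile with one Gaussian bump peaking at ``apex``."""
    x = np.arange(0, length_um, step_um)
    return baseline + (apex - baseline) * np.exp(-((x - center_um) ** 2) / (2 * sigma_um**2))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
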