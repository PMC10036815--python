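"""Shared fixtures: small synthetic datasets at fixed seeds.

All data is generated at test time; session scope keeps the heavier
generator calls to one per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from nirwood.core import average_replicates, random_split, to_absorbance
from nirwood.synthgen import SynthConfig, generate_dataset

# 256-point grid spanning the full 350-2390 nm range (8 nm step) so every
# absorption band stays on-grid while tests run at desk scale.
P256 = dict(wavelength_start=350.0, wavelength_stop=2390.0, wavelength_step=8.0)


@pytest.fixture(scope="session")
def small_dataset():
    """Replicate-level synthetic dataset: 30 samples x 3 replicates, p=256."""
    cfg = SynthConfig(n_samples=30, seed=7, **P256)
    dataset, truth = generate_dataset(cfg)
    return dataset, truth, cfg


@pytest.fixture(scope="session")
def absorbance_split(small_dataset):
    """Averaged, log(1/R)-converted and split version of the small dataset."""
    dataset, truth, cfg = small_dataset
    ab = to_absorbance(average_replicates(dataset, 3))
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            split = random_split(ab, 0.7, seed=7)
    return split, truth, cfg


@pytest.fixture(scope="session")
def recovery_dataset():
    """Sample-level data for selection-recovery: n=120, p=256, low noise."""
    cfg = SynthConfig(n_samples=120, seed=11, noise_sd=0.005, **P256)
    dataset, truth = generate_dataset(cfg)
    ab = to_absorbance(average_replicates(dataset, 3))
    return ab, truth, cfg
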