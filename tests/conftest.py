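"""Shared fixtures: small synthetic screens and reference objects.

The expensive default-noise 104-compound screen is simulated once per
session; small zero-noise screens are built per test from explicit ground
truths so every expected value can be computed in closed form.
"""

import numpy as np
import pandas as pd
import pytest

from redoxscreen import (
    CompoundTruth,
    ScreenDataset,
    SimConfig,
    default_truth_library,
    quantify_screen,
    simulate_screen,
)


@pytest.fixture(scope="session")
def default_screen():
    """Full 104-compound two-stage screen at default (nonzero) noise."""
    truths = default_truth_library(seed=11)
    config = SimConfig(seed=11)
    return simulate_screen(config, truths)


@pytest.fixture(scope="session")
def default_effects(default_screen):
    return quantify_screen(default_screen)


def make_screen(truths, **config_kwargs):
    """Simulate a screen for explicit truths; n_compounds inferred."""
    config = SimConfig(n_compounds=len(truths), **config_kwargs)
    return config, simulate_screen(config, truths)


@pytest.fixture()
def zero_noise_trio():
    """Three-compound zero-noise screen: one enhancer (with antioxidant
    activity), one toxic compound, one neutral."""
    truths = [
        CompoundTruth("enh", "enhancer", migration_effect=0.5,
                      ros_effect=-0.3, ec50=5.0, hill=1.0),
        CompoundTruth("tox", "toxic", viability=0.5, ec50=5.0, hill=1.0),
        CompoundTruth("neu", "neutral"),
    ]
    config, ds = make_screen(truths, noise_sd=0.0, seed=4)
    return truths, config, ds
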