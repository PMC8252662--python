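"""Shared fixtures: all synthetic inputs are generated here at test time."""

from __future__ import annotations

import numpy as np
import pytest

import optolight as ol
from optolight.simulate import GeneratorConfig, render_field, sample_cells, single_region_field


def tiny_config(**overrides) -> GeneratorConfig:
    """A small, fast generator configuration for unit tests."""
    defaults = dict(
        seed=11,
        region_width_um=160.0,
        region_height_um=120.0,
        cell_density_per_mm2=3000.0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def conditions():
    return {str(i): ol.get_condition(str(i)) for i in range(10)}


@pytest.fixture(scope="session")
def small_irradiated_stack(conditions):
    """One small irradiated region (condition 7) rendered over 6 frames.

    Session-scoped: several tests read from it without re-rendering.
    Returns (stack, per-cell truth table, generator config).
    """
    gen = tiny_config(seed=21)
    fs = single_region_field(gen, "7", irradiated=True)
    rng = np.random.default_rng(gen.seed)
    cells = sample_cells(gen, fs, rng)
    stack, truth = render_field(
        cells, fs, gen, np.arange(6) * 240.0, conditions, rng,
        ("nuclei", "iRFP", "EGFP", "mCherry", "stain", "edu"),
    )
    return stack, truth, gen
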