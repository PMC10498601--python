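"""Shared fixtures: phantoms and a pipeline run on the small phantom."""

import copy

import numpy as np
import pytest

import voxflap as vf


def small_config() -> dict:
    """Default pipeline config adapted to the small phantom's geometry."""
    cfg = vf.default_config()
    cfg["segmentation"]["vessels"]["reference_roi"]["center_mm"] = [32.0, 20.0, 16.0]
    cfg["struts"] = [
        {"from": [32.0, 12.0, 6.0], "to": [32.0, 12.0, 17.0], "radius_mm": 1.5},
        {"from": [32.0, 52.0, 6.0], "to": [32.0, 52.0, 17.0], "radius_mm": 1.5},
    ]
    return cfg


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free 64x64x48 phantom: (volume, truth)."""
    return vf.make_phantom(vf.PhantomSpec.small())


@pytest.fixture(scope="session")
def small_pipeline(small_phantom):
    """Full reference pipeline run on the small phantom (no file output)."""
    vol, truth = small_phantom
    return vf.run_reference_pipeline(vol, truth=truth, config=small_config())


@pytest.fixture(scope="session")
def default_phantom():
    """Noise-free default 128x128x96 phantom."""
    return vf.make_phantom(vf.PhantomSpec())
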