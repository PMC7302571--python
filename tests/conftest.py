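"""Shared fixtures: small programmatically generated datasets and configs."""

import numpy as np
import pytest

from nirparity.ann import LmConfig
from nirparity.autoencoder import AeConfig
from nirparity.dataset import SpectralDataset
from nirparity.pipeline import PipelineConfig


@pytest.fixture
def tiny_dataset() -> SpectralDataset:
    """Three samples on a three-point grid, both classes present."""
    return SpectralDataset(
        wavelengths_nm=[500, 501, 502],
        absorbance=[[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]],
        sample_ids=["a", "b", "c"],
        labels=[0, 1, 0],
        cohort=["site-x"] * 3,
    )


@pytest.fixture
def full_grid_dataset() -> SpectralDataset:
    """A small cohort on the full 350-2500 nm grid (2151 points)."""
    rng = np.random.default_rng(7)
    wl = np.arange(350, 2501)
    n = 12
    absorbance = 0.5 + 0.3 * rng.random((n, wl.size))
    return SpectralDataset(
        wavelengths_nm=wl,
        absorbance=absorbance,
        sample_ids=[f"m{i}" for i in range(n)],
        labels=np.tile([0, 1], n // 2),
    )


@pytest.fixture
def cheap_pipeline_config() -> PipelineConfig:
    """A deliberately small pipeline for fast end-to-end plumbing tests."""
    return PipelineConfig(
        step_dims=(32, 10),
        ae_config=AeConfig(epochs=3),
        lm_config=LmConfig(max_iterations=30),
        repeats=3,
    )
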