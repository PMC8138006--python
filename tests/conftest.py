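"""Shared fixtures: small synthetic blocks and cohorts, reused across modules."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from specell.channels import default_channel_set
from specell.preprocess import preprocess_block
from specell.synthetic import CohortConfig, generate_datablock, make_endmembers

logging.getLogger("specell").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def channel_set():
    return default_channel_set()


@pytest.fixture(scope="session")
def spectra(channel_set):
    return make_endmembers(channel_set, seed=1)


@pytest.fixture(scope="session")
def small_cfg():
    return CohortConfig(seed=3, image_shape=(128, 128))


@pytest.fixture(scope="session")
def small_block(small_cfg, spectra):
    """One 128x128 field with 3 cells plus its ground truth."""
    block, mask, truth = generate_datablock(
        small_cfg, spectra, patient_id="G1P01", group_label=1, field_id="G1P01F01"
    )
    return block, mask, truth


@pytest.fixture(scope="session")
def processed_small_block(small_block):
    block, mask, truth = small_block
    processed, bad_map = preprocess_block(block)
    return processed, mask, truth, bad_map


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
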