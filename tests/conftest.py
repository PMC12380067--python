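"""Shared fixtures: synthetic datasets and (expensive) field solutions."""

import numpy as np
import pytest

from flexb2b import field as fld
from flexb2b.decoder import DecoderConfig
from flexb2b.preprocess import preprocess_trial, to_tensor
from flexb2b.synth import SynthSpec, synth_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """8 classes x 6 trials at +10 dB, preprocessed and tensorized."""
    trials = synth_dataset(6, SynthSpec(snr_db=10.0, seed=7))
    x, y = to_tensor([preprocess_trial(t) for t in trials])
    return x, y


@pytest.fixture(scope="session")
def tiny_config():
    """Small dual-branch architecture for fast training tests."""
    return DecoderConfig(
        time_blocks=((8, (1, 25), (1, 8)), (8, (8, 11), (1, 8))),
        freq_channels=8,
        n_res_blocks=1,
        branch_dim=16,
    )


@pytest.fixture(scope="session")
def tissue():
    return fld.TissueModel()


@pytest.fixture(scope="session")
def coarse_flex_solution(tissue):
    geom = fld.build_geometry("flexible_array", tissue)
    return fld.solve_field(geom, tissue, 5.0, grid="coarse")


@pytest.fixture(scope="session")
def coarse_wire_solution(tissue):
    geom = fld.build_geometry("microwire", tissue)
    return fld.solve_field(geom, tissue, 1.0, grid="coarse")


@pytest.fixture(scope="session")
def coarse_rigid_solution(tissue):
    geom = fld.build_geometry("rigid_array", tissue)
    return fld.solve_field(geom, tissue, 1.0, grid="coarse")


@pytest.fixture(scope="session")
def bare_wire_solution():
    """Microwire with no glial layer, for the analytic disc oracle."""
    tissue = fld.TissueModel(glial_thickness=0.0)
    geom = fld.build_geometry("microwire", tissue)
    return fld.solve_field(geom, tissue, 10.0, grid="coarse")


def pytest_configure(config):
    np.seterr(over="raise", invalid="raise")
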