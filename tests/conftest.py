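"""Shared fixtures: atlas, designs, a small simulated cohort, one full
pipeline run reused by the structural and orchestration tests."""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pytest

import connsweep as cs
from connsweep.io import write_cohort
from connsweep.pipeline import PipelineConfig, run_pipeline
from connsweep.synthetic_data import EffectConfig, simulate_cohort


@pytest.fixture(scope="session")
def atlas():
    return cs.default_atlas()


@pytest.fixture(scope="session")
def atlas_path():
    with resources.as_file(
        resources.files("connsweep.data").joinpath("atlas160_synthetic.tsv")
    ) as p:
        yield str(p)


@pytest.fixture(scope="session")
def default_design():
    """The study's acquisition defaults: TR 2.45 s, 260 volumes, 27.5 s
    blocks, 12 cycles."""
    return cs.make_design()


@pytest.fixture
def toy_design():
    return cs.make_design(tr=1.0, n_volumes=10, block_duration=5.0, n_cycles=1)


@pytest.fixture(scope="session")
def small_cohort(atlas, default_design):
    """Four simulated sessions (2 HC / 2 PPV) at the study defaults."""
    effects = EffectConfig(seed=11, n_hc=2, n_ppv=2)
    return simulate_cohort(atlas, default_design, effects)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, atlas, atlas_path, default_design):
    """One complete pipeline run on a 6-participant synthetic cohort."""
    tmp = tmp_path_factory.mktemp("pipeline")
    effects = EffectConfig(seed=23, n_hc=3, n_ppv=3)
    bundles, participants = simulate_cohort(atlas, default_design, effects)
    write_cohort(bundles, participants, tmp / "in")
    config = PipelineConfig(atlas=atlas_path, data_dir=str(tmp / "in"),
                            output_dir=str(tmp / "out"), seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny-n Mauchly boundary warnings
        out = run_pipeline(config)
    return config, out
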