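"""Shared fixtures: synthetic samples and a pipeline-run helper.

All fixtures are generated programmatically; nothing is read from disk
except what a test itself writes to tmp_path.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import spiraltremor as st
from spiraltremor.cli import RunConfig, run_extract

_CFG_KEYS = (
    "origin",
    "fit_point_1",
    "fit_point_2",
    "zones",
    "crop_rect",
    "s_min",
    "t_to_draw",
)


def run_config_for(spec: st.SimulationSpec, **overrides) -> RunConfig:
    """RunConfig with the click coordinates a user would supply, from truth."""
    inputs = st.analysis_inputs(spec)
    d = {k: v for k, v in inputs.items() if k in _CFG_KEYS}
    d.update(overrides)
    return RunConfig.from_dict(d)


def extract_signal(img: st.InkImage, spec: st.SimulationSpec, **overrides):
    """Run fit -> flatten -> crop -> extract -> resample on a synthetic image."""
    cfg = run_config_for(spec, **overrides)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_extract(img, cfg)


@pytest.fixture(scope="session")
def clean_spec() -> st.SimulationSpec:
    """An artifact-free drawing with a well-resolved 5 Hz tremor."""
    return st.SimulationSpec(
        params=st.default_params(theta_r=1.3),
        tremor_amplitude=10.0,
        tremor_freq=5.0,
        t_to_draw=10.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_sample(clean_spec):
    img, truth = st.compose(clean_spec)
    return img, truth, clean_spec


@pytest.fixture(scope="session")
def clean_signal(clean_sample):
    img, truth, spec = clean_sample
    signal, band, params = extract_signal(img, spec)
    return signal


def truth_deviation_at(truth: st.GroundTruth, s: np.ndarray) -> np.ndarray:
    """Ground-truth radial deviation interpolated at arbitrary arc lengths."""
    return np.interp(s, truth.s, truth.d)
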