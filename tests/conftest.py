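"""Shared fixtures: synthetic scenarios at two scales.

The reference fixture (full scale, seed 7) backs the end-to-end recovery and
filtering checks; the small fixture keeps unit-level scenario tests fast.
Both are built once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from iqspred.simulate import REFERENCE_PARAMS, build_fixture, scaled_params


@pytest.fixture(scope="session")
def reference_fixture():
    """(train, test) scenarios at the reference parameters (seed 7)."""
    return build_fixture(REFERENCE_PARAMS)


@pytest.fixture(scope="session")
def reference_run(reference_fixture):
    """Full scenario evaluation on the reference fixture."""
    from iqspred.scenario import run_scenario

    train, test = reference_fixture
    report, preds, models = run_scenario(train, test)
    return report, preds, models


@pytest.fixture(scope="session")
def small_fixture():
    """(train, test) scenarios at 1/4 scale for fast unit tests."""
    return build_fixture(scaled_params(0.25, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
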