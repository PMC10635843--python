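"""Shared fixtures.

Heavy objects (charted entrainment fields) are session-scoped so the
acceptance tests and module tests share one computation.
"""

import numpy as np
import pytest

from gammadbs.synth import (
    REFERENCE_AMP_MAX,
    reference_parameter_set,
)
from gammadbs.tongue import chart_arnold_tongue


@pytest.fixture(scope="session")
def reference():
    params, f0 = reference_parameter_set()
    return params, f0


@pytest.fixture(scope="session")
def reference_field(reference):
    """Arnold-tongue chart of the reference model on the standard grid:
    40-200 Hz (2 Hz step) x 11 amplitudes, 3 repeats, 50 cycles."""
    params, _ = reference
    return chart_arnold_tongue(
        params,
        np.arange(40.0, 201.0, 2.0),
        np.linspace(0.0, REFERENCE_AMP_MAX, 11),
        n_repeats=3, n_cycles=50, seed=11)


@pytest.fixture(scope="session")
def fine_field(reference):
    """Finer-amplitude chart over the tongue region, used by the
    amplitude-scale statistics (scale resolution ~ amplitude step)."""
    params, _ = reference
    return chart_arnold_tongue(
        params,
        np.arange(100.0, 161.0, 2.0),
        np.linspace(0.0, REFERENCE_AMP_MAX, 41),
        n_repeats=3, n_cycles=50, seed=21)


@pytest.fixture(scope="session")
def column_130(reference):
    """Fine amplitude sweep of the 130 Hz stimulation column."""
    params, _ = reference
    return chart_arnold_tongue(
        params, np.array([130.0]),
        np.linspace(0.0, REFERENCE_AMP_MAX, 41),
        n_repeats=3, n_cycles=50, seed=3)
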