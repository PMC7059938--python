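"""Shared fixtures.

The expensive strand simulations are session-scoped so the acceptance tests
and property tests reuse the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from nohm import protocols


@pytest.fixture(scope="session")
def baseline_runs():
    """One paced beat of each of the four models: instantaneous Cx43-Cx43,
    full coupling — the high-coupling reference condition."""
    out = {}
    for model in ("cm-clamped", "cm-gated", "lhm", "nohm"):
        out[model] = protocols.run_model(
            model, channel="Cx43-Cx43", regime="instantaneous", beta=1.0,
            t_end=60.0,
        )
    return out


@pytest.fixture(scope="session")
def baseline_cvs(baseline_runs):
    return {
        model: protocols.conduction_velocity(res).cv
        for model, res in baseline_runs.items()
    }


@pytest.fixture(scope="session")
def gated_ss_low_beta_runs():
    """CM voltage-gated, steady-state Cx43-Cx43, at 1% and 0.5% coupling
    (the cellular conduction-block experiment; the 1% run crawls at
    ~1 cm/s so it dominates the suite's runtime)."""
    out = {}
    for beta in (0.01, 0.005):
        out[beta] = protocols.run_model(
            "cm-gated", channel="Cx43-Cx43", regime="steady_state", beta=beta,
            t_end=800.0,
        )
    return out
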