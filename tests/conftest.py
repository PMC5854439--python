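"""Shared fixtures.

Heavy artifacts (the standard tissue scenario, its ground truth, the
regional APD table) are session-scoped and built lazily, so unit tests
that do not need them never pay for them.
"""

from __future__ import annotations

import numpy as np
import pytest

from basketmap.ionic_models import PacingProtocol, build_membrane_model, \
    measure_apd, pace_single_cell

REGIONS = ("RA_PM", "CT_BBRA", "TVR", "RAA", "LA", "BBLA", "MVR", "LAA", "PV")


@pytest.fixture(scope="session")
def apd_table():
    """APDs of all nine regional variants under the two pacing protocols.

    Returns dict with keys (region, protocol) where protocol is one of
    'bcl1000' (control, 60 beats; values (APD95, APD90)) and
    'bcl500_control'/'bcl500_cAF' (120 beats; value APD90).
    """
    table = {}
    p1000 = PacingProtocol(bcl=1000.0, n_beats=60)
    p500 = PacingProtocol(bcl=500.0, n_beats=120)
    for region in REGIONS:
        ctrl = build_membrane_model(region, "control")
        tr = pace_single_cell(ctrl, p1000, dt=0.01)
        table[(region, "bcl1000")] = (measure_apd(tr, 0.95),
                                      measure_apd(tr, 0.90))
        tr = pace_single_cell(ctrl, p500, dt=0.01)
        table[(region, "bcl500_control")] = measure_apd(tr, 0.90)
        caf = build_membrane_model(region, "cAF")
        tr = pace_single_cell(caf, p500, dt=0.01)
        table[(region, "bcl500_cAF")] = measure_apd(tr, 0.90)
    return table


@pytest.fixture(scope="session")
def standard_scenario():
    from basketmap.synthetic_data import make_standard_scenario
    return make_standard_scenario()


@pytest.fixture(scope="session")
def scenario_ground_truth(standard_scenario):
    from basketmap.pipeline import ground_truth
    return ground_truth(standard_scenario)


@pytest.fixture(scope="session")
def scenario_sources(standard_scenario):
    from basketmap.forward_egm import compute_sources
    return compute_sources(standard_scenario.movie)


@pytest.fixture(scope="session")
def pacing_only_scenario():
    from basketmap.synthetic_data import make_pacing_only_scenario
    return make_pacing_only_scenario(duration_ms=1500.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
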