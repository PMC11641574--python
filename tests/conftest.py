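"""Shared fixtures.

The expensive simulation runs (propulsion controls and the coverage
trend) are session-scoped so the control tests and the trend test share
them.
"""

import numpy as np
import pytest

from janusmpc.driver import make_fixture_scenario, run_simulation
from janusmpc.observables import autocorrelated_standard_error


@pytest.fixture(scope="session")
def micro_config():
    return make_fixture_scenario("micro", phi=0.5, seed=7)


@pytest.fixture(scope="session")
def micro_run(micro_config):
    """A short full-physics run used by several bookkeeping tests."""
    return run_simulation(micro_config, n_cycles=6, frame_stride=2)


@pytest.fixture(scope="session")
def tiny_conservation_runs():
    """Tiny-fixture runs of 10^4 MD intervals, reactions on and off."""
    out = {}
    for rx in (True, False):
        cfg = make_fixture_scenario("tiny", phi=0.5, seed=2)
        out[rx] = run_simulation(cfg, n_cycles=100, reactions_enabled=rx)
    return out


#: run length (MPC cycles) for the propulsion runs: the largest that
#: fits the suite's time budget; uncertainties come from seed-to-seed
#: scatter of independent replicas
PROPULSION_CYCLES = 280
PROPULSION_SEEDS = (11, 12, 13)


@pytest.fixture(scope="session")
def propulsion_runs():
    """Small-fixture coverage scan: phi in {0, 0.4, 0.8} x 3 seeds.

    Returns {phi: {"vu": pooled post-burn-in samples, "means": per-seed
    means}}; shared by the sign control and the coverage-trend test.
    """
    out = {}
    for phi in (0.0, 0.4, 0.8):
        samples, means, ses = [], [], []
        for seed in PROPULSION_SEEDS:
            cfg = make_fixture_scenario("small", phi=phi, seed=seed)
            res = run_simulation(cfg, n_cycles=PROPULSION_CYCLES)
            vu = res.series.vu
            post = vu[int(0.3 * len(vu)):]
            means.append(post.mean())
            ses.append(autocorrelated_standard_error(post))
            samples.append(post)
        out[phi] = {"vu": np.concatenate(samples),
                    "means": np.array(means), "ses": np.array(ses)}
    return out


@pytest.fixture(scope="session")
def null_control_means():
    """Equal-epsilon control: no interaction contrast, hence no
    propulsion.  Six independent seeds; returns the per-seed mean Vu."""
    means = []
    for seed in (21, 22, 23, 24, 25, 26):
        cfg = make_fixture_scenario(
            "small", phi=0.8, seed=seed,
            eps_A_E0=1.0, eps_A_E1=1.0, eps_A_E2=1.0,
            eps_I_E0=1.0, eps_I_E1=1.0, eps_I_E2=1.0,
            eps_B_E0=1.0, eps_B_E1=1.0, eps_B_E2=1.0)
        res = run_simulation(cfg, n_cycles=110)
        vu = res.series.vu
        means.append(vu[int(0.3 * len(vu)):].mean())
    return np.array(means)
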