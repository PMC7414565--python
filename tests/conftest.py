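"""Shared fixtures: simulated tree batches are session-scoped because the
acceptance checks and several unit tests draw on the same study conditions
(crown 50 Ma, sampling fraction 0.74, optional 95%-kill event at 34 Ma)."""

import numpy as np
import pytest

from pulsetree import simdata, treeio

# study conditions for the event-recovery experiments: the event regime uses
# a turnover that leaves ~90 sampled tips after a 95% kill at 34 Ma; the
# no-event regime matches the same tip window with net diversification
# close to the fitted empirical value (~0.085 per Myr)
EVENT_CONFIG = dict(crown_age=50.0, lambda0=0.25, mu0=0.11, rho=0.74,
                    min_tips=60, max_tips=130, events=[(34.0, 0.05)])
NOEVENT_CONFIG = dict(crown_age=50.0, lambda0=0.11, mu0=0.028, rho=0.74,
                      min_tips=60, max_tips=130)


def simulate_batch(n, seed0, **kwargs):
    out = []
    for i in range(n):
        cfg = simdata.TreeSimConfig(seed=seed0 + i, **kwargs)
        tree, truth = simdata.simulate_tree(cfg)
        out.append((treeio.branching_times(tree), truth))
    return out


@pytest.fixture(scope="session")
def small_trees():
    """20 modest no-window trees for likelihood cross-checks."""
    out = []
    for i in range(20):
        cfg = simdata.TreeSimConfig(
            crown_age=30.0, lambda0=0.15, mu0=0.05, rho=1.0,
            min_tips=10, max_tips=200, seed=100 + i,
        )
        tree, _ = simdata.simulate_tree(cfg)
        out.append(treeio.branching_times(tree))
    return out


@pytest.fixture(scope="session")
def event_trees():
    """50 reconstructed trees simulated with a 95%-kill event at 34 Ma."""
    return simulate_batch(50, 1000, **EVENT_CONFIG)


@pytest.fixture(scope="session")
def noevent_trees():
    """50 reconstructed trees with no event, same tip window."""
    return simulate_batch(50, 2000, **NOEVENT_CONFIG)


@pytest.fixture(scope="session")
def recovery_trees():
    """50 ~200-tip constant-rate trees (lambda 0.25, mu 0.19, rho 1)."""
    return simulate_batch(
        50, 3000, crown_age=77.0, lambda0=0.25, mu0=0.19, rho=1.0,
        min_tips=150, max_tips=260,
    )
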