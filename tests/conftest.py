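"""Shared fixtures: parameter table, toy chain, and reusable short ensembles.

The replica ensembles are session-scoped because Langevin runs are the
expensive part of the suite; every test that needs sampled trajectories
shares the same two small ensembles (interacting and excluded-volume).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import stigroove as sg
from stigroove.cg_model import SimulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return sg.load_parameter_table()


@pytest.fixture(scope="session")
def toy_chain():
    return sg.make_toy_multidomain_chain()


@pytest.fixture(scope="session")
def toy_topology(toy_chain, params):
    return sg.build_topology(
        toy_chain.sequence, params, toy_chain.reference_coords,
        toy_chain.domains, enm_cutoff=toy_chain.enm_cutoff,
    )


@pytest.fixture(scope="session")
def ev_topology(toy_topology):
    return sg.excluded_volume_variant(toy_topology)


@pytest.fixture(scope="session")
def short_sim_config():
    return SimulationConfig(
        duration_ns=0.4, equilibration_ns=0.1,
        save_interval_ps=2.0, n_replicas=2,
    )


@pytest.fixture(scope="session")
def trajs_interacting(toy_topology, short_sim_config):
    return sg.run_replicas(toy_topology, short_sim_config, seed_base=42)


@pytest.fixture(scope="session")
def trajs_ev(ev_topology, short_sim_config):
    return sg.run_replicas(ev_topology, short_sim_config, seed_base=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
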