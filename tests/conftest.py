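"""Shared fixtures: registry, assembled scenarios and cached heavy objects.

Everything expensive (steady states, the 48-state single-cell library,
population runs) is computed once per session and reused across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from punisher_sim import circuits as cir
from punisher_sim import population as pop
from punisher_sim import scenarios_io as sio
from punisher_sim import threshold_analysis as ta


@pytest.fixture(scope="session")
def registry():
    return sio.load_registry()


@pytest.fixture(scope="session")
def host_params(registry):
    return sio.host_params(registry)


@pytest.fixture(scope="session")
def host_only_ss(registry):
    sc = sio.build_scenario("host_only", None, registry)
    y, rates, converged = cir.steady_state(sc)
    return sc, y, rates, converged


@pytest.fixture(scope="session")
def fig1_scenario(registry):
    fx = sio.make_fixture("fig1_single_gene")
    cfg = fx["config"]
    return sio.build_scenario(cfg.topology, None, registry,
                              mutations=cfg.mutations)


@pytest.fixture(scope="session")
def fig1_trajectory(fig1_scenario):
    return cir.simulate(fig1_scenario, (0.0, 60.0), n_samples=600)


@pytest.fixture(scope="session")
def burden_context(registry):
    """Pre/post-mutation burden summaries of the single-gene scenario with
    the switch pinned low and excision frozen (reference backgrounds)."""
    ov = {"k_sx_plus": 0.0, "K_s": 1e12}
    sc = sio.build_scenario("single_burdensome_gene_with_punisher", None,
                            registry, overrides=ov)
    bs_pre = ta.burden_summary(sc)
    bs_post = ta.burden_summary(sc.with_genes_mutated(("b",)))
    pp = sio.punisher_params(registry)
    return pp, bs_pre, bs_post


@pytest.fixture(scope="session")
def cell_library(registry):
    return pop.build_cell_library(registry)


@pytest.fixture(scope="session")
def transition_rates(registry, cell_library):
    return pop.deterministic_transition_rates(registry, cell_library)


@pytest.fixture(scope="session")
def population_runs(registry, cell_library, transition_rates):
    """Punisher and control population trajectories at the default mu."""
    mp, x0p = pop.punisher_population_model(registry, library=cell_library,
                                            transition_rates=transition_rates)
    mc, x0c = pop.control_population_model(registry, library=cell_library,
                                           transition_rates=transition_rates)
    tp = pop.simulate_population(mp, x0p)
    tc = pop.simulate_population(mc, x0c)
    return (mp, x0p, tp), (mc, x0c, tc)
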