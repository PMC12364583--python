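"""Shared fixtures.

The expensive simulations (benchmark battery, gastric scenario runs) are
session-scoped so that unit tests and the acceptance checks share a single
execution of each scenario.
"""

from __future__ import annotations

import numpy as np
import pytest

from gastrosim.config import NumericsConfig, SimulationConfig
from gastrosim.geometry import WaveParameters, build_lumen


# problem sizes for the gastric scenario runs used across the suite:
# h = 0.5 mm (8 cells per particle diameter) and shortened durations with
# the analysis window starting at t = 20 s (post-descent).
GRID_H = 0.5
DUR_MAIN = 70.0      # healthy, low viscosity: shuttling + emptying window
DUR_LIQUID = 60.0    # liquid-only emptying comparison ([20, 60] = 2 periods)
DUR_HYPO = 45.0      # hypomotile low viscosity
DUR_VISC = 35.0      # high-viscosity pair


def _gastric_cfg(motility="healthy", mu=1.0, particles=True, duration=DUR_MAIN):
    return SimulationConfig(
        motility=motility,
        mu_mPas=mu,
        include_particles=particles,
        duration_s=duration,
        numerics=NumericsConfig(grid_h_mm=GRID_H),
    )


def _run(cfg, tmp_path_factory, name):
    from gastrosim.runner import run

    out = tmp_path_factory.mktemp(name)
    return run(cfg, out)


@pytest.fixture(scope="session")
def healthy_mu1(tmp_path_factory):
    """Healthy motility, mu = 1 mPa s, eight particles."""
    return _run(_gastric_cfg(), tmp_path_factory, "healthy_mu1")


@pytest.fixture(scope="session")
def nosolids_mu1(tmp_path_factory):
    """Liquid-only meal, otherwise identical to healthy_mu1."""
    return _run(_gastric_cfg(particles=False, duration=DUR_LIQUID),
                tmp_path_factory, "nosolids_mu1")


@pytest.fixture(scope="session")
def hypo_mu1(tmp_path_factory):
    return _run(_gastric_cfg(motility="hypomotile", duration=DUR_HYPO),
                tmp_path_factory, "hypo_mu1")


@pytest.fixture(scope="session")
def healthy_mu10(tmp_path_factory):
    return _run(_gastric_cfg(mu=10.0, duration=DUR_VISC), tmp_path_factory, "healthy_mu10")


@pytest.fixture(scope="session")
def hypo_mu10(tmp_path_factory):
    return _run(_gastric_cfg(motility="hypomotile", mu=10.0, duration=DUR_VISC),
                tmp_path_factory, "hypo_mu10")


@pytest.fixture(scope="session")
def analytic_suite():
    from gastrosim.bench import run_analytic_suite

    return {r.name: r for r in run_analytic_suite()}


@pytest.fixture(scope="session")
def falling_particle():
    from gastrosim.bench import run_falling_particle_channel

    return run_falling_particle_channel()


@pytest.fixture(scope="session")
def dkt():
    from gastrosim.bench import run_draft_kiss_tumble

    return run_draft_kiss_tumble()


@pytest.fixture()
def stomach():
    """Default stomach lumen with healthy waves."""
    return build_lumen(waves=WaveParameters())


@pytest.fixture()
def static_stomach():
    return build_lumen(waves=None)
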