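import numpy as np
import pytest

import capsim as cs

import matplotlib

matplotlib.use("Agg")


@pytest.fixture(scope="session")
def small_grid():
    """Compact mesh with the production node spacing (5 µm)."""
    return cs.GridSpec(nodes_per_side=60, side_length=300, capsule_radius=105)


@pytest.fixture(scope="session")
def transport():
    return cs.TransportConfig()


@pytest.fixture(scope="session")
def small_domain(small_grid, transport):
    """Seeded stochastic capsule on the small mesh, diffusivity initialized."""
    cfg = cs.PlacementConfig(seed=2, n_spheroids=1, spheroid_radius=30,
                             n_fibro_single=6, n_fibro_cluster=2)
    dom = cs.place_elements(cs.build_domain(small_grid), cfg)
    return cs.init_diffusivity(dom, transport)


@pytest.fixture(scope="session")
def short_sim():
    return cs.SimulationConfig(total_time_min=60, store_diffusivity=False)


@pytest.fixture(scope="session")
def small_run(small_domain, short_sim, transport):
    return cs.run_simulation(small_domain, short_sim,
                             cs.SaturationParams(1.0, 1.0, 1.0), transport)


def radial_reference(R, D, c_inj, t_final_s, dr, safety=0.4):
    """Independent 1-D finite-volume solution of radial diffusion in a disc.

    Zero-flux center, Dirichlet c_inj at r = R.  Serves as the refined
    radially symmetric oracle for the 2-D solver; it shares no code with the
    2-D stencil.
    """
    n = int(round(R / dr))
    r_faces = np.arange(n + 1) * dr
    r_cent = (np.arange(n) + 0.5) * dr
    C = np.zeros(n)
    dt = safety * dr * dr / (2 * D)
    steps = int(np.ceil(t_final_s / dt))
    dt = t_final_s / steps
    for _ in range(steps):
        flux = np.zeros(n + 1)
        flux[1:-1] = r_faces[1:-1] * D * (C[1:] - C[:-1]) / dr
        flux[-1] = r_faces[-1] * D * (c_inj - C[-1]) / (dr / 2)
        C = C + dt * (flux[1:] - flux[:-1]) / (r_cent * dr)
    return r_cent, C
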