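import numpy as np
import pytest

from gdipol import (Discretization, PerturbationSpec, control_parameters,
                    homogeneous_steady_state, random_lattice_perturbation,
                    run_to_steady_state, simulate)


@pytest.fixture(scope="session")
def p_control():
    return control_parameters()


@pytest.fixture(scope="session")
def base_control(p_control):
    return homogeneous_steady_state(p_control)


@pytest.fixture(scope="session")
def disc16(p_control):
    return Discretization(p_control, L=16, nr=16)


@pytest.fixture(scope="session")
def control_trajectory(p_control, base_control, disc16):
    """Control-cell polarization from a 1% random-lattice perturbation.

    One shared nonlinear run (4000 s of simulated time) used by the
    dynamics, metrics and acceptance tests.
    """
    init = random_lattice_perturbation(
        PerturbationSpec(seed=1), p_control, base_control, disc16)
    return simulate(p_control, init, 4000.0,
                    output_times=np.linspace(0.0, 4000.0, 41), dt=0.5)


@pytest.fixture(scope="session")
def rotated_runs(p_control, base_control):
    """Two broad-cap runs with rotated initial directions, to steady state.

    Used for the rotational-equivariance checks: the final cluster must
    follow the seed direction with identical shape.
    """
    from gdipol import broad_cap_perturbation, cluster_stats
    results = []
    for direction in [(0.0, 0.0, 1.0), (0.70710678, 0.0, -0.70710678)]:
        disc = Discretization(p_control, L=16, nr=16)
        init = broad_cap_perturbation(
            PerturbationSpec(kind="broad_cap", amplitude=0.01,
                             cap_direction=direction),
            p_control, base_control, disc)
        final, info = run_to_steady_state(p_control, init, tol=1e-6,
                                          t_max=8000.0, dt=0.5)
        assert info["polarized"]
        stats = cluster_stats(final.cdc42_membrane_field(), disc.grid)
        results.append((stats, np.asarray(direction)))
    return results


@pytest.fixture(scope="session")
def control_steady(p_control, control_trajectory):
    """Polarized steady state continued from the shared trajectory."""
    state, info = run_to_steady_state(
        p_control, control_trajectory.final_state, tol=1e-6, t_max=6000.0, dt=0.5)
    assert info["converged"] and info["polarized"]
    return state
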