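"""Shared fixtures: phantoms and the two slow reference simulations.

The full experiments run at quarter resolution (~2,500 elements) here; the
acceptance checks apply the same bands at that scale.
"""

import numpy as np
import pytest

import tdcsim as t
from tdcsim.experiments import experiment_ap_conduction, experiment_tdcs, run_experiment


@pytest.fixture(scope="session")
def phantom():
    """The five-tissue phantom at quarter resolution (~2,500 triangles)."""
    return t.build_annulus_phantom(target_element_count=2500)


@pytest.fixture(scope="session")
def coarse_mesh():
    """A ~500-element phantom, small enough for dense linear-algebra oracles."""
    return t.build_annulus_phantom(target_element_count=500)


@pytest.fixture(scope="session")
def ap_run():
    """Full AP-conduction experiment (100 ms) at quarter resolution."""
    return run_experiment(experiment_ap_conduction(), scale=0.25)


@pytest.fixture(scope="session")
def ap_run_full():
    """AP-conduction experiment at the full 10,000-element resolution."""
    return run_experiment(experiment_ap_conduction(), scale=1.0)


@pytest.fixture(scope="session")
def tdcs_runs():
    """Both tDCS electrode configurations (100 ms) at quarter resolution."""
    return {
        1: run_experiment(experiment_tdcs(1), scale=0.25),
        2: run_experiment(experiment_tdcs(2), scale=0.25),
    }


@pytest.fixture(scope="session")
def tdcs_runs_full():
    """Both tDCS configurations at the full 10,000-element resolution."""
    return {
        1: run_experiment(experiment_tdcs(1), scale=1.0),
        2: run_experiment(experiment_tdcs(2), scale=1.0),
    }


@pytest.fixture()
def toy_triangle():
    """A single unit right triangle tagged as white matter."""
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    elements = np.array([[0, 1, 2]])
    tags = np.array([int(t.Tissue.WM)])
    return t.SimplicialMesh(nodes=nodes, elements=elements, tissue_tag=tags)


@pytest.fixture()
def toy_square():
    """Four triangles around the center of a unit square (4 hull edges)."""
    nodes = np.array(
        [[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.5, 0.5]]
    )
    elements = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
    tags = np.array([int(t.Tissue.GM)] * 4)
    return t.SimplicialMesh(nodes=nodes, elements=elements, tissue_tag=tags)
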