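"""Stationary volume-conductor (Laplace) tDCS model, the validation reference.

The classical forward model of tDCS treats the whole head as a passive
conductor:  div(M grad Phi) = 0 with the same electrode boundary
conditions as the multiscale model (anode Neumann current, grounded
cathode, insulated scalp elsewhere) and extracellular conductivities only.
After the coupled model's transients settle, its electric potential should
match this single-field solution; :func:`compare_fields` quantifies the
agreement as a relative L2 difference using P1 mass-matrix inner products.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .assembly import ConductivityField, facet_load_vector, mass_matrix, stiffness_matrix, _eliminate_symmetric
from .mesh import ElectrodeKind, ElectrodePatch, SimplicialMesh
from . import solver as _solver

__all__ = ["solve_laplace", "compare_fields"]


def solve_laplace(
    mesh: SimplicialMesh,
    conductivity: ConductivityField,
    anode: ElectrodePatch,
    cathode: ElectrodePatch,
    rel_tol: float = 1e-8,
    omega: float = 0.5,
    max_iters: int = 20000,
) -> np.ndarray:
    """P1 solution of div(M_e grad Phi) = 0 with tDCS electrodes.

    Returns the nodal potential (V).  Solved with the same RILU(0)-
    preconditioned conjugate-gradient machinery as the coupled model.
    """
    if cathode is None or len(cathode.facet_indices) == 0:
        raise ValueError("cathode must be non-empty: pure-Neumann Laplace is singular")
    if anode.kind is not ElectrodeKind.ANODE or cathode.kind is not ElectrodeKind.CATHODE:
        raise ValueError("electrode kinds are swapped or duplicated")

    K = stiffness_matrix(mesh, conductivity.sigma_e)
    measure = float(mesh.boundary_facet_measures()[anode.facet_indices].sum())
    load = facet_load_vector(mesh, anode, anode.total_current / measure)
    dirichlet = cathode.nodes(mesh)
    Kc = _eliminate_symmetric(K, dirichlet)
    load[dirichlet] = 0.0
    pre = _solver.rilu0(Kc, omega)
    phi, _ = _solver.pcg_solve(Kc, load, pre, rel_tol=rel_tol, max_iters=max_iters)
    return phi


def compare_fields(
    mesh: SimplicialMesh,
    phi_a: np.ndarray,
    phi_b: np.ndarray,
    region: np.ndarray | None = None,
) -> float:
    """Relative L2 difference ||a - b|| / ||b|| over a region (element mask).

    Norms use the P1 mass matrix of the region, i.e. true L2 integrals of
    the interpolants.  ``region`` defaults to the whole domain.
    """
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if not region.any():
            raise ValueError("comparison region is empty")
    M = mass_matrix(mesh, region)
    d = np.asarray(phi_a, dtype=float) - np.asarray(phi_b, dtype=float)
    denom = float(np.asarray(phi_b) @ (M @ np.asarray(phi_b)))
    if denom == 0.0:
        raise ValueError("reference field is identically zero on the region")
    return float(np.sqrt((d @ (M @ d)) / denom))
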