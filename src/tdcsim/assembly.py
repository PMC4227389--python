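"""P1 finite-element assembly of the coupled bidomain/volume-conductor system.

One implicit-Euler step of the diffusion substep solves, in weak form, the
symmetric 2x2 block system

    [ A  B ] [ v   ]   [ alpha ]
    [ B' C ] [ Phi ] = [  g    ]

with, writing beta = dt / (chi * C_m),

    A = mass(Omega_B) + beta * stiffness(M_i, Omega_B)
    B = beta * stiffness(M_i, Omega_B)            (brain rows, all columns)
    C = beta * [stiffness(M_i + M_e, Omega_B) + stiffness(M_e, elsewhere)]
    alpha = mass(Omega_B) @ v_tilde

v lives on brain nodes only (nodes of GM/WM elements, including the brain
interface), Phi on all nodes.  M_i and M_e are the intracellular and
extracellular conductivity tensors; M_i vanishes outside the brain, which
confines intracellular current to Omega_B without any explicit boundary
term.  tDCS enters through the Phi block: a uniform inward Neumann current
density under the anode (load vector g) and a grounded Dirichlet cathode,
enforced by symmetric row/column elimination so conjugate gradients stay
applicable.

All integrals are exact for P1 elements (constant gradients; order-2 mass
rule), so there is no quadrature tolerance anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mesh import ElectrodeKind, ElectrodePatch, SimplicialMesh, Tissue

__all__ = [
    "DEFAULT_EXTRACELLULAR",
    "DEFAULT_INTRACELLULAR",
    "ConductivityField",
    "BlockSystem",
    "build_conductivity",
    "assemble_blocks",
    "apply_tdcs_bcs",
    "build_rhs",
    "mass_matrix",
    "stiffness_matrix",
]

#: Isotropic extracellular conductivities (S/m) per tissue.
DEFAULT_EXTRACELLULAR: dict[Tissue, float] = {
    Tissue.SKIN: 0.465,
    Tissue.SKULL: 0.010,
    Tissue.CSF: 1.654,
    Tissue.GM: 0.276,
    Tissue.WM: 0.126,
}

#: Isotropic intracellular conductivity (S/m) in GM and WM.
DEFAULT_INTRACELLULAR: float = 0.1


@dataclass
class ConductivityField:
    """Per-element intracellular and extracellular conductivity tensors.

    Stored as full (n_elements, d, d) symmetric tensors; isotropic tissues
    are sigma * I.  ``sigma_i`` is identically zero outside brain elements.
    """

    sigma_e: np.ndarray
    sigma_i: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sigma_e", "sigma_i"):
            t = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, t)
            if t.ndim != 3 or t.shape[1] != t.shape[2]:
                raise ValueError(f"{name} must be (n_elements, d, d)")
            if not np.allclose(t, np.swapaxes(t, 1, 2)):
                raise ValueError(f"{name} tensors must be symmetric")
        ev = np.linalg.eigvalsh(self.sigma_i)
        if ev.min() < -1e-12:
            raise ValueError("sigma_i tensors must be positive semidefinite")
        ev = np.linalg.eigvalsh(self.sigma_e)
        if ev.min() <= 0:
            raise ValueError("sigma_e tensors must be positive definite")


def build_conductivity(
    mesh: SimplicialMesh,
    table: dict[Tissue, float] | None = None,
    intra_sigma: float = DEFAULT_INTRACELLULAR,
    sigma_e_tensors: dict[int, np.ndarray] | None = None,
    sigma_i_tensors: dict[int, np.ndarray] | None = None,
) -> ConductivityField:
    """Build isotropic per-tissue conductivities, with tensor overrides.

    ``table`` maps each of the five tissues to its extracellular scalar
    conductivity (S/m); ``intra_sigma`` is applied on GM/WM elements and
    zero elsewhere.  ``sigma_*_tensors`` optionally override individual
    elements with full (d, d) tensors (used verbatim in the stiffness
    integration, e.g. for anisotropic white matter).
    """
    if table is None:
        table = DEFAULT_EXTRACELLULAR
    missing = [t.name for t in Tissue if t not in table]
    if missing:
        raise ValueError(f"conductivity table missing tissues: {missing}")
    d = mesh.dim
    eye = np.eye(d)
    sig_e_scalar = np.empty(mesh.n_elements)
    for t in Tissue:
        sig_e_scalar[mesh.tissue_tag == int(t)] = table[t]
    sigma_e = sig_e_scalar[:, None, None] * eye
    sigma_i = np.zeros_like(sigma_e)
    sigma_i[mesh.brain_element_mask()] = intra_sigma * eye
    for store, overrides in ((sigma_e, sigma_e_tensors), (sigma_i, sigma_i_tensors)):
        if overrides:
            for eid, tensor in overrides.items():
                store[eid] = np.asarray(tensor, dtype=float)
    return ConductivityField(sigma_e=sigma_e, sigma_i=sigma_i)


# ---------------------------------------------------------------------------
# Elementary P1 matrices
# ---------------------------------------------------------------------------


def _p1_gradients(mesh: SimplicialMesh) -> np.ndarray:
    """Constant basis-function gradients, shape (n_elements, d, d+1)."""
    p = mesh.nodes[mesh.elements]          # (m, d+1, d)
    v = p[:, 1:, :] - p[:, :1, :]          # edge matrix rows
    vinv = np.linalg.inv(v)                # (m, d, d)
    # gradients of barycentric coords 1..d are columns of v^{-1};
    # gradient of coord 0 closes the partition of unity
    g = np.empty((mesh.n_elements, mesh.dim, mesh.dim + 1))
    g[:, :, 1:] = vinv
    g[:, :, 0] = -vinv.sum(axis=2)
    return g


def mass_matrix(mesh: SimplicialMesh, element_mask: np.ndarray | None = None) -> sp.csr_matrix:
    """Consistent P1 mass matrix over the whole mesh or an element subset."""
    elems = mesh.elements if element_mask is None else mesh.elements[element_mask]
    meas = mesh.element_measures() if element_mask is None else mesh.element_measures()[element_mask]
    nloc = mesh.dim + 1
    # exact: integral N_i N_j = measure * (1 + delta_ij) / ((d+1)(d+2))
    base = (np.ones((nloc, nloc)) + np.eye(nloc)) / ((nloc) * (nloc + 1))
    local = meas[:, None, None] * base
    rows = np.repeat(elems, nloc, axis=1).ravel()
    cols = np.tile(elems, (1, nloc)).ravel()
    M = sp.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return M.tocsr()


def stiffness_matrix(
    mesh: SimplicialMesh,
    sigma: np.ndarray,
    element_mask: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Stiffness matrix  integral of (sigma grad N_j) . grad N_i.

    ``sigma`` is an (n_elements, d, d) tensor field; rows for elements
    outside ``element_mask`` are skipped entirely.
    """
    if element_mask is None:
        element_mask = np.ones(mesh.n_elements, dtype=bool)
    elems = mesh.elements[element_mask]
    meas = mesh.element_measures()[element_mask]
    g = _p1_gradients(mesh)[element_mask]            # (m, d, d+1)
    sig = np.asarray(sigma)[element_mask]
    local = meas[:, None, None] * np.einsum("eai,eab,ebj->eij", g, sig, g)
    # enforce exact elementwise symmetry so the assembled operator (and the
    # full block matrix) is symmetric to the last bit, as CG requires
    local = 0.5 * (local + local.transpose(0, 2, 1))
    nloc = mesh.dim + 1
    rows = np.repeat(elems, nloc, axis=1).ravel()
    cols = np.tile(elems, (1, nloc)).ravel()
    K = sp.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return K.tocsr()


# ---------------------------------------------------------------------------
# Block system
# ---------------------------------------------------------------------------


@dataclass
class BlockSystem:
    """The assembled 2x2 block system and its boundary-condition state."""

    mesh: SimplicialMesh
    conductivity: ConductivityField
    chi: float
    c_m: float
    dt: float
    brain_nodes: np.ndarray        # global node index per v-DOF
    A: sp.csr_matrix               # (n_v, n_v)
    B: sp.csr_matrix               # (n_v, n_phi)
    C: sp.csr_matrix               # (n_phi, n_phi), unconstrained
    mass_brain: sp.csr_matrix      # (n_v, n_v)
    anode_load: np.ndarray | None = None      # (n_phi,), beta-scaled
    dirichlet_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def beta(self) -> float:
        return self.dt / (self.chi * self.c_m)

    @property
    def n_v(self) -> int:
        return len(self.brain_nodes)

    @property
    def n_phi(self) -> int:
        return self.mesh.n_nodes

    @property
    def n_total(self) -> int:
        return self.n_v + self.n_phi

    def constrained_C(self) -> sp.csr_matrix:
        """C with cathode rows/columns symmetrically eliminated."""
        if "C_con" not in self._cache:
            self._cache["C_con"] = _eliminate_symmetric(self.C, self.dirichlet_nodes)
        return self._cache["C_con"]

    def full_matrix(self) -> sp.csr_matrix:
        """Constrained [[A, B], [B', C]] as one CSR matrix."""
        if "K" not in self._cache:
            B = self.B
            if len(self.dirichlet_nodes):
                B = B.tolil(copy=True)
                B[:, self.dirichlet_nodes] = 0.0
                B = B.tocsr()
            K = sp.bmat([[self.A, B], [B.T, self.constrained_C()]], format="csr")
            self._cache["K"] = K
        return self._cache["K"]


def _eliminate_symmetric(K: sp.csr_matrix, dofs: np.ndarray) -> sp.csr_matrix:
    """Zero rows and columns ``dofs`` and put 1 on their diagonal."""
    if len(dofs) == 0:
        return K
    n = K.shape[0]
    keep = np.ones(n)
    keep[dofs] = 0.0
    P = sp.diags(keep)
    out = (P @ K @ P).tolil()
    for i in dofs:
        out[i, i] = 1.0
    return out.tocsr()


def assemble_blocks(
    mesh: SimplicialMesh,
    conductivity: ConductivityField,
    chi: float,
    c_m: float,
    dt: float,
) -> BlockSystem:
    """Assemble the A, B, C blocks for one implicit-Euler diffusion step.

    ``chi`` is the membrane surface-to-volume ratio (1/m), ``c_m`` the
    membrane capacitance (F/m^2), ``dt`` the global time step (s).
    """
    if dt <= 0 or chi <= 0 or c_m <= 0:
        raise ValueError("dt, chi and c_m must all be positive")
    beta = dt / (chi * c_m)
    brain_mask = mesh.brain_element_mask()
    brain_nodes = mesh.brain_nodes()

    Ki = stiffness_matrix(mesh, conductivity.sigma_i, brain_mask)
    Ke = stiffness_matrix(mesh, conductivity.sigma_e)  # all elements
    Mb = mass_matrix(mesh, brain_mask)

    # restrict to v-DOFs: any column of Ki outside brain_nodes is identically 0
    Ki_bb = Ki[brain_nodes][:, brain_nodes].tocsr()
    Mb_bb = Mb[brain_nodes][:, brain_nodes].tocsr()
    A = (Mb_bb + beta * Ki_bb).tocsr()
    B = (beta * Ki[brain_nodes]).tocsr()
    C = (beta * (Ki + Ke)).tocsr()
    return BlockSystem(
        mesh=mesh,
        conductivity=conductivity,
        chi=chi,
        c_m=c_m,
        dt=dt,
        brain_nodes=brain_nodes,
        A=A,
        B=B,
        C=C,
        mass_brain=Mb_bb,
    )


def facet_load_vector(
    mesh: SimplicialMesh, patch: ElectrodePatch, density: float
) -> np.ndarray:
    """Integrate a uniform boundary current density against P1 facet bases."""
    load = np.zeros(mesh.n_nodes)
    facets = mesh.boundary_facets[patch.facet_indices]
    meas = mesh.boundary_facet_measures()[patch.facet_indices]
    share = density * meas / facets.shape[1]  # equal split, exact for P1 on facets
    for f, s in zip(facets, share):
        load[f] += s
    return load


def apply_tdcs_bcs(
    system: BlockSystem,
    anode: ElectrodePatch | None,
    cathode: ElectrodePatch | None,
) -> BlockSystem:
    """Install tDCS electrode boundary conditions on an assembled system.

    Anode: inhomogeneous Neumann — a uniform inward current density
    ``total_current / electrode measure`` integrated against the facet basis
    functions and scaled by beta, consistent with the block scaling.
    Cathode: grounded Dirichlet, by symmetric row/column elimination.  Every
    other scalp facet is naturally insulated.  Returns ``system`` mutated.
    """
    if anode is not None and (cathode is None or len(cathode.facet_indices) == 0):
        raise ValueError(
            "an active anode requires a non-empty cathode: the Phi problem is "
            "otherwise singular (defined only up to a constant)"
        )
    system._cache.clear()
    if anode is not None:
        if anode.kind is not ElectrodeKind.ANODE:
            raise ValueError("anode patch has wrong kind")
        measure = float(
            system.mesh.boundary_facet_measures()[anode.facet_indices].sum()
        )
        density = anode.total_current / measure
        system.anode_load = system.beta * facet_load_vector(
            system.mesh, anode, density
        )
    if cathode is not None:
        if cathode.kind is not ElectrodeKind.CATHODE:
            raise ValueError("cathode patch has wrong kind")
        cath_nodes = cathode.nodes(system.mesh)
        if anode is not None:
            an_nodes = anode.nodes(system.mesh)
            if np.intersect1d(cath_nodes, an_nodes).size:
                raise ValueError("anode and cathode electrodes overlap")
        system.dirichlet_nodes = cath_nodes
        if system.anode_load is not None:
            system.anode_load[cath_nodes] = 0.0
    return system


def build_rhs(system: BlockSystem, v_tilde: np.ndarray) -> np.ndarray:
    """Right-hand side [mass(Omega_B) v_tilde ; anode load] for Eq solve."""
    v_tilde = np.asarray(v_tilde, dtype=float)
    if v_tilde.shape != (system.n_v,):
        raise ValueError(
            f"v_tilde has shape {v_tilde.shape}, expected ({system.n_v},)"
        )
    rhs = np.zeros(system.n_total)
    rhs[: system.n_v] = system.mass_brain @ v_tilde
    if system.anode_load is not None:
        rhs[system.n_v :] = system.anode_load
    if len(system.dirichlet_nodes):
        rhs[system.n_v + system.dirichlet_nodes] = 0.0
    return rhs
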