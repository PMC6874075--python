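"""Voxel-based homogeneous linear-elastic micro-FE stiffness and strength.

Every bone voxel becomes an 8-noded hexahedral element with isotropic
linear-elastic material (default E = 14.8 GPa, ν = 0.3). Two load cases on
the longitudinal (Z) axis:

* stiffness — proximal surface fully constrained, a prescribed axial
  displacement on every distal-surface node (transverse DOFs free);
  apparent stiffness is the summed proximal axial reaction divided by the
  applied displacement (N/mm);
* strength — proximal surface fully constrained, a unit probe load equally
  distributed over the distal-surface nodes; the failure load scales the
  probe so that 2% of the considered nodes exceed −10300 με third principal
  (compressive) or +8000 με first principal (tensile) strain, with nodes
  within 10% of the total length of either end excluded from the criterion.

Units: lengths mm, Young's modulus MPa (N/mm²), forces N, strains με.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import linalg as splinalg

from .imgproc import BoneMask, STRUCT_6


@dataclass
class FEModelSpec:
    """Material, boundary-condition and failure-criterion parameters."""

    E_mpa: float = 14800.0  # Young's modulus (14.8 GPa)
    nu: float = 0.3  # Poisson's ratio
    applied_displacement_mm: float = 1.0  # stiffness case
    applied_load_n: float = 1.0  # strength probe load
    end_exclusion_fraction: float = 0.10
    failure_node_fraction: float = 0.02
    eps_comp_limit_ue: float = -10300.0  # third principal strain limit
    eps_tens_limit_ue: float = 8000.0  # first principal strain limit
    rtol: float = 1e-8
    solver: str = "auto"  # auto | direct | cg

    def __post_init__(self) -> None:
        if not 0 <= self.nu < 0.5:
            raise ValueError("Poisson's ratio must be in [0, 0.5)")
        if self.eps_comp_limit_ue >= 0 or self.eps_tens_limit_ue <= 0:
            raise ValueError("strain limits must be signed (comp < 0 < tens)")
        for f in (self.end_exclusion_fraction, self.failure_node_fraction):
            if not 0 < f < 1:
                raise ValueError("fractions must lie in (0, 1)")


@dataclass
class VoxelMesh:
    """Hexahedral mesh of the largest 6-connected voxel component."""

    elements: np.ndarray  # (ne, 8) global node ids, local corner order
    node_coords: np.ndarray  # (nn, 3) in voxel index units (z, y, x)
    edge_mm: float  # element edge length
    proximal_nodes: np.ndarray  # node ids on the first occupied slice
    distal_nodes: np.ndarray  # node ids on the last occupied slice

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def node_z_mm(self) -> np.ndarray:
        return self.node_coords[:, 0] * self.edge_mm


@dataclass
class FEResult:
    stiffness_n_per_mm: float | None = None
    strength_n: float | None = None
    nodal_eps1_ue: np.ndarray | None = None
    nodal_eps3_ue: np.ndarray | None = None
    n_nodes: int = 0
    n_elements: int = 0
    solver_iterations: int = 0
    residual: float = 0.0


# local corner offsets in (z, y, x); nodes ordered so that the first four
# lie in the lower-z plane, counter-clockwise in (x, y)
_CORNERS = np.array([
    [0, 0, 0], [0, 0, 1], [0, 1, 1], [0, 1, 0],
    [1, 0, 0], [1, 0, 1], [1, 1, 1], [1, 1, 0],
])
# matching natural coordinates (xi, eta, zeta) of the 8 nodes
_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)


def build_mesh(mask: BoneMask, connectivity: int = 6) -> VoxelMesh:
    """Mesh the largest 6-connected component of a bone mask.

    Shared faces share nodes. Proximal/distal node sets are the nodes in
    the first/last occupied slice's node planes.
    """
    if mask.count() == 0:
        raise ValueError("empty mask cannot be meshed")
    struct = STRUCT_6 if connectivity == 6 else ndimage.generate_binary_structure(3, 3)
    labels, n = ndimage.label(mask.data, structure=struct)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        keep = labels == (int(np.argmax(counts)) + 1)
    else:
        keep = mask.data
    vox = np.argwhere(keep)
    corners = vox[:, None, :] + _CORNERS[None, :, :]  # (ne, 8, 3)
    nz, ny, nx = mask.shape
    lin = (corners[..., 0] * (ny + 1) + corners[..., 1]) * (nx + 1) + corners[..., 2]
    uniq, inv = np.unique(lin, return_inverse=True)
    elements = inv.reshape(-1, 8).astype(np.int64)
    node_coords = np.stack(
        np.unravel_index(uniq, (nz + 1, ny + 1, nx + 1)), axis=1
    ).astype(float)
    z_first, z_last = vox[:, 0].min(), vox[:, 0].max()
    proximal = np.flatnonzero(node_coords[:, 0] == z_first)
    distal = np.flatnonzero(node_coords[:, 0] == z_last + 1)
    return VoxelMesh(elements, node_coords, mask.spacing / 1000.0,
                     proximal, distal)


# ---------------------------------------------------------------------------
# element stiffness
# ---------------------------------------------------------------------------

def elastic_moduli(E: float, nu: float) -> np.ndarray:
    """6×6 isotropic elasticity matrix (engineering shear strains)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] = lam + 2 * mu
    D[3, 3] = D[4, 4] = D[5, 5] = mu
    return D


def _shape_gradients(xi: np.ndarray, edge: float) -> np.ndarray:
    """dN/d(x,y,z) for the 8 trilinear shape functions at natural point xi.

    Returns an (8, 3) array of gradients with respect to physical
    coordinates (x, y, z) for a cube of side ``edge``.
    """
    g = np.empty((8, 3))
    for a in range(8):
        xa, ya, za = _XI[a]
        g[a, 0] = xa * (1 + ya * xi[1]) * (1 + za * xi[2]) / 8.0
        g[a, 1] = ya * (1 + xa * xi[0]) * (1 + za * xi[2]) / 8.0
        g[a, 2] = za * (1 + xa * xi[0]) * (1 + ya * xi[1]) / 8.0
    return g * (2.0 / edge)  # jacobian of the cube is (edge/2) I


def _b_matrix(grad: np.ndarray) -> np.ndarray:
    """6×24 strain-displacement matrix from shape-function gradients.

    DOF order is node-major (u_x, u_y, u_z per node); strain order
    (εxx, εyy, εzz, γxy, γyz, γzx).
    """
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grad[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


_GAUSS = np.array([-1.0, 1.0]) / np.sqrt(3.0)


def element_stiffness(E: float, nu: float, edge_mm: float) -> np.ndarray:
    """24×24 stiffness of a uniform cube element, 2×2×2 Gauss quadrature."""
    if nu >= 0.5:
        raise ValueError("Poisson's ratio must be < 0.5")
    D = elastic_moduli(E, nu)
    detJ = (edge_mm / 2.0) ** 3
    Ke = np.zeros((24, 24))
    for gx in _GAUSS:
        for gy in _GAUSS:
            for gz in _GAUSS:
                B = _b_matrix(_shape_gradients(np.array([gx, gy, gz]), edge_mm))
                Ke += B.T @ D @ B * detJ
    return Ke


def mean_b_matrix(edge_mm: float) -> np.ndarray:
    """Strain-displacement matrix averaged over the 2×2×2 Gauss points.

    Used for element centroid strain recovery.
    """
    B = np.zeros((6, 24))
    for gx in _GAUSS:
        for gy in _GAUSS:
            for gz in _GAUSS:
                B += _b_matrix(_shape_gradients(np.array([gx, gy, gz]), edge_mm))
    return B / 8.0


# ---------------------------------------------------------------------------
# assembly and solve
# ---------------------------------------------------------------------------

def _element_dofs(mesh: VoxelMesh) -> np.ndarray:
    """(ne, 24) global DOF ids; DOFs are (x, y, z) per node.

    Within an element the DOF order matches the B-matrix convention:
    node-major, components (x, y, z).
    """
    return (3 * mesh.elements[:, :, None]
            + np.arange(3)[None, None, :]).reshape(-1, 24)


def assemble(mesh: VoxelMesh, spec: FEModelSpec) -> sparse.csr_matrix:
    """Assemble the global stiffness matrix (double precision)."""
    Ke = element_stiffness(spec.E_mpa, spec.nu, mesh.edge_mm)
    edof = _element_dofs(mesh)
    ne = edof.shape[0]
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    data = np.tile(Ke.ravel(), ne)
    ndof = 3 * mesh.n_nodes
    K = sparse.coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


def _solve(K: sparse.csr_matrix, fixed: np.ndarray, u_fixed: np.ndarray,
           f: np.ndarray, spec: FEModelSpec):
    """Solve K u = f with prescribed DOFs; returns (u, iterations, residual)."""
    ndof = K.shape[0]
    free = np.setdiff1d(np.arange(ndof), fixed, assume_unique=False)
    u = np.zeros(ndof)
    u[fixed] = u_fixed
    rhs = f[free] - K[free][:, fixed] @ u_fixed
    Kff = K[free][:, free].tocsr()
    its = 0
    if spec.solver == "direct" or (spec.solver == "auto" and free.size <= 40_000):
        uf = splinalg.spsolve(Kff.tocsc(), rhs)
    else:
        diag = Kff.diagonal()
        M = sparse.diags(1.0 / diag)
        counter = {"n": 0}

        def cb(_):
            counter["n"] += 1

        uf, info = splinalg.cg(Kff, rhs, M=M, rtol=spec.rtol, atol=0.0,
                               maxiter=10 * free.size, callback=cb)
        its = counter["n"]
        if info != 0:
            res = np.linalg.norm(Kff @ uf - rhs) / np.linalg.norm(rhs)
            raise RuntimeError(
                f"CG failed to converge (info={info}, rel. residual {res:.2e})"
            )
    u[free] = uf
    res = float(np.linalg.norm(Kff @ uf - rhs)
                / max(np.linalg.norm(rhs), 1e-300))
    return u, its, res


def solve_stiffness(mesh: VoxelMesh, spec: FEModelSpec | None = None) -> FEResult:
    """Apparent compressive stiffness (N/mm) under prescribed displacement.

    Proximal nodes are fixed in all three DOFs; distal nodes carry a
    prescribed axial displacement directed proximally (compression) with
    transverse DOFs left free. Stiffness is the magnitude of the summed
    proximal axial reactions divided by the applied displacement.
    """
    spec = spec or FEModelSpec()
    K = assemble(mesh, spec)
    d = spec.applied_displacement_mm
    fixed_p = (3 * mesh.proximal_nodes[:, None] + np.arange(3)).ravel()
    fixed_d = 3 * mesh.distal_nodes + 2  # z component only
    fixed = np.concatenate([fixed_p, fixed_d])
    u_fixed = np.concatenate([np.zeros(fixed_p.size), np.full(fixed_d.size, -d)])
    f = np.zeros(K.shape[0])
    u, its, res = _solve(K, fixed, u_fixed, f, spec)
    reactions = K @ u
    rz_prox = reactions[3 * mesh.proximal_nodes + 2]
    stiffness = abs(rz_prox.sum()) / d
    return FEResult(stiffness_n_per_mm=float(stiffness),
                    n_nodes=mesh.n_nodes, n_elements=mesh.n_elements,
                    solver_iterations=its, residual=res)


def nodal_principal_strains(mesh: VoxelMesh, u: np.ndarray):
    """Per-node principal strains (ε1 ≥ ε3, in με).

    Element strains are evaluated with the Gauss-point-averaged
    strain-displacement matrix (centroid strain); nodal strains are the
    volume average of the adjacent element strains (uniform element
    volumes, so a plain mean).
    """
    Bavg = mean_b_matrix(mesh.edge_mm)
    edof = _element_dofs(mesh)
    ue = u[edof]  # (ne, 24)
    eps_e = ue @ Bavg.T  # (ne, 6)
    nn = mesh.n_nodes
    sums = np.zeros((nn, 6))
    counts = np.zeros(nn)
    np.add.at(sums, mesh.elements.ravel(),
              np.repeat(eps_e, 8, axis=0))
    np.add.at(counts, mesh.elements.ravel(), 1.0)
    eps_n = sums / counts[:, None]
    exx, eyy, ezz, gxy, gyz, gzx = eps_n.T
    T = np.empty((nn, 3, 3))
    T[:, 0, 0] = exx
    T[:, 1, 1] = eyy
    T[:, 2, 2] = ezz
    T[:, 0, 1] = T[:, 1, 0] = gxy / 2.0
    T[:, 1, 2] = T[:, 2, 1] = gyz / 2.0
    T[:, 0, 2] = T[:, 2, 0] = gzx / 2.0
    evals = np.linalg.eigvalsh(T)  # ascending
    eps3 = evals[:, 0] * 1e6
    eps1 = evals[:, 2] * 1e6
    return eps1, eps3


def failure_factors(eps1_ue: np.ndarray, eps3_ue: np.ndarray,
                    spec: FEModelSpec) -> np.ndarray:
    """Per-node load scale factor at which the strain criterion trips.

    λ = min(|comp limit| / |ε3| if ε3 < 0, tens limit / ε1 if ε1 > 0);
    ∞ where neither applies.
    """
    lam = np.full(eps1_ue.shape, np.inf)
    comp = eps3_ue < 0
    lam[comp] = np.abs(spec.eps_comp_limit_ue) / np.abs(eps3_ue[comp])
    tens = eps1_ue > 0
    lam[tens] = np.minimum(lam[tens],
                           spec.eps_tens_limit_ue / eps1_ue[tens])
    return lam


def solve_strength(mesh: VoxelMesh, spec: FEModelSpec | None = None) -> FEResult:
    """Failure load (N) under an equally distributed distal probe load.

    The probe load is applied axially (compression) and scaled linearly:
    the structure fails when ``failure_node_fraction`` of the considered
    nodes (those at least ``end_exclusion_fraction`` of the total length
    away from both ends) reach a principal-strain limit. With λ the sorted
    per-node scale factors, strength = probe load × λ_(k),
    k = ceil(fraction × N_considered).
    """
    spec = spec or FEModelSpec()
    K = assemble(mesh, spec)
    fixed = (3 * mesh.proximal_nodes[:, None] + np.arange(3)).ravel()
    f = np.zeros(K.shape[0])
    f[3 * mesh.distal_nodes + 2] = -spec.applied_load_n / mesh.distal_nodes.size
    u, its, res = _solve(K, fixed, np.zeros(fixed.size), f, spec)
    eps1, eps3 = nodal_principal_strains(mesh, u)
    z = mesh.node_z_mm()
    zmin, zmax = z.min(), z.max()
    length = zmax - zmin
    margin = spec.end_exclusion_fraction * length
    considered = (z >= zmin + margin) & (z <= zmax - margin)
    lam = failure_factors(eps1[considered], eps3[considered], spec)
    if not np.isfinite(lam).any():
        raise RuntimeError("zero strain field: no node can reach a limit")
    k = int(np.ceil(spec.failure_node_fraction * lam.size))
    lam_sorted = np.sort(lam)
    strength = spec.applied_load_n * lam_sorted[k - 1]
    return FEResult(strength_n=float(strength),
                    nodal_eps1_ue=eps1, nodal_eps3_ue=eps3,
                    n_nodes=mesh.n_nodes, n_elements=mesh.n_elements,
                    solver_iterations=its, residual=res)


def downsample_mask(mask: BoneMask, factor: int) -> BoneMask:
    """Coarsen a mask by an integer factor (majority rule per block).

    Used to keep whole-bone FE models tractable: the element edge becomes
    ``factor`` voxel spacings.
    """
    if factor == 1:
        return mask
    nz, ny, nx = mask.shape
    cz, cy, cx = (n // factor for n in (nz, ny, nx))
    trimmed = mask.data[:cz * factor, :cy * factor, :cx * factor]
    blocks = trimmed.reshape(cz, factor, cy, factor, cx, factor)
    frac = blocks.mean(axis=(1, 3, 5))
    return BoneMask(frac >= 0.5, mask.spacing * factor, mask.threshold)
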