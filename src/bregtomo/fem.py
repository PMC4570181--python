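"""P1 finite-element discretization of the diffusion approximation.

Photon transport in highly scattering tissue is modeled by the diffusion
approximation to the radiative transfer equation:

    -div( D grad(phi) ) + mu_a * phi = q        in the domain,
    phi + 2 A_n D dphi/dnu = 0                  on the boundary,

with diffusion coefficient D = 1/(3 (mu_a + mu_s')) and A_n the
refractive-index mismatch factor of the Robin boundary condition. On a
tetrahedral mesh with linear elements this yields the sparse SPD system

    K phi = b,   K = K_diff + K_abs + K_bnd,

where b = M q for a nodal source *density* q (M the P1 mass matrix) or a
unit vector for a point source of unit power at a node.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

from .mesh import TetMesh, _all_faces


def mismatch_factor(refractive_index: float) -> float:
    """Robin boundary factor A_n for a tissue-air interface.

    Uses the standard polynomial fit of the effective Fresnel
    reflectance: R_eff = -1.4399 n^-2 + 0.7099 n^-1 + 0.6681 + 0.0636 n,
    A_n = (1 + R_eff) / (1 - R_eff). Returns 1 for matched media (n = 1).
    """
    n = float(refractive_index)
    if abs(n - 1.0) < 1e-12:
        return 1.0
    r_eff = -1.4399 / n ** 2 + 0.7099 / n + 0.6681 + 0.0636 * n
    return (1.0 + r_eff) / (1.0 - r_eff)


# reference P1 mass matrix on a tet, scaled by volume at assembly:
# V/10 on the diagonal, V/20 off-diagonal
_MASS_REF = (np.ones((4, 4)) + np.eye(4)) / 20.0
_FACE_MASS_REF = (np.ones((3, 3)) + np.eye(3)) / 12.0


def _shape_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Per-tet volumes and gradients of the 4 barycentric shape functions."""
    p = nodes[tets]                       # (t, 4, 3)
    J = p[:, 1:] - p[:, :1]               # rows: edge vectors
    vol = np.linalg.det(J) / 6.0
    Jinv = np.linalg.inv(J)
    G = np.empty((len(tets), 4, 3))
    G[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    G[:, 0, :] = -G[:, 1:, :].sum(axis=1)
    return vol, G


def _boundary_face_regions(mesh: TetMesh) -> np.ndarray:
    """Region label of the tet owning each boundary face (same order)."""
    sf, owners = _all_faces(mesh.tets)
    order = np.lexsort(sf.T[::-1])
    sf, owners = sf[order], owners[order]
    eq_prev = np.r_[False, np.all(sf[1:] == sf[:-1], axis=1)]
    eq_next = np.r_[eq_prev[1:], False]
    single = ~(eq_prev | eq_next)
    key = {tuple(f): mesh.region[t] for f, t in zip(sf[single], owners[single])}
    return np.array([key[tuple(sorted(f))] for f in mesh.boundary_faces],
                    dtype=np.int64)


def assemble_diffusion_system(mesh: TetMesh, optics: dict,
                              ) -> tuple[csr_matrix, csr_matrix]:
    """Assemble the diffusion operator K and mass matrix M.

    Parameters
    ----------
    mesh : TetMesh
    optics : dict
        Maps every region label present in the mesh to an
        :class:`~bregtomo.phantoms.OpticalProperties` for the wavelength
        channel being assembled.

    Returns
    -------
    K, M : scipy.sparse.csr_matrix
        K is symmetric positive definite (diffusion + absorption + Robin
        boundary terms); M maps a nodal source density to its load vector.
    """
    labels = np.unique(mesh.region)
    missing = set(labels) - set(optics)
    if missing:
        raise ValueError(f"no optical properties for region(s) {sorted(missing)}")
    D = np.empty(mesh.n_tets)
    mu_a = np.empty(mesh.n_tets)
    for lab in labels:
        sel = mesh.region == lab
        D[sel] = optics[lab].diffusion_coefficient
        mu_a[sel] = optics[lab].mu_a

    vol, G = _shape_gradients(mesh.nodes, mesh.tets)
    if np.any(vol <= 0):
        raise ValueError("mesh contains inverted tets")
    # element matrices, vectorized over tets
    k_diff = (D * vol)[:, None, None] * np.einsum("tid,tjd->tij", G, G)
    m_el = vol[:, None, None] * _MASS_REF[None]
    k_el = k_diff + mu_a[:, None, None] * m_el

    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    n = mesh.n_nodes
    K = coo_matrix((k_el.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()
    M = coo_matrix((m_el.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()

    # Robin boundary term: (1/(2 A_n)) * face mass matrix per boundary face
    bf = mesh.boundary_faces
    if len(bf):
        face_reg = _boundary_face_regions(mesh)
        alpha = np.array(
            [1.0 / (2.0 * mismatch_factor(optics[r].refractive_index))
             for r in face_reg])
        p = mesh.nodes[bf]
        area = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
        fb = (alpha * area)[:, None, None] * _FACE_MASS_REF[None]
        frows = np.repeat(bf, 3, axis=1).reshape(-1)
        fcols = np.tile(bf, (1, 3)).reshape(-1)
        K = K + coo_matrix((fb.reshape(-1), (frows, fcols)),
                           shape=(n, n)).tocsr()
    return K, M


class DiffusionSolver:
    """Factorized diffusion system for repeated forward/adjoint solves."""

    def __init__(self, mesh: TetMesh, optics: dict):
        self.mesh = mesh
        self.K, self.M = assemble_diffusion_system(mesh, optics)
        self._lu = splu(self.K.tocsc())

    def solve(self, load: np.ndarray) -> np.ndarray:
        """Fluence for a given load vector (supports multiple columns)."""
        return self._lu.solve(np.asarray(load, dtype=float))

    def fluence_from_density(self, q: np.ndarray) -> np.ndarray:
        """Fluence for a nodal source density q (load = M q)."""
        return self._lu.solve(self.M @ q)

    def point_source_fluence(self, node: int, power: float = 1.0) -> np.ndarray:
        """Fluence for a point source of given power at a mesh node."""
        b = np.zeros(self.mesh.n_nodes)
        b[node] = power
        return self._lu.solve(b)


def greens_function_infinite(r, mu_a: float, mu_s_prime: float):
    """Infinite-medium diffusion Green's function for a unit point source.

    phi(r) = exp(-mu_eff r) / (4 pi D r), mu_eff = sqrt(mu_a / D).
    Used as the analytic oracle for FEM verification far from boundaries.
    """
    D = 1.0 / (3.0 * (mu_a + mu_s_prime))
    mu_eff = np.sqrt(mu_a / D)
    r = np.asarray(r, dtype=float)
    return np.exp(-mu_eff * r) / (4.0 * np.pi * D * r)
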