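"""Boundary detectors, sensitivity matrices and simulated measurements.

The sensitivity (system) matrix A is the discrete linear map from the
nodal source density S to the boundary measurements Phi, giving the
model A S = Phi that the inverse solvers invert. Two constructions are
supported:

``emission-only``
    Bioluminescence / Cerenkov style: A[(e, d), j] is the fluence at
    detector node d due to a unit source density at node j, solved with
    emission-channel optics; rows are identical across excitations.

``excitation-weighted``
    Fluorescence style (Born approximation): each row is additionally
    weighted by the excitation fluence phi_x^(e)(j) produced by the
    point excitation source e with excitation-channel optics.

Rows are computed by one adjoint solve per unique detector node (K is
symmetric, so the adjoint and forward constructions agree to solver
precision; ``via="forward"`` exposes the per-column route for
verification on small problems).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import DiffusionSolver
from .mesh import TetMesh
from .phantoms import Phantom


@dataclass
class DetectorSet:
    """Excitation points and their per-excitation detector node groups."""

    excitation_nodes: np.ndarray        # boundary node index per excitation
    excitation_positions: np.ndarray    # (n_exc, 3) mm
    detector_nodes: np.ndarray          # union of all group members, sorted
    groups: list                        # per excitation: array of node ids


@dataclass
class SensitivityMatrix:
    """Dense m x n sensitivity matrix with row/column metadata.

    row_meta[i] = (excitation id, detector node); col_nodes[j] is the
    mesh node index of candidate source column j.
    """

    entries: np.ndarray
    row_meta: list
    col_nodes: np.ndarray
    col_coords: np.ndarray
    n_mesh_nodes: int
    channel: str

    @property
    def shape(self):
        return self.entries.shape

    def embed(self, s_cols: np.ndarray) -> np.ndarray:
        """Re-embed a candidate-column vector into the full nodal vector."""
        full = np.zeros(self.n_mesh_nodes)
        full[self.col_nodes] = s_cols
        return full

    def restrict_to_nodes(self, node_mask: np.ndarray) -> "SensitivityMatrix":
        keep = node_mask[self.col_nodes]
        if not keep.any():
            raise ValueError("restriction removes every candidate column")
        return SensitivityMatrix(
            entries=self.entries[:, keep], row_meta=self.row_meta,
            col_nodes=self.col_nodes[keep], col_coords=self.col_coords[keep],
            n_mesh_nodes=self.n_mesh_nodes, channel=self.channel)


@dataclass
class MeasurementSet:
    """Boundary flux vector Phi in the row order of its SensitivityMatrix."""

    values: np.ndarray
    noise_model: str = "noiseless"
    seed: int | None = None


def _lateral_boundary(mesh: TetMesh, tol: float = 1e-6):
    """Boundary nodes on the curved (maximal-radius) cylinder surface."""
    bn = mesh.boundary_nodes()
    r = np.linalg.norm(mesh.nodes[bn, :2], axis=1)
    return bn[r >= r.max() - tol - 1e-12 * r.max()]


def _circ_dist(a, b):
    d = np.abs(a - b) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def place_detectors(mesh: TetMesh, n_excitations: int = 4,
                    fov_degrees: float = 160.0,
                    z_band: float | None = None) -> DetectorSet:
    """Equally spaced excitation points with opposite-side detector arcs.

    Excitation sources sit on the boundary circle at z = 0 at angles
    2*pi*e/n_excitations. The detector group of the excitation at angle
    theta is every lateral boundary node whose angular coordinate lies
    within fov/2 of theta + 180 degrees and whose |z| <= z_band
    (default: the full cylinder height).
    """
    if n_excitations < 1:
        raise ValueError("n_excitations must be >= 1")
    if not (0 < fov_degrees <= 360):
        raise ValueError("fov_degrees must be in (0, 360]")
    lat = _lateral_boundary(mesh)
    if z_band is not None:
        lat = lat[np.abs(mesh.nodes[lat, 2]) <= z_band + 1e-12]
    if lat.size == 0:
        raise ValueError("no lateral boundary nodes within the z band")
    ang = np.arctan2(mesh.nodes[lat, 1], mesh.nodes[lat, 0])
    R = np.linalg.norm(mesh.nodes[lat, :2], axis=1).max()
    half_fov = np.deg2rad(fov_degrees) / 2.0
    exc_nodes, exc_pos, groups = [], [], []
    for e in range(n_excitations):
        theta = 2.0 * np.pi * e / n_excitations
        target = np.array([R * np.cos(theta), R * np.sin(theta), 0.0])
        bn = mesh.boundary_nodes()
        exc = bn[int(np.argmin(np.linalg.norm(mesh.nodes[bn] - target, axis=1)))]
        sel = _circ_dist(ang, theta + np.pi) <= half_fov + 1e-12
        if not sel.any():
            raise ValueError(
                f"excitation {e}: empty detector group; increase "
                "fov_degrees or refine the mesh")
        exc_nodes.append(exc)
        exc_pos.append(target)
        groups.append(lat[sel])
    return DetectorSet(
        excitation_nodes=np.array(exc_nodes),
        excitation_positions=np.array(exc_pos),
        detector_nodes=np.unique(np.concatenate(groups)),
        groups=groups)


def build_sensitivity_matrix(phantom: Phantom, detectors: DetectorSet,
                             channel: str = "emission-only",
                             candidate_nodes: np.ndarray | None = None,
                             via: str = "adjoint") -> SensitivityMatrix:
    """Assemble the sensitivity matrix A of the phantom + detector layout.

    Parameters
    ----------
    channel : {"emission-only", "excitation-weighted"}
    candidate_nodes : array of node indices, optional
        Candidate source columns; defaults to all interior nodes.
    via : {"adjoint", "forward"}
        "adjoint" does one solve per unique detector node; "forward" one
        solve per candidate column (slow; for verification).
    """
    mesh = phantom.mesh
    if candidate_nodes is None:
        candidate_nodes = mesh.interior_nodes()
    candidate_nodes = np.asarray(candidate_nodes, dtype=np.int64)
    em = DiffusionSolver(mesh, phantom.optics("emission"))

    det_nodes = detectors.detector_nodes
    if via == "adjoint":
        rhs = np.zeros((mesh.n_nodes, len(det_nodes)))
        rhs[det_nodes, np.arange(len(det_nodes))] = 1.0
        gcols = em.solve(rhs)                       # K^-1 e_d per column
        green = (em.M @ gcols).T[:, candidate_nodes]  # rows: detectors
    elif via == "forward":
        rows = []
        for j in candidate_nodes:
            q = np.zeros(mesh.n_nodes)
            q[j] = 1.0
            rows.append(em.fluence_from_density(q)[det_nodes])
        green = np.array(rows).T
    else:
        raise ValueError("via must be 'adjoint' or 'forward'")

    det_row = {d: i for i, d in enumerate(det_nodes)}
    if channel == "excitation-weighted":
        ex = DiffusionSolver(mesh, phantom.optics("excitation"))
        rhs = np.zeros((mesh.n_nodes, len(detectors.excitation_nodes)))
        rhs[detectors.excitation_nodes,
            np.arange(rhs.shape[1])] = 1.0
        phi_x = ex.solve(rhs)[candidate_nodes]      # (n_cand, n_exc)
    elif channel != "emission-only":
        raise ValueError(
            "channel must be 'emission-only' or 'excitation-weighted'")

    blocks, row_meta = [], []
    for e, group in enumerate(detectors.groups):
        block = green[[det_row[d] for d in group]]
        if channel == "excitation-weighted":
            block = block * phi_x[:, e][None, :]
        blocks.append(block)
        row_meta.extend((e, int(d)) for d in group)
    A = np.vstack(blocks)
    return SensitivityMatrix(
        entries=A, row_meta=row_meta, col_nodes=candidate_nodes,
        col_coords=mesh.nodes[candidate_nodes], n_mesh_nodes=mesh.n_nodes,
        channel=channel)


def simulate_measurements(A: SensitivityMatrix, s_true: np.ndarray,
                          noise_sigma_rel: float = 0.0,
                          seed: int | None = None) -> MeasurementSet:
    """Phi = A S_true + Gaussian noise of std noise_sigma_rel * max|Phi|.

    ``s_true`` may be a full nodal vector (restricted to the candidate
    columns automatically) or already column-sized.
    """
    s_true = np.asarray(s_true, dtype=float)
    if s_true.shape[0] == A.n_mesh_nodes:
        s_cols = s_true[A.col_nodes]
    elif s_true.shape[0] == A.shape[1]:
        s_cols = s_true
    else:
        raise ValueError(
            f"source vector length {s_true.shape[0]} matches neither mesh "
            f"({A.n_mesh_nodes}) nor candidate columns ({A.shape[1]})")
    if noise_sigma_rel < 0:
        raise ValueError("noise_sigma_rel must be >= 0")
    phi = A.entries @ s_cols
    if noise_sigma_rel > 0:
        rng = np.random.default_rng(seed)
        phi = phi + rng.normal(
            0.0, noise_sigma_rel * np.abs(phi).max(), size=phi.shape)
        model = f"gaussian(rel_sigma={noise_sigma_rel})"
    else:
        model = "noiseless"
    return MeasurementSet(values=phi, noise_model=model, seed=seed)


def restrict_psr(A: SensitivityMatrix, box) -> SensitivityMatrix:
    """Keep only candidate columns inside a permissible source region.

    ``box`` is three closed intervals ((x0, x1), (y0, y1), (z0, z1)) in
    mm. Restricting the candidate space shrinks the system matrix and
    improves the conditioning of the inverse problem; reconstructions
    re-embed to the full mesh with zeros outside the box via ``embed``.
    """
    (x0, x1), (y0, y1), (z0, z1) = box
    c = A.col_coords
    keep = ((c[:, 0] >= x0) & (c[:, 0] <= x1) &
            (c[:, 1] >= y0) & (c[:, 1] <= y1) &
            (c[:, 2] >= z0) & (c[:, 2] <= z1))
    if not keep.any():
        raise ValueError(f"permissible source region {box} contains no "
                         "candidate node")
    return A.restrict_to_nodes(
        np.isin(np.arange(A.n_mesh_nodes), A.col_nodes[keep]))
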