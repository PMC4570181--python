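"""Digital phantoms: labeled meshes, tissue optics and ground-truth sources.

A :class:`Phantom` couples a :class:`~bregtomo.mesh.TetMesh` with per-region
optical properties (per wavelength channel) and a ground-truth nodal source
vector. The packaged ``cylinder_4tissue`` preset regenerates the
heterogeneous cylindrical phantom used throughout the tests: a 20 mm
diameter / 20 mm height cylinder with muscle background and lung, bone and
heart inclusions, and two spherical sources S1 = (6, 5, 0) and
S2 = (6, -5, 0) snapped to mesh nodes.

The exact inclusion geometry of that phantom's cross-section is a
documented qualitative layout (see ``CYLINDER_4TISSUE_LAYOUT``); source
localization accuracy depends on the printed source positions, not on
where the inclusions sit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .mesh import TetMesh, generate_cylinder_mesh

#: region labels of the 4-tissue cylinder preset
MUSCLE, LUNGS, BONE, HEART = 1, 2, 3, 4
REGION_NAMES = {MUSCLE: "muscle", LUNGS: "lungs", BONE: "bone", HEART: "heart"}

PRESETS = ("cylinder_4tissue", "mouse_tissues", "homogeneous")


@dataclass(frozen=True)
class OpticalProperties:
    """Tissue optics at one wavelength.

    mu_a and mu_s_prime are the absorption and reduced scattering
    coefficients in mm^-1; refractive_index defaults to 1.37 (soft
    tissue). The diffusion coefficient is D = 1 / (3 (mu_a + mu_s')).
    """

    mu_a: float
    mu_s_prime: float
    refractive_index: float = 1.37

    def __post_init__(self):
        if self.mu_a <= 0:
            raise ValueError("mu_a must be positive")
        if self.mu_s_prime <= 0:
            raise ValueError("mu_s_prime must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")

    @property
    def diffusion_coefficient(self) -> float:
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))


@dataclass(frozen=True)
class SourceSpec:
    """A spherical source: center (mm), radius (mm), density (power/volume).

    ``snapped_center`` is filled in by :func:`place_sources`: the center is
    moved to the nearest mesh node so that ground truth lives on the mesh.
    """

    center: tuple
    radius: float = 1.0
    density: float = 1.0
    snapped_center: tuple | None = None


@dataclass(frozen=True)
class Inclusion:
    """Analytic inclusion: an axis-aligned cylinder or ellipsoid.

    kind="cylinder": ``radii=(r, half_height)``, axis along z.
    kind="ellipsoid": ``radii=(a, b, c)`` semi-axes.
    """

    kind: str
    center: tuple
    radii: tuple
    label: int

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = pts - np.asarray(self.center)
        if self.kind == "cylinder":
            r, hh = self.radii
            return (d[:, 0] ** 2 + d[:, 1] ** 2 <= r ** 2) & (
                np.abs(d[:, 2]) <= hh)
        if self.kind == "ellipsoid":
            a, b, c = self.radii
            return (d[:, 0] / a) ** 2 + (d[:, 1] / b) ** 2 + (
                d[:, 2] / c) ** 2 <= 1.0
        raise ValueError(f"unknown inclusion kind {self.kind!r}")


# Qualitative reconstruction of the 4-tissue cross-section: two lung
# cylinders, a central bone column, a heart ellipsoid, muscle elsewhere.
CYLINDER_4TISSUE_LAYOUT = (
    Inclusion("cylinder", (-3.5, 3.5, 0.0), (2.0, 6.0), LUNGS),
    Inclusion("cylinder", (-3.5, -3.5, 0.0), (2.0, 6.0), LUNGS),
    Inclusion("cylinder", (0.5, 0.0, 0.0), (1.3, 8.0), BONE),
    Inclusion("ellipsoid", (3.5, 0.0, 1.0), (1.8, 1.8, 2.5), HEART),
)


@dataclass
class Phantom:
    """Labeled mesh + optics per channel + ground-truth sources."""

    mesh: TetMesh
    optics_by_region: dict  # channel name -> {label: OpticalProperties}
    true_sources: list = field(default_factory=list)
    true_source_vector: np.ndarray = None  # type: ignore[assignment]
    name: str = "phantom"

    def __post_init__(self):
        if self.true_source_vector is None:
            self.true_source_vector = np.zeros(self.mesh.n_nodes)
        for channel, table in self.optics_by_region.items():
            missing = set(np.unique(self.mesh.region)) - set(table)
            if missing:
                raise ValueError(
                    f"channel {channel!r} lacks optics for regions {sorted(missing)}")

    def optics(self, channel: str) -> dict:
        try:
            return self.optics_by_region[channel]
        except KeyError:
            raise KeyError(
                f"no optics for channel {channel!r}; available: "
                f"{sorted(self.optics_by_region)}") from None

    def true_centers(self) -> np.ndarray:
        """Snapped ground-truth source centers, (k, 3)."""
        return np.array([s.snapped_center for s in self.true_sources])


def assign_regions(mesh: TetMesh, layout) -> TetMesh:
    """Label tets by analytic inclusions; later layout entries win ties.

    Every tet whose centroid falls inside an inclusion takes that
    inclusion's label; all remaining tets take the background label
    ``MUSCLE`` (1). Node and tet arrays are shared, not copied.
    """
    cent = mesh.tet_centroids()
    region = np.full(mesh.n_tets, MUSCLE, dtype=np.int64)
    for inc in layout:
        inside = inc.contains(cent)
        if not inside.any():
            warnings.warn(
                f"inclusion {inc.kind} at {inc.center} contains no tet "
                "centroid", stacklevel=2)
        region[inside] = inc.label
    return TetMesh(nodes=mesh.nodes, tets=mesh.tets, region=region,
                   boundary_faces=mesh.boundary_faces)


# backwards-friendly alias used in the docs
assign_cylinder_regions = assign_regions


def place_sources(mesh: TetMesh, sources) -> tuple[np.ndarray, list]:
    """Build the ground-truth nodal source vector.

    Each source center is snapped to the nearest node (ties broken by
    lowest index). radius = 0 assigns ``density`` to that single node;
    radius > 0 assigns ``density`` to every node within ``radius`` of the
    snapped center. Returns (vector, sources with snapped_center filled).
    """
    vec = np.zeros(mesh.n_nodes)
    snapped = []
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    for s in sources:
        c = np.asarray(s.center, dtype=float)
        if np.any(c < lo - 1e-9) or np.any(c > hi + 1e-9):
            raise ValueError(
                f"source center {tuple(c)} outside mesh bounding box "
                f"[{lo}, {hi}]")
        d = np.linalg.norm(mesh.nodes - c, axis=1)
        nearest = int(np.argmin(d))  # argmin takes the lowest index on ties
        center = mesh.nodes[nearest]
        if s.radius > 0:
            hit = np.linalg.norm(mesh.nodes - center, axis=1) <= s.radius
            vec[hit] = s.density
        else:
            vec[nearest] = s.density
        snapped.append(SourceSpec(center=tuple(s.center), radius=s.radius,
                                  density=s.density,
                                  snapped_center=tuple(center)))
    return vec, snapped


def support_cluster_count(mesh: TetMesh, vec: np.ndarray) -> int:
    """Number of connected node clusters in the support of ``vec``."""
    sup = np.nonzero(vec)[0]
    if sup.size == 0:
        return 0
    adj = mesh.node_adjacency()[np.ix_(sup, sup)]
    ncomp, _ = connected_components(adj, directed=False)
    return ncomp


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("bregtomo.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def cylinder_4tissue_optics() -> dict:
    """Excitation/emission optics tables of the 4-tissue cylinder."""
    df = _load_table("cylinder_4tissue_optics.csv")
    ex, em = {}, {}
    for row in df.itertuples():
        ex[int(row.label)] = OpticalProperties(row.mu_ax, row.mu_sx_prime)
        em[int(row.label)] = OpticalProperties(row.mu_am, row.mu_sm_prime)
    return {"excitation": ex, "emission": em}


def mouse_tissue_optics() -> dict:
    """Single-wavelength mouse tissue optics keyed by tissue name."""
    df = _load_table("mouse_tissue_optics.csv")
    return {row.tissue: OpticalProperties(row.mu_a, row.mu_s_prime)
            for row in df.itertuples()}


def make_phantom(preset_name: str, resolution: float = 1.0, seed: int = 0,
                 *, mesh: TetMesh | None = None,
                 tissue_by_label: dict | None = None,
                 optics: OpticalProperties | None = None,
                 sources=None, source_radius: float = 1.0,
                 source_density: float = 1.0) -> Phantom:
    """Build a named phantom preset.

    Presets
    -------
    ``cylinder_4tissue``
        The two-source heterogeneous cylinder: 20 mm diameter and height,
        4 tissue regions with the packaged excitation/emission optics,
        sources at (6, 5, 0) and (6, -5, 0) of radius ``source_radius``.
    ``mouse_tissues``
        Attaches the packaged mouse tissue optics (single channel,
        "emission") to a user-supplied labeled ``mesh``;
        ``tissue_by_label`` maps each region label to a tissue name.
    ``homogeneous``
        Single-region cylinder with user ``optics`` (default
        mu_a = 0.01, mu_s' = 1.0 mm^-1).
    """
    if preset_name == "cylinder_4tissue":
        m = generate_cylinder_mesh(10.0, 20.0, resolution, seed)
        m = assign_regions(m, CYLINDER_4TISSUE_LAYOUT)
        if sources is None:
            sources = [SourceSpec((6.0, 5.0, 0.0), source_radius, source_density),
                       SourceSpec((6.0, -5.0, 0.0), source_radius, source_density)]
        vec, snapped = place_sources(m, sources)
        return Phantom(mesh=m, optics_by_region=cylinder_4tissue_optics(),
                       true_sources=snapped, true_source_vector=vec,
                       name=preset_name)
    if preset_name == "mouse_tissues":
        if mesh is None or tissue_by_label is None:
            raise ValueError(
                "preset 'mouse_tissues' requires a labeled `mesh` and a "
                "`tissue_by_label` mapping (no in-vivo dataset is shipped)")
        table = mouse_tissue_optics()
        try:
            em = {int(lab): table[t] for lab, t in tissue_by_label.items()}
        except KeyError as e:
            raise ValueError(
                f"unknown tissue {e.args[0]!r}; known: {sorted(table)}") from None
        vec, snapped = ((np.zeros(mesh.n_nodes), []) if sources is None
                        else place_sources(mesh, sources))
        return Phantom(mesh=mesh, optics_by_region={"emission": em},
                       true_sources=snapped, true_source_vector=vec,
                       name=preset_name)
    if preset_name == "homogeneous":
        m = mesh if mesh is not None else generate_cylinder_mesh(
            10.0, 20.0, resolution, seed)
        op = optics if optics is not None else OpticalProperties(0.01, 1.0)
        em = {int(lab): op for lab in np.unique(m.region)}
        vec, snapped = ((np.zeros(m.n_nodes), []) if sources is None
                        else place_sources(m, sources))
        return Phantom(mesh=m, optics_by_region={"emission": em},
                       true_sources=snapped, true_source_vector=vec,
                       name=preset_name)
    raise ValueError(
        f"unknown preset {preset_name!r}; available presets: {PRESETS}")
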