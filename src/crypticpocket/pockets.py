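"""Grid-based cavity detection and volumetrics.

A regular grid (default 0.5 A spacing, registered so the including-sphere
center lies on a grid point) spans the including sphere's bounding box. A
grid point is "free" iff it lies inside the including sphere, outside every
excluding sphere, and farther than (vdW radius + probe) from every atom
center. The pocket is the contiguous component of free points reachable from
a seed, where contiguity means "within the contiguous cutoff" (default 4 A);
its volume is the free-point count times spacing^3. Van der Waals radii
default to the Bondi set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

#: Bondi van der Waals radii, A
BONDI_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


class UnknownElementError(KeyError):
    pass


def vdw_radius(element: str, table=None) -> float:
    table = BONDI_RADII if table is None else table
    key = element.strip().upper()
    if key not in table:
        raise UnknownElementError(
            f"no van der Waals radius for element {element!r}")
    return table[key]


@dataclass
class PocketDefinition:
    """Geometric definition of the region where a pocket may lie."""

    center: np.ndarray
    including_radius: float = 6.0
    excluding_spheres: Sequence = field(default_factory=list)  # (center, radius)
    grid_spacing: float = 0.5
    contiguous_cutoff: float = 4.0
    radii_table: Optional[dict] = None
    probe_radius: float = 0.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.including_radius <= 0 or self.grid_spacing <= 0:
            raise ValueError("including radius and spacing must be positive")
        if self.grid_spacing > self.including_radius:
            raise ValueError("grid spacing exceeds the including radius")
        if self.contiguous_cutoff < self.grid_spacing:
            raise ValueError("contiguous cutoff must be at least the spacing")
        for _, radius in self.excluding_spheres:
            if radius <= 0:
                raise ValueError("excluding-sphere radii must be positive")


def _grid_points(center, radius, spacing) -> np.ndarray:
    """Grid spanning the sphere's bounding box, registered to the center."""
    n = int(np.ceil(radius / spacing))
    axis = np.arange(-n, n + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1) + center


def _occupied_mask(points, coordinates, elements, radii_table, probe):
    """True where a point lies within (vdW + probe) of any atom; computed per
    element so heterogeneous radii stay exact."""
    occupied = np.zeros(len(points), dtype=bool)
    coordinates = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    if len(coordinates) == 0:
        return occupied
    elements = np.asarray([e.strip().upper() for e in elements])
    for element in np.unique(elements):
        radius = vdw_radius(element, radii_table)
        tree = cKDTree(coordinates[elements == element])
        dist, _ = tree.query(points, k=1)
        occupied |= dist <= radius + probe
    return occupied


def free_grid_points(coordinates, elements,
                     definition: PocketDefinition) -> np.ndarray:
    """All free grid points (N, 3) for a single structure frame.

    ``coordinates``/``elements`` may be empty, in which case every in-sphere
    point is free and the result integrates to the including-sphere volume.
    """
    points = _grid_points(definition.center, definition.including_radius,
                          definition.grid_spacing)
    inside = (np.sum((points - definition.center) ** 2, axis=1)
              <= definition.including_radius ** 2)
    points = points[inside]
    keep = np.ones(len(points), dtype=bool)
    for ex_center, ex_radius in definition.excluding_spheres:
        ex_center = np.asarray(ex_center, dtype=float)
        keep &= np.sum((points - ex_center) ** 2, axis=1) > ex_radius ** 2
    points = points[keep]
    occupied = _occupied_mask(points, coordinates, elements,
                              definition.radii_table, definition.probe_radius)
    return points[~occupied]


def contiguous_component(free_points: np.ndarray, seed,
                         cutoff: float) -> np.ndarray:
    """Contiguous pocket component: reflexive-transitive closure of "within
    cutoff" starting from the free points within cutoff of the seed.

    Order-independent by construction (connected components of the distance
    graph). An empty result (no free point within cutoff of the seed) is not
    an error.
    """
    free_points = np.asarray(free_points, dtype=float).reshape(-1, 3)
    seed = np.asarray(seed, dtype=float)
    if len(free_points) == 0:
        return free_points
    tree = cKDTree(free_points)
    start = tree.query_ball_point(seed, cutoff)
    if not start:
        return np.empty((0, 3))
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    n = len(free_points)
    if len(pairs):
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        graph = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                           shape=(n, n))
    else:
        graph = csr_matrix((n, n), dtype=np.int8)
    _, labels = connected_components(graph, directed=False)
    component_ids = np.unique(labels[np.asarray(start, dtype=int)])
    return free_points[np.isin(labels, component_ids)]


def pocket_volume(component: np.ndarray, spacing: float) -> float:
    """Volume (A^3) of a grid component: point count x spacing^3, exactly."""
    return len(np.asarray(component).reshape(-1, 3)) * float(spacing) ** 3


def measure_pocket(coordinates, elements, definition: PocketDefinition,
                   seed=None):
    """Free points -> contiguous component from the seed -> volume.

    The default seed is the including-sphere center, falling back to the
    nearest free point within the contiguous cutoff. Returns
    (component points, volume A^3).
    """
    free = free_grid_points(coordinates, elements, definition)
    if seed is None:
        seed = definition.center
    component = contiguous_component(free, seed, definition.contiguous_cutoff)
    return component, pocket_volume(component, definition.grid_spacing)


def molecular_volume(coordinates, elements, spacing: float = 0.2,
                     radii_table=None) -> float:
    """Van der Waals volume (A^3) of a molecule: grid occupancy of the union
    of atom spheres over the molecule's padded bounding box."""
    coordinates = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    if len(coordinates) == 0:
        raise ValueError("molecule has no atoms")
    radii = np.array([vdw_radius(e, radii_table) for e in elements])
    pad = radii.max() + spacing
    lo = coordinates.min(axis=0) - pad
    hi = coordinates.max(axis=0) + pad
    # register the grid on the first atom's center so an isolated sphere is
    # sampled symmetrically (unbiased occupancy at its surface)
    origin = coordinates[0]
    axes = [origin[d] - np.arange(int(np.ceil((origin[d] - lo[d]) / spacing)),
                                  -int(np.ceil((hi[d] - origin[d]) / spacing))
                                  - 1, -1) * spacing
            for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    occupied = _occupied_mask(points, coordinates, elements, radii_table, 0.0)
    return float(np.count_nonzero(occupied)) * spacing ** 3


def lining_residues(component: np.ndarray, coordinates, atoms: pd.DataFrame,
                    lining_cutoff: float = 4.5) -> pd.DataFrame:
    """Residues with at least one heavy atom within ``lining_cutoff`` of the
    component, each with its minimum atom-to-component distance (A).

    Returns a DataFrame (chain, res_id, res_name, min_distance) sorted by
    chain then residue number.
    """
    component = np.asarray(component, dtype=float).reshape(-1, 3)
    if len(component) == 0:
        raise ValueError("empty pocket component")
    coordinates = np.asarray(coordinates, dtype=float)
    heavy = atoms["is_heavy"].to_numpy()
    tree = cKDTree(component)
    dist, _ = tree.query(coordinates[heavy], k=1)
    sub = atoms.loc[heavy, ["chain", "res_id", "res_name"]].copy()
    sub["min_distance"] = dist
    sub = sub[sub["min_distance"] <= lining_cutoff]
    if sub.empty:
        return pd.DataFrame(columns=["chain", "res_id", "res_name",
                                     "min_distance"])
    out = (sub.groupby(["chain", "res_id", "res_name"], as_index=False)
              ["min_distance"].min())
    return out.sort_values(["chain", "res_id"]).reset_index(drop=True)


def lining_atoms(component: np.ndarray, coordinates, atoms: pd.DataFrame,
                 lining_cutoff: float = 4.5) -> pd.DataFrame:
    """Heavy atoms within ``lining_cutoff`` of the component, with distances."""
    component = np.asarray(component, dtype=float).reshape(-1, 3)
    if len(component) == 0:
        raise ValueError("empty pocket component")
    heavy_idx = np.flatnonzero(atoms["is_heavy"].to_numpy())
    tree = cKDTree(component)
    dist, _ = tree.query(np.asarray(coordinates, dtype=float)[heavy_idx], k=1)
    mask = dist <= lining_cutoff
    out = atoms.iloc[heavy_idx[mask]].copy()
    out["min_distance"] = dist[mask]
    return out.reset_index(drop=True)


def pocket_centroid_distance(component_a: np.ndarray,
                             component_b: np.ndarray) -> float:
    """Euclidean distance (A) between the unweighted point centroids."""
    a = np.asarray(component_a, dtype=float).reshape(-1, 3)
    b = np.asarray(component_b, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both components must be non-empty")
    return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))


def write_component_pdb(component: np.ndarray, path) -> None:
    """Write pocket free points as HETATM pseudo-atoms for visualization."""
    component = np.asarray(component, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(component, start=1):
            fh.write(f"HETATM{i % 100000:5d}  PKT PKT X{(i - 1) % 10000:4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           X\n")
        fh.write("END\n")
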