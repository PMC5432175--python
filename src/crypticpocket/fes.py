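"""Free-energy surface in the PC1/PC2 subspace and watershed clustering.

The sampled probability density over the first two principal components is
Boltzmann-inverted, G = -kT ln(p / p_max), so the global minimum sits at
G = 0 and empty bins carry a finite sentinel (max finite G + 3 kT) rather
than NaN. Basins are found by flooding bins in order of increasing G: a bin
with no already-assigned neighbour seeds a new basin (it is a local minimum
under the processing order), otherwise it joins the basin of its lowest-G
assigned 8-neighbour. Ties are broken by row-major bin index, which makes
the partition deterministic and independent of frame order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .pca import ProjectionSet

#: Boltzmann constant in kcal/(mol K)
BOLTZMANN_KCAL = 0.0019872041


def thermal_energy(temperature: float = 300.0) -> float:
    """kT in kcal/mol at the given temperature (K). 0.5962 at 300 K."""
    return BOLTZMANN_KCAL * temperature


@dataclass
class FreeEnergySurface:
    """Binned PC1/PC2 probability density and its Boltzmann inversion."""

    edges1: np.ndarray          # B1+1 monotone bin edges, A
    edges2: np.ndarray          # B2+1 monotone bin edges, A
    density: np.ndarray         # (B1, B2), sums to 1
    g: Optional[np.ndarray] = None   # (B1, B2), kcal/mol; sentinel in empty bins
    kT: Optional[float] = None       # kcal/mol
    n_frames: int = 0

    @property
    def shape(self):
        return self.density.shape

    @property
    def empty_mask(self) -> np.ndarray:
        return self.density <= 0.0

    @property
    def sentinel(self) -> float:
        if self.g is None:
            raise ValueError("surface has no free energy yet")
        finite = self.g[~self.empty_mask]
        return float(finite.max() + 3.0 * self.kT)


@dataclass
class ClusterPartition:
    """Watershed basins: bin labels (0 = unassigned/empty), per-frame labels,
    populations (fraction of assigned frames, sum 1), per-basin minimum and
    medoid representative frame."""

    bin_labels: np.ndarray            # (B1, B2) ints, 0 = unassigned
    frame_labels: np.ndarray          # (F,) ints
    populations: dict                 # basin id -> fraction
    minima: dict                      # basin id -> ((i, j), G)
    representatives: dict = None      # basin id -> frame id

    @property
    def n_basins(self) -> int:
        return len(self.populations)

    def summary(self) -> list:
        rows = []
        for basin in sorted(self.populations):
            row = {
                "basin": int(basin),
                "population": float(self.populations[basin]),
                "minimum_bin": [int(v) for v in self.minima[basin][0]],
                "minimum_g": float(self.minima[basin][1]),
            }
            if self.representatives is not None:
                row["representative_frame"] = int(self.representatives[basin])
            rows.append(row)
        return rows


def _padded_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 0.0:
        lo, hi = lo - 0.5, hi + 0.5
        return np.linspace(lo, hi, n_bins + 1)
    width = (hi - lo) / max(n_bins - 2, 1)
    return np.linspace(lo - width, hi + width, n_bins + 1)


def density_map(projections: ProjectionSet, bins=(100, 100),
                smooth_sigma: float = 2.0) -> FreeEnergySurface:
    """2D histogram of the PC1/PC2 projections, normalized to sum 1.

    Edges span the data range padded by one bin on each side so no frame sits
    on the outer boundary. A mild Gaussian kernel (``smooth_sigma`` in bin
    units, 0 disables it) regularizes the finite-sample histogram so that
    shot noise does not carve spurious minima into the inverted surface; it
    never zeroes an occupied bin, so every frame stays assignable.
    """
    if projections.n_frames == 0:
        raise ValueError("empty projection set")
    if projections.k < 2:
        raise ValueError("density map needs at least 2 projection components")
    if np.isscalar(bins):
        bins = (int(bins), int(bins))
    b1, b2 = bins
    if b1 < 2 or b2 < 2:
        raise ValueError("need at least 2 bins per axis")
    pc1 = projections.projections[:, 0]
    pc2 = projections.projections[:, 1]
    edges1 = _padded_edges(pc1, b1)
    edges2 = _padded_edges(pc2, b2)
    hist, _, _ = np.histogram2d(pc1, pc2, bins=[edges1, edges2])
    if np.count_nonzero(hist) == 1:
        warnings.warn("degenerate density: all frames fall in a single bin; "
                      "watershed will return one basin")
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter
        hist = gaussian_filter(hist, sigma=smooth_sigma, mode="constant")
    density = hist / hist.sum()
    return FreeEnergySurface(edges1, edges2, density,
                             n_frames=projections.n_frames)


def boltzmann_invert(surface: FreeEnergySurface,
                     kT: float = None) -> FreeEnergySurface:
    """Fill G = -kT ln(p / p_max) on the surface; min finite G is 0.

    Empty bins receive the sentinel value (max finite G + 3 kT), keeping the
    grid free of NaN arithmetic.
    """
    if kT is None:
        kT = thermal_energy(300.0)
    if kT <= 0:
        raise ValueError("kT must be positive")
    density = surface.density
    occupied = density > 0.0
    g = np.zeros_like(density)
    p_max = density[occupied].max()
    g[occupied] = -kT * np.log(density[occupied] / p_max)
    sentinel = g[occupied].max() + 3.0 * kT
    g[~occupied] = sentinel
    return FreeEnergySurface(surface.edges1, surface.edges2, density, g, kT,
                             surface.n_frames)


_NEIGHBOURS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
               if (di, dj) != (0, 0)]


def _flood(g: np.ndarray, occupied: np.ndarray) -> np.ndarray:
    """Order-of-increasing-G flooding with deterministic tie-breaking."""
    b1, b2 = g.shape
    flat_idx = np.flatnonzero(occupied.ravel())
    order = flat_idx[np.lexsort((flat_idx, g.ravel()[flat_idx]))]
    labels = np.zeros((b1, b2), dtype=int)
    next_label = 1
    for flat in order:
        i, j = divmod(int(flat), b2)
        best = None   # (G, flat_index, label) of lowest assigned neighbour
        for di, dj in _NEIGHBOURS:
            ni, nj = i + di, j + dj
            if 0 <= ni < b1 and 0 <= nj < b2 and labels[ni, nj] > 0:
                cand = (g[ni, nj], ni * b2 + nj, labels[ni, nj])
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            labels[i, j] = next_label
            next_label += 1
        else:
            labels[i, j] = best[2]
    return labels


def _assign_frames(projections: ProjectionSet,
                   surface: FreeEnergySurface) -> np.ndarray:
    """Bin index (i, j) of every frame, flattened; clips onto the outer bin."""
    pc1 = projections.projections[:, 0]
    pc2 = projections.projections[:, 1]
    i = np.clip(np.searchsorted(surface.edges1, pc1, side="right") - 1,
                0, surface.shape[0] - 1)
    j = np.clip(np.searchsorted(surface.edges2, pc2, side="right") - 1,
                0, surface.shape[1] - 1)
    return i, j


def _boundary_g(g, labels, basin: int):
    """For each basin adjacent to *basin*, the lowest pass value
    max(G_a, G_b) over adjacent bin pairs spanning the two basins."""
    b1, b2 = g.shape
    passes = {}
    ii, jj = np.nonzero(labels == basin)
    for di, dj in _NEIGHBOURS:
        ni, nj = ii + di, jj + dj
        ok = (ni >= 0) & (ni < b1) & (nj >= 0) & (nj < b2)
        oi, oj = ni[ok], nj[ok]
        other = labels[oi, oj]
        sel = (other > 0) & (other != basin)
        if not sel.any():
            continue
        pass_g = np.maximum(g[ii[ok][sel], jj[ok][sel]], g[oi[sel], oj[sel]])
        for lab in np.unique(other[sel]):
            val = float(pass_g[other[sel] == lab].min())
            lab = int(lab)
            if lab not in passes or val < passes[lab]:
                passes[lab] = val
    return passes


def watershed_partition(surface: FreeEnergySurface,
                        projections: ProjectionSet,
                        min_basin_population: float = 0.0,
                        min_barrier: Optional[float] = None) -> ClusterPartition:
    """Partition the free-energy surface into basins and label every frame.

    Two merge rules clean up the raw flood. First, basins separated from a
    neighbour by a barrier (lowest pass minus the basin's own minimum) below
    ``min_barrier`` are absorbed into that neighbour: on a sampled surface
    such sub-kT corrugation is shot noise, not metastability (default 1 kT).
    Second, basins whose frame population falls below
    ``min_basin_population`` are merged into the neighbouring basin with the
    lowest shared-boundary G, smallest basin first. Empty bins stay
    unassigned. Set both thresholds to 0 for the raw watershed.
    """
    if surface.g is None:
        raise ValueError("surface has no free energy; run boltzmann_invert")
    if min_barrier is None:
        min_barrier = surface.kT if surface.kT else 0.0
    occupied = ~surface.empty_mask
    if not occupied.any():
        raise ValueError("no occupied bins on the surface")
    labels = _flood(surface.g, occupied)
    fi, fj = _assign_frames(projections, surface)
    frame_labels = labels[fi, fj]
    n_assigned = np.count_nonzero(frame_labels)
    if n_assigned == 0:
        raise ValueError("no frame falls in an occupied bin")

    def _pops(flabels):
        ids, counts = np.unique(flabels[flabels > 0], return_counts=True)
        return dict(zip(ids.tolist(), (counts / n_assigned).tolist()))

    populations = _pops(frame_labels)

    def _merge_target(basin, candidates):
        """Adjacent basin with the lowest pass; for an island basin with no
        occupied-bin adjacency, the candidate whose bin set is nearest in
        grid-index space (deterministic tie-break by basin id)."""
        passes = _boundary_g(surface.g, labels, basin)
        passes = {b: g for b, g in passes.items() if b in candidates}
        if passes:
            return min(passes, key=lambda b: (passes[b], b))
        own = np.argwhere(labels == basin).astype(float)
        best = None
        for other in sorted(candidates):
            if other == basin:
                continue
            cells = np.argwhere(labels == other).astype(float)
            d = np.sqrt(((own[:, None, :] - cells[None, :, :]) ** 2)
                        .sum(-1)).min()
            if best is None or (d, other) < best[:2]:
                best = (d, other)
        return best[1]

    # absorb basins that contain bins but no frames (possible only through
    # numerical edge effects) into their lowest-pass neighbour
    for basin in sorted(set(np.unique(labels)) - {0} - set(populations)):
        target = _merge_target(basin, set(populations))
        labels[labels == basin] = target
    if min_barrier > 0.0:
        while len(populations) > 1:
            basin_min = {b: surface.g[labels == b].min()
                         for b in populations}
            best = None     # (persistence, basin id, merge target)
            for basin in sorted(populations):
                passes = _boundary_g(surface.g, labels, basin)
                if not passes:
                    continue    # island basin; population rule handles it
                target = min(passes, key=lambda b: (passes[b], b))
                persistence = passes[target] - basin_min[basin]
                if persistence < min_barrier and (
                        best is None or (persistence, basin) < best[:2]):
                    best = (persistence, basin, target)
            if best is None:
                break
            _, basin, target = best
            labels[labels == basin] = target
            frame_labels[frame_labels == basin] = target
            populations = _pops(frame_labels)
    if min_basin_population > 0.0:
        while len(populations) > 1:
            basin = min(populations, key=lambda b: (populations[b], b))
            if populations[basin] >= min_basin_population:
                break
            target = _merge_target(basin, set(populations) - {basin})
            labels[labels == basin] = target
            frame_labels[frame_labels == basin] = target
            populations = _pops(frame_labels)
    # compact basin ids to 1..K in row-major order of their minima
    minima = {}
    for basin in populations:
        cells = labels == basin
        g_vals = np.where(cells, surface.g, np.inf)
        flat = int(np.argmin(g_vals))
        ij = np.unravel_index(flat, surface.shape)
        minima[basin] = (ij, float(surface.g[ij]))
    remap = {old: new for new, old in enumerate(
        sorted(populations, key=lambda b: minima[b][0]), start=1)}
    new_labels = np.zeros_like(labels)
    for old, new in remap.items():
        new_labels[labels == old] = new
    new_frame_labels = np.zeros_like(frame_labels)
    for old, new in remap.items():
        new_frame_labels[frame_labels == old] = new
    return ClusterPartition(
        new_labels, new_frame_labels,
        {remap[b]: populations[b] for b in populations},
        {remap[b]: minima[b] for b in populations},
    )


def representative_frames(partition: ClusterPartition,
                          projections: ProjectionSet) -> dict:
    """Medoid frame per basin: the frame minimizing summed squared PC-space
    distance to the basin's frames (equivalently, closest to the basin
    centroid); ties go to the lowest frame id."""
    if len(partition.frame_labels) != projections.n_frames:
        raise ValueError("partition and projections are inconsistent")
    reps = {}
    proj = projections.projections
    for basin in sorted(partition.populations):
        members = np.flatnonzero(partition.frame_labels == basin)
        centroid = proj[members].mean(axis=0)
        dist2 = np.sum((proj[members] - centroid) ** 2, axis=1)
        reps[basin] = int(members[np.argmin(dist2)])
    partition.representatives = reps
    return reps


def refit_and_subcluster(ensemble, family_frame_ids, selection,
                         bins=(100, 100), kT: float = None,
                         min_basin_population: float = 0.0,
                         superpose_tol: float = 1e-4) -> ClusterPartition:
    """Second-stage clustering inside one conformational family.

    The family's frames are re-superposed onto their iterative mean over the
    selection, PCA is refit on those frames, and the density -> Boltzmann
    inversion -> watershed chain is rerun in the refit PC1/PC2 subspace.
    Returned frame labels are local to the family (same order as
    ``family_frame_ids``).
    """
    from .ensemble import iterative_mean_reference, superpose
    from .pca import fit_pca, project

    family_frame_ids = np.asarray(family_frame_ids, dtype=int)
    if len(family_frame_ids) < 2:
        raise ValueError("family must contain at least 2 frames")
    family = ensemble.subset_frames(family_frame_ids)
    ref = iterative_mean_reference(family, selection, tol=superpose_tol)
    fitted, _ = superpose(family, selection, ref.coordinates)
    model = fit_pca(fitted, selection)
    k = min(2, model.n_modes)
    proj = project(model, fitted, selection, k=k)
    if k == 1:  # pad a zero second component so the 2D histogram is defined
        proj.projections = np.column_stack(
            [proj.projections, np.zeros(proj.n_frames)])
    surface = boltzmann_invert(density_map(proj, bins), kT)
    partition = watershed_partition(surface, proj, min_basin_population)
    representative_frames(partition, proj)
    return partition


def write_opendx(path, surface_values: np.ndarray, origin, deltas,
                 name: str = "free_energy") -> None:
    """Write a 2D or 3D scalar grid as an OpenDX file for visualization."""
    values = np.asarray(surface_values, dtype=float)
    if values.ndim == 2:
        values = values[:, :, None]
        origin = (*origin, 0.0)
        deltas = (*deltas, 1.0)
    nx, ny, nz = values.shape
    dx, dy, dz = deltas
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*origin))
        fh.write(f"delta {dx:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {dy:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {dz:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items "
                 f"{values.size} data follows\n")
        flat = values.ravel()
        for start in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[start:start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write(f'object "{name}" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
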