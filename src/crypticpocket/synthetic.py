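"""Synthetic ground-truth generators.

These emulate the statistical structure the ensemble analysis assumes, with
no physics: a two-state flexible-loop ensemble of configurable populations
and displacement, hollow atom fixtures enclosing cavities of known volume,
and contact-distance series of known occupancy. Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ensemble import ConformationalEnsemble, write_structure


class LeakyShellError(ValueError):
    """Raised when a hollow-shell fixture is too thin to enclose its cavity."""


# ---------------------------------------------------------------------------
# base scaffold
# ---------------------------------------------------------------------------

def base_scaffold(n_residues: int = 50):
    """Deterministic 3-loop peptide-like scaffold.

    Each residue carries three heavy atoms (N, CA, C) and one hydrogen, so
    selections such as "8-14, heavy only" are exercised. The backbone follows
    a smooth 3D curve whose shape depends only on ``n_residues``.

    Returns (atoms DataFrame, coordinates (A, 3)).
    """
    t = np.linspace(0.0, 6.0 * np.pi, n_residues)
    # gently coiled curve, ~3.5 A between consecutive residues
    backbone = np.stack([
        8.0 * np.cos(t / 3.0) + 1.5 * np.cos(2 * t),
        8.0 * np.sin(t / 3.0) + 1.5 * np.sin(2 * t),
        1.8 * t,
    ], axis=1)
    records = []
    coords = []
    offsets = {
        "N": np.array([-0.7, 0.5, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([0.8, 0.4, 0.3]),
        "H": np.array([-0.7, 1.2, 0.6]),
    }
    serial = 1
    for i in range(n_residues):
        for name in ("N", "CA", "C", "H"):
            element = "H" if name == "H" else name[0]
            records.append({
                "serial": serial, "name": name, "element": element,
                "res_name": "ALA", "res_id": i + 1, "chain": "A",
                "ins_code": "", "is_heavy": element != "H",
            })
            coords.append(backbone[i] + offsets[name])
            serial += 1
    return pd.DataFrame.from_records(records), np.asarray(coords)


def loop_displacement_field(atoms: pd.DataFrame, residue_ranges,
                            magnitude: float = 3.0,
                            direction=(1.0, 1.0, 0.0)) -> np.ndarray:
    """Per-atom displacement field (A), non-zero on the given residue ranges.

    The displacement tapers linearly to zero at the range edges so the out
    state is a smooth loop opening rather than a rigid shift.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    res_id = atoms["res_id"].to_numpy()
    disp = np.zeros((len(atoms), 3))
    for first, last in residue_ranges:
        span = max(last - first, 1)
        mid = 0.5 * (first + last)
        in_range = (res_id >= first) & (res_id <= last)
        taper = 1.0 - np.abs(res_id[in_range] - mid) / (0.5 * span + 0.5)
        disp[in_range] = magnitude * taper[:, None] * direction
    return disp


# ---------------------------------------------------------------------------
# two-state ensembles
# ---------------------------------------------------------------------------

@dataclass
class TwoStateSpec:
    """Specification of a two-state (in/out) loop ensemble.

    populations are (pi_in, pi_out) and must sum to 1; displacement is a
    per-atom (A, 3) field added in the *out* state; noise_sd is the isotropic
    per-coordinate Gaussian fluctuation within a state; extra_modes is an
    optional list of (direction field (A, 3), amplitude sd in A) adding
    Gaussian-amplitude collective motions shared by both states.
    """

    n_frames: int
    populations: tuple = (0.7, 0.3)
    displacement: Optional[np.ndarray] = None
    noise_sd: float = 0.3
    extra_modes: Sequence = field(default_factory=list)
    seed: int = 0
    n_residues: int = 50
    loop_ranges: Sequence = ((8, 14), (20, 30), (40, 48))
    displacement_magnitude: float = 3.0

    def __post_init__(self):
        pi_in, pi_out = self.populations
        if not np.isclose(pi_in + pi_out, 1.0):
            raise ValueError("populations must sum to 1")
        if not (0.0 <= pi_out <= 1.0):
            raise ValueError("populations must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")


def make_two_state_ensemble(spec: TwoStateSpec):
    """Draw an i.i.d. two-state ensemble.

    Frame i: state ~ Bernoulli(pi_out); coordinates = base geometry
    (+ displacement if out) + N(0, noise_sd) per coordinate (+ extra-mode
    contributions with Gaussian amplitudes). Returns
    (ConformationalEnsemble, true_state_labels) with labels 0 = in, 1 = out.
    Bit-reproducible for a fixed spec and seed.
    """
    atoms, base = base_scaffold(spec.n_residues)
    disp = spec.displacement
    if disp is None:
        disp = loop_displacement_field(atoms, spec.loop_ranges,
                                       spec.displacement_magnitude)
    disp = np.asarray(disp, dtype=float)
    if disp.shape != base.shape:
        raise ValueError("displacement field shape must match atom count")
    pi_out = spec.populations[1]
    if np.linalg.norm(disp) == 0.0 and 0.0 < pi_out < 1.0:
        warnings.warn("degenerate spec: two states requested but displacement "
                      "norm is zero; states are indistinguishable")
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n_frames) < pi_out).astype(int)
    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    coords += labels[:, None, None] * disp[None, :, :]
    for mode_field, amp_sd in spec.extra_modes:
        mode_field = np.asarray(mode_field, dtype=float)
        amplitudes = rng.normal(0.0, amp_sd, size=spec.n_frames)
        coords += amplitudes[:, None, None] * mode_field[None, :, :]
    if spec.noise_sd > 0:
        coords += rng.normal(0.0, spec.noise_sd, size=coords.shape)
    prov = pd.DataFrame({
        "replica": np.zeros(spec.n_frames, dtype=int),
        "time_ns": np.arange(spec.n_frames, dtype=float),
        "source": ["synthetic:two_state"] * spec.n_frames,
    })
    return ConformationalEnsemble(coords, atoms, prov), labels


# ---------------------------------------------------------------------------
# cavity fixtures
# ---------------------------------------------------------------------------

@dataclass
class CavityFixture:
    """Atom arrangement enclosing a cavity of independently known volume."""

    coordinates: np.ndarray          # (N, 3), A; may be empty
    radii: np.ndarray                # (N,), A
    cavity_center: np.ndarray        # (3,), A
    including_radius: float          # A; bound used by the volume oracle
    oracle_volume: float             # A^3
    oracle_description: str
    kind: str


def fine_grid_free_volume(coordinates, radii, center, including_radius,
                          spacing: float = 0.1, probe: float = 0.0) -> float:
    """Independent fine-grid occupancy oracle for cavity volume.

    Counts grid points inside the including sphere farther than
    (radius + probe) from every atom; deliberately a plain dense computation
    kept separate from the production volumetrics. Requires a uniform atom
    radius so a single nearest-neighbour query decides occupancy.
    """
    coordinates = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    center = np.asarray(center, dtype=float)
    n = int(np.ceil(including_radius / spacing))
    axis = np.arange(-n, n + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1) + center
    inside = np.sum((pts - center) ** 2, axis=1) <= including_radius ** 2
    pts = pts[inside]
    if len(coordinates) == 0:
        return len(pts) * spacing ** 3
    if not np.allclose(radii, radii[0]):
        raise ValueError("fine-grid oracle requires a uniform atom radius")
    tree = cKDTree(coordinates)
    dist, _ = tree.query(pts, k=1)
    free = dist > radii[0] + probe
    return float(np.count_nonzero(free)) * spacing ** 3


def _lattice(half_extent: float, spacing: float) -> np.ndarray:
    n = int(np.floor(half_extent / spacing))
    axis = np.arange(-n, n + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def make_cavity_fixture(kind: str, *, radius: float = 6.0,
                        carve_radius: float = 4.0, half_extent: float = 7.0,
                        lattice_spacing: float = 1.0, atom_radius: float = 1.5,
                        oracle_spacing: float = 0.1) -> CavityFixture:
    """Build a validation fixture for grid volumetrics.

    kind "empty_sphere": no atoms; oracle volume is the analytic volume of the
    including sphere of the given radius. kind "solid_block": dense cubic atom
    lattice (spacing <= 1.2 A, radius 1.5 A); oracle volume 0. kind
    "hollow_shell": the same lattice with atoms removed inside a carved sphere
    of ``carve_radius``; oracle volume from the fine-grid occupancy oracle.
    """
    center = np.zeros(3)
    if kind == "empty_sphere":
        if radius <= 0:
            raise ValueError("radius must be positive")
        return CavityFixture(
            np.empty((0, 3)), np.empty(0), center, radius,
            4.0 / 3.0 * np.pi * radius ** 3,
            "analytic sphere volume 4/3*pi*r^3", kind)
    if lattice_spacing > 1.2:
        raise ValueError("lattice spacing must be <= 1.2 A to be vdW-tight")
    if kind == "solid_block":
        pts = _lattice(half_extent, lattice_spacing)
        return CavityFixture(
            pts, np.full(len(pts), atom_radius), center, half_extent,
            0.0, "solid lattice encloses no free space", kind)
    if kind == "hollow_shell":
        if half_extent - carve_radius < 2.0 * atom_radius:
            raise LeakyShellError(
                f"shell thickness {half_extent - carve_radius:.2f} A is below "
                f"the atom diameter {2 * atom_radius:.2f} A; cavity would leak")
        pts = _lattice(half_extent, lattice_spacing)
        keep = np.sum(pts ** 2, axis=1) > carve_radius ** 2
        pts = pts[keep]
        radii = np.full(len(pts), atom_radius)
        including = carve_radius + 1.0
        vol = fine_grid_free_volume(pts, radii, center, including,
                                    spacing=oracle_spacing)
        return CavityFixture(
            pts, radii, center, including, vol,
            f"fine-grid occupancy oracle at {oracle_spacing} A spacing", kind)
    raise ValueError(f"unknown fixture kind {kind!r}")


def fixture_as_atoms(fixture: CavityFixture) -> pd.DataFrame:
    """Atom table for a cavity fixture (pseudo-carbon probes, one residue per
    atom) so fixtures can flow through the structure-based operations."""
    n = len(fixture.coordinates)
    return pd.DataFrame({
        "serial": np.arange(1, n + 1),
        "name": ["C"] * n,
        "element": ["C"] * n,
        "res_name": ["PRB"] * n,
        "res_id": np.arange(1, n + 1),
        "chain": ["X"] * n,
        "ins_code": [""] * n,
        "is_heavy": [True] * n,
    })


# ---------------------------------------------------------------------------
# contact series
# ---------------------------------------------------------------------------

def make_contact_series(n_frames: int, occupancy: float,
                        bound_mean: float = 2.9, bound_sd: float = 0.15,
                        unbound_mean: float = 6.0, unbound_sd: float = 0.8,
                        seed: int = 0):
    """Distance series with known contact occupancy.

    Per frame a Bernoulli(occupancy) label chooses the bound or unbound
    Gaussian; distances are truncated to stay positive. Returns
    (distances, true_labels) with labels 1 = bound.
    """
    if not (0.0 <= occupancy <= 1.0):
        raise ValueError("occupancy must lie in [0, 1]")
    if bound_mean >= unbound_mean:
        raise ValueError("bound_mean must be below unbound_mean")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n_frames) < occupancy).astype(int)
    bound = rng.normal(bound_mean, bound_sd, size=n_frames)
    unbound = rng.normal(unbound_mean, unbound_sd, size=n_frames)
    distances = np.where(labels == 1, bound, unbound)
    distances = np.clip(distances, 1e-6, None)
    return distances, labels


# ---------------------------------------------------------------------------
# fixture persistence
# ---------------------------------------------------------------------------

def write_ground_truth(path, **kv) -> None:
    """Sidecar plain-text key-value ground-truth file."""
    with open(path, "w") as fh:
        for key, value in kv.items():
            if isinstance(value, (list, tuple, np.ndarray)):
                value = " ".join(str(v) for v in np.asarray(value).ravel())
            fh.write(f"{key} = {value}\n")


def write_two_state_fixture(spec: TwoStateSpec, prefix) -> None:
    """Write a two-state ensemble as multi-model PDB plus its ground truth."""
    ens, labels = make_two_state_ensemble(spec)
    write_structure(ens, f"{prefix}.pdb")
    write_ground_truth(f"{prefix}.truth.txt",
                       pi_in=spec.populations[0], pi_out=spec.populations[1],
                       noise_sd=spec.noise_sd, seed=spec.seed,
                       state_labels=labels)
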