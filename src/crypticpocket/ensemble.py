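"""Conformational-ensemble container, multi-model PDB I/O, atom selection and
rigid-body superposition.

Coordinates are in Angstrom throughout; residue numbering is 1-based as read
from the PDB; atom indices are 0-based positions into the ensemble. A "heavy"
atom is any atom whose element is not hydrogen or deuterium (decided by the
element column, with an atom-name fallback when the element field is blank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class StructureFormatError(ValueError):
    """Raised when an input structure file cannot be interpreted."""


class EmptyInputError(ValueError):
    """Raised when a structure contains no atoms."""


class DegenerateFitError(ValueError):
    """Raised when a superposition fit is under-determined."""


_HYDROGEN_ELEMENTS = {"H", "D"}

ATOM_COLUMNS = ["serial", "name", "element", "res_name", "res_id",
                "chain", "ins_code", "is_heavy"]


def _infer_element(name: str) -> str:
    """Fallback element inference from a PDB atom name."""
    stripped = name.strip()
    # names like "1HB1" or "HG21" are hydrogens
    core = stripped.lstrip("0123456789")
    if not core:
        return ""
    if core[0] in ("H", "D") and not core.startswith(("HG", "HF", "HO", "HE")):
        # HG/HE/HF could be mercury/helium/hafnium in HETATMs, but in protein
        # context names beginning with H are hydrogens; keep the simple rule.
        return core[0]
    if core[0] in ("H", "D"):
        return core[0]
    return core[0]


@dataclass
class ConformationalEnsemble:
    """Frames x atoms x 3 coordinates (A) with atom and frame metadata.

    Attributes
    ----------
    coordinates : ndarray, shape (F, A, 3)
        Cartesian coordinates in Angstrom.
    atoms : pandas.DataFrame
        One row per atom: serial, name, element, res_name, res_id, chain,
        ins_code, is_heavy.
    provenance : pandas.DataFrame
        One row per frame: replica, time_ns, source.
    """

    coordinates: np.ndarray
    atoms: pd.DataFrame
    provenance: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (F, A, 3)")
        if self.n_atoms == 0:
            raise EmptyInputError("ensemble contains no atoms")
        if self.n_frames < 1:
            raise ValueError("ensemble must contain at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates in ensemble")
        if len(self.atoms) != self.n_atoms:
            raise ValueError("atom table length does not match coordinates")
        if self.provenance is None:
            self.provenance = pd.DataFrame({
                "replica": np.zeros(self.n_frames, dtype=int),
                "time_ns": np.arange(self.n_frames, dtype=float),
                "source": [""] * self.n_frames,
            })
        if len(self.provenance) != self.n_frames:
            raise ValueError("provenance length does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame *i*, shape (A, 3)."""
        return self.coordinates[i]

    def subset_frames(self, frame_ids) -> "ConformationalEnsemble":
        frame_ids = np.asarray(frame_ids, dtype=int)
        return ConformationalEnsemble(
            self.coordinates[frame_ids],
            self.atoms,
            self.provenance.iloc[frame_ids].reset_index(drop=True),
        )

    @classmethod
    def from_frames(cls, atoms: pd.DataFrame, frames, provenance=None):
        """Adapter entry point: build an ensemble from any reader that yields
        per-frame (A, 3) coordinate arrays in Angstrom plus an atom table."""
        coords = np.stack([np.asarray(f, dtype=float) for f in frames])
        return cls(coords, atoms.reset_index(drop=True), provenance)


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, unique 0-based atom indices plus a human-readable description."""

    indices: np.ndarray
    description: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("selection indices must be one-dimensional")
        if len(idx) and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            raise ValueError("selection indices must be strictly increasing and non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


def _atoms_dataframe(array: struc.AtomArray) -> pd.DataFrame:
    elements = [e.strip().upper() for e in array.element]
    names = list(array.atom_name)
    elements = [e if e else _infer_element(n) for e, n in zip(elements, names)]
    is_heavy = [e not in _HYDROGEN_ELEMENTS for e in elements]
    if "atom_id" in array.get_annotation_categories():
        serial = np.asarray(array.atom_id, dtype=int)
    else:
        serial = np.arange(1, array.array_length() + 1)
    ins = (array.ins_code if "ins_code" in array.get_annotation_categories()
           else np.full(array.array_length(), "", dtype="U1"))
    return pd.DataFrame({
        "serial": serial,
        "name": names,
        "element": elements,
        "res_name": list(array.res_name),
        "res_id": np.asarray(array.res_id, dtype=int),
        "chain": list(array.chain_id),
        "ins_code": list(ins),
        "is_heavy": is_heavy,
    })


def read_structure(path, format: str = "pdb") -> ConformationalEnsemble:
    """Read a single- or multi-model structure into a ConformationalEnsemble.

    One frame per MODEL record; hydrogens are retained if present; alternate
    locations are resolved to the highest-occupancy conformer (ties broken by
    altLoc label order). Raises StructureFormatError on unreadable input and
    EmptyInputError on a structure with zero atoms.
    """
    if format.lower() != "pdb":
        raise StructureFormatError(
            f"unsupported format {format!r}; use multi-model PDB or the "
            "ConformationalEnsemble.from_frames adapter for trajectories")
    try:
        pdb_file = PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None, altloc="occupancy",
                                       extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises several error types
        raise StructureFormatError(f"cannot read {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise EmptyInputError(f"{path} contains no atoms")
    coords = np.asarray(stack.coord, dtype=float)
    atoms = _atoms_dataframe(stack[0])
    prov = pd.DataFrame({
        "replica": np.zeros(coords.shape[0], dtype=int),
        "time_ns": np.arange(coords.shape[0], dtype=float),
        "source": [str(path)] * coords.shape[0],
    })
    return ConformationalEnsemble(coords, atoms, prov)


def write_structure(ensemble: ConformationalEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL delimited)."""
    n = ensemble.n_atoms
    array = struc.AtomArray(n)
    a = ensemble.atoms
    array.chain_id = np.asarray(a["chain"], dtype="U4")
    array.res_id = np.asarray(a["res_id"], dtype=int)
    array.ins_code = np.asarray(a["ins_code"], dtype="U1")
    array.res_name = np.asarray(a["res_name"], dtype="U5")
    array.atom_name = np.asarray(a["name"], dtype="U6")
    array.element = np.asarray(a["element"], dtype="U2")
    array.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([array] * ensemble.n_frames)
    stack.coord = np.asarray(ensemble.coordinates, dtype=np.float32)
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def select_loops(ensemble: ConformationalEnsemble, residue_ranges,
                 heavy_only: bool = True) -> AtomSelection:
    """Select all atoms whose residue number lies in any (first, last) range,
    inclusive on both ends; hydrogens excluded when heavy_only.

    A range matching no atoms is recorded as a warning in the selection
    description (truncated constructs are common), not an error.
    """
    if not residue_ranges:
        raise ValueError("residue_ranges must be non-empty")
    res_id = ensemble.atoms["res_id"].to_numpy()
    heavy = ensemble.atoms["is_heavy"].to_numpy()
    mask = np.zeros(ensemble.n_atoms, dtype=bool)
    notes = []
    for first, last in residue_ranges:
        if first > last:
            raise ValueError(f"invalid residue range ({first}, {last})")
        in_range = (res_id >= first) & (res_id <= last)
        if heavy_only:
            in_range &= heavy
        if not in_range.any():
            notes.append(f"warning: range {first}-{last} matched no atoms")
        mask |= in_range
    desc = ",".join(f"{a}-{b}" for a, b in residue_ranges)
    if heavy_only:
        desc += " (heavy atoms)"
    if notes:
        desc += "; " + "; ".join(notes)
    return AtomSelection(np.flatnonzero(mask), desc)


def kabsch_transform(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation R and translation t minimizing ||R x + t - target||^2
    over paired points, with no reflection (det R = +1)."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    return rot, trans


def _check_fit_atoms(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear; rotation under-determined")


def superpose(ensemble: ConformationalEnsemble, fit_selection: AtomSelection,
              reference: np.ndarray):
    """Rigid-body fit of every frame onto *reference* over *fit_selection*.

    Returns (superposed ensemble, per-frame RMSD over the fit selection, A).
    The whole frame is transformed; RMSD is computed after fitting. Reflections
    are never applied.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ensemble.n_atoms, 3):
        raise ValueError("reference must be a single frame with matching atom count")
    if len(fit_selection) == 0:
        raise ValueError("fit selection is empty")
    idx = fit_selection.indices
    ref_sel = reference[idx]
    _check_fit_atoms(ref_sel)
    mobile = ensemble.coordinates[:, idx, :]
    mob_center = mobile.mean(axis=1, keepdims=True)
    ref_center = ref_sel.mean(axis=0)
    # batched Kabsch: one 3x3 SVD per frame
    h = np.einsum("fai,aj->fij", mobile - mob_center, ref_sel - ref_center)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fji,fkj->fik", vt, u))
    corr = np.repeat(np.eye(3)[None], ensemble.n_frames, axis=0)
    corr[:, 2, 2] = np.sign(det)
    rot = np.einsum("fji,fjk,flk->fil", vt, corr, u)
    trans = ref_center - np.einsum("fij,fj->fi", rot, mob_center[:, 0, :])
    out = (np.einsum("fij,faj->fai", rot, ensemble.coordinates)
           + trans[:, None, :])
    diff = out[:, idx, :] - ref_sel
    rmsd = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    fitted = replace(ensemble, coordinates=out)
    return fitted, rmsd


def rmsd(a: np.ndarray, b: np.ndarray, indices=None) -> float:
    """Plain (no refitting) root-mean-square deviation between two frames."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if indices is not None:
        a = a[indices]
        b = b[indices]
    diff = a - b
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


@dataclass
class MeanReference:
    """Result of the iterative mean-structure computation."""
    coordinates: np.ndarray
    converged: bool
    n_iterations: int


def iterative_mean_reference(ensemble: ConformationalEnsemble,
                             fit_selection: AtomSelection,
                             tol: float = 1e-4,
                             max_iter: int = 50) -> MeanReference:
    """Iterative mean structure: superpose to the current mean, recompute the
    mean, repeat until the mean shifts by less than *tol* (A, RMSD over all
    atoms). Seeded by frame 0; deterministic given input order. On
    non-convergence the last mean is returned with ``converged=False``."""
    if ensemble.n_frames < 2:
        raise ValueError("iterative mean needs at least 2 frames")
    mean = ensemble.coordinates[0].copy()
    converged = False
    n_it = 0
    for n_it in range(1, max_iter + 1):
        fitted, _ = superpose(ensemble, fit_selection, mean)
        new_mean = fitted.coordinates.mean(axis=0)
        shift = rmsd(new_mean, mean)
        mean = new_mean
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn("iterative mean reference did not converge "
                      f"within {max_iter} iterations")
    return MeanReference(mean, converged, n_it)
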