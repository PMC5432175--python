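"""Principal component analysis of loop heavy-atom coordinates.

The ensemble is assumed to be superposed on the fit selection already; the
3N coordinate vector of the selected atoms is centered and its population
covariance (1/F normalization) eigendecomposed. Coordinates are unweighted
and unscaled. Eigenvector signs are fixed so the largest-magnitude component
of each mode is positive, making outputs reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import AtomSelection, ConformationalEnsemble


class InsufficientFramesError(ValueError):
    pass


class DegenerateEnsembleError(ValueError):
    pass


@dataclass
class PCAModel:
    """Mean structure, orthonormal modes and variances of a coordinate PCA.

    mean is the 3A-vector of the selection's mean coordinates (A); modes is a
    (M, 3A) array of orthonormal eigenvectors sorted by decreasing variance;
    variances are the eigenvalues (A^2); explained_fraction sums to 1 over
    all retained modes.
    """

    mean: np.ndarray
    modes: np.ndarray
    variances: np.ndarray
    explained_fraction: np.ndarray
    fit_selection: AtomSelection
    n_frames_fit: int

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


@dataclass
class ProjectionSet:
    """Per-frame coordinates (A) on the first k modes, with frame provenance."""

    projections: np.ndarray      # (F, k)
    provenance: pd.DataFrame

    @property
    def n_frames(self) -> int:
        return self.projections.shape[0]

    @property
    def k(self) -> int:
        return self.projections.shape[1]

    def to_csv(self, path) -> None:
        df = self.provenance.copy().reset_index(drop=True)
        df.insert(0, "frame", np.arange(self.n_frames))
        for j in range(self.k):
            df[f"PC{j + 1}"] = self.projections[:, j]
        df.to_csv(path, index=False)


def _selection_matrix(ensemble: ConformationalEnsemble,
                      selection: AtomSelection) -> np.ndarray:
    coords = ensemble.coordinates[:, selection.indices, :]
    return coords.reshape(ensemble.n_frames, -1)


def fit_pca(ensemble: ConformationalEnsemble,
            selection: AtomSelection) -> PCAModel:
    """Eigendecompose the population covariance of the selected coordinates.

    Computed through the thin SVD of the centered frame matrix, which is
    equivalent to diagonalizing the 3Ax3A covariance but stable for large
    frame counts. Modes with numerically zero variance are dropped.
    """
    if ensemble.n_frames < 2:
        raise InsufficientFramesError("PCA requires at least 2 frames")
    x = _selection_matrix(ensemble, selection)
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD of X_c / sqrt(F): singular values squared are covariance eigenvalues
    u, s, vt = np.linalg.svd(xc / np.sqrt(ensemble.n_frames),
                             full_matrices=False)
    variances = s ** 2
    total = variances.sum()
    if total <= 1e-12:
        raise DegenerateEnsembleError("ensemble has zero coordinate variance")
    keep = variances > total * 1e-12
    variances = variances[keep]
    modes = vt[keep]
    # sign convention: largest-magnitude component of each mode positive
    for row in modes:
        peak = np.argmax(np.abs(row))
        if row[peak] < 0:
            row *= -1.0
    return PCAModel(mean, modes, variances, variances / variances.sum(),
                    selection, ensemble.n_frames)


def project(model: PCAModel, ensemble: ConformationalEnsemble,
            selection: AtomSelection, k: int) -> ProjectionSet:
    """Project frames onto the first k modes: dot(frame - mean, mode)."""
    if k < 1 or k > model.n_modes:
        raise IndexError(f"k={k} outside available modes (1..{model.n_modes})")
    if len(selection) != len(model.fit_selection):
        raise ValueError("selection incompatible with the model's fit selection")
    x = _selection_matrix(ensemble, selection)
    proj = (x - model.mean) @ model.modes[:k].T
    return ProjectionSet(proj, ensemble.provenance.copy())


def explained_variance(model: PCAModel, k: int) -> float:
    """Cumulative fraction of total variance carried by the first k modes."""
    if k < 1 or k > model.n_modes:
        raise IndexError(f"k={k} outside available modes (1..{model.n_modes})")
    return float(model.explained_fraction[:k].sum())


def mode_extremes(model: PCAModel, mode_index: int, amplitude: float):
    """Pair of structures mean +/- amplitude * mode, as (n_sel, 3) coordinate
    arrays for the fit selection's atoms."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if mode_index < 0 or mode_index >= model.n_modes:
        raise IndexError("mode_index out of range")
    mode = model.modes[mode_index]
    plus = (model.mean + amplitude * mode).reshape(-1, 3)
    minus = (model.mean - amplitude * mode).reshape(-1, 3)
    return plus, minus


def save_model(model: PCAModel, path) -> None:
    """Persist a PCA model as an NPZ archive with documented field names."""
    np.savez(path, mean=model.mean, modes=model.modes,
             variances=model.variances,
             explained_fraction=model.explained_fraction,
             selection_indices=model.fit_selection.indices,
             selection_description=np.asarray(model.fit_selection.description),
             n_frames_fit=np.asarray(model.n_frames_fit))


def load_model(path) -> PCAModel:
    data = np.load(path, allow_pickle=False)
    sel = AtomSelection(data["selection_indices"],
                        str(data["selection_description"]))
    return PCAModel(data["mean"], data["modes"], data["variances"],
                    data["explained_fraction"], sel,
                    int(data["n_frames_fit"]))
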