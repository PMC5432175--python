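"""Ensemble RMSD profiles and interaction (contact) statistics.

The RMSD profile of a set of replicas carries two flavours per time point:
the mean over replicas of each frame's RMSD to the reference, and the RMSD
of the across-replica average structure at that time. By convexity the
second never exceeds the first.

Hydrogen bonds are scored as heavy-atom donor-acceptor distances (default
cutoff 3.5 A, no angle term); salt bridges as charged-group minimum
distances (default 4.0 A). Occupancy is the fraction of window frames whose
distance is at or below the cutoff; the window defaults to the final 40% of
frames, mirroring the tail-of-production convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ensemble import ConformationalEnsemble, rmsd


@dataclass
class RMSDProfile:
    times: np.ndarray                   # ns
    ensemble_mean_rmsd: np.ndarray      # A
    ensemble_variance: np.ndarray       # A^2
    average_structure_rmsd: np.ndarray  # A

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ns": self.times,
            "ensemble_mean_rmsd": self.ensemble_mean_rmsd,
            "ensemble_variance": self.ensemble_variance,
            "average_structure_rmsd": self.average_structure_rmsd,
        })


@dataclass
class ContactSeries:
    distances: np.ndarray    # A, one per frame
    pair: str                # human-readable pair definition
    mode: str                # "minimum" or "com"
    cutoff: float = 3.5      # A


@dataclass
class OccupancyResult:
    fraction: float
    mean_distance: Optional[float]   # over in-contact frames; None if none
    sd_distance: Optional[float]
    n_window: int
    n_contact: int


def rmsd_profile(replicas: Sequence[ConformationalEnsemble],
                 reference: np.ndarray, selection) -> RMSDProfile:
    """Both profile flavours per time point across pre-superposed replicas.

    Replicas must share the atom layout and the time grid (provenance
    time_ns); a mismatched grid raises an alignment error.
    """
    if not replicas:
        raise ValueError("no replicas given")
    times = replicas[0].provenance["time_ns"].to_numpy()
    for rep in replicas[1:]:
        other = rep.provenance["time_ns"].to_numpy()
        if len(other) != len(times) or not np.allclose(other, times):
            raise ValueError("replicas do not share a common time grid")
    idx = selection.indices
    reference_sel = np.asarray(reference, dtype=float)[idx]
    n_t = len(times)
    per_replica = np.empty((len(replicas), n_t))
    for r, rep in enumerate(replicas):
        diff = rep.coordinates[:, idx, :] - reference_sel
        per_replica[r] = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    mean_rmsd = per_replica.mean(axis=0)
    variance = per_replica.var(axis=0)
    avg_rmsd = np.empty(n_t)
    stackc = np.stack([rep.coordinates[:, idx, :] for rep in replicas])
    avg_structures = stackc.mean(axis=0)        # (T, n_sel, 3)
    for t in range(n_t):
        avg_rmsd[t] = rmsd(avg_structures[t], reference_sel)
    return RMSDProfile(times, mean_rmsd, variance, avg_rmsd)


def contact_distance_series(ensemble: ConformationalEnsemble,
                            group_a, group_b, mode: str = "minimum",
                            cutoff: float = 3.5,
                            label: str = "") -> ContactSeries:
    """Per-frame inter-group distance.

    mode "minimum": minimum heavy-atom pair distance; mode "com": distance
    between the groups' centers of geometry. Groups are given as atom-index
    sequences or AtomSelection objects.
    """
    idx_a = np.asarray(getattr(group_a, "indices", group_a), dtype=int)
    idx_b = np.asarray(getattr(group_b, "indices", group_b), dtype=int)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("contact groups must be non-empty")
    ca = ensemble.coordinates[:, idx_a, :]
    cb = ensemble.coordinates[:, idx_b, :]
    if mode == "minimum":
        diff = ca[:, :, None, :] - cb[:, None, :, :]
        dist = np.sqrt(np.sum(diff * diff, axis=3))
        series = dist.reshape(ensemble.n_frames, -1).min(axis=1)
    elif mode == "com":
        series = np.linalg.norm(ca.mean(axis=1) - cb.mean(axis=1), axis=1)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return ContactSeries(series, label or f"{len(idx_a)}x{len(idx_b)} atoms",
                         mode, cutoff)


def default_window(n_frames: int, fraction: float = 0.4):
    """Final-fraction window as a (start, stop) frame range."""
    start = int(np.floor(n_frames * (1.0 - fraction)))
    return start, n_frames


def occupancy(series: ContactSeries, cutoff: Optional[float] = None,
              window=None) -> OccupancyResult:
    """Fraction of window frames with distance <= cutoff, plus the mean and
    sd of the distance over those in-contact frames.

    With no in-contact frame the fraction is 0 and the mean/sd are flagged
    as undefined (None), never NaN-propagated.
    """
    cutoff = series.cutoff if cutoff is None else cutoff
    if window is None:
        window = (0, len(series.distances))
    start, stop = window
    values = series.distances[start:stop]
    if len(values) == 0:
        raise ValueError("occupancy window is empty")
    contact = values <= cutoff
    n_contact = int(np.count_nonzero(contact))
    if n_contact == 0:
        return OccupancyResult(0.0, None, None, len(values), 0)
    in_contact = values[contact]
    sd = float(np.std(in_contact, ddof=1)) if n_contact > 1 else 0.0
    return OccupancyResult(n_contact / len(values),
                           float(np.mean(in_contact)), sd, len(values),
                           n_contact)


@dataclass
class InteractionDefinition:
    """A named contact with its groups, aggregation mode and cutoff (A)."""
    name: str
    group_a: object
    group_b: object
    cutoff: float = 3.5
    mode: str = "minimum"


def interaction_report(ensemble: ConformationalEnsemble,
                       definitions: Sequence[InteractionDefinition],
                       motifs: Optional[dict] = None,
                       window=None) -> pd.DataFrame:
    """One row per interaction (occupancy, mean +/- sd distance) plus one row
    per motif, where a motif is a named conjunction of interactions counted
    on frames satisfying all member cutoffs simultaneously."""
    if window is None:
        window = (0, ensemble.n_frames)
    start, stop = window
    rows = []
    contact_masks = {}
    for d in definitions:
        series = contact_distance_series(ensemble, d.group_a, d.group_b,
                                         d.mode, d.cutoff, d.name)
        contact_masks[d.name] = series.distances[start:stop] <= d.cutoff
        occ = occupancy(series, window=window)
        rows.append({
            "interaction": d.name, "kind": "single",
            "occupancy": occ.fraction,
            "mean_distance": occ.mean_distance,
            "sd_distance": occ.sd_distance,
            "window_start": start, "window_stop": stop,
        })
    for name, members in (motifs or {}).items():
        mask = np.ones(stop - start, dtype=bool)
        for member in members:
            mask &= contact_masks[member]
        rows.append({
            "interaction": name, "kind": "motif",
            "occupancy": float(np.mean(mask)),
            "mean_distance": None, "sd_distance": None,
            "window_start": start, "window_stop": stop,
        })
    return pd.DataFrame(rows)
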