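"""Pocket druggability scoring on a 0-1 scale.

Candidate pockets (grid components from :mod:`crypticpocket.pockets`) are
described by hydrophobicity, polarity and shape descriptors and mapped to a
druggability score through a logistic model,

    score = sigma(b0 + b1*apolar_fraction + b2*enclosure
                  + b3*ln(1 + volume) + b4*polar_density),

strictly increasing in apolar fraction and enclosure and decreasing in polar
density. The coefficients were calibrated once against four synthetic
descriptor fixtures (a hydrophobic enclosed pocket scoring >= 0.8, a shallow
all-polar groove <= 0.1, a mixed medium pocket near 0.5, and a tiny pocket
<= 0.2) and are stored as the default configuration.

Atom polarity is decided by element (N/O polar, C/S apolar); the apolar
residue class is {Ala, Val, Leu, Ile, Pro, Phe, Met, Trp, Cys}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pockets import lining_atoms, lining_residues, pocket_volume, vdw_radius

APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP",
                   "CYS"}

#: logistic coefficients (b0, apolar_fraction, enclosure, ln(1+volume),
#: polar_density), calibrated on the four synthetic descriptor fixtures
DEFAULT_COEFFICIENTS = (-9.5, 4.0, 3.0, 1.0, -0.6)

#: number of quasi-uniform rays used for the enclosure descriptor
N_ENCLOSURE_RAYS = 146

#: maximum ray length (A) when probing enclosure
ENCLOSURE_RANGE = 8.0


@dataclass
class PocketDescriptors:
    volume: float                       # A^3
    apolar_fraction: float              # lining heavy atoms that are C/S
    polar_density: float                # lining N/O atoms per 100 A^3
    enclosure: float                    # fraction of rays hitting protein
    hydrophobic_residue_fraction: float # lining residues in the apolar class


@dataclass
class DruggabilityReport:
    descriptors: PocketDescriptors
    score: float
    coefficients: tuple

    def to_dict(self) -> dict:
        return {"descriptors": asdict(self.descriptors),
                "score": self.score,
                "coefficients": list(self.coefficients)}


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice on the sphere)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def enclosure_fraction(centroid, coordinates, elements,
                       n_rays: int = N_ENCLOSURE_RAYS,
                       max_range: float = ENCLOSURE_RANGE,
                       radii_table=None) -> float:
    """Fraction of quasi-uniform rays from the centroid that intersect a
    protein atom's vdW sphere within ``max_range`` A."""
    centroid = np.asarray(centroid, dtype=float)
    coordinates = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    if len(coordinates) == 0:
        return 0.0
    radii = np.array([vdw_radius(e, radii_table) for e in elements])
    rel = coordinates - centroid
    near = np.linalg.norm(rel, axis=1) <= max_range + radii.max()
    rel, radii = rel[near], radii[near]
    if len(rel) == 0:
        return 0.0
    directions = fibonacci_sphere(n_rays)
    hits = 0
    for d in directions:
        t = rel @ d                       # along-ray projection of atom centers
        perp2 = np.sum(rel * rel, axis=1) - t * t
        ok = (t > 0.0) & (t <= max_range) & (perp2 <= radii * radii)
        hits += bool(ok.any())
    return hits / n_rays


def pocket_descriptors(component: np.ndarray, coordinates,
                       atoms: pd.DataFrame, spacing: float,
                       lining_cutoff: float = 4.5,
                       radii_table=None) -> PocketDescriptors:
    """Descriptors of a pocket component against its surrounding structure.

    With an empty lining, all fractions are reported as 0 with a warning
    (the pocket floats free of any protein surface).
    """
    component = np.asarray(component, dtype=float).reshape(-1, 3)
    if len(component) == 0:
        raise ValueError("empty pocket component")
    volume = pocket_volume(component, spacing)
    lin_atoms = lining_atoms(component, coordinates, atoms, lining_cutoff)
    lin_res = lining_residues(component, coordinates, atoms, lining_cutoff)
    if lin_atoms.empty:
        warnings.warn("pocket has no lining atoms within the cutoff; "
                      "fraction descriptors reported as 0")
        apolar = polar_density = hydrophobic = 0.0
    else:
        elements = lin_atoms["element"].str.upper()
        apolar = float(elements.isin(["C", "S"]).mean())
        n_polar = int(elements.isin(["N", "O"]).sum())
        polar_density = 100.0 * n_polar / volume if volume > 0 else 0.0
        hydrophobic = float(
            lin_res["res_name"].str.upper().isin(APOLAR_RESIDUES).mean())
    centroid = component.mean(axis=0)
    heavy = atoms["is_heavy"].to_numpy()
    enclosure = enclosure_fraction(
        centroid, np.asarray(coordinates, dtype=float)[heavy],
        atoms.loc[heavy, "element"], radii_table=radii_table)
    return PocketDescriptors(volume, apolar, polar_density, enclosure,
                             hydrophobic)


def druggability_score(descriptors: PocketDescriptors,
                       coefficients=DEFAULT_COEFFICIENTS) -> float:
    """Logistic druggability score, strictly inside (0, 1)."""
    b0, b_apolar, b_enclosure, b_volume, b_polar = coefficients
    z = (b0
         + b_apolar * descriptors.apolar_fraction
         + b_enclosure * descriptors.enclosure
         + b_volume * np.log1p(max(descriptors.volume, 0.0))
         + b_polar * descriptors.polar_density)
    return float(1.0 / (1.0 + np.exp(-z)))


def score_pocket(component, coordinates, atoms, spacing,
                 coefficients=DEFAULT_COEFFICIENTS,
                 lining_cutoff: float = 4.5) -> DruggabilityReport:
    """Descriptors plus score for one pocket component."""
    desc = pocket_descriptors(component, coordinates, atoms, spacing,
                              lining_cutoff)
    return DruggabilityReport(desc, druggability_score(desc, coefficients),
                              tuple(coefficients))


# ---------------------------------------------------------------------------
# calibration descriptor fixtures (synthetic; used to pin the coefficients)
# ---------------------------------------------------------------------------

CALIBRATION_FIXTURES = {
    # deep, well-enclosed, lipophilic cavity: should be clearly druggable
    "hydrophobic_enclosed": PocketDescriptors(
        volume=800.0, apolar_fraction=0.90, polar_density=0.5,
        enclosure=0.95, hydrophobic_residue_fraction=0.85),
    # open solvent-exposed polar groove: should be clearly undruggable
    "polar_shallow": PocketDescriptors(
        volume=150.0, apolar_fraction=0.20, polar_density=4.0,
        enclosure=0.40, hydrophobic_residue_fraction=0.10),
    # mid-size mixed-character pocket: should sit near the decision boundary
    "mixed_medium": PocketDescriptors(
        volume=400.0, apolar_fraction=0.55, polar_density=2.0,
        enclosure=0.70, hydrophobic_residue_fraction=0.50),
    # too small to hold a drug-like fragment regardless of character
    "tiny_pocket": PocketDescriptors(
        volume=40.0, apolar_fraction=0.60, polar_density=1.0,
        enclosure=0.80, hydrophobic_residue_fraction=0.60),
}
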