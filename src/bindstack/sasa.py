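"""Shrake-Rupley solvent-accessible surface area with deterministic points.

For each atom, ``n_points`` quasi-uniform test points are placed on the
solvent-expanded sphere of radius ``r_atom + probe`` by a golden-spiral
(Fibonacci) lattice; the accessible area is the fraction of points strictly
outside every neighbour's expanded sphere times the sphere area
4*pi*(r+probe)^2.  The lattice is a fixed function of ``n_points``, so results
are bit-reproducible with no random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["DEFAULT_RADII", "SasaResult", "golden_spiral_points", "shrake_rupley", "compute_sasa"]

#: van der Waals radii (Angstrom) by element; "*" is the fallback for
#: elements not listed.  Values are the conventional Bondi-style set.
DEFAULT_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "*": 1.80,
}


@dataclass(frozen=True)
class SasaResult:
    per_atom: np.ndarray  # (n,) Angstrom^2
    probe_radius: float
    n_sphere_points: int
    per_residue: dict = field(default_factory=dict)  # residue key -> Angstrom^2

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def golden_spiral_points(n: int) -> np.ndarray:
    """(n, 3) quasi-uniform unit vectors on the sphere (Fibonacci lattice)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * k  # golden angle increments
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def shrake_rupley(
    coords: np.ndarray,
    radii: Sequence[float],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom accessible areas (Angstrom^2) for arbitrary sphere sets."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if radii.shape != (coords.shape[0],):
        raise ValueError("radii must match the number of atoms")
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a usable estimate")
    expanded = radii + probe_radius
    sphere = golden_spiral_points(n_points)

    tree = cKDTree(coords)
    reach = 2.0 * expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= expanded[j]  # strictly inside buries a point
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def _radius_for(element: str, table: Mapping[str, float]) -> float:
    if element in table:
        return table[element]
    if "*" in table:
        return table["*"]
    raise KeyError(f"no van der Waals radius for element {element!r} and no '*' fallback")


def compute_sasa(
    atoms,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii_table: Mapping[str, float] | None = None,
    residue_keys: Sequence | None = None,
) -> SasaResult:
    """SASA of a collection of :class:`~bindstack.structure.AtomRecord`.

    ``residue_keys`` (one hashable key per atom) requests per-residue totals,
    each the sum of its atoms' areas.  Unknown elements raise unless the
    radii table carries a "*" fallback (the default table does).
    """
    atoms = list(atoms)
    if not atoms:
        raise ValueError("no atoms given")
    table = DEFAULT_RADII if radii_table is None else radii_table
    missing = sorted(
        {a.element for a in atoms if a.element not in table} - ({"*"} if "*" in table else set())
    )
    if missing and "*" not in table:
        raise KeyError(f"no radius for element(s): {', '.join(missing)}")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([_radius_for(a.element, table) for a in atoms])
    per_atom = shrake_rupley(coords, radii, probe_radius, n_sphere_points)

    per_residue: dict = {}
    if residue_keys is not None:
        if len(residue_keys) != len(atoms):
            raise ValueError("residue_keys must match the number of atoms")
        for key, area in zip(residue_keys, per_atom):
            per_residue[key] = per_residue.get(key, 0.0) + float(area)
    return SasaResult(
        per_atom=per_atom,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
        per_residue=per_residue,
    )
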