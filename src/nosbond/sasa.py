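"""Shrake–Rupley solvent-accessible surface area with a deterministic point set.

Each atom is expanded by the probe radius and sampled with a fixed
golden-spiral (Fibonacci) distribution of surface points; a point survives if
it lies outside every neighbouring expanded sphere.  The point set depends
only on ``n_points``, so the computation is bit-reproducible across runs and
platforms with the same inputs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["VDW_RADII", "sphere_points", "shrake_rupley", "structure_sasa"]

#: van der Waals radii (Å) used for SASA
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_RADIUS = 1.70

WATER_RESIDUES = {"HOH", "WAT", "DOD"}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere, shape (n, 3)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (Å²) for atoms at *coords* with vdW *radii*.

    ``coords`` is (n, 3); ``radii`` is (n,).  Returns (n,) areas.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    pts = sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n)
    for i in range(n):
        r_i = expanded[i]
        surface = coords[i] + r_i * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], r_i + max_reach / 2.0):
            if j == i:
                continue
            r_j = expanded[j]
            d2 = np.sum((surface - coords[j]) ** 2, axis=1)
            accessible &= d2 > r_j * r_j
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * r_i * r_i * accessible.sum() / n_points
    return areas


def structure_sasa(
    structure,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[dict, dict]:
    """SASA tables for a :class:`~nosbond.structure_io.StructureModel`.

    Waters are excluded from the computation entirely; hydrogens, if present,
    participate with their own radius.  Returns ``(per_atom, per_residue)``
    dictionaries keyed by atom key and residue key; residue SASA is exactly
    the sum of its atoms' SASA.
    """
    atoms = [a for a in structure.atoms if a.residue_name not in WATER_RESIDUES]
    if not atoms:
        return {}, {}
    coords = np.array([a.coords for a in atoms])
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        r = VDW_RADII.get(a.element.strip().capitalize())
        if r is None:
            warnings.warn(
                f"unknown element {a.element!r} for {a.atom_key}; "
                f"using default radius {DEFAULT_RADIUS} Å"
            )
            r = DEFAULT_RADIUS
        radii[i] = r
    areas = shrake_rupley(coords, radii, probe=probe, n_points=n_points)
    per_atom = {a.atom_key: float(areas[i]) for i, a in enumerate(atoms)}
    per_residue: dict = {}
    for i, a in enumerate(atoms):
        per_residue[a.residue_key] = per_residue.get(a.residue_key, 0.0) + float(areas[i])
    return per_atom, per_residue
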