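"""Shrake–Rupley solvent-accessible surface area.

Each heavy atom is inflated by the probe radius and covered with a
deterministic Fibonacci-spiral point set; the accessible fraction is the
fraction of points not inside any neighbouring inflated sphere. Defaults:
1.4 Å probe, 960 points per atom (quadrature error well under 1% on
isolated spheres).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .pdb import Structure

__all__ = ["sphere_points", "compute_sasa", "atom_sasa"]

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> np.ndarray:
    """Per-atom accessible area (Å²) for atoms with van der Waals ``radii``."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    inflated = radii + probe_radius
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.empty(n)
    max_r = inflated.max() if n else 0.0
    for i in range(n):
        surface = coords[i] + inflated[i] * pts
        # only neighbours whose inflated sphere can reach atom i's surface
        nbr = [j for j in tree.query_ball_point(coords[i], inflated[i] + max_r) if j != i]
        if nbr:
            d = np.linalg.norm(surface[:, None, :] - coords[nbr][None, :, :], axis=2)
            accessible = np.all(d >= inflated[nbr][None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * inflated[i] ** 2 * frac
    return areas


def compute_sasa(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> dict[int, float]:
    """Residue-level SASA map ``{residue index: area Å²}`` over protein heavy atoms."""
    idx = structure.protein_atom_indices()
    if idx.size == 0:
        raise ValueError("structure has no protein heavy atoms")
    radii = structure.atom_radii(idx)
    areas = atom_sasa(structure.coords[idx], radii, probe_radius, n_points)
    out: dict[int, float] = {}
    for a, area in zip(idx, areas):
        r = int(structure.atom_residue[a])
        out[r] = out.get(r, 0.0) + float(area)
    return out
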