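"""The 89 protein-level predictive variables.

A protein is described by its *surface* composition and a few global
descriptors:

* 20 per-residue surface coverage fractions (counts over exposed residues),
* 5 residue-category fractions (small / + / - / polar / hydrophobic),
* 15 neighbouring-pair category fractions (same chain, within 5 Å),
* the same 40 composition features weighted by solvent-accessible area,
* 9 globals: pI, total SASA (Å²), radius of gyration (Å), GRAVY, sGRAVY,
  SCE, sSCE, POL, sPOL.

The coverage and pair blocks each live on a probability simplex, and the
surface scale averages (sGRAVY/sSCE/sPOL) are by construction the
coverage-weighted means of the per-residue scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pdb import Structure
from .sasa import compute_sasa
from .scales import (
    AMINO_ACIDS,
    CATEGORIES,
    CATEGORY_PAIRS,
    PKA_TABLE,
    category_pair,
    residue_category,
    residue_scale,
)

__all__ = [
    "GLOBAL_FEATURES",
    "feature_names",
    "surface_residues",
    "neighbor_pair_fractions",
    "scale_average",
    "isoelectric_point",
    "radius_of_gyration",
    "protein_feature_vector",
    "composition_features_from_fractions",
]

DEFAULT_EXPOSURE_THRESHOLD = 2.5   # Å² of exposed residue surface
DEFAULT_NEIGHBOR_CUTOFF = 5.0      # Å, minimal heavy-atom distance

GLOBAL_FEATURES = ("pI", "SASA", "Rg", "GRAVY", "sGRAVY", "SCE", "sSCE", "POL", "sPOL")


def feature_names() -> list[str]:
    """The 89 feature names in their stable column order."""
    comp = (
        [f"frac_{aa}" for aa in AMINO_ACIDS]
        + [f"cat_{c}" for c in CATEGORIES]
        + [f"pair_{p}" for p in CATEGORY_PAIRS]
    )
    return comp + [f"w_{name}" for name in comp] + list(GLOBAL_FEATURES)


def surface_residues(sasa_map: dict[int, float], threshold: float = DEFAULT_EXPOSURE_THRESHOLD) -> set[int]:
    """Residues whose exposed area is at least ``threshold`` Å² (boundary inclusive)."""
    if threshold <= 0:
        raise ValueError("exposure threshold must be positive")
    return {r for r, area in sasa_map.items() if area >= threshold}


def neighbor_pair_fractions(
    structure: Structure,
    surface_set: set[int],
    cutoff: float = DEFAULT_NEIGHBOR_CUTOFF,
    sasa_map: dict[int, float] | None = None,
) -> tuple[pd.Series, pd.Series, bool]:
    """Category fractions of neighbouring surface-residue pairs.

    A pair is counted once per unordered residue pair on the same chain with
    minimal heavy-atom distance ≤ ``cutoff`` and both residues exposed. The
    weighted variant multiplies each pair count by the mean exposed area of
    its residues before normalising.

    Returns ``(fractions, weighted_fractions, has_pairs)``; when no pair
    exists both vectors are all-zero and ``has_pairs`` is False.
    """
    if cutoff <= 0:
        raise ValueError("neighbor cutoff must be positive")
    idx = structure.protein_atom_indices()
    keep = np.array([int(structure.atom_residue[i]) in surface_set for i in idx])
    idx = idx[keep]
    counts = dict.fromkeys(CATEGORY_PAIRS, 0.0)
    weighted = dict.fromkeys(CATEGORY_PAIRS, 0.0)
    if idx.size:
        tree = cKDTree(structure.coords[idx])
        seen: set[tuple[int, int]] = set()
        for a, b in tree.query_pairs(cutoff):
            ra = int(structure.atom_residue[idx[a]])
            rb = int(structure.atom_residue[idx[b]])
            if ra == rb:
                continue
            res_a, res_b = structure.residues[ra], structure.residues[rb]
            if res_a.chain != res_b.chain:
                continue
            pair_key = (min(ra, rb), max(ra, rb))
            if pair_key in seen:
                continue
            seen.add(pair_key)
            aa, ab = res_a.one_letter, res_b.one_letter
            if aa is None or ab is None:
                continue
            sym = category_pair(residue_category(aa), residue_category(ab))
            counts[sym] += 1.0
            if sasa_map is not None:
                weighted[sym] += 0.5 * (sasa_map.get(ra, 0.0) + sasa_map.get(rb, 0.0))
    total = sum(counts.values())
    has_pairs = total > 0
    frac = pd.Series(counts, index=list(CATEGORY_PAIRS), dtype=float)
    wfrac = pd.Series(weighted, index=list(CATEGORY_PAIRS), dtype=float)
    if has_pairs:
        frac /= total
        wtotal = wfrac.sum()
        wfrac = wfrac / wtotal if wtotal > 0 else frac.copy()
    return frac, wfrac, has_pairs


def scale_average(residues: list[str], scale: str) -> float:
    """Unweighted mean of a residue scale over one-letter codes ``residues``."""
    if not residues:
        raise ValueError("cannot average a scale over an empty residue selection")
    table = residue_scale(scale)
    return float(np.mean([table[aa] for aa in residues]))


def _net_charge(sequence: str, ph: float) -> float:
    pos = {"K", "R", "H"}
    neg = {"D", "E", "C", "Y"}
    q = 1.0 / (1.0 + 10.0 ** (ph - PKA_TABLE["nterm"]))
    q -= 1.0 / (1.0 + 10.0 ** (PKA_TABLE["cterm"] - ph))
    for aa in sequence:
        if aa in pos:
            q += 1.0 / (1.0 + 10.0 ** (ph - PKA_TABLE[aa]))
        elif aa in neg:
            q -= 1.0 / (1.0 + 10.0 ** (PKA_TABLE[aa] - ph))
    return q


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH at which the Henderson–Hasselbalch net charge vanishes (bisection on [0, 14])."""
    if not sequence:
        raise ValueError("empty sequence")
    unknown = set(sequence) - set(AMINO_ACIDS)
    if unknown:
        raise ValueError(f"non-standard residues in sequence: {sorted(unknown)}")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = _net_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def radius_of_gyration(structure: Structure) -> float:
    """Mass-unweighted RMS distance of protein heavy atoms from their centroid (Å)."""
    idx = structure.protein_atom_indices()
    if idx.size == 0:
        raise ValueError("structure has no protein heavy atoms")
    xyz = structure.coords[idx]
    centered = xyz - xyz.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def composition_features_from_fractions(frac: pd.Series) -> pd.Series:
    """Category fractions and sGRAVY/sSCE/sPOL implied by 20 coverage fractions.

    The surface scale averages are uniquely determined by the composition:
    they are the coverage-weighted means of the per-residue scales.
    """
    cats = pd.Series(0.0, index=list(CATEGORIES))
    for aa in AMINO_ACIDS:
        cats[residue_category(aa)] += frac[f"frac_{aa}" if f"frac_{aa}" in frac.index else aa]

    def wmean(scale: str) -> float:
        table = residue_scale(scale)
        return float(
            sum(
                frac[f"frac_{aa}" if f"frac_{aa}" in frac.index else aa] * table[aa]
                for aa in AMINO_ACIDS
            )
        )

    out = pd.Series({f"cat_{c}": cats[c] for c in CATEGORIES})
    out["sGRAVY"] = wmean("gravy")
    out["sSCE"] = wmean("sce")
    out["sPOL"] = wmean("pol")
    return out


@dataclass
class FeatureOptions:
    exposure_threshold: float = DEFAULT_EXPOSURE_THRESHOLD
    neighbor_cutoff: float = DEFAULT_NEIGHBOR_CUTOFF
    probe_radius: float = 1.4
    n_sphere_points: int = 960


def protein_feature_vector(structure: Structure, options: FeatureOptions | None = None) -> pd.Series:
    """Compute the full 89-feature vector for one structure.

    Raises ``ValueError`` when the exposed surface is empty (no residue
    reaches the exposure threshold).
    """
    opts = options or FeatureOptions()
    sasa_map = compute_sasa(structure, opts.probe_radius, opts.n_sphere_points)
    surf = surface_residues(sasa_map, opts.exposure_threshold)
    if not surf:
        raise ValueError("no residue exceeds the exposure threshold; surface is empty")

    surf_res = [structure.residues[r] for r in sorted(surf)]
    surf_aas = [r.one_letter for r in surf_res if r.one_letter is not None]
    if not surf_aas:
        raise ValueError("surface contains no standard residues")

    vec = pd.Series(0.0, index=feature_names())

    # unweighted coverage: count fractions over exposed residues
    n_surf = len(surf_aas)
    for aa in surf_aas:
        vec[f"frac_{aa}"] += 1.0 / n_surf
    # SASA-weighted coverage
    total_surf_area = sum(sasa_map[r] for r in surf if structure.residues[r].one_letter)
    for r in surf:
        aa = structure.residues[r].one_letter
        if aa is not None:
            vec[f"w_frac_{aa}"] += sasa_map[r] / total_surf_area

    for prefix in ("", "w_"):
        sub = pd.Series({aa: vec[f"{prefix}frac_{aa}"] for aa in AMINO_ACIDS})
        derived = composition_features_from_fractions(sub)
        for c in CATEGORIES:
            vec[f"{prefix}cat_{c}"] = derived[f"cat_{c}"]
        if prefix == "":
            vec["sGRAVY"] = derived["sGRAVY"]
            vec["sSCE"] = derived["sSCE"]
            vec["sPOL"] = derived["sPOL"]

    pairs, wpairs, _has = neighbor_pair_fractions(structure, surf, opts.neighbor_cutoff, sasa_map)
    for p in CATEGORY_PAIRS:
        vec[f"pair_{p}"] = pairs[p]
        vec[f"w_pair_{p}"] = wpairs[p]

    all_aas = [r.one_letter for r in structure.residues if r.one_letter is not None]
    vec["GRAVY"] = scale_average(all_aas, "gravy")
    vec["SCE"] = scale_average(all_aas, "sce")
    vec["POL"] = scale_average(all_aas, "pol")
    vec["pI"] = isoelectric_point("".join(all_aas))
    vec["SASA"] = float(sum(sasa_map.values()))
    vec["Rg"] = radius_of_gyration(structure)
    return vec
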