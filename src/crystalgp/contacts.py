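"""Crystal-contact identification and profiling.

A crystal contact is a surface region within 5 Å of a symmetry-related
neighbouring chain in the crystal lattice. Symmetry mates are produced by
applying the crystallographic operators from REMARK 290 (Cartesian form)
plus lattice translations within a shell of unit cells, then pruning
copies too far from the asymmetric unit to matter. Contact residues are
profiled by residue category and by *cross-chain* category pairs, and the
profiles compared between sGRAVY–sSCE quadrants with Kolmogorov–Smirnov
tests.

Only heavy atoms are considered throughout (hydrogens are typically
absent from X-ray structures).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mechanisms import ks_two_sample
from .pdb import Structure, SymmetryOp, orthogonalization_matrix
from .sasa import compute_sasa
from .scales import CATEGORIES, CATEGORY_PAIRS, category_pair, residue_category
from .protein_features import DEFAULT_EXPOSURE_THRESHOLD, surface_residues

__all__ = [
    "SymmetryNeighbor",
    "ContactProfile",
    "expand_symmetry",
    "contact_residues",
    "contact_profile",
    "contact_enrichment",
]

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 5.0  # Å
BBOX_MARGIN = 5.0             # Å added to the contact cutoff when pruning copies


@dataclass
class SymmetryNeighbor:
    coords: np.ndarray          # transformed heavy-atom coordinates
    atom_residue: np.ndarray    # indices into the parent structure's residues
    operator_index: int
    lattice_shift: tuple[int, int, int]


def expand_symmetry(structure: Structure, shell: int = 1) -> list[SymmetryNeighbor]:
    """Symmetry-mate copies of the protein within ±``shell`` unit cells.

    Requires CRYST1 and at least one REMARK 290 operator; raises with
    guidance otherwise. The identity copy (identity operator, zero shift)
    is excluded; copies whose bounding box is farther than the contact
    cutoff plus margin from the asymmetric unit are pruned.
    """
    if structure.cell is None:
        raise ValueError(
            "structure has no CRYST1 record; crystal-contact analysis needs the unit cell"
        )
    if not structure.symmetry_ops:
        raise ValueError(
            "structure has no REMARK 290 SMTRY operators; cannot build symmetry mates"
        )
    A = orthogonalization_matrix(structure.cell)
    idx = structure.protein_atom_indices()
    base = structure.coords[idx]
    atom_res = structure.atom_residue[idx]
    lo, hi = base.min(axis=0), base.max(axis=0)
    reach = DEFAULT_CONTACT_CUTOFF + BBOX_MARGIN

    neighbors = []
    shifts = list(itertools.product(range(-shell, shell + 1), repeat=3))
    for k, op in enumerate(structure.symmetry_ops):
        for shift in shifts:
            if op.is_identity and shift == (0, 0, 0):
                continue
            t = op.translation + A @ np.asarray(shift, dtype=float)
            moved = base @ op.rotation.T + t
            mlo, mhi = moved.min(axis=0), moved.max(axis=0)
            gap = np.maximum(np.maximum(lo - mhi, mlo - hi), 0.0)
            if np.linalg.norm(gap) > reach:
                continue
            neighbors.append(
                SymmetryNeighbor(
                    coords=moved, atom_residue=atom_res.copy(),
                    operator_index=k, lattice_shift=shift,
                )
            )
    return neighbors


def contact_residues(
    structure: Structure,
    neighbors: list[SymmetryNeighbor],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    surface_set: set[int] | None = None,
) -> set[int]:
    """Surface residues with any heavy atom within ``cutoff`` of a neighbour chain."""
    if cutoff <= 0:
        return set()
    if surface_set is None:
        surface_set = surface_residues(compute_sasa(structure), DEFAULT_EXPOSURE_THRESHOLD)
    idx = structure.protein_atom_indices()
    keep = np.array([int(structure.atom_residue[i]) in surface_set for i in idx])
    idx = idx[keep]
    if idx.size == 0 or not neighbors:
        return set()
    own = structure.coords[idx]
    tree = cKDTree(own)
    found: set[int] = set()
    for nb in neighbors:
        pairs = tree.query_ball_point(nb.coords, cutoff)
        for hits in pairs:
            for a in hits:
                found.add(int(structure.atom_residue[idx[a]]))
    return found


@dataclass
class ContactProfile:
    protein_id: str
    contact_residues: set[int]
    category_fractions: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    pair_fractions: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def as_row(self) -> pd.Series:
        row = pd.Series(
            {f"contact_cat_{c}": self.category_fractions.get(c, 0.0) for c in CATEGORIES}
        )
        for p in CATEGORY_PAIRS:
            row[f"contact_pair_{p}"] = self.pair_fractions.get(p, 0.0)
        row["n_contact_residues"] = float(len(self.contact_residues))
        return row


def contact_profile(
    structure: Structure,
    contacts: set[int],
    neighbors: list[SymmetryNeighbor],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    protein_id: str = "protein",
) -> ContactProfile:
    """Category and cross-chain pair composition of the contact residues.

    Pair fractions count unordered category pairs between a contact residue
    and the neighbour-chain residues within ``cutoff`` of it — interactions
    between residues on *different* chains, one pair per residue pair.
    """
    cats = pd.Series(0.0, index=list(CATEGORIES))
    for r in contacts:
        aa = structure.residues[r].one_letter
        if aa is not None:
            cats[residue_category(aa)] += 1.0
    if cats.sum() > 0:
        cats /= cats.sum()

    pairs = pd.Series(0.0, index=list(CATEGORY_PAIRS))
    idx = structure.protein_atom_indices()
    keep = np.array([int(structure.atom_residue[i]) in contacts for i in idx])
    idx = idx[keep]
    if idx.size and neighbors:
        tree = cKDTree(structure.coords[idx])
        seen: set[tuple[int, int, int, tuple[int, int, int]]] = set()
        for nb in neighbors:
            hits = tree.query_ball_point(nb.coords, cutoff)
            for j, own_hits in enumerate(hits):
                rb = int(nb.atom_residue[j])
                for a in own_hits:
                    ra = int(structure.atom_residue[idx[a]])
                    key = (ra, rb, nb.operator_index, nb.lattice_shift)
                    if key in seen:
                        continue
                    seen.add(key)
                    aa = structure.residues[ra].one_letter
                    ab = structure.residues[rb].one_letter
                    if aa is None or ab is None:
                        continue
                    pairs[category_pair(residue_category(aa), residue_category(ab))] += 1.0
        if pairs.sum() > 0:
            pairs /= pairs.sum()
    return ContactProfile(protein_id, set(contacts), cats, pairs)


def contact_enrichment(
    profiles: pd.DataFrame,
    quadrant_assignments: pd.DataFrame,
    alpha: float = 0.05,
    min_group_size: int = 10,
) -> pd.DataFrame:
    """Pairwise-quadrant KS tests on contact-profile features.

    ``profiles`` is a per-protein table of contact features (as produced by
    stacking :meth:`ContactProfile.as_row`); quadrants below
    ``min_group_size`` are skipped. Direction compares medians of the
    first group against the second.
    """
    rows = []
    quads = []
    for quad in sorted(quadrant_assignments["quadrant"].unique()):
        members = [
            p for p in quadrant_assignments.index[quadrant_assignments["quadrant"] == quad]
            if p in profiles.index
        ]
        if len(members) >= min_group_size:
            quads.append((quad, members))
        else:
            logger.info("quadrant %s skipped in contact enrichment (n=%d)", quad, len(members))
    feature_cols = [c for c in profiles.columns if c.startswith("contact_")]
    for (qa, ma), (qb, mb) in itertools.combinations(quads, 2):
        for feat in feature_cols:
            va = profiles.loc[ma, feat].to_numpy()
            vb = profiles.loc[mb, feat].to_numpy()
            d, p = ks_two_sample(va, vb)
            if p < alpha:
                rows.append(
                    {
                        "group_a": qa,
                        "group_b": qb,
                        "feature": feat,
                        "D": d,
                        "p_value": p,
                        "direction": "enriched" if np.median(va) > np.median(vb) else "depleted",
                    }
                )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "feature", "D", "p_value", "direction"])
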