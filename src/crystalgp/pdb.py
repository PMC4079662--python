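"""Minimal PDB reader for the structural analysis.

Parses ATOM/HETATM records (fixed-column format), the CRYST1 unit cell and
the crystallographic symmetry operators from REMARK 290 SMTRY records.
Only what the surface-feature and crystal-contact code needs is kept: heavy
atoms with coordinates, a residue table, the cell and the operator list.

Altloc policy: for duplicated (residue, atom-name) entries the highest
occupancy conformer is kept; on an occupancy tie the 'A' conformer (first
alphabetically) wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scales import THREE_TO_ONE, VDW_RADII

__all__ = ["Residue", "Structure", "SymmetryOp", "parse_structure", "orthogonalization_matrix"]

_WATERS = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Residue:
    chain: str
    seq: int
    name3: str

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.name3)


@dataclass(frozen=True)
class SymmetryOp:
    """Crystallographic operator in Cartesian form: x' = R @ x + t (t in Å)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=1e-9) and np.allclose(
            self.translation, 0.0, atol=1e-9
        )


@dataclass
class Structure:
    residues: list[Residue]
    coords: np.ndarray           # (n_atoms, 3) Å
    elements: list[str]
    atom_residue: np.ndarray     # (n_atoms,) index into residues
    het_mask: np.ndarray         # (n_atoms,) bool, True for HETATM
    cell: tuple[float, float, float, float, float, float] | None = None
    symmetry_ops: list[SymmetryOp] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("structure contains non-finite coordinates")
        if len(self.residues) and self.atom_residue.size:
            if self.atom_residue.max() >= len(self.residues):
                raise ValueError("atom references a residue outside the residue table")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def protein_atom_indices(self) -> np.ndarray:
        """Indices of heavy protein atoms (no HETATM, no waters, no hydrogens)."""
        keep = ~self.het_mask
        keep &= np.array([e != "H" for e in self.elements])
        return np.flatnonzero(keep)

    def atom_radii(self, indices: np.ndarray) -> np.ndarray:
        radii = np.empty(indices.size)
        for k, i in enumerate(indices):
            elem = self.elements[i]
            try:
                radii[k] = VDW_RADII[elem]
            except KeyError:
                raise ValueError(f"no van der Waals radius for element {elem!r}") from None
        return radii

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def sequence(self, chain: str | None = None) -> str:
        return "".join(
            r.one_letter or "X"
            for r in self.residues
            if (chain is None or r.chain == chain) and r.name3 not in _WATERS
        )


def orthogonalization_matrix(cell: tuple[float, ...]) -> np.ndarray:
    """Fractional→Cartesian matrix (columns are the cell vectors, Å)."""
    a, b, c, alpha, beta, gamma = cell
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    sg = math.sin(math.radians(gamma))
    v = math.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
    return np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * v / sg],
        ]
    )


def _parse_float(text: str, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"malformed {what} field on line {lineno}: {text.strip()!r}") from None


def parse_structure(pdb_text: str) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Raises ``ValueError`` when no ATOM records are present or a coordinate
    field cannot be read (the error names the offending line number).
    """
    cell = None
    smtry: dict[int, dict[int, tuple[list[float], float]]] = {}
    # best[(chain, seq, name3, atom_name)] = (occupancy, altloc, element, xyz, het)
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    n_atom_records = 0

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec == "CRYST1":
            cell = tuple(
                _parse_float(line[i:j], lineno, "cell")
                for i, j in ((6, 15), (15, 24), (24, 33), (33, 40), (40, 47), (47, 54))
            )
        elif rec == "REMARK" and line[7:10] == "290" and line[13:19].startswith("SMTRY"):
            row = int(line[18]) - 1          # SMTRY1/2/3 → row 0/1/2
            opno = int(line[19:23])
            fields = line[23:].split()
            if len(fields) != 4:
                raise ValueError(f"malformed SMTRY record on line {lineno}")
            vals = [_parse_float(f, lineno, "SMTRY") for f in fields]
            smtry.setdefault(opno, {})[row] = (vals[:3], vals[3])
        elif rec in ("ATOM  ", "HETATM"):
            n_atom_records += rec == "ATOM  "
            atom_name = line[12:16].strip()
            altloc = line[16]
            name3 = line[17:20].strip()
            chain = line[21].strip() or "A"
            try:
                seq = int(line[22:26])
            except ValueError:
                raise ValueError(f"malformed residue number on line {lineno}") from None
            xyz = tuple(
                _parse_float(line[i:j], lineno, "coordinate")
                for i, j in ((30, 38), (38, 46), (46, 54))
            )
            occ_text = line[54:60].strip()
            occ = _parse_float(occ_text, lineno, "occupancy") if occ_text else 1.0
            elem = line[76:78].strip().upper()
            if not elem:
                # fall back to the atom-name convention (first non-digit char)
                elem = next((ch for ch in atom_name if ch.isalpha()), "C").upper()
            key = (chain, seq, name3, atom_name)
            het = rec == "HETATM"
            if key not in best:
                best[key] = (occ, altloc, elem, xyz, het)
                order.append(key)
            else:
                prev_occ, prev_alt, *_ = best[key]
                if occ > prev_occ or (occ == prev_occ and altloc < prev_alt):
                    best[key] = (occ, altloc, elem, xyz, het)

    if n_atom_records == 0:
        raise ValueError("no ATOM records found in PDB input")

    residues: list[Residue] = []
    res_index: dict[tuple[str, int, str], int] = {}
    coords, elements, atom_res, het_mask = [], [], [], []
    for key in order:
        chain, seq, name3, _ = key
        occ, _alt, elem, xyz, het = best[key]
        rkey = (chain, seq, name3)
        if rkey not in res_index:
            res_index[rkey] = len(residues)
            residues.append(Residue(chain, seq, name3))
        coords.append(xyz)
        elements.append(elem)
        atom_res.append(res_index[rkey])
        het_mask.append(het)

    ops: list[SymmetryOp] = []
    for opno in sorted(smtry):
        rows = smtry[opno]
        if set(rows) != {0, 1, 2}:
            raise ValueError(f"incomplete SMTRY operator {opno}")
        rot = np.array([rows[r][0] for r in range(3)])
        trans = np.array([rows[r][1] for r in range(3)])
        ops.append(SymmetryOp(rot, trans))

    return Structure(
        residues=residues,
        coords=np.asarray(coords, dtype=float),
        elements=elements,
        atom_residue=np.asarray(atom_res, dtype=int),
        het_mask=np.asarray(het_mask, dtype=bool),
        cell=cell,
        symmetry_ops=ops,
    )
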