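"""Per-residue physico-chemical scales and the five-way residue classification.

Three scales drive the surface descriptors used throughout the package:

* ``gravy`` — Kyte–Doolittle hydropathy index.
* ``sce``  — side-chain conformational entropy (kcal/mol near 300 K),
  oriented so that flexible residues (Lys, Arg, Gln, ...) score high and
  conformationally restricted ones (Gly, Ala, Pro) score ~0.
* ``pol``  — Grantham polarity.

Residues are additionally grouped into five categories used for the
coarse-grained composition features: small (S), positively charged (+),
negatively charged (-), polar (P) and hydrophobic (H).
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

__all__ = [
    "AMINO_ACIDS",
    "CATEGORIES",
    "CATEGORY_PAIRS",
    "THREE_TO_ONE",
    "residue_scale",
    "residue_category",
    "category_pair",
    "PKA_TABLE",
    "VDW_RADII",
]

#: canonical one-letter codes, alphabetical
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: the five residue categories in report order
CATEGORIES = ("S", "+", "-", "P", "H")

#: the 15 unordered category pairs, in lexicographic category order
CATEGORY_PAIRS = tuple(
    CATEGORIES[i] + CATEGORIES[j]
    for i in range(len(CATEGORIES))
    for j in range(i, len(CATEGORIES))
)

# EMBOSS pKa set used for the isoelectric point (termini included)
PKA_TABLE = {
    "nterm": 8.6,
    "cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

# Bondi van der Waals radii (Å) by element, heavy atoms of standard residues
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.20,
}


@lru_cache(maxsize=1)
def _load_table() -> dict[str, dict[str, object]]:
    text = resources.files("crystalgp.data").joinpath("residue_scales.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    table = {}
    for r in rows:
        table[r["aa"]] = {
            "name3": r["name3"],
            "gravy": float(r["gravy"]),
            "sce": float(r["sce"]),
            "pol": float(r["pol"]),
            "category": r["category"],
        }
    if set(table) != set(AMINO_ACIDS):
        raise RuntimeError("residue scale table does not cover the 20 standard residues")
    return table


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def residue_scale(scale: str) -> dict[str, float]:
    """Return ``{one-letter residue: value}`` for ``scale`` in {gravy, sce, pol}."""
    if scale not in ("gravy", "sce", "pol"):
        raise ValueError(f"unknown scale {scale!r}; expected gravy, sce or pol")
    return {aa: _load_table()[aa][scale] for aa in AMINO_ACIDS}


def residue_category(aa: str) -> str:
    """Category symbol (S, +, -, P or H) for a one-letter residue code."""
    try:
        return _load_table()[aa]["category"]
    except KeyError:
        raise KeyError(f"unknown residue code {aa!r}") from None


def category_pair(cat_a: str, cat_b: str) -> str:
    """Canonical unordered pair symbol for two categories (e.g. '+-' not '-+')."""
    order = {c: i for i, c in enumerate(CATEGORIES)}
    a, b = sorted((cat_a, cat_b), key=order.__getitem__)
    return a + b
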