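"""Residue topology: canonical atom order, chi definitions, ideal templates.

Ideal heavy-atom geometry comes from the chemical component dictionary
templates bundled with biotite; this module wraps them with the bookkeeping
the sampler needs (which atoms move when a chi angle turns, which pairs are
bonded and therefore exempt from clash checks, van der Waals radii).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

AROMATIC_RESIDUES = frozenset({"HIS", "TYR", "PHE", "TRP"})

STANDARD_RESIDUES = (
    "GLY", "ALA", "SER", "CYS", "THR", "VAL", "LEU", "ILE", "MET",
    "PHE", "TYR", "TRP", "HIS", "ASP", "ASN", "GLU", "GLN", "LYS",
    "ARG", "PRO",
)

#: chi angles as ordered 4-atom name tuples
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "SD"),
        ("CB", "CG", "SD", "CE"),
    ],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ],
    "GLN": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "ARG": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ],
    "PRO": [("N", "CA", "CB", "CG")],
    "GLY": [],
    "ALA": [],
}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: element symbol for standard protein heavy-atom names (first character)
def element_of(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    ch = name[0]
    if ch.isdigit():
        ch = name[1]
    return ch.upper()


def is_hydrogen_name(atom_name: str) -> bool:
    return element_of(atom_name) in ("H", "D")


def n_chi(residue_type: str) -> int:
    try:
        return len(CHI_ATOMS[residue_type])
    except KeyError:
        raise KeyError(f"unknown residue type {residue_type!r}") from None


@lru_cache(maxsize=None)
def ideal_template(residue_type: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Heavy-atom names (canonical order) and ideal coordinates for a residue.

    Canonical order is backbone N, CA, C, O first, then side-chain atoms by
    increasing remoteness, which is the order the dictionary templates use.
    OXT and hydrogens are dropped.
    """
    if residue_type not in STANDARD_RESIDUES:
        raise KeyError(f"unknown residue type {residue_type!r}")
    import biotite.structure.info as info

    tmpl = info.residue(residue_type)
    keep = [
        i
        for i, (name, el) in enumerate(zip(tmpl.atom_name, tmpl.element))
        if el not in ("H", "D") and name != "OXT"
    ]
    names = tuple(str(tmpl.atom_name[i]) for i in keep)
    coords = np.asarray(tmpl.coord[keep], dtype=float)
    return names, coords


def canonical_atom_order(residue_type: str) -> tuple[str, ...]:
    return ideal_template(residue_type)[0]


@lru_cache(maxsize=None)
def _bond_list(residue_type: str) -> tuple[tuple[str, str], ...]:
    """Intra-residue heavy-atom bonds, from the dictionary template."""
    import biotite.structure.info as info

    tmpl = info.residue(residue_type)
    names, _ = ideal_template(residue_type)
    name_set = set(names)
    bonds = []
    arr, _kinds = tmpl.bonds.get_all_bonds()
    atom_names = [str(n) for n in tmpl.atom_name]
    for i, partners in enumerate(arr):
        for j in partners:
            if j < 0 or j <= i:
                continue
            a, b = atom_names[i], atom_names[int(j)]
            if a in name_set and b in name_set:
                bonds.append((a, b))
    return tuple(bonds)


@lru_cache(maxsize=None)
def excluded_pairs(residue_type: str) -> frozenset[frozenset[str]]:
    """Atom-name pairs within two bonds (1-2 and 1-3) inside one residue."""
    bonds = _bond_list(residue_type)
    adj: dict[str, set[str]] = {}
    for a, b in bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    pairs: set[frozenset[str]] = set()
    for a, b in bonds:
        pairs.add(frozenset((a, b)))
    for center, nbrs in adj.items():
        for a in nbrs:
            for b in nbrs:
                if a < b:
                    pairs.add(frozenset((a, b)))
    return frozenset(pairs)


@lru_cache(maxsize=None)
def chi_downstream(residue_type: str, chi_index: int) -> tuple[str, ...]:
    """Atoms that move when chi_{chi_index} (1-based) rotates.

    These are the atoms on the far side of the rotating bond: everything
    connected to the chi's third atom when the bond between the second and
    third chi atoms is cut, minus the axis atom itself.
    """
    chis = CHI_ATOMS[residue_type]
    if not 1 <= chi_index <= len(chis):
        raise IndexError(
            f"{residue_type} has {len(chis)} chi angle(s); got index {chi_index}"
        )
    a, b, c, _ = chis[chi_index - 1]
    adj: dict[str, set[str]] = {}
    for x, y in _bond_list(residue_type):
        adj.setdefault(x, set()).add(y)
        adj.setdefault(y, set()).add(x)
    # flood fill from c with the b-c bond removed
    seen = {b, c}
    stack = [c]
    while stack:
        cur = stack.pop()
        for nxt in adj.get(cur, ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    # the first chi atom can be reached through a ring (proline); it sits on
    # the fixed side together with the axis atoms
    seen -= {a, b, c}
    order = canonical_atom_order(residue_type)
    return tuple(n for n in order if n in seen)
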