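"""Multiconformer structural data model and PDB I/O.

The in-memory model is a shallow hierarchy: a :class:`StructureModel` holds
:class:`ResidueModel` objects in chain/sequence order, each of which holds one
to five :class:`Conformer` objects (alternative conformations with altloc
labels and occupancy weights), each of which holds :class:`Atom` objects.

File parsing and formatting is delegated to gemmi; this module only converts
between gemmi's atom-level altloc representation and the conformer-grouped
model used by the rest of the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import residues as res_info

__all__ = [
    "Atom",
    "Conformer",
    "ResidueModel",
    "StructureModel",
    "ParseError",
    "read_pdb",
    "write_pdb",
    "strip_to_single_conformer",
    "conformer_rmsd",
]

_EIGHT_PI2 = 8.0 * math.pi**2


class ParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) Angstrom
    b_iso: float = 15.0  # Angstrom^2
    occupancy: float = 1.0
    u_aniso: np.ndarray | None = None  # (3,3) Angstrom^2, displacement tensor

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float).reshape(3)
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, dtype=float).reshape(3, 3)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def validate(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0 + 1e-9:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.b_iso > 0:
            raise ValueError(f"atom {self.name}: non-positive B-factor {self.b_iso}")
        if self.u_aniso is not None:
            b_equiv = np.trace(self.u_aniso) / 3.0 * _EIGHT_PI2
            if b_equiv > 0 and abs(b_equiv - self.b_iso) > 0.1 * self.b_iso:
                warnings.warn(
                    f"atom {self.name}: anisotropic tensor (B_eq {b_equiv:.1f}) "
                    f"inconsistent with B_iso {self.b_iso:.1f}",
                    stacklevel=2,
                )

    def copy(self) -> "Atom":
        return Atom(
            self.name,
            self.element,
            self.pos.copy(),
            self.b_iso,
            self.occupancy,
            None if self.u_aniso is None else self.u_aniso.copy(),
        )


@dataclass
class Conformer:
    residue_type: str
    atoms: list[Atom]
    altloc: str = ""
    occupancy: float = 1.0

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)

    @coords.setter
    def coords(self, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float)
        for atom, pos in zip(self.atoms, value, strict=True):
            atom.pos = pos.copy()

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.residue_type} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def side_chain_atoms(self) -> list[Atom]:
        return [
            a
            for a in self.heavy_atoms()
            if a.name not in res_info.BACKBONE_ATOMS
        ]

    def copy(self) -> "Conformer":
        return Conformer(
            self.residue_type,
            [a.copy() for a in self.atoms],
            self.altloc,
            self.occupancy,
        )

    def set_occupancy(self, occ: float) -> None:
        self.occupancy = float(occ)
        for a in self.atoms:
            a.occupancy = float(occ)


def conformer_rmsd(a: Conformer, b: Conformer, subset: str = "all") -> float:
    """Name-paired RMSD between two conformers of the same residue type.

    No superposition is applied: the models are assumed to share a frame, so
    a rigid displacement counts as real motion.  ``subset`` is one of
    ``"all"`` (heavy atoms), ``"backbone"``, or ``"sidechain"`` (falls back
    to all heavy atoms when the residue has no side chain).
    """
    if subset == "backbone":
        names = [n for n in res_info.BACKBONE_ATOMS if a.has_atom(n) and b.has_atom(n)]
    else:
        names = [
            at.name
            for at in a.heavy_atoms()
            if b.has_atom(at.name)
            and (subset == "all" or at.name not in res_info.BACKBONE_ATOMS)
        ]
        if subset == "sidechain" and not names:
            names = [at.name for at in a.heavy_atoms() if b.has_atom(at.name)]
    if not names:
        raise ValueError("no common atoms for RMSD")
    pa = np.array([a.atom(n).pos for n in names])
    pb = np.array([b.atom(n).pos for n in names])
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


@dataclass
class ResidueModel:
    chain: str
    seq_id: int
    conformers: list[Conformer]

    MAX_CONFORMERS = 5

    @property
    def residue_type(self) -> str:
        return self.conformers[0].residue_type

    @property
    def occupancy_sum(self) -> float:
        return float(sum(c.occupancy for c in self.conformers))

    def validate(self) -> None:
        if not 1 <= len(self.conformers) <= self.MAX_CONFORMERS:
            raise ValueError(
                f"residue {self.chain}{self.seq_id}: {len(self.conformers)} conformers"
            )
        if self.occupancy_sum > 1.0 + 1e-6:
            raise ValueError(
                f"residue {self.chain}{self.seq_id}: occupancies sum to "
                f"{self.occupancy_sum:.4f} > 1"
            )

    def copy(self) -> "ResidueModel":
        return ResidueModel(self.chain, self.seq_id, [c.copy() for c in self.conformers])

    def all_atoms(self) -> list[Atom]:
        return [a for c in self.conformers for a in c.atoms]

    def coords_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.array([a.pos for a in self.all_atoms()])
        return pts.min(axis=0), pts.max(axis=0)


@dataclass
class StructureModel:
    residues: list[ResidueModel] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def get(self, chain: str, seq_id: int) -> ResidueModel:
        for r in self.residues:
            if r.chain == chain and r.seq_id == seq_id:
                return r
        raise KeyError(f"no residue {chain}{seq_id}")

    def copy(self) -> "StructureModel":
        return StructureModel([r.copy() for r in self.residues], dict(self.annotations))

    def all_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.all_atoms()]

    def coords_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.array([a.pos for a in self.all_atoms()])
        return pts.min(axis=0), pts.max(axis=0)


# ---------------------------------------------------------------------------
# PDB reading


def _scan_pdb_records(path: str) -> None:
    """Light pre-validation so malformed records fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                raise ParseError(
                    f"line {lineno}: MODEL/ENDMDL multi-model files are not supported"
                )
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"line {lineno}: truncated {rec} record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                if line[54:60].strip():
                    float(line[54:60])
                if line[60:66].strip():
                    float(line[60:66])
                int(line[22:26])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed {rec} record: {exc}") from None
            if line[26] != " ":
                raise ParseError(
                    f"line {lineno}: insertion codes are not supported"
                )


def _atom_from_gemmi(ga: gemmi.Atom) -> Atom:
    u = None
    if ga.aniso.nonzero():
        a = ga.aniso
        u = np.array(
            [
                [a.u11, a.u12, a.u13],
                [a.u12, a.u22, a.u23],
                [a.u13, a.u23, a.u33],
            ]
        )  # U convention, A^2 (B = 8 pi^2 U)
    return Atom(
        name=ga.name,
        element=ga.element.name,
        pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
        b_iso=float(ga.b_iso),
        occupancy=float(ga.occ),
        u_aniso=u,
    )


def _canonical_sort(atoms: list[Atom], residue_type: str) -> list[Atom]:
    try:
        order = {n: i for i, n in enumerate(res_info.canonical_atom_order(residue_type))}
    except KeyError:
        order = {}
    heavy = [a for a in atoms if not a.is_hydrogen]
    hydro = [a for a in atoms if a.is_hydrogen]
    heavy.sort(key=lambda a: order.get(a.name, len(order) + 1))
    return heavy + hydro


def read_pdb(path: str, strip_hydrogens: bool = False) -> StructureModel:
    """Read a (multiconformer) PDB file into a :class:`StructureModel`.

    Atoms sharing an altloc letter form one conformer; altloc-blank atoms in
    a residue that also has lettered atoms (a shared backbone, typically) are
    replicated into every lettered conformer.
    """
    _scan_pdb_records(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no coordinates")
    model = StructureModel(annotations={"source": str(path)})
    for chain in st[0]:
        for gres in chain:
            if gres.name in ("HOH", "WAT"):
                continue
            by_alt: dict[str, list[Atom]] = {}
            for ga in gres:
                alt = ga.altloc if ga.altloc != "\0" else ""
                atom = _atom_from_gemmi(ga)
                if strip_hydrogens and atom.is_hydrogen:
                    continue
                bucket = by_alt.setdefault(alt.strip(), [])
                if any(a.name == atom.name for a in bucket):
                    raise ParseError(
                        f"{chain.name}{gres.seqid.num} {gres.name}: duplicate atom "
                        f"{atom.name!r} within altloc {alt or 'blank'!r}"
                    )
                bucket.append(atom)
            if not by_alt:
                continue
            shared = by_alt.pop("", None)
            conformers = []
            if by_alt:
                for alt in sorted(by_alt):
                    atoms = [a.copy() for a in shared] if shared else []
                    atoms += by_alt[alt]
                    occ = by_alt[alt][0].occupancy
                    conformers.append(
                        Conformer(
                            gres.name,
                            _canonical_sort(atoms, gres.name),
                            altloc=alt,
                            occupancy=occ,
                        )
                    )
            else:
                conformers.append(
                    Conformer(
                        gres.name,
                        _canonical_sort(shared, gres.name),
                        altloc="",
                        occupancy=shared[0].occupancy,
                    )
                )
            residue = ResidueModel(chain.name, gres.seqid.num, conformers)
            residue.validate()
            model.residues.append(residue)
    model.residues.sort(key=lambda r: (r.chain, r.seq_id))
    return model


# ---------------------------------------------------------------------------
# PDB writing


def write_pdb(model: StructureModel, path: str) -> None:
    """Write the model as fixed-format PDB (altloc column 17, ANISOU records)."""
    st = gemmi.Structure()
    st.name = "mcbuild"
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for residue in model.residues:
        if len(residue.conformers) > 26:
            raise ValueError(
                f"residue {residue.chain}{residue.seq_id}: more than 26 conformers "
                "cannot be represented in the PDB altloc column"
            )
        chain = chains.get(residue.chain)
        if chain is None:
            chain = gemmi.Chain(residue.chain)
            chains[residue.chain] = chain
        gres = gemmi.Residue()
        gres.name = residue.residue_type
        gres.seqid = gemmi.SeqId(residue.seq_id, " ")
        gres.het_flag = "A"
        for conf in residue.conformers:
            for atom in conf.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = round(conf.occupancy, 2)
                ga.b_iso = atom.b_iso
                ga.altloc = conf.altloc if conf.altloc else "\0"
                if atom.u_aniso is not None:
                    u = atom.u_aniso
                    ga.aniso = gemmi.SMat33f(
                        u[0, 0], u[1, 1], u[2, 2], u[0, 1], u[0, 2], u[1, 2]
                    )
                gres.add_atom(ga)
        chain.add_residue(gres)
    for chain in chains.values():
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def strip_to_single_conformer(model: StructureModel) -> StructureModel:
    """Reduce every residue to one conformer and drop hydrogens.

    A residue keeps its blank-altloc conformer if it only has one, otherwise
    the altloc-A conformer; residues whose lettered conformers lack an A keep
    the lexicographically first label (with a warning).  The retained
    conformer's occupancy is reset to 1.
    """
    out = StructureModel(annotations=dict(model.annotations))
    for residue in model.residues:
        if len(residue.conformers) == 1:
            keep = residue.conformers[0]
        else:
            by_alt = {c.altloc: c for c in residue.conformers}
            if "A" in by_alt:
                keep = by_alt["A"]
            else:
                label = sorted(by_alt)[0]
                keep = by_alt[label]
                warnings.warn(
                    f"residue {residue.chain}{residue.seq_id}: no altloc A; "
                    f"keeping {label!r}",
                    stacklevel=2,
                )
        new = keep.copy()
        new.atoms = [a for a in new.atoms if not a.is_hydrogen]
        new.altloc = ""
        new.set_occupancy(1.0)
        out.residues.append(ResidueModel(residue.chain, residue.seq_id, [new]))
    return out
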