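"""Candidate conformer enumeration for one residue.

The sampling moves mirror the staged residue search of the builder:

* rigid backbone translations along local (or anisotropic-B principal) axes,
* Calpha-Cbeta-Cgamma angle bends for aromatic residues,
* chi-dihedral sweeps around idealized rotamer modes,
* endo/exo ring pucker sweeps for proline,
* hard-sphere clash and RMSD redundancy pruning,
* B-factor multiplier expansion.

All operations are pure: the same inputs produce the same candidate list in
the same order.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import residues as res_info
from .geometry import bond_angle, dihedral, rotate_about_bond, rotation_about_axis
from .structure import Conformer, ResidueModel, conformer_rmsd

__all__ = [
    "SamplingConfig",
    "RotamerLibrary",
    "default_library",
    "measure_chi",
    "set_chi",
    "sample_backbone",
    "sample_aromatic_angle",
    "sample_chi",
    "sample_proline_pucker",
    "prune_candidates",
    "sample_bfactors",
]


@dataclass
class SamplingConfig:
    """Tunable constants of the candidate search.

    Defaults are the builder's published operating point: 0.1 A backbone
    translation steps out to 0.3 A, +/-3.75 deg aromatic-angle steps out to
    +/-7.5 deg, chi sweeps every 6 deg for 24 deg either side of a rotamer
    mode, a 0.01 A redundancy threshold, B multipliers 0.5-1.5 in steps of
    0.2, at most five conformers, and a 0.2 occupancy floor (0.3 in EM mode).
    """

    bb_step: float = 0.1
    bb_amplitude: float = 0.3
    arom_step: float = 3.75
    arom_range: float = 7.5
    chi_step: float = 6.0
    chi_range: float = 24.0
    redundancy_rmsd: float = 0.01
    b_multipliers: tuple[float, ...] = (0.5, 0.7, 0.9, 1.1, 1.3, 1.5)
    cardinality: int = 5
    threshold: float = 0.2
    overlap_factor: float = 0.75
    qp_keep: int = 15  # candidate cap after the QP reduction step

    def __post_init__(self) -> None:
        if self.bb_step <= 0 or self.arom_step <= 0 or self.chi_step <= 0:
            raise ValueError("steps must be positive")
        if self.bb_amplitude < 0 or self.arom_range < self.arom_step - 1e-9:
            if self.arom_range != 0:
                raise ValueError("range must be >= step")
        if self.chi_range < self.chi_step:
            raise ValueError("chi range must be >= chi step")
        if self.threshold * self.cardinality > 1.0 + 1e-9:
            raise ValueError("threshold * cardinality must not exceed 1")

    @classmethod
    def for_em(cls, **kwargs) -> "SamplingConfig":
        kwargs.setdefault("threshold", 0.3)
        return cls(**kwargs)


@dataclass
class RotamerLibrary:
    """Modal chi angles per residue type, keyed by rotamer name."""

    rotamers: dict[str, list[tuple[str, tuple[float, ...]]]] = field(default_factory=dict)

    def names(self, residue_type: str) -> list[str]:
        return [name for name, _ in self.rotamers.get(residue_type, [])]

    def chis(self, residue_type: str, name: str) -> tuple[float, ...]:
        for n, chis in self.rotamers.get(residue_type, []):
            if n == name:
                return chis
        raise KeyError(f"{residue_type} has no rotamer {name!r}")

    def modal_values(self, residue_type: str, chi_index: int) -> list[tuple[str, float]]:
        """(name, modal value) for one chi (1-based), skipping shorter entries."""
        out = []
        for name, chis in self.rotamers.get(residue_type, []):
            if chi_index <= len(chis):
                out.append((name, chis[chi_index - 1]))
        return out


_library_cache: RotamerLibrary | None = None


def default_library() -> RotamerLibrary:
    """The packaged compact modal-chi rotamer table."""
    global _library_cache
    if _library_cache is None:
        lib = RotamerLibrary()
        text = (
            resources.files("mcbuild").joinpath("data/rotamers.tsv").read_text()
        )
        for row in csv.reader(text.splitlines(), delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            res, name, *chis = row
            lib.rotamers.setdefault(res, []).append(
                (name, tuple(float(c) for c in chis if c != ""))
            )
        _library_cache = lib
    return _library_cache


# ---------------------------------------------------------------------------
# chi measurement and manipulation


def measure_chi(conf: Conformer, chi_index: int) -> float:
    names = res_info.CHI_ATOMS[conf.residue_type][chi_index - 1]
    return dihedral(*(conf.atom(n).pos for n in names))


def set_chi(conf: Conformer, chi_index: int, value: float) -> None:
    """Rotate the atoms downstream of chi_{chi_index} so the torsion equals *value*.

    The rotation is rigid, so all internal geometry not involving the sampled
    torsion is preserved exactly.
    """
    names = res_info.CHI_ATOMS[conf.residue_type][chi_index - 1]
    current = measure_chi(conf, chi_index)
    delta = value - current
    moved = res_info.chi_downstream(conf.residue_type, chi_index)
    p1 = conf.atom(names[1]).pos
    p2 = conf.atom(names[2]).pos
    for name in moved:
        if conf.has_atom(name):
            atom = conf.atom(name)
            atom.pos = rotate_about_bond(atom.pos, p1, p2, delta)


# ---------------------------------------------------------------------------
# backbone translation sampling


def _backbone_axes(conf: Conformer) -> np.ndarray:
    """Translation axes: principal axes of the Cbeta anisotropic tensor when
    present, otherwise the local Calpha-Cbeta, C-N, and cross-product frame.

    Glycine uses an idealized virtual Cbeta for the frame.
    """
    ca = conf.atom("CA").pos
    c = conf.atom("C").pos
    n = conf.atom("N").pos
    if conf.has_atom("CB"):
        cb_atom = conf.atom("CB")
        if cb_atom.u_aniso is not None:
            w, v = np.linalg.eigh(cb_atom.u_aniso)
            return v.T  # rows = principal directions
        cb = cb_atom.pos
    else:
        # virtual Cbeta from the backbone frame (tetrahedral construction)
        b1 = (n - ca) / np.linalg.norm(n - ca)
        b2 = (c - ca) / np.linalg.norm(c - ca)
        bisector = -(b1 + b2)
        bisector /= np.linalg.norm(bisector)
        perp = np.cross(b2, b1)
        perp /= np.linalg.norm(perp)
        ang = math.radians(54.0)
        cb = ca + 1.53 * (math.cos(ang) * bisector + math.sin(ang) * perp)
    a1 = cb - ca
    a1 /= np.linalg.norm(a1)
    a2 = n - c
    a2 /= np.linalg.norm(a2)
    a3 = np.cross(a1, a2)
    a3 /= np.linalg.norm(a3)
    return np.array([a1, a2, a3])


def sample_backbone(residue: ResidueModel, config: SamplingConfig) -> list[Conformer]:
    """Rigid whole-residue translations along three local axes.

    Displacement magnitudes are +/-step, +/-2*step, ... out to the amplitude
    along each axis independently, plus the identity (19 conformers at the
    defaults).  The side chain is carried along: internal geometry is exactly
    preserved.
    """
    out: list[Conformer] = []
    for conf in residue.conformers:
        for name in ("N", "CA", "C", "O"):
            if not conf.has_atom(name):
                raise ValueError(
                    f"residue {residue.chain}{residue.seq_id}: missing backbone "
                    f"atom {name}"
                )
        out.append(conf.copy())
        if config.bb_amplitude <= 0:
            continue
        axes = _backbone_axes(conf)
        n_steps = int(round(config.bb_amplitude / config.bb_step))
        for axis in axes:
            for i in range(1, n_steps + 1):
                for sign in (+1.0, -1.0):
                    shift = sign * i * config.bb_step * axis
                    new = conf.copy()
                    for atom in new.atoms:
                        atom.pos = atom.pos + shift
                    out.append(new)
    return out


# ---------------------------------------------------------------------------
# aromatic angle sampling


def sample_aromatic_angle(conf: Conformer, config: SamplingConfig) -> list[Conformer]:
    """Bend the Calpha-Cbeta-Cgamma angle for aromatic residues.

    Offsets run from -range to +range in steps of the configured step (five
    partial conformations at the defaults).  The gamma-and-beyond moiety is
    rotated about the normal of the CA-CB-CG plane through CB, which realizes
    the angle change with minimal motion.  Non-aromatic residues are returned
    unchanged.
    """
    if conf.residue_type not in res_info.AROMATIC_RESIDUES:
        return [conf]
    for name in ("CB", "CG"):
        if not conf.has_atom(name):
            raise ValueError(f"{conf.residue_type}: missing atom {name}")
    ca = conf.atom("CA").pos
    cb = conf.atom("CB").pos
    cg = conf.atom("CG").pos
    normal = np.cross(ca - cb, cg - cb)
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        raise ValueError("degenerate CA-CB-CG geometry")
    normal /= nn
    moved = res_info.chi_downstream(conf.residue_type, 1)  # CG and beyond... via chi1
    moved = tuple(n for n in moved if n != "CB")
    n_steps = int(round(config.arom_range / config.arom_step))
    offsets = [i * config.arom_step for i in range(-n_steps, n_steps + 1)]
    out = []
    for off in offsets:
        new = conf.copy()
        if off != 0.0:
            R = rotation_about_axis(normal, off)
            for name in moved:
                if new.has_atom(name):
                    atom = new.atom(name)
                    atom.pos = (atom.pos - cb) @ R.T + cb
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# chi sweeps


def sample_chi(
    conformers: list[Conformer],
    chi_index: int,
    library: RotamerLibrary,
    config: SamplingConfig,
) -> list[Conformer]:
    """Sweep chi_{chi_index} around every library rotamer mode.

    For each input conformer and each modal value, the torsion is set to
    mode + offset for offsets -range..+range in steps of chi_step (9 values
    at the defaults).  Residues without a chi at this index yield an empty
    list (Ala/Gly) or raise (index beyond the residue's chi count).
    """
    if not conformers:
        return []
    rtype = conformers[0].residue_type
    nchi = res_info.n_chi(rtype)
    if nchi == 0:
        return []
    if chi_index > nchi:
        raise IndexError(f"{rtype} has {nchi} chi angle(s); requested {chi_index}")
    modes = library.modal_values(rtype, chi_index)
    n_steps = int(round(config.chi_range / config.chi_step))
    offsets = [i * config.chi_step for i in range(-n_steps, n_steps + 1)]
    seen_modes: list[float] = []
    out = []
    for _, mode in modes:
        if any(abs((mode - m + 180) % 360 - 180) < 1e-6 for m in seen_modes):
            continue
        seen_modes.append(mode)
        for conf in conformers:
            for off in offsets:
                new = conf.copy()
                set_chi(new, chi_index, mode + off)
                out.append(new)
    return out


# ---------------------------------------------------------------------------
# proline ring pucker


def _close_proline_ring(conf: Conformer) -> bool:
    """Adjust the CB-CG torsion (moving CD only) to restore the CD-N bond.

    Returns True when closure succeeds within 0.1 A of the ideal length.
    """
    from scipy.optimize import minimize_scalar

    ideal = 1.474
    n = conf.atom("N").pos
    cb = conf.atom("CB").pos
    cg = conf.atom("CG").pos
    cd0 = conf.atom("CD").pos.copy()

    def mismatch(delta: float) -> float:
        cd = rotate_about_bond(cd0, cb, cg, delta)
        return (np.linalg.norm(cd - n) - ideal) ** 2

    best = minimize_scalar(mismatch, bounds=(-180.0, 180.0), method="bounded")
    cd = rotate_about_bond(cd0, cb, cg, float(best.x))
    conf.atom("CD").pos = cd
    return abs(np.linalg.norm(cd - n) - ideal) <= 0.1


def sample_proline_pucker(conf: Conformer, config: SamplingConfig) -> list[Conformer]:
    """Endo and exo pyrrolidine ring puckers, each swept on the ring torsion.

    chi1 is set to +/- the library pucker mode plus offsets of
    -range..+range in chi_step increments; for every candidate the CD
    position is re-closed onto N (candidates that cannot close within 0.1 A
    of the ideal CD-N bond are discarded).
    """
    if conf.residue_type != "PRO":
        raise ValueError("proline pucker sampling requires a Pro residue")
    lib = default_library()
    n_steps = int(round(config.chi_range / config.chi_step))
    offsets = [i * config.chi_step for i in range(-n_steps, n_steps + 1)]
    out = []
    for _, mode in lib.modal_values("PRO", 1):
        for off in offsets:
            new = conf.copy()
            set_chi(new, 1, mode + off)
            if _close_proline_ring(new):
                out.append(new)
    return out


# ---------------------------------------------------------------------------
# pruning and B-factor expansion


def _internal_clash(conf: Conformer, overlap_factor: float) -> bool:
    heavy = conf.heavy_atoms()
    excluded = res_info.excluded_pairs(conf.residue_type)
    for i in range(len(heavy)):
        for j in range(i + 1, len(heavy)):
            a, b = heavy[i], heavy[j]
            if frozenset((a.name, b.name)) in excluded:
                continue
            r = res_info.VDW_RADII.get(a.element, 1.7) + res_info.VDW_RADII.get(
                b.element, 1.7
            )
            if np.linalg.norm(a.pos - b.pos) < overlap_factor * r:
                return True
    return False


def prune_candidates(
    candidates: list[Conformer], config: SamplingConfig
) -> list[Conformer]:
    """Drop self-clashing candidates, then deduplicate by all-atom RMSD.

    Clashes are hard-sphere overlaps between non-bonded heavy atoms of the
    same conformer (1-2 and 1-3 pairs exempt).  Of any pair within the
    redundancy RMSD, the earlier candidate is kept; the operation is
    idempotent.
    """
    survivors = [c for c in candidates if not _internal_clash(c, config.overlap_factor)]
    kept: list[Conformer] = []
    kept_coords: list[np.ndarray] = []
    for cand in survivors:
        coords = cand.coords
        redundant = False
        for prev in kept_coords:
            if prev.shape == coords.shape:
                rmsd = math.sqrt(float(np.mean(np.sum((prev - coords) ** 2, axis=1))))
                if rmsd < config.redundancy_rmsd:
                    redundant = True
                    break
        if not redundant:
            kept.append(cand)
            kept_coords.append(coords)
    return kept


def sample_bfactors(
    conformers: list[Conformer], config: SamplingConfig
) -> tuple[list[Conformer], list[int]]:
    """Expand each conformer into B-multiplier variants.

    Returns the variants plus a parallel list mapping each variant to the
    index of its parent conformer (the geometric identity used when counting
    distinct conformations).
    """
    if not conformers:
        raise ValueError("conformer list must be non-empty")
    if any(m <= 0 for m in config.b_multipliers):
        raise ValueError("B multipliers must be positive")
    out: list[Conformer] = []
    parents: list[int] = []
    for i, conf in enumerate(conformers):
        for m in config.b_multipliers:
            new = conf.copy()
            for atom in new.atoms:
                atom.b_iso *= m
                if atom.u_aniso is not None:
                    atom.u_aniso = atom.u_aniso * m
            out.append(new)
            parents.append(i)
    return out, parents
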