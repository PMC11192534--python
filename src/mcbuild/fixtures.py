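"""Synthetic ground-truth structures and end-to-end test scenarios.

Peptides are built in an extended conformation from ideal-geometry residue
templates; ground-truth alternative conformations are installed by rotating
side-chain chi angles to library rotamer modes with chosen occupancies; the
matching noisy map comes from the synthetic-data generator.  Together these
provide scenarios with known statistical structure for exercising the full
build pipeline without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import residues as res_info
from .density import DensityMap, SyntheticSpec, make_synthetic_map
from .geometry import place_atom
from .sampling import default_library, set_chi
from .structure import (
    Atom,
    Conformer,
    ResidueModel,
    StructureModel,
    strip_to_single_conformer,
)

__all__ = ["ScenarioSpec", "SiteSpec", "build_ideal_peptide", "make_scenario"]

# extended-chain backbone torsions and inter-residue link geometry
PHI_DEFAULT = -139.0
PSI_DEFAULT = 135.0
OMEGA = 180.0
PHI_PRO = -75.0
PEPTIDE_BOND = 1.329  # C-N, Angstrom
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
DEFAULT_B = 15.0


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) minimizing ||R P + t - Q||."""
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


def _template_geom(residue_type: str) -> dict[str, np.ndarray]:
    names, coords = res_info.ideal_template(residue_type)
    return dict(zip(names, coords))


def build_ideal_peptide(
    sequence: list[str] | tuple[str, ...],
    b_iso: float = DEFAULT_B,
    chain: str = "A",
) -> StructureModel:
    """Extended-chain peptide with ideal bond lengths and angles.

    Intra-residue geometry (including side chains) is taken rigidly from the
    ideal residue templates; consecutive residues are linked with standard
    peptide-bond geometry.  Every residue is a single conformer with
    occupancy 1 and uniform isotropic B.
    """
    sequence = [s.upper() for s in sequence]
    for rt in sequence:
        if rt not in res_info.STANDARD_RESIDUES:
            raise ValueError(f"unknown residue type {rt!r}")
    model = StructureModel(annotations={"ideal_peptide": "-".join(sequence)})
    prev_n = prev_ca = prev_c = None
    for i, rt in enumerate(sequence):
        tmpl = _template_geom(rt)
        d_nca = np.linalg.norm(tmpl["CA"] - tmpl["N"])
        d_cac = np.linalg.norm(tmpl["C"] - tmpl["CA"])
        from .geometry import bond_angle

        ang_ncac = bond_angle(tmpl["N"], tmpl["CA"], tmpl["C"])
        phi = PHI_PRO if rt == "PRO" else PHI_DEFAULT
        if i == 0:
            n = np.zeros(3)
            ca = np.array([d_nca, 0.0, 0.0])
            ang = np.radians(180.0 - ang_ncac)
            c = ca + d_cac * np.array([np.cos(ang), np.sin(ang), 0.0])
        else:
            n = place_atom(prev_n, prev_ca, prev_c, PEPTIDE_BOND, ANGLE_CA_C_N, PSI_DEFAULT)
            ca = place_atom(prev_ca, prev_c, n, d_nca, ANGLE_C_N_CA, OMEGA)
            c = place_atom(prev_c, n, ca, d_cac, ang_ncac, phi)
        # graft the rigid template onto the built backbone triad
        R, t = _kabsch(
            np.array([tmpl["N"], tmpl["CA"], tmpl["C"]]), np.array([n, ca, c])
        )
        atoms = []
        for name in res_info.canonical_atom_order(rt):
            pos = R @ tmpl[name] + t
            atoms.append(
                Atom(name, res_info.element_of(name), pos, b_iso=b_iso, occupancy=1.0)
            )
        conf = Conformer(rt, atoms, altloc="", occupancy=1.0)
        # carbonyl O points anti to the next N: set psi-dependent placement
        d_co = np.linalg.norm(tmpl["O"] - tmpl["C"])
        ang_caco = bond_angle(tmpl["CA"], tmpl["C"], tmpl["O"])
        conf.atom("O").pos = place_atom(n, ca, c, d_co, ang_caco, PSI_DEFAULT + 180.0)
        model.residues.append(ResidueModel(chain, i + 1, [conf]))
        prev_n, prev_ca, prev_c = n, ca, c
    return model


@dataclass
class SiteSpec:
    """Ground-truth conformations at one site: rotamer names and occupancies."""

    rotamers: list[str]
    occupancies: list[float]

    def __post_init__(self) -> None:
        if len(self.rotamers) != len(self.occupancies):
            raise ValueError("rotamers and occupancies must align")
        if not 1 <= len(self.rotamers) <= 5:
            raise ValueError("1-5 conformers per site")
        if abs(sum(self.occupancies) - 1.0) > 1e-9:
            raise ValueError("site occupancies must sum to 1")


@dataclass
class ScenarioSpec:
    """A complete synthetic study condition."""

    sequence: list[str]
    sites: dict[int, SiteSpec] = field(default_factory=dict)  # seq_id -> spec
    resolution: float = 1.5
    seed: int = 0
    shake_scale: float = 0.2
    noise_scale: float = 0.5
    base_resolution: float = 0.8
    mode: str = "xray"
    b_iso: float = DEFAULT_B


def _install_site(residue: ResidueModel, site: SiteSpec) -> None:
    lib = default_library()
    base = residue.conformers[0]
    rt = base.residue_type
    nchi = res_info.n_chi(rt)
    conformers = []
    for label, (rot, occ) in zip("ABCDE", zip(site.rotamers, site.occupancies)):
        conf = base.copy()
        chis = lib.chis(rt, rot)
        for ci in range(1, min(nchi, len(chis)) + 1):
            set_chi(conf, ci, chis[ci - 1])
        conf.altloc = label
        conf.set_occupancy(occ)
        conformers.append(conf)
    residue.conformers = conformers


def make_scenario(
    spec: ScenarioSpec,
) -> tuple[StructureModel, StructureModel, DensityMap]:
    """Build (ground truth, stripped single-conformer input, noisy map).

    The returned ground truth carries the B-factor inflation applied for the
    target resolution — it is the comparison reference for the map.  The
    single-conformer input is the reference stripped to altloc A, emulating
    a model built without knowledge of the alternative conformations.
    """
    model = build_ideal_peptide(spec.sequence, b_iso=spec.b_iso)
    for seq_id, site in spec.sites.items():
        _install_site(model.get("A", seq_id), site)
    synth = SyntheticSpec(
        target_resolution=spec.resolution,
        base_resolution=spec.base_resolution,
        shake_scale=spec.shake_scale,
        noise_scale=spec.noise_scale,
        seed=spec.seed,
        mode=spec.mode,
    )
    dmap, reference = make_synthetic_map(model, synth)
    single = strip_to_single_conformer(reference)
    return reference, single, dmap
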