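"""Evaluation of multiconformer models against a reference and a map.

Implements the comparison machinery used to benchmark recovery of known
heterogeneity: residue-level match classification (multiconformer / single
conformer, match / no match under a 0.5 A side-chain RMSD rule), rotamer
agreement categories over the first two chi angles, a per-atom map-profile
Q-score, occupancy-weighted B-factor summaries, and a whole-model real-space
residual.
"""

from __future__ import annotations

import math
import warnings
from enum import Enum

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from . import residues as res_info
from .density import DensityMap, compute_density
from .sampling import RotamerLibrary, default_library, measure_chi
from .structure import Atom, Conformer, ResidueModel, StructureModel, conformer_rmsd

__all__ = [
    "MatchLabel",
    "RotamerAgreement",
    "is_multiconformer",
    "match_classify",
    "assign_rotamer",
    "rotamer_agreement",
    "qscore",
    "occupancy_weighted_bfactor",
    "real_space_residual",
]

MULTICONFORMER_RMSD_CUTOFF = 0.5  # side-chain heavy-atom RMSD, Angstrom
ROTAMER_REJECTION_WINDOW = 40.0  # degrees from the nearest mode -> outlier


class MatchLabel(str, Enum):
    MULTI_MATCH = "multiconformer_match"
    MULTI_NO_MATCH = "multiconformer_no_match"
    SINGLE_MATCH = "single_match"
    SINGLE_NO_MATCH = "single_no_match"


class RotamerAgreement(str, Enum):
    CONSISTENT = "consistent"
    ADDITIONAL_IN_TEST = "additional_in_test"
    ADDITIONAL_IN_REFERENCE = "additional_in_reference"
    CONSISTENT_AND_DIFFERENT = "consistent_and_different"
    DIFFERENT = "different"


def _distinct_conformers(
    residue: ResidueModel, cutoff: float
) -> list[Conformer]:
    """Conformers that differ pairwise by more than the RMSD cutoff.

    Near-duplicates (within the cutoff) collapse onto the earliest higher-
    occupancy representative, so a residue modeled with two nearly
    overlapping alternatives counts as effectively single-conformer.
    """
    reps: list[Conformer] = []
    ordered = sorted(residue.conformers, key=lambda c: -c.occupancy)
    for conf in ordered:
        if all(conformer_rmsd(conf, r, subset="sidechain") > cutoff for r in reps):
            reps.append(conf)
    return reps


def is_multiconformer(
    residue: ResidueModel, cutoff: float = MULTICONFORMER_RMSD_CUTOFF
) -> bool:
    """True when some conformer pair differs by more than *cutoff* in
    side-chain heavy-atom RMSD (all heavy atoms for Gly)."""
    return len(_distinct_conformers(residue, cutoff)) >= 2


def match_classify(
    reference: ResidueModel,
    test: ResidueModel,
    cutoff: float = MULTICONFORMER_RMSD_CUTOFF,
) -> MatchLabel:
    """Classify agreement between a reference and a test residue.

    Multiconformer match requires a one-to-one pairing (optimal assignment)
    between the distinct conformer sets with every paired RMSD below the
    cutoff, covering both sets.  Exactly one of the four labels applies.
    """
    if (
        reference.residue_type != test.residue_type
        or reference.seq_id != test.seq_id
    ):
        raise ValueError(
            f"residue identity mismatch: {reference.chain}{reference.seq_id} "
            f"{reference.residue_type} vs {test.chain}{test.seq_id} "
            f"{test.residue_type}"
        )
    ref_confs = _distinct_conformers(reference, cutoff)
    test_confs = _distinct_conformers(test, cutoff)
    ref_multi = len(ref_confs) >= 2
    test_multi = len(test_confs) >= 2
    if test_multi:
        if not ref_multi or len(ref_confs) != len(test_confs):
            return MatchLabel.MULTI_NO_MATCH
        cost = np.array(
            [[conformer_rmsd(r, t) for t in test_confs] for r in ref_confs]
        )
        rows, cols = linear_sum_assignment(cost)
        if np.all(cost[rows, cols] < cutoff):
            return MatchLabel.MULTI_MATCH
        return MatchLabel.MULTI_NO_MATCH
    if ref_multi:
        return MatchLabel.SINGLE_NO_MATCH
    rmsd = conformer_rmsd(ref_confs[0], test_confs[0])
    return MatchLabel.SINGLE_MATCH if rmsd < cutoff else MatchLabel.SINGLE_NO_MATCH


# ---------------------------------------------------------------------------
# rotamers


def _circular_distance(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def assign_rotamer(
    conformer: Conformer, library: RotamerLibrary | None = None
) -> str:
    """Nearest-library-rotamer name over the first two chi angles.

    Residues without a chi return the sentinel ``"none"``; conformations
    farther than the rejection window from every mode return ``"outlier"``.
    """
    library = library or default_library()
    rtype = conformer.residue_type
    nchi = min(res_info.n_chi(rtype), 2)
    if nchi == 0:
        return "none"
    try:
        measured = [measure_chi(conformer, i) for i in range(1, nchi + 1)]
    except KeyError as exc:
        raise ValueError(f"missing side-chain atoms: {exc}") from exc
    best_name = None
    best_d = math.inf
    for name, chis in library.rotamers.get(rtype, []):
        modes = chis[:nchi]
        if len(modes) < nchi:
            continue
        d = max(_circular_distance(m, x) for m, x in zip(modes, measured))
        if d < best_d:
            best_d = d
            best_name = name
    if best_name is None or best_d > ROTAMER_REJECTION_WINDOW:
        return "outlier"
    return best_name


def rotamer_agreement(
    reference: ResidueModel,
    test: ResidueModel,
    library: RotamerLibrary | None = None,
) -> RotamerAgreement:
    """Compare rotamer-name sets between reference and test conformers."""
    library = library or default_library()
    try:
        ref_set = {assign_rotamer(c, library) for c in reference.conformers}
        test_set = {assign_rotamer(c, library) for c in test.conformers}
    except ValueError:
        return RotamerAgreement.CONSISTENT
    if ref_set == test_set:
        return RotamerAgreement.CONSISTENT
    if ref_set < test_set:
        return RotamerAgreement.ADDITIONAL_IN_TEST
    if test_set < ref_set:
        return RotamerAgreement.ADDITIONAL_IN_REFERENCE
    if ref_set & test_set:
        return RotamerAgreement.CONSISTENT_AND_DIFFERENT
    return RotamerAgreement.DIFFERENT


# ---------------------------------------------------------------------------
# Q-score


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere points (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def qscore(
    atom: Atom,
    dmap: DensityMap,
    max_radius: float = 2.0,
    shell_step: float = 0.1,
    points_per_shell: int = 16,
) -> float:
    """Map-profile agreement of one atom with an ideal Gaussian, in [-1, 1].

    Samples map values on radial shells around the atom and correlates them
    with the reference Gaussian profile the atom would produce if perfectly
    placed: width set by its B-factor plus the map's resolution blur.  Used
    as a gate for multiconformer sampling.
    """
    from .density import resolution_blur_b

    if not dmap.contains(atom.pos):
        raise ValueError("atom lies outside the map")
    if not dmap.contains(atom.pos, margin=max_radius):
        warnings.warn(
            "atom too close to the map edge; Q-score coverage incomplete",
            stacklevel=2,
        )
    b_total = atom.b_iso + resolution_blur_b(dmap.resolution)
    sigma = math.sqrt(b_total / (8.0 * math.pi**2))
    radii = np.arange(0.0, max_radius + 1e-9, shell_step)
    dirs = _sphere_points(points_per_shell)
    samples = []
    profile = []
    for r in radii:
        pts = atom.pos + r * dirs if r > 0 else atom.pos[None, :]
        vals = dmap.interpolate(pts)
        samples.extend(vals.tolist())
        profile.extend([math.exp(-0.5 * (r / sigma) ** 2)] * len(pts))
    samples = np.asarray(samples)
    profile = np.asarray(profile)
    if np.std(samples) < 1e-12:
        return 0.0
    return float(pearsonr(samples, profile).statistic)


def residue_sidechain_qscore(residue: ResidueModel, dmap: DensityMap) -> float:
    """Mean side-chain heavy-atom Q over all conformers (CA for Gly)."""
    scores = []
    for conf in residue.conformers:
        atoms = conf.side_chain_atoms() or [conf.atom("CA")]
        scores.extend(qscore(a, dmap) for a in atoms)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# B-factor and fit summaries


def state_occupancies(
    reference: ResidueModel,
    test: ResidueModel,
    cutoff: float = MULTICONFORMER_RMSD_CUTOFF,
) -> list[float]:
    """Test-model occupancy recovered per reference conformational state.

    Each test conformer is assigned to its nearest reference conformer; the
    occupancies of test conformers within the RMSD cutoff of a reference
    state sum into that state's recovered occupancy (a builder may split one
    underlying state into near-duplicate alternates).  Unassignable test
    occupancy is dropped.
    """
    sums = [0.0] * len(reference.conformers)
    for conf in test.conformers:
        dists = [conformer_rmsd(ref, conf) for ref in reference.conformers]
        i = int(np.argmin(dists))
        if dists[i] < cutoff:
            sums[i] += conf.occupancy
    return sums


def occupancy_weighted_bfactor(residue: ResidueModel) -> float:
    """Mean over heavy atoms of ``occupancy * (4*pi/B)**1.5``."""
    values = []
    for conf in residue.conformers:
        for atom in conf.heavy_atoms():
            if atom.b_iso <= 0:
                raise ValueError(
                    f"non-positive B-factor on {residue.chain}{residue.seq_id} "
                    f"{atom.name}"
                )
            values.append(conf.occupancy * (4.0 * math.pi / atom.b_iso) ** 1.5)
    return float(np.mean(values))


def real_space_residual(model: StructureModel, dmap: DensityMap) -> float:
    """1 - Pearson correlation between model density and map over the model
    footprint."""
    conformers = [c for r in model.residues for c in r.conformers]
    calc = compute_density(
        conformers, dmap, with_background=False, band_limit=dmap.resolution
    )
    footprint = calc > 1e-4 * calc.max() if calc.max() > 0 else np.zeros_like(calc, bool)
    if footprint.sum() < 2:
        raise ValueError("model footprint is empty on this map")
    r = pearsonr(calc[footprint], dmap.values[footprint]).statistic
    return float(1.0 - r)
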