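"""Reconnecting independently fitted residues into a consistent model.

Residues are fitted one at a time, so adjacent residues can end up with
incompatible conformer sets and occupancies.  This module identifies
*segments* — maximal runs of consecutive residues that each have multiple
backbone conformations — enumerates combinations of member conformers over
a sliding three-residue window, selects combinations by density fit and a
segment-level BIC, harmonizes occupancies along each segment, and finally
assigns altloc letters with a Monte Carlo steric model so that conformers
sharing a letter do not clash across residues.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from . import residues as res_info
from .density import DensityMap, compute_density, extract_residue_subgrid
from .selection import CandidateMatrix, select_by_bic
from .sampling import SamplingConfig
from .structure import Conformer, ResidueModel, StructureModel, conformer_rmsd

__all__ = [
    "Segment",
    "find_segments",
    "assemble_segment",
    "relabel_altlocs",
    "segment_only_expand",
    "occupancy_groups",
]

BACKBONE_DISTINCT_RMSD = 1e-3
COMBINATION_CAP = 1024


@dataclass
class Segment:
    residues: list[ResidueModel]

    def __len__(self) -> int:
        return len(self.residues)


def _has_multiple_backbones(residue: ResidueModel) -> bool:
    confs = residue.conformers
    for i in range(len(confs)):
        for j in range(i + 1, len(confs)):
            if conformer_rmsd(confs[i], confs[j], subset="backbone") > BACKBONE_DISTINCT_RMSD:
                return True
    return False


def find_segments(model: StructureModel) -> list[Segment]:
    """Maximal runs of consecutive multi-backbone residues.

    Residues with a single conformer, or several conformers sharing one
    backbone, delimit segments.  Chain breaks (non-consecutive numbering)
    also delimit.
    """
    segments: list[Segment] = []
    current: list[ResidueModel] = []
    prev: ResidueModel | None = None
    for residue in model.residues:
        contiguous = (
            prev is not None
            and residue.chain == prev.chain
            and residue.seq_id == prev.seq_id + 1
        )
        if not contiguous and current:
            segments.append(Segment(current))
            current = []
        if _has_multiple_backbones(residue):
            current.append(residue)
        elif current:
            segments.append(Segment(current))
            current = []
        prev = residue
    if current:
        segments.append(Segment(current))
    return segments


def _merge_conformers(path: tuple[Conformer, ...]) -> Conformer:
    """Concatenate residue conformers into one unit-occupancy scoring unit."""
    atoms = []
    for conf in path:
        for a in conf.atoms:
            unit = a.copy()
            unit.occupancy = 1.0
            atoms.append(unit)
    return Conformer("SEG", atoms, occupancy=1.0)


def _segment_subgrid(dmap: DensityMap, residues: list[ResidueModel], padding: float):
    dummy = ResidueModel(
        residues[0].chain,
        residues[0].seq_id,
        [c for r in residues for c in r.conformers],
    )
    return extract_residue_subgrid(dmap, dummy, padding)


def assemble_segment(
    segment: Segment,
    dmap: DensityMap,
    config: SamplingConfig,
    padding: float = 4.0,
    context: list[Conformer] | None = None,
) -> Segment:
    """Select a harmonious set of cross-residue conformer combinations.

    A sliding window of up to three residues advances one residue at a time;
    combinations already selected act as frozen prefixes for later windows.
    The surviving combinations become per-residue conformers that share the
    combination occupancies, so backbone-connected conformers in neighboring
    residues have exactly equal occupancy.  ``context`` conformers (the
    fixed surroundings) have their calculated density subtracted from the
    target.
    """
    residues = segment.residues
    if not residues:
        raise ValueError("empty segment")
    # paths: tuples of per-residue conformer choices covering residues[:k]
    paths: list[tuple[Conformer, ...]] = [()]
    weights = np.array([1.0])
    k = 0
    while k < len(residues):
        take = residues[k]
        new_paths = [
            p + (c,) for p in paths for c in take.conformers
        ]
        if len(new_paths) > COMBINATION_CAP:
            order = np.argsort(
                -np.repeat(weights, len(take.conformers))
            )[:COMBINATION_CAP]
            new_paths = [new_paths[i] for i in order]
            warnings.warn(
                f"segment window at {take.chain}{take.seq_id}: combination "
                f"explosion capped at {COMBINATION_CAP}",
                stacklevel=2,
            )
        k += 1
        window = residues[max(0, k - 3) : k]
        subgrid = _segment_subgrid(dmap, window, padding)
        # the full path contributes density (earlier residues only matter
        # near the window boundary); scoring voxels come from the window box
        merged = [_merge_conformers(p) for p in new_paths]
        columns = np.stack(
            [
                compute_density(
                    [c], subgrid, weights=[1.0], with_background=False,
                    band_limit=subgrid.resolution,
                ).ravel()
                for c in merged
            ],
            axis=1,
        )
        from .pipeline import context_baseline

        fixed = list(context or [])
        target = (
            subgrid.values.ravel()
            - context_baseline(
                subgrid, fixed, [c for r in window for c in r.conformers]
            )
        )
        active = np.any(columns > 1e-4 * max(columns.max(), 1e-30), axis=1)
        cm = CandidateMatrix(
            columns[active], target[active], conformers=None
        )
        result = select_by_bic(
            cm,
            n_atoms=0,
            cardinality=config.cardinality,
            threshold=config.threshold,
            context="segment",
        )
        paths = [new_paths[i] for i in result.chosen]
        weights = np.asarray(result.weights, dtype=float)
    # normalize combination weights into occupancies summing to 1
    total = weights.sum()
    if total <= 0:
        raise RuntimeError("segment assembly produced zero total occupancy")
    occs = weights / total
    out_residues = []
    for idx, residue in enumerate(residues):
        conformers = []
        for label, (path, occ) in zip("ABCDE", zip(paths, occs)):
            conf = path[idx].copy()
            conf.altloc = label if len(paths) > 1 else ""
            conf.set_occupancy(float(occ))
            conformers.append(conf)
        out_residues.append(ResidueModel(residue.chain, residue.seq_id, conformers))
    return Segment(out_residues)


# ---------------------------------------------------------------------------
# altloc relabeling


_ADJACENT_EXEMPT = {
    frozenset(("C", "N")),
    frozenset(("CA", "N")),
    frozenset(("O", "N")),
    frozenset(("C", "CA")),
}


def _pair_clashes(
    ca: Conformer, cb: Conformer, adjacent: bool, overlap: float
) -> int:
    count = 0
    for a in ca.heavy_atoms():
        for b in cb.heavy_atoms():
            if adjacent and frozenset((a.name, b.name)) in _ADJACENT_EXEMPT:
                continue
            r = res_info.VDW_RADII.get(a.element, 1.7) + res_info.VDW_RADII.get(
                b.element, 1.7
            )
            if np.linalg.norm(a.pos - b.pos) < overlap * r:
                count += 1
    return count


#: energy assessed when same-letter conformers of sequence neighbors do not
#: form a contiguous peptide bond (dominates any steric term)
_CONTINUITY_PENALTY = 100


def _continuity_penalty(upstream: Conformer, downstream: Conformer) -> int:
    """Same-letter sequence neighbors must stay backbone-connected."""
    try:
        d = float(
            np.linalg.norm(upstream.atom("C").pos - downstream.atom("N").pos)
        )
    except KeyError:
        return 0
    return _CONTINUITY_PENALTY if abs(d - 1.33) > 0.5 else 0


def relabel_altlocs(
    model: StructureModel,
    seed: int = 0,
    steps: int = 10000,
    t0: float = 1.0,
    cooling: float = 0.99,
    overlap_factor: float = 0.75,
) -> StructureModel:
    """Assign altloc letters to spatially coupled conformers.

    Metropolis Monte Carlo over per-residue letter permutations; the energy
    is the number of heavy-atom hard-sphere overlaps between conformers that
    share a letter in different residues (atoms bridging a peptide bond are
    exempt within two bonds).  Geometric cooling; the best labeling visited
    is returned.  Deterministic for a fixed seed.
    """
    out = model.copy()
    multi = [r for r in out.residues if len(r.conformers) > 1]
    if not multi:
        return out
    # pairwise clash tables between conformers of nearby residue pairs
    tables: dict[tuple[int, int], np.ndarray] = {}
    for i in range(len(multi)):
        for j in range(i + 1, len(multi)):
            ri, rj = multi[i], multi[j]
            ci = np.mean([c.atom("CA").pos for c in ri.conformers], axis=0)
            cj = np.mean([c.atom("CA").pos for c in rj.conformers], axis=0)
            if np.linalg.norm(ci - cj) > 12.0:
                continue
            adjacent = ri.chain == rj.chain and abs(ri.seq_id - rj.seq_id) == 1
            tab = np.zeros((len(ri.conformers), len(rj.conformers)), dtype=int)
            for a in range(len(ri.conformers)):
                for b in range(len(rj.conformers)):
                    tab[a, b] = _pair_clashes(
                        ri.conformers[a], rj.conformers[b], adjacent, overlap_factor
                    )
                    if adjacent:
                        up, down = (
                            (ri.conformers[a], rj.conformers[b])
                            if ri.seq_id < rj.seq_id
                            else (rj.conformers[b], ri.conformers[a])
                        )
                        tab[a, b] += _continuity_penalty(up, down)
            if tab.any():
                tables[(i, j)] = tab
    # state: permutation per residue mapping conformer slot -> letter index
    perms = [np.arange(len(r.conformers)) for r in multi]

    def energy(p: list[np.ndarray]) -> int:
        e = 0
        for (i, j), tab in tables.items():
            # letters shared by both residues: letter L sits at slot
            # argwhere(perm == L)
            inv_i = np.argsort(p[i])
            inv_j = np.argsort(p[j])
            n_shared = min(len(inv_i), len(inv_j))
            for letter in range(n_shared):
                e += int(tab[inv_i[letter], inv_j[letter]])
        return e

    rng = np.random.default_rng(seed)
    current = energy(perms)
    best = current
    best_perms = [p.copy() for p in perms]
    temp = t0
    for step in range(steps):
        if step and step % 100 == 0:
            temp *= cooling
        ridx = int(rng.integers(len(multi)))
        n_conf = len(multi[ridx].conformers)
        if n_conf < 2:
            continue
        a, b = rng.choice(n_conf, size=2, replace=False)
        perms[ridx][a], perms[ridx][b] = perms[ridx][b], perms[ridx][a]
        proposed = energy(perms)
        accept = proposed <= current or rng.random() < np.exp(
            -(proposed - current) / max(temp, 1e-9)
        )
        if accept:
            current = proposed
            if current < best:
                best = current
                best_perms = [p.copy() for p in perms]
        else:
            perms[ridx][a], perms[ridx][b] = perms[ridx][b], perms[ridx][a]
    letters = "ABCDE"
    for residue, perm in zip(multi, best_perms):
        for slot, conf in enumerate(residue.conformers):
            conf.altloc = letters[int(perm[slot])]
        residue.conformers.sort(key=lambda c: c.altloc)
    return out


def segment_only_expand(model: StructureModel) -> StructureModel:
    """Equalize conformer counts within each segment by duplication.

    Residues with fewer conformers than the segment maximum gain copies of
    their existing conformers (cycling A, B, ...), each parent's occupancy
    split equally over its copies; occupancies are then harmonized across
    the segment and altlocs relabeled.
    """
    out = model.copy()
    for segment in find_segments(out):
        target = max(len(r.conformers) for r in segment.residues)
        if target > ResidueModel.MAX_CONFORMERS:
            raise ValueError(
                f"segment at {segment.residues[0].chain}"
                f"{segment.residues[0].seq_id}: {target} conformers exceed the "
                f"altloc budget of {ResidueModel.MAX_CONFORMERS}"
            )
        for residue in segment.residues:
            base = list(residue.conformers)
            base_occ = [c.occupancy for c in base]
            parent_of = list(range(len(base)))
            k = 0
            while len(residue.conformers) < target:
                pid = k % len(base)
                residue.conformers.append(base[pid].copy())
                parent_of.append(pid)
                k += 1
            # split each parent's occupancy equally over its copies
            n_copies = [parent_of.count(i) for i in range(len(base))]
            for conf, pid in zip(residue.conformers, parent_of):
                conf.set_occupancy(base_occ[pid] / n_copies[pid])
        # harmonize: all residues share the per-slot mean occupancy
        occ = np.zeros(target)
        for residue in segment.residues:
            occ += [c.occupancy for c in residue.conformers]
        occ /= len(segment.residues)
        occ /= occ.sum()
        for residue in segment.residues:
            for conf, o in zip(residue.conformers, occ):
                conf.set_occupancy(float(o))
            for conf, letter in zip(residue.conformers, "ABCDE"):
                conf.altloc = letter
    return relabel_altlocs(out)


def occupancy_groups(model: StructureModel) -> list[dict]:
    """Plain listing of same-occupancy conformer groups along segments.

    Each entry carries chain, residue range, altloc and group occupancy —
    the language-neutral analog of a group-occupancy refinement restraint
    file.
    """
    groups = []
    gid = 0
    for segment in find_segments(model):
        counts = {len(r.conformers) for r in segment.residues}
        if len(counts) != 1:
            continue
        n = counts.pop()
        for slot in range(n):
            gid += 1
            first = segment.residues[0]
            last = segment.residues[-1]
            groups.append(
                {
                    "group": gid,
                    "chain": first.chain,
                    "start": first.seq_id,
                    "end": last.seq_id,
                    "altloc": first.conformers[slot].altloc or "-",
                    "occupancy": round(first.conformers[slot].occupancy, 4),
                }
            )
    return groups
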