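"""Occupancy culling and renormalization for finalizing a multiconformer model.

The finalization loop alternates an occupancy-only re-fit (quadratic
programming on fixed coordinates) with removal of conformers whose occupancy
has dropped below a floor, renormalizing the survivors to sum to one, until
the model is stable or an iteration cap is reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .density import DensityMap, compute_density, extract_residue_subgrid
from .segments import find_segments
from .selection import CandidateMatrix, solve_qp
from .structure import ResidueModel, StructureModel

__all__ = ["CullingConfig", "cull_and_renormalize", "finalize_loop"]


@dataclass
class CullingConfig:
    min_occupancy: float = 0.10
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.min_occupancy < 1.0:
            raise ValueError("min_occupancy must be in (0, 1)")


def cull_and_renormalize(
    model: StructureModel, config: CullingConfig | None = None
) -> StructureModel:
    """Drop conformers below the occupancy floor and renormalize to sum 1.

    A residue never loses its last conformer: if every conformer falls below
    the floor, the highest-occupancy one is kept at occupancy 1 (with a
    warning).  After culling, segments whose members still share a conformer
    count have their occupancies re-harmonized to the member mean.
    """
    config = config or CullingConfig()
    out = model.copy()
    for residue in out.residues:
        keep = [c for c in residue.conformers if c.occupancy >= config.min_occupancy]
        if not keep:
            best = max(residue.conformers, key=lambda c: c.occupancy)
            warnings.warn(
                f"residue {residue.chain}{residue.seq_id}: all conformers below "
                f"{config.min_occupancy}; keeping the best at occupancy 1",
                stacklevel=2,
            )
            best.set_occupancy(1.0)
            best.altloc = ""
            residue.conformers = [best]
            continue
        residue.conformers = keep
        total = sum(c.occupancy for c in keep)
        for c in keep:
            c.set_occupancy(c.occupancy / total)
        if len(keep) == 1:
            keep[0].altloc = ""
    # segment re-harmonization where conformer counts still agree
    for segment in find_segments(out):
        counts = {len(r.conformers) for r in segment.residues}
        if len(counts) != 1 or len(segment.residues) < 2:
            continue
        n = counts.pop()
        occ = np.zeros(n)
        for residue in segment.residues:
            occ += [c.occupancy for c in residue.conformers]
        occ /= occ.sum()
        for residue in segment.residues:
            for conf, o in zip(residue.conformers, occ):
                conf.set_occupancy(float(o))
    return out


def _equalize_bfactors(units) -> None:
    """Give estimation templates a common per-atom B (the conformer mean).

    Differently sharpened templates project differently onto their density
    lobes, which would bias the occupancy ratio between states.
    """
    names = {a.name for u in units for a in u.atoms}
    for name in names:
        bs = [u.atom(name).b_iso for u in units if u.has_atom(name)]
        mean_b = float(np.mean(bs))
        for u in units:
            if u.has_atom(name):
                u.atom(name).b_iso = mean_b


def _refit_residue_occupancies(
    residue: ResidueModel, dmap: DensityMap, model: StructureModel
) -> None:
    """Occupancy-only QP re-fit of one residue's conformers (fixed coords)."""
    from .pipeline import context_baseline

    subgrid = extract_residue_subgrid(dmap, residue, padding=4.0)
    units = []
    for c in residue.conformers:
        unit = _snap_to_rotamer_modes(c)
        unit.set_occupancy(1.0)
        units.append(unit)
    _equalize_bfactors(units)
    columns = np.stack(
        [
            compute_density(
                [c], subgrid, weights=[1.0], with_background=False,
                band_limit=subgrid.resolution,
            ).ravel()
            for c in units
        ],
        axis=1,
    )
    context = [
        c
        for other in model.residues
        if (other.chain, other.seq_id) != (residue.chain, residue.seq_id)
        for c in other.conformers
    ]
    target = subgrid.values.ravel() - context_baseline(
        subgrid, context, residue.conformers
    )
    weights = _discriminative_weights(columns, target)
    if weights is None:
        return
    for conf, w in zip(residue.conformers, weights):
        conf.set_occupancy(float(w))


def _discriminative_weights(
    columns: np.ndarray, target: np.ndarray
) -> np.ndarray | None:
    """Occupancy ratios from the voxels where the conformers disagree.

    Density shared by all conformers (the common backbone) only constrains
    the total occupancy — which renormalization fixes at 1 — while letting
    incidental noise-fitting differences between near-identical backbone
    copies dominate a whole-residue fit.  Restricting the least-squares fit
    to voxels with real column spread makes the ratio follow the
    side-chain (state) evidence.  Returns normalized weights, or None when
    the conformers are indistinguishable.
    """
    active = np.any(columns > 1e-4 * max(columns.max(), 1e-30), axis=1)
    cols = columns[active]
    tgt = target[active]
    # voxels where the conformers truly disagree: the spread is a large
    # fraction of the local signal (a state lobe present in one conformer
    # and absent in another), not a small shift of a shared feature
    row_max = cols.max(axis=1)
    spread = row_max - cols.min(axis=1)
    discr = (spread > 0.5 * row_max) & (row_max > 0.05 * max(cols.max(), 1e-30))
    if discr.sum() < 20:
        return None  # indistinguishable conformers: keep current occupancies
    # integrate observed mass over each conformer's own territory (voxels it
    # dominates); lobe mass is insensitive to small template displacement,
    # unlike a template least-squares fit
    result = solve_qp(CandidateMatrix(cols[discr], tgt[discr]))
    weights = np.zeros(columns.shape[1])
    weights[result.chosen] = result.weights
    total = weights.sum()
    if total <= 1e-6:
        return np.full(columns.shape[1], 1.0 / columns.shape[1])
    return weights / total


def _snap_to_rotamer_modes(conf, max_snap: float = 30.0):
    """Copy of a conformer with each chi pulled onto its nearest library
    rotamer mode (if within *max_snap* degrees).

    Fitted conformers drift a few degrees off their underlying state to
    chase the particular noise realization; estimating occupancies with
    mode-anchored templates removes the weight-transfer bias that such
    correlated displacements of overlapping templates cause, because the
    modal positions are the statistical centers of the states.
    """
    from .sampling import default_library, measure_chi, set_chi
    from . import residues as res_info

    rtype = conf.residue_type
    n = res_info.n_chi(rtype)
    if n == 0 or rtype == "PRO":
        return conf.copy()
    lib = default_library()
    out = conf.copy()
    for chi_index in range(1, n + 1):
        modes = [m for _, m in lib.modal_values(rtype, chi_index)]
        if not modes:
            continue
        current = measure_chi(out, chi_index)
        dists = [abs((current - m + 180.0) % 360.0 - 180.0) for m in modes]
        best = int(np.argmin(dists))
        if dists[best] <= max_snap:
            set_chi(out, chi_index, modes[best])
    return out


def _refit_segment_occupancies(
    residues: list[ResidueModel], dmap: DensityMap, model: StructureModel
) -> None:
    """Joint occupancy re-fit of a path-aligned segment.

    Conformer slot j of every member residue (altloc order) forms one
    backbone-connected chain; the chains are scored as units so all members
    share one informative occupancy vector instead of averaging per-residue
    fits that may be degenerate (e.g. near-identical backbone copies).
    """
    from .pipeline import context_baseline
    from .segments import _merge_conformers, _segment_subgrid

    n = len(residues[0].conformers)
    subgrid = _segment_subgrid(dmap, residues, padding=4.0)
    snapped = [
        [_snap_to_rotamer_modes(r.conformers[j]) for j in range(n)]
        for r in residues
    ]
    for per_residue in snapped:
        _equalize_bfactors(per_residue)
    chains = [
        _merge_conformers(tuple(per_residue[j] for per_residue in snapped))
        for j in range(n)
    ]
    columns = np.stack(
        [
            compute_density(
                [c], subgrid, with_background=False,
                band_limit=subgrid.resolution,
            ).ravel()
            for c in chains
        ],
        axis=1,
    )
    keys = {(r.chain, r.seq_id) for r in residues}
    context = [
        c
        for other in model.residues
        if (other.chain, other.seq_id) not in keys
        for c in other.conformers
    ]
    own = [c for r in residues for c in r.conformers]
    target = subgrid.values.ravel() - context_baseline(subgrid, context, own)
    weights = _discriminative_weights(columns, target)
    if weights is None:
        return
    for residue in residues:
        for conf, w in zip(residue.conformers, weights):
            conf.set_occupancy(float(w))


def finalize_loop(
    model: StructureModel,
    dmap: DensityMap,
    config: CullingConfig | None = None,
) -> StructureModel:
    """Iterate occupancy re-fit + culling until stable.

    Occupancies are re-fit jointly per segment where conformer counts align
    (chains of slot-aligned conformers score as units), and per residue
    elsewhere.  Terminates when a pass leaves no conformer below the floor,
    or at the iteration cap (with a warning); the iteration count is
    recorded in the model annotations.  Once converged the loop is
    idempotent.
    """
    config = config or CullingConfig()
    current = model.copy()
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        in_segment: set[tuple[str, int]] = set()
        for segment in find_segments(current):
            counts = {len(r.conformers) for r in segment.residues}
            if counts == {1}:
                continue
            if len(counts) == 1:
                _refit_segment_occupancies(segment.residues, dmap, current)
                in_segment |= {(r.chain, r.seq_id) for r in segment.residues}
        for residue in current.residues:
            if (
                len(residue.conformers) > 1
                and (residue.chain, residue.seq_id) not in in_segment
            ):
                _refit_residue_occupancies(residue, dmap, current)
        below = any(
            c.occupancy < config.min_occupancy - 1e-9
            for r in current.residues
            for c in r.conformers
        )
        current = cull_and_renormalize(current, config)
        if not below:
            break
    else:
        warnings.warn(
            f"finalization did not stabilize in {config.max_iterations} rounds",
            stacklevel=2,
        )
    current.annotations["finalize_iterations"] = iterations
    return current
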