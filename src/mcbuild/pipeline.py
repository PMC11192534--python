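"""End-to-end multiconformer building, evaluation and synthesis runs.

``build_multiconformer_model`` is the library core: for each residue it
samples backbone translations, aromatic-angle bends and staged chi sweeps,
scores candidates against the local density by QP, expands B-factors, and
selects a parsimonious conformer set by cardinality-constrained MIQP with
BIC arbitration; residues are then reconnected through segment assembly,
altloc relabeling and the occupancy finalization loop.

The ``run_*`` functions wrap the core with file I/O and are what the
command-line interface calls.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import residues as res_info
from .density import (
    DensityMap,
    XRAY_SOLVENT_LEVEL,
    compute_density,
    extract_residue_subgrid,
    read_map,
    solvent_mask,
    write_map,
)
from .evaluate import (
    MatchLabel,
    match_classify,
    occupancy_weighted_bfactor,
    qscore,
    residue_sidechain_qscore,
    rotamer_agreement,
    assign_rotamer,
)
from .fixtures import ScenarioSpec, make_scenario
from .postprocess import CullingConfig, cull_and_renormalize, finalize_loop
from .sampling import (
    SamplingConfig,
    default_library,
    prune_candidates,
    sample_aromatic_angle,
    sample_backbone,
    sample_bfactors,
    sample_chi,
    sample_proline_pucker,
)
from .segments import (
    Segment,
    assemble_segment,
    find_segments,
    occupancy_groups,
    relabel_altlocs,
)
from .selection import (
    CandidateMatrix,
    SelectionResult,
    SolverError,
    select_by_bic,
    solve_qp,
)
from .structure import (
    Conformer,
    ResidueModel,
    StructureModel,
    conformer_rmsd,
    read_pdb,
    strip_to_single_conformer,
    write_pdb,
)

__all__ = [
    "RunConfig",
    "fit_residue",
    "build_multiconformer_model",
    "run_build",
    "run_evaluate",
    "run_synthesize",
]

DEFAULT_QSCORE_CUTOFF = 0.7


@dataclass
class RunConfig:
    """Configuration of one build run."""

    resolution: float
    em: bool = False
    only_segment: bool = False
    qscores: dict[tuple[str, int], float] | None = None
    qscore_cutoff: float = DEFAULT_QSCORE_CUTOFF
    cardinality: int = 5
    threshold: float | None = None  # None -> 0.2 X-ray / 0.3 EM
    seed: int = 0
    sampling: SamplingConfig | None = None
    culling: CullingConfig = field(default_factory=CullingConfig)
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.threshold is None:
            self.threshold = 0.3 if self.em else 0.2
        # a higher occupancy floor implies fewer representable conformers;
        # EM mode's 0.3 floor caps the cardinality at 3
        self.cardinality = min(self.cardinality, int(1.0 / self.threshold + 1e-9))
        if self.sampling is None:
            self.sampling = SamplingConfig(
                cardinality=self.cardinality, threshold=self.threshold
            )

    @property
    def mode(self) -> str:
        return "em" if self.em else "xray"


# ---------------------------------------------------------------------------
# candidate scoring helpers


def _candidate_matrix(
    candidates: list[Conformer],
    subgrid: DensityMap,
    parents: list[int] | None = None,
    baseline: np.ndarray | None = None,
) -> CandidateMatrix:
    """Density columns for candidates over the informative voxel set.

    The voxel universe is the union of the candidates' density footprints
    within the residue sub-box.  *baseline* (flattened, same voxel order) is
    subtracted from the target before fitting: it carries the calculated
    density of the fixed surroundings plus, in X-ray mode, the flat solvent
    level inside the model mask, so the linear occupancy model sees only the
    residue's own atom density.
    """
    from .density import density_columns

    columns, active = density_columns(
        candidates, subgrid, band_limit=subgrid.resolution
    )
    target = subgrid.values.ravel()[active].copy()
    if baseline is not None:
        target = target - baseline[active]
    elif subgrid.mode == "xray":
        mask = solvent_mask(candidates, subgrid).ravel()
        target = target - XRAY_SOLVENT_LEVEL * mask[active]
    return CandidateMatrix(
        columns, target, parents=parents, conformers=candidates
    )


def context_baseline(
    subgrid: DensityMap,
    context: list[Conformer],
    own: list[Conformer],
) -> np.ndarray:
    """Fixed-surroundings density plus solvent level over a sub-box.

    ``context`` are the conformers of all *other* residues (weighted by
    their occupancies); ``own`` are the conformers of the residue being
    fitted, used only to extend the solvent mask.
    """
    if context:
        baseline = compute_density(
            context, subgrid, with_background=False,
            band_limit=subgrid.resolution,
        )
    else:
        baseline = np.zeros(subgrid.shape)
    if subgrid.mode == "xray":
        mask = solvent_mask(list(context) + list(own), subgrid)
        baseline = baseline + XRAY_SOLVENT_LEVEL * mask
    return baseline.ravel()


def _subgrid_for(
    candidates: list[Conformer], chain: str, seq_id: int, dmap: DensityMap,
    padding: float = 4.0,
) -> DensityMap:
    probe = ResidueModel(chain, seq_id, list(candidates))
    return extract_residue_subgrid(dmap, probe, padding)


def _qp_reduce(
    candidates: list[Conformer],
    subgrid: DensityMap,
    keep: int,
    baseline: np.ndarray | None,
) -> list[Conformer]:
    """One QP round to thin the candidate pool (keeps positive weights,
    capped at *keep* by weight)."""
    cm = _candidate_matrix(candidates, subgrid, baseline=baseline)
    result = solve_qp(cm)
    if not result.chosen:
        return candidates[:keep]
    order = np.argsort(-result.weights)
    chosen = [result.chosen[i] for i in order[:keep]]
    return [candidates[i] for i in sorted(chosen)]


def _miqp_stage(
    candidates: list[Conformer],
    subgrid: DensityMap,
    config: SamplingConfig,
    final: bool,
    n_atoms: int,
    baseline: np.ndarray | None,
) -> tuple[list[Conformer], SelectionResult]:
    """QP reduction, B-factor expansion, then MIQP (BIC-arbitrated if final)."""
    reduced = _qp_reduce(candidates, subgrid, config.qp_keep, baseline)
    variants, parents = sample_bfactors(reduced, config)
    cm = _candidate_matrix(variants, subgrid, parents=parents, baseline=baseline)
    if final:
        result = select_by_bic(
            cm,
            n_atoms=n_atoms,
            cardinality=config.cardinality,
            threshold=config.threshold,
            context="residue",
        )
    else:
        from .selection import solve_miqp_robust, _collapse_variants

        raw = solve_miqp_robust(cm, config.cardinality, config.threshold)
        result = _collapse_variants(raw, cm.parents)
    chosen_confs = [variants[i] for i in result.chosen]
    return chosen_confs, result


def _polish_selected_chis(
    chosen: list[Conformer],
    weights: np.ndarray,
    subgrid: DensityMap,
    baseline: np.ndarray,
    rounds: int = 2,
    span: float = 6.0,
    step: float = 1.5,
) -> tuple[list[Conformer], np.ndarray]:
    """Fine local chi sweep of the selected conformers with joint re-weighting.

    The coarse 6-degree chi grid leaves each selected conformer slightly off
    its density optimum; because alternate states overlap, those offsets
    redistribute occupancy between states.  Sweeping each chi of each chosen
    conformer over a fine grid around its current value (re-fitting all
    weights by QP at every trial) removes that bias.  Coordinates move only
    along the already-sampled torsional degrees of freedom.
    """
    from .sampling import measure_chi, set_chi

    rtype = chosen[0].residue_type
    if rtype == "PRO" or res_info.n_chi(rtype) == 0:
        return chosen, weights
    chosen = [c.copy() for c in chosen]
    offsets = np.arange(-span, span + 1e-9, step)

    def joint_fit(confs):
        cm = _candidate_matrix(confs, subgrid, baseline=baseline)
        result = solve_qp(cm)
        w = np.zeros(len(confs))
        w[result.chosen] = result.weights
        return w, result.rss

    weights, best_rss = joint_fit(chosen)
    for _ in range(rounds):
        improved = False
        for i in range(len(chosen)):
            for chi_index in range(1, res_info.n_chi(rtype) + 1):
                current = measure_chi(chosen[i], chi_index)
                best_delta = 0.0
                for delta in offsets:
                    if delta == 0.0:
                        continue
                    trial = chosen[i].copy()
                    set_chi(trial, chi_index, current + delta)
                    confs = chosen[:i] + [trial] + chosen[i + 1 :]
                    w, rss = joint_fit(confs)
                    if rss < best_rss - 1e-12:
                        best_rss = rss
                        best_delta = delta
                        weights = w
                if best_delta != 0.0:
                    set_chi(chosen[i], chi_index, current + best_delta)
                    improved = True
        if not improved:
            break
    return chosen, weights


def fit_residue(
    residue: ResidueModel,
    dmap: DensityMap,
    config: SamplingConfig,
    library=None,
    context: list[Conformer] | None = None,
) -> ResidueModel:
    """Sample, score and select a parsimonious conformer set for one residue.

    Staged search: backbone translations; aromatic-angle bends (aromatics
    only); per-chi sweeps with a QP / B-factor / MIQP round after each chi
    (proline ring puckers replace the chi sweep); and a final BIC-arbitrated
    MIQP across cardinalities 1-5.  ``context`` carries the conformers of
    the surrounding residues, whose calculated density is subtracted from
    the target before fitting.
    """
    library = library or default_library()
    rtype = residue.residue_type
    n_chi = res_info.n_chi(rtype)

    current = sample_backbone(residue, config)
    if rtype in res_info.AROMATIC_RESIDUES:
        current = [c for conf in current for c in sample_aromatic_angle(conf, config)]
    n_atoms = len(residue.conformers[0].heavy_atoms())
    subgrid_all = extract_residue_subgrid(dmap, residue, padding=5.0)
    baseline = context_baseline(subgrid_all, context or [], residue.conformers)

    def stage(cands: list[Conformer], final: bool) -> tuple[list[Conformer], SelectionResult]:
        cands = prune_candidates(cands, config)
        if not cands:
            raise SolverError("all candidates pruned")
        return _miqp_stage(cands, subgrid_all, config, final, n_atoms, baseline)

    if rtype == "PRO":
        cands = [c for conf in current for c in sample_proline_pucker(conf, config)]
        chosen, result = stage(cands, final=True)
    elif n_chi == 0:
        chosen, result = stage(current, final=True)
    else:
        for chi_index in range(1, n_chi + 1):
            cands = sample_chi(current, chi_index, library, config)
            final = chi_index == n_chi
            chosen, result = stage(cands, final=final)
            current = chosen
    polished, weights = _polish_selected_chis(
        chosen, np.asarray(result.weights, float), subgrid_all, baseline
    )
    if weights.sum() <= 1e-6:
        polished, weights = chosen, np.asarray(result.weights, float)
    keep = weights > 1e-6
    polished = [c for c, k in zip(polished, keep) if k]
    weights = weights[keep]
    ordered = sorted(
        zip(polished, weights), key=lambda cw: -cw[1]
    )
    conformers = []
    for (conf, w), label in zip(ordered, "ABCDE"):
        new = conf.copy()
        new.altloc = label if len(ordered) > 1 else ""
        new.set_occupancy(float(w))
        conformers.append(new)
    fitted = ResidueModel(residue.chain, residue.seq_id, conformers)
    fitted.validate()
    return fitted


def _merge_near_duplicates(model: StructureModel, rmsd: float = 0.01) -> None:
    """Merge conformers of one residue closer than *rmsd*, summing occupancy."""
    for residue in model.residues:
        merged: list[Conformer] = []
        for conf in residue.conformers:
            twin = next(
                (m for m in merged if conformer_rmsd(m, conf) < rmsd), None
            )
            if twin is None:
                merged.append(conf)
            else:
                twin.set_occupancy(twin.occupancy + conf.occupancy)
        if len(merged) < len(residue.conformers):
            residue.conformers = merged
            if len(merged) == 1:
                merged[0].altloc = ""


def build_multiconformer_model(
    model: StructureModel,
    dmap: DensityMap,
    config: RunConfig,
) -> tuple[StructureModel, dict]:
    """Run the full residue -> segment -> finalize pipeline.

    Per-residue failures degrade to retaining the input conformer with a
    warning instead of aborting the run.  Returns the final model and a run
    report (per-residue conformer counts, timings, config echo).
    """
    t0 = time.time()
    report: dict = {
        "config": {
            "resolution": config.resolution,
            "mode": config.mode,
            "threshold": config.threshold,
            "cardinality": config.cardinality,
            "qscore_cutoff": config.qscore_cutoff if config.qscores else None,
            "seed": config.seed,
        },
        "residues": [],
    }
    work = model.copy()
    fitted_residues = []
    for residue in work.residues:
        key = (residue.chain, residue.seq_id)
        gated = False
        if config.qscores is not None:
            q = config.qscores.get(key)
            if q is not None and q < config.qscore_cutoff:
                gated = True
        if gated:
            fitted = residue.copy()
            note = "qscore_gated"
        else:
            context = [
                c
                for other in work.residues
                if (other.chain, other.seq_id) != key
                for c in other.conformers
            ]
            try:
                fitted = fit_residue(residue, dmap, config.sampling, context=context)
                note = "fitted"
            except Exception as exc:  # degrade, never abort the whole run
                warnings.warn(
                    f"residue {residue.chain}{residue.seq_id} "
                    f"{residue.residue_type}: {exc}; keeping input conformer",
                    stacklevel=2,
                )
                fitted = residue.copy()
                note = f"failed: {exc}"
        fitted_residues.append(fitted)
        report["residues"].append(
            {
                "chain": residue.chain,
                "seq_id": residue.seq_id,
                "residue_type": residue.residue_type,
                "n_conformers": len(fitted.conformers),
                "status": note,
            }
        )
    built = StructureModel(fitted_residues, dict(work.annotations))
    # reconnect: segment assembly over multi-backbone runs
    for segment in find_segments(built):
        seg_keys = {(r.chain, r.seq_id) for r in segment.residues}
        seg_context = [
            c
            for other in built.residues
            if (other.chain, other.seq_id) not in seg_keys
            for c in other.conformers
        ]
        try:
            assembled = assemble_segment(
                segment, dmap, config.sampling, context=seg_context
            )
        except Exception as exc:
            warnings.warn(f"segment assembly failed: {exc}", stacklevel=2)
            continue
        for res_new in assembled.residues:
            for i, res_old in enumerate(built.residues):
                if (res_old.chain, res_old.seq_id) == (res_new.chain, res_new.seq_id):
                    built.residues[i] = res_new
    built = relabel_altlocs(built, seed=config.seed)
    built = finalize_loop(built, dmap, config.culling)
    _merge_near_duplicates(built)
    built = relabel_altlocs(built, seed=config.seed)
    report["groups"] = occupancy_groups(built)
    report["wall_time_s"] = round(time.time() - t0, 2)
    report["multiconformer_residues"] = sum(
        1 for r in built.residues if len(r.conformers) > 1
    )
    return built, report


# ---------------------------------------------------------------------------
# file-level runs


def run_build(
    model_path: str,
    map_path: str,
    output_dir: str,
    config: RunConfig,
) -> StructureModel:
    """Build a multiconformer model from a PDB file and a CCP4/MRC map."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dmap = read_map(map_path, resolution=config.resolution, mode=config.mode)
    model = read_pdb(model_path)
    if config.only_segment:
        from .segments import segment_only_expand

        final = segment_only_expand(model)
        report = {"mode": "only_segment", "groups": occupancy_groups(final)}
    else:
        single = strip_to_single_conformer(model)
        final, report = build_multiconformer_model(single, dmap, config)
    write_pdb(final, out / "multiconformer_model.pdb")
    with open(out / "occupancy_groups.txt", "w") as fh:
        fh.write("# group\tchain\tstart\tend\taltloc\toccupancy\n")
        for g in report.get("groups", []):
            fh.write(
                f"{g['group']}\t{g['chain']}\t{g['start']}\t{g['end']}\t"
                f"{g['altloc']}\t{g['occupancy']}\n"
            )
    with open(out / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return final


def run_evaluate(
    reference: StructureModel,
    test: StructureModel,
    dmap: DensityMap | None = None,
) -> dict:
    """Per-residue match labels, rotamer agreement and summary fractions."""
    ref_index = {(r.chain, r.seq_id): r for r in reference.residues}
    test_index = {(r.chain, r.seq_id): r for r in test.residues}
    missing = sorted(set(ref_index) ^ set(test_index))
    if missing:
        raise ValueError(f"residue numbering mismatch at {missing}")
    rows = []
    for key in sorted(ref_index):
        ref_res = ref_index[key]
        test_res = test_index[key]
        row = {
            "chain": key[0],
            "seq_id": key[1],
            "residue_type": ref_res.residue_type,
            "match": match_classify(ref_res, test_res).value,
            "rotamer_agreement": rotamer_agreement(ref_res, test_res).value,
            "ref_rotamers": sorted(
                {assign_rotamer(c) for c in ref_res.conformers}
            ),
            "test_rotamers": sorted(
                {assign_rotamer(c) for c in test_res.conformers}
            ),
            "occ_weighted_b": round(occupancy_weighted_bfactor(test_res), 6),
        }
        if dmap is not None:
            row["mean_sidechain_q"] = round(
                residue_sidechain_qscore(test_res, dmap), 4
            )
        rows.append(row)
    n = len(rows)
    fractions = {
        label.value: sum(1 for r in rows if r["match"] == label.value) / n
        for label in MatchLabel
    }
    return {"rows": rows, "fractions": fractions, "n_residues": n}


def write_evaluation_tsv(evaluation: dict, path: str) -> None:
    rows = evaluation["rows"]
    cols = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def run_synthesize(spec: ScenarioSpec, output_dir: str) -> dict:
    """Write ground-truth PDB, stripped input PDB, map, and a manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ground_truth, single, dmap = make_scenario(spec)
    write_pdb(ground_truth, out / "ground_truth.pdb")
    write_pdb(single, out / "single_conformer_input.pdb")
    write_map(dmap, out / "synthetic_map.ccp4")
    manifest = {
        "sequence": spec.sequence,
        "sites": {
            str(k): {"rotamers": v.rotamers, "occupancies": v.occupancies}
            for k, v in spec.sites.items()
        },
        "resolution": spec.resolution,
        "seed": spec.seed,
        "shake_scale": spec.shake_scale,
        "shake_rmse": spec.shake_scale * spec.resolution,
        "noise_scale": spec.noise_scale,
        "base_resolution": spec.base_resolution,
        "mode": spec.mode,
        "files": [
            "ground_truth.pdb",
            "single_conformer_input.pdb",
            "synthetic_map.ccp4",
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
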