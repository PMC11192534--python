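"""Occupancy fitting of candidate conformers against observed density.

The observed density over a residue's voxels is modelled as a non-negative
combination of per-candidate calculated densities with total weight at most
one.  Plain quadratic programming (QP) gives the unconstrained-cardinality
fit; the mixed-integer variant (MIQP) additionally limits the number of
selected candidates and imposes a minimum occupancy per selected candidate.
The MIQP is solved exactly with branch-and-bound on the selection
indicators, using the box/sum-constrained QP relaxation as the bound.

Model complexity is arbitrated with a Bayesian information criterion,
``BIC = n*ln(rss/n) + k*ln(n)*0.95``, where n is the voxel count and k the
parameter count (4 per atom per conformer at the residue level; the number
of conformations at the segment level).
"""

from __future__ import annotations

import heapq
import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure import Conformer, conformer_rmsd

__all__ = [
    "CandidateMatrix",
    "SelectionResult",
    "SolverError",
    "solve_qp",
    "solve_miqp",
    "miqp_nonconvex_fallback",
    "solve_miqp_robust",
    "compute_bic",
    "select_by_bic",
]

BIC_SCALING = 0.95
_WEIGHT_EPS = 1e-6


class SolverError(RuntimeError):
    """Raised when the occupancy solver cannot produce a solution."""


@dataclass
class CandidateMatrix:
    """Calculated candidate densities (columns) and the observed target.

    ``columns`` is (n_voxels, n_candidates); ``parents`` maps each candidate
    to a geometric-conformer identity (B-factor variants of one geometry
    share a parent); ``conformers`` optionally carries the candidate
    conformers for RMSD-based degeneracy handling.
    """

    columns: np.ndarray
    target: np.ndarray
    parents: list[int] | None = None
    conformers: list[Conformer] | None = None

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        self.target = np.asarray(self.target, dtype=float).ravel()
        if self.columns.shape[0] != self.target.shape[0]:
            raise ValueError("columns and target must share the voxel axis")
        if self.parents is None:
            self.parents = list(range(self.columns.shape[1]))
        if self.n_voxels < self.n_candidates:
            warnings.warn(
                f"underdetermined fit: {self.n_candidates} candidates over "
                f"{self.n_voxels} voxels",
                stacklevel=2,
            )

    @property
    def n_voxels(self) -> int:
        return self.columns.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.columns.shape[1]

    def subset(self, idx: list[int]) -> "CandidateMatrix":
        return CandidateMatrix(
            self.columns[:, idx],
            self.target,
            [self.parents[i] for i in idx],
            None if self.conformers is None else [self.conformers[i] for i in idx],
        )


@dataclass
class SelectionResult:
    chosen: list[int]
    weights: np.ndarray
    rss: float
    bic: float | None = None
    cardinality_used: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)

    def weight_of(self, candidate: int) -> float:
        for i, c in enumerate(self.chosen):
            if c == candidate:
                return float(self.weights[i])
        return 0.0


# ---------------------------------------------------------------------------
# box + sum constrained QP in Gram space


def _project_box_sum(w: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {lb <= w <= ub, sum(w) <= 1}."""
    x = np.clip(w, lb, ub)
    if x.sum() <= 1.0 + 1e-12:
        return x
    # bisection on the shift lambda: sum(clip(w - lam, lb, ub)) = 1
    lo, hi = 0.0, float(np.max(w - lb)) + 1.0
    for _ in range(100):
        lam = 0.5 * (lo + hi)
        s = np.clip(w - lam, lb, ub).sum()
        if s > 1.0:
            lo = lam
        else:
            hi = lam
    return np.clip(w - hi, lb, ub)


def _qp_box_sum(
    G: np.ndarray,
    b: np.ndarray,
    yty: float,
    lb: np.ndarray,
    ub: np.ndarray,
    L: float | None = None,
) -> tuple[np.ndarray, float]:
    """Minimize ||y - Aw||^2 over {lb <= w <= ub, sum w <= 1}.

    Works on the Gram matrix G = A'A and b = A'y.  Columns with a zero
    upper bound are eliminated; the rest is shifted to a non-negative
    least-squares problem with a penalty-weighted total-occupancy slack,
    solved by scipy's active-set NNLS on the Cholesky factor and refined by
    an exact KKT solve on the identified active set.  Returns (w, rss).
    """
    from scipy.optimize import nnls

    m = len(b)
    if np.sum(lb) > 1.0 + 1e-9:
        raise SolverError("infeasible bounds: sum of lower bounds exceeds 1")
    alive = np.where(ub > 1e-12)[0]
    w_full = np.zeros(m)
    w_full[:] = 0.0
    if len(alive) == 0:
        return w_full, max(yty, 0.0)
    Ga = G[np.ix_(alive, alive)]
    ba = b[alive]
    lba = lb[alive]
    budget = 1.0 - float(np.sum(lba))  # remaining occupancy above the lower bounds
    scale = float(np.max(np.diag(Ga)))
    if scale <= 0:
        w_full[alive] = lba
        w = w_full
        return w, max(float(yty - 2.0 * b @ w + w @ G @ w), 0.0)
    ridge = 1e-10 * scale
    R = np.linalg.cholesky(Ga + ridge * np.eye(len(alive))).T
    # substitute w = lb + u (u >= 0): residual b term becomes b - G lb
    bu = ba - Ga @ lba
    rhs = np.linalg.solve(R.T, bu)
    # penalty row sqrt(mu) * (sum(u) + s - budget) with slack s >= 0
    mu = math.sqrt(1e8 * scale)
    k = len(alive)
    A_aug = np.zeros((k + 1, k + 1))
    A_aug[:k, :k] = R
    A_aug[k, :k] = mu
    A_aug[k, k] = mu
    y_aug = np.concatenate([rhs, [mu * budget]])
    u, _ = nnls(A_aug, y_aug)
    u = u[:k]
    w_full[alive] = lba + u
    w = _project_box_sum(w_full, lb, ub)
    w = _kkt_polish(G, b, lb, ub, w)
    rss = float(yty - 2.0 * b @ w + w @ G @ w)
    return w, max(rss, 0.0)


def _kkt_polish(G, b, lb, ub, w0, tol: float = 1e-9):
    """Exact equality solve on the active set implied by w0, kept if feasible
    and objective-improving."""
    m = len(b)
    free = (w0 > lb + 1e-7) & (w0 < ub - 1e-7)
    at_lb = ~free & (np.abs(w0 - lb) <= np.abs(ub - w0))
    sum_active = w0.sum() > 1.0 - 1e-7
    w = np.where(at_lb, lb, np.where(free, w0, ub))
    idx = np.where(free)[0]
    if len(idx) > 0:
        Gf = G[np.ix_(idx, idx)]
        ridge = 1e-12 * max(float(np.max(np.diag(Gf))), 1.0)
        Gf = Gf + ridge * np.eye(len(idx))
        fixed = w.copy()
        fixed[idx] = 0.0
        bf = b[idx] - G[np.ix_(idx, np.arange(m))] @ fixed
        if sum_active:
            # KKT with equality sum(w) = 1: bordered system
            n = len(idx)
            K = np.zeros((n + 1, n + 1))
            K[:n, :n] = Gf
            K[:n, n] = 0.5
            K[n, :n] = 1.0
            rhs = np.concatenate([bf, [1.0 - fixed.sum()]])
            try:
                sol = np.linalg.solve(K, rhs)
                w_try = w.copy()
                w_try[idx] = sol[:n]
            except np.linalg.LinAlgError:
                return w0
        else:
            try:
                w_try = w.copy()
                w_try[idx] = np.linalg.solve(Gf, bf)
            except np.linalg.LinAlgError:
                return w0
        feasible = (
            np.all(w_try >= lb - tol)
            and np.all(w_try <= ub + tol)
            and w_try.sum() <= 1.0 + tol
        )
        if feasible:
            w_try = _project_box_sum(np.clip(w_try, lb, ub), lb, ub)
            obj_new = float(w_try @ G @ w_try - 2.0 * b @ w_try)
            obj_old = float(w0 @ G @ w0 - 2.0 * b @ w0)
            if obj_new <= obj_old + 1e-12:
                return w_try
    return w0


def _gram(cm: CandidateMatrix):
    A = cm.columns
    y = cm.target
    return A.T @ A, A.T @ y, float(y @ y)


def solve_qp(cm: CandidateMatrix) -> SelectionResult:
    """Least-squares occupancy fit with w >= 0 and sum(w) <= 1."""
    if cm.n_candidates < 1:
        raise ValueError("need at least one candidate")
    G, b, yty = _gram(cm)
    m = cm.n_candidates
    w, rss = _qp_box_sum(G, b, yty, np.zeros(m), np.ones(m))
    chosen = [i for i in range(m) if w[i] > _WEIGHT_EPS]
    return SelectionResult(
        chosen=chosen,
        weights=w[chosen],
        rss=rss,
        cardinality_used=len(chosen),
    )


# ---------------------------------------------------------------------------
# MIQP: cardinality + occupancy-threshold constrained fit


def solve_miqp(
    cm: CandidateMatrix,
    cardinality: int,
    threshold: float,
    node_limit: int = 20000,
) -> SelectionResult:
    """Exact cardinality/threshold-constrained fit via branch-and-bound.

    Selected candidates get weight in [threshold, 1]; at most *cardinality*
    candidates are selected; total weight is at most 1.  Raises
    :class:`SolverError` if the bound search exceeds the node budget (the
    caller may then invoke the RMSD-based degeneracy fallback).
    """
    if cardinality < 1:
        raise ValueError("cardinality must be >= 1")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if threshold * cardinality > 1.0 + 1e-9:
        raise SolverError(
            f"infeasible constraints: threshold {threshold} x cardinality "
            f"{cardinality} exceeds total occupancy 1"
        )
    G, b, yty = _gram(cm)
    m = cm.n_candidates
    lip = 2.0 * float(np.linalg.norm(G, 2)) if m > 1 else 2.0 * float(G[0, 0])

    def relax(fixed_in: frozenset[int], fixed_out: frozenset[int]):
        lb = np.zeros(m)
        ub = np.ones(m)
        for i in fixed_in:
            lb[i] = threshold
        for i in fixed_out:
            ub[i] = 0.0
        if len(fixed_in) >= cardinality:
            for i in range(m):
                if i not in fixed_in:
                    ub[i] = 0.0
        return _qp_box_sum(G, b, yty, lb, ub, L=lip)

    def feasible(w: np.ndarray) -> bool:
        support = np.where(w > _WEIGHT_EPS)[0]
        if len(support) > cardinality:
            return False
        return bool(np.all(w[support] >= threshold - 1e-6))

    def exact_rss(w: np.ndarray) -> float:
        return float(yty - 2.0 * b @ w + w @ G @ w)

    best_w: np.ndarray | None = None
    best_rss = math.inf

    # greedy warm start: top-c candidates from the plain QP
    w0, _ = _qp_box_sum(G, b, yty, np.zeros(m), np.ones(m), L=lip)
    top = list(np.argsort(-w0)[: min(cardinality, m)])
    lb = np.zeros(m)
    ub = np.zeros(m)
    for i in top:
        lb[i] = threshold
        ub[i] = 1.0
    try:
        w_g, rss_g = _qp_box_sum(G, b, yty, lb, ub, L=lip)
        # dropping forced members below threshold may do better; try support-only
        if feasible(w_g):
            best_w, best_rss = w_g, rss_g
    except SolverError:
        pass
    for keep in range(1, min(cardinality, m)):
        lb = np.zeros(m)
        ub = np.zeros(m)
        for i in top[:keep]:
            lb[i] = threshold
            ub[i] = 1.0
        try:
            w_g, rss_g = _qp_box_sum(G, b, yty, lb, ub, L=lip)
            if feasible(w_g) and rss_g < best_rss:
                best_w, best_rss = w_g, rss_g
        except SolverError:
            continue

    counter = itertools.count()
    heap: list = []
    w_root, rss_root = relax(frozenset(), frozenset())
    heapq.heappush(heap, (rss_root, next(counter), frozenset(), frozenset(), w_root))
    nodes = 0
    while heap:
        bound, _, fin, fout, w_rel = heapq.heappop(heap)
        if bound >= best_rss - 1e-9:
            continue
        nodes += 1
        if nodes > node_limit:
            raise SolverError(
                f"branch-and-bound exceeded {node_limit} nodes "
                "(near-degenerate candidate set)"
            )
        if feasible(w_rel):
            rss = exact_rss(w_rel)
            if rss < best_rss:
                best_w, best_rss = w_rel, rss
            continue
        free = [
            i
            for i in range(m)
            if i not in fin and i not in fout and w_rel[i] > _WEIGHT_EPS
        ]
        if not free:
            continue
        branch = max(free, key=lambda i: w_rel[i])
        for child_in, child_out in (
            (fin | {branch}, fout),
            (fin, fout | {branch}),
        ):
            if len(child_in) > cardinality:
                continue
            if threshold * len(child_in) > 1.0 + 1e-9:
                continue
            try:
                w_c, rss_c = relax(child_in, child_out)
            except SolverError:
                continue
            if rss_c < best_rss - 1e-9:
                heapq.heappush(
                    heap, (rss_c, next(counter), child_in, child_out, w_c)
                )
    if best_w is None:
        raise SolverError("no feasible MIQP solution found")
    w = best_w
    chosen = [i for i in range(m) if w[i] > _WEIGHT_EPS]
    return SelectionResult(
        chosen=chosen,
        weights=w[chosen],
        rss=best_rss,
        cardinality_used=len(chosen),
    )


def miqp_nonconvex_fallback(
    cm: CandidateMatrix, cardinality: int, threshold: float
) -> SelectionResult:
    """Degeneracy fallback: iteratively remove one of the two most similar
    candidates (lower QP weight loses; ties drop the later index) and retry
    the MIQP until it solves.

    Similarity is all-atom RMSD when candidate conformers are attached,
    otherwise Euclidean distance between density columns.
    """
    alive = list(range(cm.n_candidates))
    while len(alive) > 1:
        sub = cm.subset(alive)
        # closest pair among the survivors
        best_pair = None
        best_d = math.inf
        for ii in range(len(alive)):
            for jj in range(ii + 1, len(alive)):
                if sub.conformers is not None:
                    d = conformer_rmsd(sub.conformers[ii], sub.conformers[jj])
                else:
                    d = float(
                        np.linalg.norm(sub.columns[:, ii] - sub.columns[:, jj])
                    )
                if d < best_d:
                    best_d = d
                    best_pair = (ii, jj)
        qp = solve_qp(sub)
        ii, jj = best_pair
        wi, wj = qp.weight_of(ii), qp.weight_of(jj)
        drop_local = jj if wj <= wi else ii  # tie drops the later index
        alive.pop(drop_local)
        try:
            result = solve_miqp(cm.subset(alive), cardinality, threshold)
        except SolverError:
            continue
        result.chosen = [alive[i] for i in result.chosen]
        return result
    raise SolverError("candidate elimination exhausted without a MIQP solution")


def solve_miqp_robust(
    cm: CandidateMatrix, cardinality: int, threshold: float
) -> SelectionResult:
    """MIQP with the iterative closest-pair elimination fallback."""
    try:
        return solve_miqp(cm, cardinality, threshold)
    except SolverError as exc:
        if "infeasible constraints" in str(exc):
            raise
        return miqp_nonconvex_fallback(cm, cardinality, threshold)


# ---------------------------------------------------------------------------
# BIC


def compute_bic(rss: float, n: int, k: int, scaling: float = BIC_SCALING) -> float:
    """``n*ln(rss/n) + k*ln(n)*scaling``; a heuristic scaling factor below 1
    accounts for coordinate parameters being correlated by chemistry."""
    if n <= 0:
        raise ValueError("n must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    if rss <= 0:
        warnings.warn("non-positive rss; substituting machine epsilon", stacklevel=2)
        rss = np.finfo(float).eps * n
    return float(n * math.log(rss / n) + k * math.log(n) * scaling)


def _collapse_variants(result: SelectionResult, parents: list[int]) -> SelectionResult:
    """Merge B-factor variants of one geometric parent: the highest-weight
    variant represents the parent and absorbs the siblings' weight."""
    by_parent: dict[int, list[int]] = {}
    for pos, cand in enumerate(result.chosen):
        by_parent.setdefault(parents[cand], []).append(pos)
    chosen: list[int] = []
    weights: list[float] = []
    for positions in by_parent.values():
        best = max(positions, key=lambda p: result.weights[p])
        chosen.append(result.chosen[best])
        weights.append(float(sum(result.weights[p] for p in positions)))
    order = np.argsort(chosen)
    return SelectionResult(
        chosen=[chosen[i] for i in order],
        weights=np.array([weights[i] for i in order]),
        rss=result.rss,
        bic=result.bic,
        cardinality_used=len(chosen),
    )


def select_by_bic(
    cm: CandidateMatrix,
    n_atoms: int,
    cardinality: int = 5,
    threshold: float = 0.2,
    context: str = "residue",
) -> SelectionResult:
    """Run the MIQP at every cardinality 1..max and keep the lowest BIC.

    The parameter count is ``conformers * atoms * 4`` at the residue level
    (x, y, z and B per atom) and simply the number of conformations at the
    segment level.  B-factor variants of one geometry count once; ties in
    BIC resolve to the smaller cardinality.
    """
    if context not in ("residue", "segment"):
        raise ValueError("context must be 'residue' or 'segment'")
    best: SelectionResult | None = None
    failures: list[str] = []
    for c in range(1, cardinality + 1):
        if threshold * c > 1.0 + 1e-9:
            break
        try:
            result = solve_miqp_robust(cm, c, threshold)
        except SolverError as exc:
            failures.append(str(exc))
            continue
        collapsed = _collapse_variants(result, cm.parents)
        c_eff = max(collapsed.cardinality_used, 1)
        k = c_eff * n_atoms * 4 if context == "residue" else c_eff
        collapsed.bic = compute_bic(max(result.rss, 0.0), cm.n_voxels, k)
        if best is None or collapsed.bic < best.bic - 1e-12:
            best = collapsed
    if best is None:
        raise SolverError(
            "no cardinality produced a feasible selection: " + "; ".join(failures)
        )
    return best
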