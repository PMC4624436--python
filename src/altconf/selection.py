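"""Occupancy selection: QP pre-fit and threshold-constrained MIQP.

Given an observed (background-subtracted) density target rho_o and candidate
conformer densities rho_i^c evaluated over masked voxels, the occupancies w
minimize  || rho_o - sum_i w_i rho_i^c ||^2  subject to

    w_i in {0} u [t, 1],     sum_i w_i <= 1,

where t is the minimum-occupancy threshold.  Together the two constraints
bound the number of selected conformers by floor(1/t) (a cardinality
constraint), which is what makes the fit parsimonious.  The convex
relaxation (w >= 0 only) is solved first; candidates with non-vanishing
relaxed occupancy survive to the exact mixed-integer stage, which here is an
exhaustive enumeration over admissible support sets with an exact active-set
solve per support -- globally optimal for the problem sizes this pipeline
produces, and deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .density import DensityMap, VoxelMask, build_mask, density_at_points, mask_radius

logger = logging.getLogger(__name__)

__all__ = [
    "FitCandidate",
    "SelectionProblem",
    "OccupancySolution",
    "build_problem",
    "qp_fit",
    "miqp_select",
    "fragment_select",
    "divide_and_conquer",
    "threshold_for_resolution",
]

#: survivors handed to the MIQP stage are capped at this many
MAX_SURVIVORS = 30
#: below this candidate count the MIQP enumerates every candidate instead
#: of only the pre-fit survivors (see miqp_select)
MAX_FULL_ENUM = 16
#: combined fragment conformations above this trigger divide-and-conquer
COMBINATORIAL_CAP = 1024


def threshold_for_resolution(d: float) -> float:
    """Default minimum-occupancy threshold schedule: 0.25 (up to four
    conformers) at better than 1.8 A, 0.33 (up to three) at 1.8 A and
    worse."""
    return 0.25 if d < 1.8 else 1.0 / 3.0


@dataclass
class FitCandidate:
    """One candidate conformation as seen by the selector: the atoms whose
    density forms its column rho_i^c, and the positions (sidechain Cb and
    beyond plus carbonyl O) that generate the fitting mask."""
    atoms: list
    mask_positions: np.ndarray
    meta: object = None


@dataclass
class SelectionProblem:
    target: np.ndarray            # rho_o on masked voxels
    columns: np.ndarray           # (n_voxels, n_candidates)
    threshold: float
    resolution: float
    mask: VoxelMask | None = None

    def __post_init__(self):
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold {self.threshold} outside (0, 1]")
        if self.columns.ndim != 2 or self.columns.shape[1] < 1:
            raise ValueError("need at least one candidate column")
        if not (np.all(np.isfinite(self.columns))
                and np.all(np.isfinite(self.target))):
            raise ValueError("non-finite density values")

    @property
    def n_candidates(self) -> int:
        return self.columns.shape[1]

    def cardinality(self) -> int:
        return int(1.0 / self.threshold)


@dataclass
class OccupancySolution:
    weights: np.ndarray
    indicators: np.ndarray
    objective: float
    provenance: str = "exhaustive"
    threshold: float = 0.0

    @property
    def support(self) -> np.ndarray:
        return np.nonzero(self.indicators)[0]

    def validate(self) -> None:
        w = self.weights
        t = self.threshold
        if np.any(w < -1e-9) or np.any(w > 1 + 1e-9):
            raise ValueError("weights outside [0, 1]")
        on = w > 1e-9
        if t > 0 and np.any(w[on] < t - 1e-6):
            raise ValueError("nonzero weight below threshold")
        if w.sum() > 1 + 1e-6:
            raise ValueError("weights sum above 1")
        if not np.array_equal(on, self.indicators.astype(bool)):
            raise ValueError("indicators inconsistent with weights")
        if t > 0 and on.sum() > int(1.0 / t):
            raise ValueError("cardinality bound exceeded")


# ---------------------------------------------------------------------------
# problem construction
# ---------------------------------------------------------------------------

def build_problem(residual_map: DensityMap, candidates: list[FitCandidate],
                  d: float, t: float) -> SelectionProblem:
    """Assemble target and candidate columns over the union mask.

    The mask is the union of spheres of radius r(d) around every candidate's
    mask-generating atoms (sidechain Cb and beyond, carbonyl O; for glycine
    just the carbonyl O)."""
    positions = np.concatenate([np.atleast_2d(c.mask_positions)
                                for c in candidates], axis=0)
    r = mask_radius(d)
    mask = build_mask(residual_map, positions, r)
    if len(mask) == 0:
        raise ValueError("empty fitting mask")
    centers = residual_map.voxel_centers(mask.indices)
    target = residual_map.values_at(mask.indices)
    cols = np.empty((len(mask), len(candidates)))
    for i, c in enumerate(candidates):
        cols[:, i] = density_at_points(c.atoms, centers)
    return SelectionProblem(target, cols, t, d, mask)


# ---------------------------------------------------------------------------
# convex pre-fit (threshold relaxed to zero)
# ---------------------------------------------------------------------------

def _project_capped_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {w >= 0, sum w <= 1}."""
    w = np.clip(v, 0.0, None)
    s = w.sum()
    if s <= 1.0:
        return w
    # project onto the probability simplex (sum == 1)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / (np.arange(len(v)) + 1) > 0)[0][-1]
    tau = css[rho] / (rho + 1.0)
    return np.clip(v - tau, 0.0, None)


def qp_fit(problem: SelectionProblem, max_iter: int = 5000,
           tol: float = 1e-12) -> OccupancySolution:
    """Global optimum of the relaxed QP: min ||rho_o - A w||^2 with w >= 0
    and sum(w) <= 1 (accelerated projected gradient plus an exact polish on
    the identified support)."""
    A = problem.columns
    y = problem.target
    n = problem.n_candidates
    G = A.T @ A
    b = A.T @ y
    try:
        L = 2.0 * float(np.linalg.eigvalsh(G)[-1])
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            f"QP solver failure; Gram condition {np.linalg.cond(G):.2e}"
        ) from exc
    if L <= 0:
        return OccupancySolution(np.zeros(n), np.zeros(n, dtype=int),
                                 float(y @ y), "relaxation", 0.0)
    w = np.zeros(n)
    z = w.copy()
    tk = 1.0
    f_prev = np.inf
    for _ in range(max_iter):
        grad = 2.0 * (G @ z - b)
        w_new = _project_capped_simplex(z - grad / L)
        tk_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        z = w_new + (tk - 1.0) / tk_new * (w_new - w)
        w, tk = w_new, tk_new
        f = float(w @ G @ w - 2 * b @ w)
        if abs(f_prev - f) < tol * max(1.0, abs(f)):
            break
        f_prev = f
    w[w < 1e-9] = 0.0
    support = np.nonzero(w)[0]
    if len(support):
        ws = _polish_support(A[:, support], y, G[np.ix_(support, support)],
                             b[support])
        w = np.zeros(n)
        w[support] = ws
        w[w < 1e-9] = 0.0
    obj = float(np.sum((y - A @ w) ** 2))
    return OccupancySolution(w, (w > 0).astype(int), obj, "relaxation", 0.0)


def _polish_support(A, y, G, b, iters: int = 50) -> np.ndarray:
    """Exact minimization over {w >= 0, sum <= 1} restricted to a support,
    by active-set iteration on the nonnegativity and sum constraints."""
    m = A.shape[1]
    active_zero: set[int] = set()
    for _ in range(iters):
        free = [i for i in range(m) if i not in active_zero]
        if not free:
            return np.zeros(m)
        Gf = G[np.ix_(free, free)]
        bf = b[free]
        w_free = _solve_psd(Gf, bf)
        sum_active = w_free.sum() > 1.0 + 1e-12
        if sum_active:
            ones = np.ones(len(free))
            K = np.block([[2.0 * Gf, ones[:, None]], [ones[None, :], np.zeros((1, 1))]])
            rhs = np.concatenate([2.0 * bf, [1.0]])
            sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
            w_free = sol[:len(free)]
        neg = [f for f, v in zip(free, w_free) if v < -1e-12]
        if not neg:
            w = np.zeros(m)
            for f, v in zip(free, w_free):
                w[f] = max(v, 0.0)
            return w
        active_zero.update(neg)
    return np.clip(w_free, 0, None)  # pragma: no cover


def _solve_psd(G, b):
    try:
        return np.linalg.solve(2.0 * G, 2.0 * b)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(2.0 * G, 2.0 * b, rcond=None)
        return sol


# ---------------------------------------------------------------------------
# exact MIQP over support sets
# ---------------------------------------------------------------------------

def _support_solve(A: np.ndarray, y: np.ndarray, t: float
                   ) -> tuple[np.ndarray, float] | None:
    """Exact minimum of ||A w - y||^2 with t <= w_i <= 1, sum w <= 1,
    via enumeration of active-set patterns (exact for small supports).

    Returns (w, objective) or None if infeasible."""
    m = A.shape[1]
    if m * t > 1.0 + 1e-12:
        return None
    G = A.T @ A
    b = A.T @ y

    def finish(w):
        w = np.asarray(w, float)
        if np.any(w < t - 1e-9) or np.any(w > 1 + 1e-9) or w.sum() > 1 + 1e-9:
            return None
        w = np.clip(w, t, 1.0)
        if w.sum() > 1.0:
            return None
        obj = float(np.sum((y - A @ w) ** 2))
        return w, obj

    # fast path: unconstrained optimum feasible?
    w0 = _solve_psd(G, b)
    res = finish(w0)
    best = res
    if best is not None and np.all(w0 > t + 1e-9) and np.all(w0 < 1 - 1e-9) \
            and w0.sum() < 1 - 1e-9:
        return best
    # primal-dual active-set iteration; a verified KKT certificate is a
    # proof of global optimality for this convex QP, so on success the
    # pattern enumeration below is skipped entirely
    res = _pdas_solve(A, G, b, y, t, w0)
    if res is not None:
        return res
    # enumerate bound patterns: each variable free / at t / at 1,
    # with the sum constraint inactive or tight
    for pattern in itertools.product((0, 1, 2), repeat=m):
        for sum_tight in (False, True):
            free = [i for i in range(m) if pattern[i] == 0]
            fixed = {i: (t if pattern[i] == 1 else 1.0)
                     for i in range(m) if pattern[i] != 0}
            fixed_sum = sum(fixed.values())
            if fixed_sum > 1.0 + 1e-9:
                continue
            w = np.zeros(m)
            for i, v in fixed.items():
                w[i] = v
            if free:
                bf = b[free] - G[np.ix_(free, list(fixed))] @ np.array(
                    list(fixed.values())) if fixed else b[free]
                Gf = G[np.ix_(free, free)]
                if sum_tight:
                    ones = np.ones(len(free))
                    K = np.block([[2.0 * Gf, ones[:, None]],
                                  [ones[None, :], np.zeros((1, 1))]])
                    rhs = np.concatenate([2.0 * bf, [1.0 - fixed_sum]])
                    try:
                        sol = np.linalg.solve(K, rhs)
                    except np.linalg.LinAlgError:
                        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
                    w[free] = sol[:len(free)]
                else:
                    w[free] = _solve_psd(Gf, bf)
            elif sum_tight and abs(fixed_sum - 1.0) > 1e-9:
                continue
            res = finish(w)
            if res is not None and (best is None or res[1] < best[1] - 1e-12):
                best = res
    return best


def _pdas_solve(A, G, b, y, t, w0, max_iter: int = 40, eps: float = 1e-10
                ) -> tuple[np.ndarray, float] | None:
    """Primal-dual active-set solve of min ||A w - y||^2 with t <= w <= 1,
    sum w <= 1.  Returns the optimum only with a verified KKT certificate
    (primal + dual feasibility); otherwise None and the caller enumerates.
    """
    m = len(b)
    low = {i for i in range(m) if w0[i] <= t}
    up = {i for i in range(m) if w0[i] >= 1.0}
    sum_tight = float(np.clip(w0, t, 1.0).sum()) > 1.0

    prev_states = set()
    for _ in range(max_iter):
        state = (frozenset(low), frozenset(up), sum_tight)
        if state in prev_states:
            return None  # cycling; fall back to enumeration
        prev_states.add(state)
        free = [i for i in range(m) if i not in low and i not in up]
        fixed = {i: t for i in low}
        fixed.update({i: 1.0 for i in up})
        fixed_sum = sum(fixed.values())
        if fixed_sum > 1.0 + 1e-9:
            return None
        w = np.zeros(m)
        for i, v in fixed.items():
            w[i] = v
        lam = 0.0
        if free:
            idx_fixed = list(fixed)
            bf = b[free] - (G[np.ix_(free, idx_fixed)]
                            @ np.array([fixed[i] for i in idx_fixed])
                            if idx_fixed else 0.0)
            Gf = G[np.ix_(free, free)]
            if sum_tight:
                ones = np.ones(len(free))
                K = np.block([[2.0 * Gf, ones[:, None]],
                              [ones[None, :], np.zeros((1, 1))]])
                rhs = np.concatenate([2.0 * bf, [1.0 - fixed_sum]])
                try:
                    sol = np.linalg.solve(K, rhs)
                except np.linalg.LinAlgError:
                    sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
                w[free] = sol[:-1]
                lam = float(sol[-1])
            else:
                w[free] = _solve_psd(Gf, bf)
        elif sum_tight and abs(fixed_sum - 1.0) > 1e-9:
            sum_tight = False
            continue

        grad = 2.0 * (G @ w - b)
        r = grad + lam
        changed = False
        # primal violations by free variables
        for i in list(free):
            if w[i] < t - eps:
                low.add(i)
                changed = True
            elif w[i] > 1.0 + eps:
                up.add(i)
                changed = True
        # dual violations by active bounds
        for i in list(low):
            if r[i] < -eps:
                low.discard(i)
                changed = True
        for i in list(up):
            if r[i] > eps:
                up.discard(i)
                changed = True
        # sum-constraint state
        if sum_tight and lam < -eps:
            sum_tight = False
            changed = True
        elif not sum_tight and w.sum() > 1.0 + eps:
            sum_tight = True
            changed = True
        if not changed:
            # full KKT certificate
            if (np.all(w >= t - 1e-9) and np.all(w <= 1.0 + 1e-9)
                    and w.sum() <= 1.0 + 1e-9
                    and all(r[i] >= -1e-7 for i in low)
                    and all(r[i] <= 1e-7 for i in up)
                    and (not sum_tight or lam >= -1e-9)
                    and (sum_tight or w.sum() <= 1.0 + 1e-9)
                    and all(abs(r[i]) <= 1e-6 * max(1.0, np.abs(r).max())
                            for i in free)):
                w = np.clip(w, t, 1.0)
                s = w.sum()
                if s > 1.0 + 1e-9:
                    return None
                if s > 1.0:  # shave numerical excess (<= 1e-9)
                    w = w / s
                obj = float(np.sum((y - A @ w) ** 2))
                return w, obj
            return None
    return None


def miqp_select(problem: SelectionProblem,
                prefit: OccupancySolution | None = None) -> OccupancySolution:
    """Exact MIQP optimum over the pre-fit survivors.

    Candidates with non-vanishing relaxed occupancy survive; every support
    set of size <= floor(1/t) is solved exactly and the best kept.  Ties are
    broken toward fewer conformers, then lexicographic support."""
    if prefit is None:
        prefit = qp_fit(problem)
    t = problem.threshold
    n = problem.n_candidates
    y = problem.target
    A = problem.columns
    if n <= MAX_FULL_ENUM:
        # pre-fit pruning exists only to bound the enumeration; at small
        # candidate counts (notably fragment synchronization, whose combined
        # columns are highly collinear so the relaxed optimum is non-unique)
        # restricting to one relaxed support can lose the integer optimum
        survivors = list(range(n))
    else:
        survivors = list(np.nonzero(prefit.weights > 1e-6)[0])
    if not survivors:
        survivors = [int(np.argmax(np.abs(A.T @ y)))]
    if len(survivors) > MAX_SURVIVORS:
        logger.warning("%d survivors exceed cap %d; keeping largest pre-fit "
                       "weights", len(survivors), MAX_SURVIVORS)
        order = np.argsort(prefit.weights[survivors])[::-1]
        survivors = [survivors[i] for i in order[:MAX_SURVIVORS]]
        survivors.sort()
    card = min(problem.cardinality(), len(survivors))
    G_all = A.T @ A
    b_all = A.T @ y
    yy = float(y @ y)
    # Vectorized unconstrained lower bound per support: the LS minimum on a
    # support can only be undercut by adding constraints.  Supports are
    # processed in tie-break order (size, then lexicographic), so any
    # support pruned by "bound >= incumbent" either cannot win or ties the
    # incumbent while losing the tie-break -- pruning is exact.
    entries = []  # (lb, size, support)
    for size in range(1, card + 1):
        if size * t > 1.0 + 1e-12:
            continue
        combs = np.array(list(itertools.combinations(survivors, size)),
                         dtype=int)
        Gb = G_all[combs[:, :, None], combs[:, None, :]]
        bb = b_all[combs]
        ridge = 1e-12 * max(float(np.trace(G_all)), 1.0)
        Gb = Gb + ridge * np.eye(size)
        try:
            w_u = np.linalg.solve(Gb, bb[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            w_u = np.stack([np.linalg.lstsq(Gb[i], bb[i], rcond=None)[0]
                            for i in range(len(combs))])
        lbs = (yy - 2.0 * np.einsum("ij,ij->i", bb, w_u)
               + np.einsum("ij,ijk,ik->i", w_u, Gb, w_u))
        for c, lb in zip(combs, lbs):
            entries.append((float(lb), size, tuple(int(i) for i in c)))
    entries.sort(key=lambda e: (e[1], e[2]))

    best = None  # (objective, size, support, weights)
    for lb, size, support in entries:
        if best is not None and lb >= best[0] - 1e-12:
            continue
        res = _support_solve(A[:, list(support)], y, t)
        if res is None:
            continue
        w_s, obj = res
        if best is None or obj < best[0] - 1e-12 or (
            abs(obj - best[0]) <= 1e-12
            and (size, support) < (best[1], best[2])
        ):
            best = (obj, size, support, w_s)
    if best is None:
        raise RuntimeError("MIQP found no feasible support")
    obj, _size, support, w_s = best
    w = np.zeros(n)
    for i, v in zip(support, w_s):
        w[i] = v
    sol = OccupancySolution(w, (w > 1e-9).astype(int), obj, "exhaustive", t)
    sol.validate()
    return sol


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def _combine(per_residue: list[list[FitCandidate]],
             combos) -> list[FitCandidate]:
    out = []
    for combo in combos:
        atoms = []
        pos = []
        for res_cands, idx in zip(per_residue, combo):
            c = res_cands[idx]
            atoms.extend(c.atoms)
            pos.append(np.atleast_2d(c.mask_positions))
        out.append(FitCandidate(atoms, np.concatenate(pos, axis=0), tuple(combo)))
    return out


def fragment_select(per_residue: list[list[FitCandidate]],
                    residual_map: DensityMap, d: float, t: float,
                    cap: int = COMBINATORIAL_CAP
                    ) -> tuple[OccupancySolution, list[FitCandidate]]:
    """Synchronize conformers over consecutive residues.

    All C_f = prod_i C_i combinations of per-residue conformers become
    combined candidates; one MIQP selects at most floor(1/t) of them, each
    with a single occupancy shared by every atom of the fragment.  Above
    ``cap`` combinations the divide-and-conquer path is taken."""
    c_f = int(np.prod([len(c) for c in per_residue]))
    if c_f > cap:
        return divide_and_conquer(per_residue, residual_map, d, t, cap)
    combos = itertools.product(*(range(len(c)) for c in per_residue))
    combined = _combine(per_residue, combos)
    problem = build_problem(residual_map, combined, d, t)
    sol = miqp_select(problem)
    return sol, combined


def divide_and_conquer(per_residue: list[list[FitCandidate]],
                       residual_map: DensityMap, d: float, t: float,
                       cap: int = COMBINATORIAL_CAP
                       ) -> tuple[OccupancySolution, list[FitCandidate]]:
    """Fit long fragments by splitting near the midpoint, MIQP-fitting each
    segment, recombining the surviving segment conformations, and re-fitting
    the recombination with MIQP."""
    c_f = int(np.prod([len(c) for c in per_residue]))
    if c_f <= cap:
        return fragment_select(per_residue, residual_map, d, t, cap)
    mid = len(per_residue) // 2
    left, right = per_residue[:mid], per_residue[mid:]

    def survivors(side):
        sol, combined = divide_and_conquer(side, residual_map, d, t, cap)
        keep = [combined[i] for i in sol.support]
        return keep if keep else combined[:1]

    left_keep = survivors(left)
    right_keep = survivors(right)
    recombined = []
    for lc in left_keep:
        for rc in right_keep:
            recombined.append(FitCandidate(
                lc.atoms + rc.atoms,
                np.concatenate([np.atleast_2d(lc.mask_positions),
                                np.atleast_2d(rc.mask_positions)], axis=0),
                (lc.meta, rc.meta),
            ))
    problem = build_problem(residual_map, recombined, d, t)
    sol = miqp_select(problem)
    sol.provenance = "divide-and-conquer"
    return sol, recombined
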