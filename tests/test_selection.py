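"""QP pre-fit and MIQP occupancy selection."""

import itertools

import numpy as np
import pytest

from altconf.density import DensityMap, calc_density, grid_for_atoms, mask_radius
from altconf.model import Atom
from altconf.selection import (
    FitCandidate, OccupancySolution, SelectionProblem, build_problem,
    divide_and_conquer, fragment_select, miqp_select, qp_fit,
    threshold_for_resolution,
)


def _problem(rng, n_vox=200, n_cand=10, t=0.25, truth=None, noise=0.0):
    A = rng.random((n_vox, n_cand))
    w = np.zeros(n_cand)
    for i, v in (truth or {}).items():
        w[i] = v
    y = A @ w + noise * rng.standard_normal(n_vox)
    return SelectionProblem(y, A, t, 1.5)


def _slsqp_oracle(problem):
    """Independent brute-force optimum: SLSQP over every support set."""
    from scipy.optimize import minimize

    A, y, t = problem.columns, problem.target, problem.threshold
    n = problem.n_candidates
    card = min(int(1 / t), n)
    best = np.inf
    for size in range(1, card + 1):
        if size * t > 1 + 1e-12:
            continue
        for S in itertools.combinations(range(n), size):
            As = A[:, list(S)]
            x0 = np.full(size, max(t, 1.0 / size) if size * t <= 1 else t)
            r = minimize(lambda w: np.sum((y - As @ w) ** 2), x0,
                         method="SLSQP", bounds=[(t, 1)] * size,
                         constraints=[{"type": "ineq",
                                       "fun": lambda w: 1 - np.sum(w)}],
                         options={"maxiter": 300, "ftol": 1e-14})
            best = min(best, r.fun)
    return best


class TestQPFit:
    def test_single_candidate_exact(self, rng):
        p = _problem(rng, n_cand=1, truth={0: 1.0})
        sol = qp_fit(p)
        assert sol.weights[0] == pytest.approx(1.0, abs=1e-9)
        assert sol.objective == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_70_30_recovered(self, rng):
        p = _problem(rng, truth={2: 0.7, 5: 0.3})
        sol = qp_fit(p)
        assert sol.weights[2] == pytest.approx(0.7, abs=1e-6)
        assert sol.weights[5] == pytest.approx(0.3, abs=1e-6)
        assert np.all(np.delete(sol.weights, [2, 5]) < 1e-6)

    def test_orthogonal_candidate_gets_zero(self, rng):
        A = np.zeros((60, 2))
        A[:30, 0] = 1.0
        A[30:, 1] = 1.0  # orthogonal columns
        y = 0.8 * A[:, 0]
        p = SelectionProblem(y, A, 0.25, 1.5)
        sol = qp_fit(p)
        assert sol.weights[1] == pytest.approx(0.0, abs=1e-9)

    def test_sum_constraint_binds(self, rng):
        p = _problem(rng, n_cand=3)
        p = SelectionProblem(3.0 * p.columns @ np.ones(3), p.columns, 0.25, 1.5)
        sol = qp_fit(p)
        assert sol.weights.sum() <= 1.0 + 1e-9


class TestMIQP:
    def test_threshold_one_selects_single_best(self, rng):
        p = _problem(rng, t=1.0, truth={3: 0.9})
        sol = miqp_select(p)
        assert sol.indicators.sum() == 1
        assert sol.support[0] == 3

    def test_cardinality_bound_floor_inverse_t(self, rng):
        p = _problem(rng, t=0.25,
                     truth={0: 0.3, 1: 0.25, 2: 0.25, 3: 0.2})
        sol = miqp_select(p)
        assert sol.indicators.sum() <= 4

    def test_50_50_truth_beats_decoys(self, rng):
        p = _problem(rng, n_cand=12, t=0.2, truth={1: 0.5, 7: 0.5})
        sol = miqp_select(p)
        assert set(sol.support) == {1, 7}
        assert sol.weights[1] == pytest.approx(0.5, abs=1e-6)
        assert sol.weights[7] == pytest.approx(0.5, abs=1e-6)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 13))
            t = float(rng.uniform(0.15, 1.0))
            k = int(rng.integers(1, max(2, min(int(1 / t), n) + 1)))
            idx = rng.choice(n, size=min(k, n), replace=False)
            vals = rng.dirichlet(np.ones(len(idx)))
            truth = {int(i): float(max(v, 0.05)) for i, v in zip(idx, vals)}
            p = _problem(rng, n_cand=n, t=t, truth=truth, noise=0.02)
            sol = miqp_select(p)
            sol.validate()
            oracle = _slsqp_oracle(p)
            assert sol.objective <= oracle + 1e-6 + 1e-6 * abs(oracle)

    def test_relaxation_bound_and_singleton_bound(self, rng):
        for _ in range(10):
            p = _problem(rng, n_cand=8, t=float(rng.uniform(0.2, 0.6)),
                         truth={0: 0.6, 4: 0.4}, noise=0.05)
            prefit = qp_fit(p)
            sol = miqp_select(p, prefit)
            assert prefit.objective <= sol.objective + 1e-9
            singles = []
            for i in range(p.n_candidates):
                from altconf.selection import _support_solve
                r = _support_solve(p.columns[:, [i]], p.target, p.threshold)
                if r is not None:
                    singles.append(r[1])
            assert sol.objective <= min(singles) + 1e-9

    def test_weights_respect_threshold_interval(self, rng):
        for _ in range(20):
            t = float(rng.uniform(0.1, 1.0))
            p = _problem(rng, n_cand=6, t=t,
                         truth={0: 0.5, 3: 0.5}, noise=0.1)
            sol = miqp_select(p)
            on = sol.weights > 1e-9
            assert np.all(sol.weights[on] >= t - 1e-6)
            assert sol.weights.sum() <= 1 + 1e-6
            assert on.sum() <= int(1 / t)

    def test_invalid_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            SelectionProblem(np.zeros(5), np.ones((5, 2)), 0.0, 1.5)
        with pytest.raises(ValueError):
            SelectionProblem(np.zeros(5), np.ones((5, 2)), 1.2, 1.5)


class TestBuildProblem:
    def _candidates(self, shift=0.0):
        out = []
        for x in (4.0 + shift, 6.0 + shift):
            atoms = [Atom("OG", "O", [x, 5, 5], 1.0, 12.0)]
            out.append(FitCandidate(atoms, np.array([[x, 5, 5.0]])))
        return out

    def test_masked_voxels_within_radius(self):
        cands = self._candidates()
        g = grid_for_atoms([Atom("C", "C", [5, 5, 5], 1.0, 10.0)], 1.5,
                           spacing=0.4, pad=5.0)
        prob = build_problem(g, cands, 1.5, 0.25)
        centers = g.voxel_centers(prob.mask.indices)
        pos = np.concatenate([c.mask_positions for c in cands])
        dmin = np.min(np.linalg.norm(
            centers[:, None, :] - pos[None, :, :], axis=2), axis=1)
        assert np.all(dmin <= mask_radius(1.5) + 1e-9)

    def test_mask_union_is_monotone(self):
        g = grid_for_atoms([Atom("C", "C", [5, 5, 5], 1.0, 10.0)], 1.5,
                           spacing=0.4, pad=5.0)
        small = build_problem(g, self._candidates(), 1.5, 0.25)
        big = build_problem(g, self._candidates() + self._candidates(1.0),
                            1.5, 0.25)
        small_set = {tuple(i) for i in small.mask.indices}
        big_set = {tuple(i) for i in big.mask.indices}
        assert small_set <= big_set


class TestFragments:
    def _per_residue(self, rng, counts, spread=3.0):
        """Per-residue candidate lists of single-atom conformers."""
        per = []
        x = 4.0
        for c in counts:
            cands = []
            for j in range(c):
                atoms = [Atom("O", "O", [x, 5 + j * spread, 5], 1.0, 10.0)]
                cands.append(FitCandidate(atoms, np.array([[x, 5 + j * spread,
                                                            5.0]])))
            per.append(cands)
            x += 3.0
        return per

    def _residual(self, per, weights_by_combo, d=2.0):
        all_atoms = [a for cands in per for c in cands for a in c.atoms]
        g = grid_for_atoms(all_atoms, d, spacing=0.5, pad=3.0)
        residual = g.like()
        for combo, w in weights_by_combo.items():
            atoms = []
            for cands, idx in zip(per, combo):
                atoms.extend(cands[idx].atoms)
            part = calc_density(
                [Atom(a.name, a.element, a.position, w, a.b_iso)
                 for a in atoms], g, d)
            residual.values += part.values
        return residual

    def test_combined_count_is_product(self, rng):
        per = self._per_residue(rng, (2, 3, 2))
        residual = self._residual(per, {(0, 0, 0): 1.0})
        sol, combined = fragment_select(per, residual, 2.0, 0.25)
        assert len(combined) == 12

    def test_k1_equals_per_residue_miqp(self, rng):
        per = self._per_residue(rng, (3,))
        residual = self._residual(per, {(1,): 1.0})
        sol, combined = fragment_select(per, residual, 2.0, 0.25)
        prob = build_problem(residual, per[0], 2.0, 0.25)
        direct = miqp_select(prob)
        assert set(sol.support) == set(direct.support)
        assert sol.objective == pytest.approx(direct.objective, rel=1e-9)

    def test_two_state_fragment_recovered_50_50(self, rng):
        per = self._per_residue(rng, (2, 2, 2, 2, 2, 2))
        truth = {(0,) * 6: 0.5, (1,) * 6: 0.5}
        residual = self._residual(per, truth)
        sol, combined = divide_and_conquer(per, residual, 2.0, 0.25, cap=16)
        chosen = {combined[i].meta if isinstance(combined[i].meta, tuple)
                  else combined[i].meta: sol.weights[i] for i in sol.support}
        ws = sorted(sol.weights[sol.support], reverse=True)
        assert len(ws) >= 2
        assert abs(ws[0] - 0.5) < 0.1 and abs(ws[1] - 0.5) < 0.1

    def test_divide_and_conquer_matches_exhaustive_below_cap(self, rng):
        per = self._per_residue(rng, (2, 2))
        residual = self._residual(per, {(0, 1): 0.6, (1, 0): 0.4})
        s1, c1 = fragment_select(per, residual, 2.0, 0.25)
        s2, c2 = divide_and_conquer(per, residual, 2.0, 0.25, cap=1024)
        assert s1.objective == pytest.approx(s2.objective, rel=1e-9)

    def test_divide_and_conquer_near_optimal(self, rng):
        # noisy truths keep the exhaustive optimum away from zero so the
        # relative gap is well defined
        gaps = []
        for trial in range(10):
            r2 = np.random.default_rng(100 + trial)
            per = self._per_residue(r2, (2, 2, 2, 2), spread=4.0)
            combo = tuple(int(c) for c in r2.integers(0, 2, size=4))
            other = tuple(1 - c for c in combo)
            residual = self._residual(per, {combo: 0.6, other: 0.4})
            residual.values += 0.05 * residual.values.std() \
                * r2.standard_normal(residual.values.shape)
            exh, _ = fragment_select(per, residual, 2.0, 0.25, cap=1024)
            dc, _ = divide_and_conquer(per, residual, 2.0, 0.25, cap=4)
            gaps.append((dc.objective - exh.objective)
                        / max(exh.objective, 1e-9))
        assert np.mean(gaps) < 0.05
        assert all(g >= -1e-9 for g in gaps)


def test_threshold_schedule():
    assert threshold_for_resolution(1.0) == 0.25
    assert threshold_for_resolution(1.79) == 0.25
    assert threshold_for_resolution(1.8) == pytest.approx(1 / 3)
    assert threshold_for_resolution(2.5) == pytest.approx(1 / 3)
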