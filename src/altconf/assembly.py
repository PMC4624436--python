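"""Model assembly: altloc relabeling by downhill Monte Carlo on a
Lennard-Jones score, duplicate-conformer merging, and occupancy
renormalization.

Per-residue fitting leaves conformer labels arbitrary; physically, atoms can
only coexist in one crystal copy if their altloc letters match.  The
relabeler permutes letters within each residue to minimize a simple 12-6
Lennard-Jones score summed over non-bonded atom pairs that share a letter
(or involve a shared, blank-altloc atom), accepting only improving swaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .model import ProteinModel, ResidueEnsemble

__all__ = [
    "LJParams",
    "LabelAssignment",
    "lj_score",
    "monte_carlo_relabel",
    "apply_assignment",
    "merge_duplicate_conformers",
]

_DEFAULT_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90,
                "P": 1.80, "H": 1.20}


@dataclass
class LJParams:
    """12-6 potential with minimum -epsilon at the vdW radius sum."""
    vdw: dict = field(default_factory=lambda: dict(_DEFAULT_VDW))
    epsilon: float = 1.0
    cutoff: float = 6.0

    def radius(self, element: str) -> float:
        return self.vdw.get(element.upper(), 1.7)


@dataclass
class LabelAssignment:
    """Per-residue permutation: ``perm[key][conformer_index] = label slot``."""
    perm: dict[tuple, tuple[int, ...]]
    score: float = 0.0

    def copy(self) -> "LabelAssignment":
        return LabelAssignment(dict(self.perm), self.score)


def _pair_term(r2: float, rmin: float, eps: float) -> float:
    s6 = (rmin * rmin / r2) ** 3
    return eps * (s6 * s6 - 2.0 * s6)


@lru_cache(maxsize=None)
def _intra_distances(resname: str) -> dict[tuple[str, str], int]:
    """Bond-count distances between heavy atoms within a residue type."""
    from .sidechain import _template

    names, _els, _coords, adj = _template(resname)
    import collections
    out = {}
    for i, src in enumerate(names):
        dist = {i: 0}
        dq = collections.deque([i])
        while dq:
            cur = dq.popleft()
            for nb in adj[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + 1
                    dq.append(nb)
        for j, dst in enumerate(names):
            if j in dist:
                out[(src, dst)] = dist[j]
    return out


def _bond_separation(res_i: ResidueEnsemble, name_a: str,
                     res_j: ResidueEnsemble, name_b: str) -> int:
    """Covalent bond count between two atoms; large when not near-bonded.
    Only same-residue and peptide-adjacent pairs can be <= 3 bonds apart."""
    big = 99
    try:
        if res_i.key == res_j.key:
            return _intra_distances(res_i.name).get((name_a, name_b), big)
        if res_i.chain != res_j.chain:
            return big
        if res_j.resseq == res_i.resseq + 1:
            d1 = _intra_distances(res_i.name).get((name_a, "C"), big)
            d2 = _intra_distances(res_j.name).get(("N", name_b), big)
            return d1 + 1 + d2
        if res_i.resseq == res_j.resseq + 1:
            return _bond_separation(res_j, name_b, res_i, name_a)
    except KeyError:
        pass
    return big


def _labels_interact(la: str | None, lb: str | None) -> bool:
    """Atoms coexist if either is shared (blank) or letters match."""
    return la is None or lb is None or la == lb


def _residue_pair_score(res_i: ResidueEnsemble, res_j: ResidueEnsemble,
                        slots_i, slots_j, params: LJParams) -> float:
    """LJ sum over interacting atom pairs of two residues.  ``slots`` maps
    conformer index -> label slot; shared atoms count once (slot None)."""
    cut2 = params.cutoff ** 2
    score = 0.0
    for ci, conf_i in enumerate(res_i.conformers):
        multi_i = len(res_i.conformers) > 1
        for ai in conf_i.atoms:
            if ai.shared and ci > 0:
                continue
            slot_i = None if (ai.shared or not multi_i) else slots_i[ci]
            for cj, conf_j in enumerate(res_j.conformers):
                multi_j = len(res_j.conformers) > 1
                for aj in conf_j.atoms:
                    if aj.shared and cj > 0:
                        continue
                    slot_j = None if (aj.shared or not multi_j) else slots_j[cj]
                    if not _labels_interact(slot_i, slot_j):
                        continue
                    diff = ai.position - aj.position
                    r2 = float(diff @ diff)
                    if r2 > cut2 or r2 < 1e-6:
                        continue
                    if _bond_separation(res_i, ai.name, res_j, aj.name) <= 3:
                        continue
                    rmin = params.radius(ai.element) + params.radius(aj.element)
                    score += _pair_term(r2, rmin, params.epsilon)
    return score


def _identity_assignment(model: ProteinModel) -> LabelAssignment:
    return LabelAssignment({
        r.key: tuple(range(len(r.conformers))) for r in model.residues
    })


def lj_score(model: ProteinModel, assignment: LabelAssignment | None,
             params: LJParams | None = None) -> float:
    """Total Lennard-Jones score of the labeled model: 12-6 terms over
    non-bonded (separation > 3 bonds) atom pairs of distinct residues that
    share an altloc letter or involve a blank-altloc atom, within cutoff.
    Intra-residue pairs are label-invariant and excluded."""
    params = params or LJParams()
    assignment = assignment or _identity_assignment(model)
    residues = model.residues
    total = 0.0
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            ri, rj = residues[i], residues[j]
            total += _residue_pair_score(
                ri, rj, assignment.perm[ri.key], assignment.perm[rj.key], params)
    return total


def _conformer_pair_energy(res_i: ResidueEnsemble, res_j: ResidueEnsemble,
                           params: LJParams) -> np.ndarray | None:
    """Label-dependent LJ energies between the non-shared atoms of every
    conformer pair of two multiconformer residues; None when out of reach."""
    cut2 = params.cutoff ** 2
    E = np.zeros((len(res_i.conformers), len(res_j.conformers)))
    any_pair = False
    for ci, conf_i in enumerate(res_i.conformers):
        atoms_i = [a for a in conf_i.atoms if not a.shared]
        for cj, conf_j in enumerate(res_j.conformers):
            s = 0.0
            for ai in atoms_i:
                for aj in conf_j.atoms:
                    if aj.shared:
                        continue
                    diff = ai.position - aj.position
                    r2 = float(diff @ diff)
                    if r2 > cut2 or r2 < 1e-6:
                        continue
                    if _bond_separation(res_i, ai.name, res_j, aj.name) <= 3:
                        continue
                    rmin = params.radius(ai.element) + params.radius(aj.element)
                    s += _pair_term(r2, rmin, params.epsilon)
                    any_pair = True
            E[ci, cj] = s
    return E if any_pair else None


def monte_carlo_relabel(model: ProteinModel, params: LJParams | None = None,
                        steps: int = 10000, trials: int = 10,
                        seed=None) -> LabelAssignment:
    """Downhill Monte Carlo label optimization: per trial, up to ``steps``
    random pairwise label swaps at random multiconformer residues, each
    accepted only if the score strictly improves; best of ``trials``
    returned.

    Only interactions between labeled (non-shared) atoms of multiconformer
    residue pairs depend on the labeling, so those pair energies are
    precomputed once and each proposal is scored incrementally.  Because
    acceptance is strictly downhill, a trial provably cannot improve further
    once every distinct swap has been rejected from the current state; each
    trial therefore stops early at such a local optimum (the outcome is
    identical to exhausting the remaining steps)."""
    params = params or LJParams()
    rng = np.random.default_rng(seed)
    residues = model.residues
    multi_idx = [i for i, r in enumerate(residues) if len(r.conformers) > 1]
    base = _identity_assignment(model)
    base.score = lj_score(model, base, params)
    if not multi_idx:
        return base

    # precompute label-dependent pair energies between nearby multi residues
    pair_E: dict[tuple[int, int], np.ndarray] = {}
    partners: dict[int, list[int]] = {i: [] for i in multi_idx}
    for a in range(len(multi_idx)):
        for b in range(a + 1, len(multi_idx)):
            i, j = multi_idx[a], multi_idx[b]
            E = _conformer_pair_energy(residues[i], residues[j], params)
            if E is not None:
                pair_E[(i, j)] = E
                partners[i].append(j)
                partners[j].append(i)

    def variable_score(slots: dict[int, list[int]]) -> float:
        s = 0.0
        for (i, j), E in pair_E.items():
            for ci, li in enumerate(slots[i]):
                for cj, lj in enumerate(slots[j]):
                    if li == lj:
                        s += E[ci, cj]
        return s

    id_slots = {i: list(range(len(residues[i].conformers))) for i in multi_idx}
    const = base.score - variable_score(id_slots)

    def swap_delta(slots, i, a, b) -> float:
        delta = 0.0
        la, lb = slots[i][a], slots[i][b]
        for j in partners[i]:
            E = pair_E[(i, j)] if (i, j) in pair_E else pair_E[(j, i)].T
            for cj, lj in enumerate(slots[j]):
                if lj == la:
                    delta += E[b, cj] - E[a, cj]
                elif lj == lb:
                    delta += E[a, cj] - E[b, cj]
        return delta

    all_swaps = [(i, a, b) for i in multi_idx
                 for a in range(len(residues[i].conformers))
                 for b in range(a + 1, len(residues[i].conformers))]
    best_slots = None
    best_var = None
    for _trial in range(trials):
        slots = {i: list(range(len(residues[i].conformers))) for i in multi_idx}
        var = variable_score(slots)
        rejections = 0
        step = 0
        while step < steps:
            i = multi_idx[rng.integers(len(multi_idx))]
            n = len(residues[i].conformers)
            a, b = rng.choice(n, size=2, replace=False)
            d = swap_delta(slots, i, int(a), int(b))
            step += 1
            if d < -1e-12:
                slots[i][a], slots[i][b] = slots[i][b], slots[i][a]
                var += d
                rejections = 0
            else:
                rejections += 1
            if rejections >= 2 * len(all_swaps):
                # exhaustive check: at a strict local optimum every further
                # downhill step must reject, so stopping is exact
                if all(swap_delta(slots, *sw) >= -1e-12 for sw in all_swaps):
                    break
                rejections = 0
        if best_var is None or var < best_var - 1e-12:
            best_var = var
            best_slots = {i: list(v) for i, v in slots.items()}

    perm = dict(base.perm)
    for i in multi_idx:
        perm[residues[i].key] = tuple(best_slots[i])
    return LabelAssignment(perm, const + best_var)


def apply_assignment(model: ProteinModel, assignment: LabelAssignment
                     ) -> ProteinModel:
    """Reorder/re-letter conformers per the assignment.  Only altloc letters
    change; coordinates, occupancies and B-factors are untouched."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = model.copy()
    for res in out.residues:
        if len(res.conformers) < 2:
            continue
        perm = assignment.perm[res.key]
        order = sorted(range(len(res.conformers)), key=lambda ci: perm[ci])
        res.conformers = [res.conformers[ci] for ci in order]
        for slot, conf in enumerate(res.conformers):
            conf.altloc = letters[slot]
            for a in conf.atoms:
                if not a.shared:
                    a.altloc = letters[slot]
    return out


def merge_duplicate_conformers(model: ProteinModel, tol: float = 0.15
                               ) -> ProteinModel:
    """Merge conformers indistinguishable within ``tol`` (all-atom RMSD),
    summing their occupancies, then rescale per-residue occupancies to sum
    to exactly 1.  Merging uses the transitive closure of the pairwise
    criterion, so the result is independent of conformer order."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    out = model.copy()
    for res in out.residues:
        confs = res.conformers
        n = len(confs)
        if n > 1:
            names = sorted(confs[0].atom_names())
            coords = [c.coords(names) for c in confs]
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i in range(n):
                for j in range(i + 1, n):
                    rmsd = float(np.sqrt(np.mean(
                        np.sum((coords[i] - coords[j]) ** 2, axis=1))))
                    if rmsd < tol:
                        parent[find(j)] = find(i)
            groups: dict[int, list[int]] = {}
            for i in range(n):
                groups.setdefault(find(i), []).append(i)
            merged = []
            for members in groups.values():
                members.sort()
                # representative: highest occupancy, coordinate tie-break so
                # the result is independent of conformer order
                rep_idx = min(
                    members,
                    key=lambda i: (-confs[i].occupancy,
                                   tuple(coords[i].ravel())))
                rep = confs[rep_idx].copy()
                rep.occupancy = sum(confs[i].occupancy for i in members)
                for a in rep.atoms:
                    a.occupancy = min(rep.occupancy, 1.0)
                merged.append((members[0], rep))
            merged.sort(key=lambda kv: kv[0])
            res.conformers = [c for _, c in merged]
        total = res.occupancy_sum()
        if total > 0:
            for c in res.conformers:
                c.occupancy /= total
                for a in c.atoms:
                    a.occupancy = c.occupancy if not a.shared else 1.0
        if len(res.conformers) == 1:
            conf = res.conformers[0]
            conf.altloc = ""
            for a in conf.atoms:
                a.altloc = ""
                a.shared = False
                a.occupancy = 1.0
            conf.occupancy = 1.0
    return out
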