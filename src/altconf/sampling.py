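"""Candidate conformer generation: thermal-ellipsoid-guided backbone
displacements, peptide-flip realization, nullspace inverse-kinematics
closure, and rotamer-library sidechain decoration.

Backbone sampling operates on a fragment of (up to) 7 consecutive residues
centered on the residue being rebuilt.  The free degrees of freedom are the
phi/psi dihedrals of the interior residues; the N, CA, C atoms of the first
and last fragment residues are anchors that must stay put.  A guide atom
(CB, or the carbonyl O for glycine) is pulled toward targets on the axes of
a thermal ellipsoid; every move is realized by projecting the pull onto the
nullspace of the anchor-closure Jacobian so chain geometry and anchors are
preserved exactly (moves are pure dihedral rotations).

The full candidate set per residue is (1 unflipped + 4 flipped) x
(1 undisplaced + 6 displaced) = 35 backbone conformations, or 7 where flip
sampling is suppressed (helices and sheets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .density import DensityMap
from .flips import FlipCluster, PeptideUnit, apply_flip_centroid
from .geometry import dihedral, rotation_about_axis, rotation_about_axis_rad
from .model import LARGE_SIDECHAINS, SMALL_SIDECHAINS, ProteinModel, RotamerEntry
from .sidechain import CHI_ATOMS, build_sidechain

logger = logging.getLogger(__name__)

__all__ = [
    "AnisoTensor",
    "SamplerConfig",
    "Fragment",
    "BackboneCandidate",
    "CandidateConformer",
    "density_moment_tensor",
    "sample_guide_displacements",
    "nullspace_ik_close",
    "enumerate_backbones",
    "decorate_small_sidechain",
    "decorate_large_sidechain",
    "decorate",
    "fragment_around",
    "secondary_structure",
]

#: chi offsets for the small-sidechain window: 40 deg in 10 deg steps
SMALL_OFFSETS = (-20.0, -10.0, 0.0, 10.0, 20.0)
#: proline: restricted window so the ring stays closed
PRO_OFFSETS = (-10.0, 0.0, 10.0)
#: large-sidechain hierarchical window: 50 deg in 4.5 deg steps (12 values)
LARGE_OFFSETS = tuple(-25.0 + 4.5 * i for i in range(12))


@dataclass
class AnisoTensor:
    """Symmetric PSD 3x3 displacement tensor (A^2) with sorted eigensystem."""
    tensor: np.ndarray
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)  # columns, matching order

    def __post_init__(self):
        t = np.asarray(self.tensor, dtype=float)
        if not np.allclose(t, t.T, atol=1e-8):
            raise ValueError("tensor must be symmetric")
        w, v = np.linalg.eigh(t)
        if w[0] < -1e-8:
            raise ValueError("tensor must be positive semi-definite")
        order = np.argsort(w)[::-1]
        self.tensor = t
        self.eigenvalues = np.clip(w[order], 0.0, None)
        self.eigenvectors = v[:, order]


@dataclass
class SamplerConfig:
    mc_ampl: float = 0.3          # ellipsoid displacement scale
    jitter: float = 0.05          # random addition to the scale
    fragment_half_width: int = 3  # fragment length 7
    flips_enabled: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.mc_ampl <= 0:
            raise ValueError("mc_ampl must be positive")


@dataclass
class Fragment:
    """Backbone coordinates of consecutive residues (N, CA, C, O, opt. CB)."""
    resseqs: list[int]
    resnames: list[str]
    coords: list[dict[str, np.ndarray]]
    center: int                   # index of the rebuilt residue k
    chain: str = "A"

    def __len__(self) -> int:
        return len(self.resseqs)

    def copy(self) -> "Fragment":
        return Fragment(list(self.resseqs), list(self.resnames),
                        [{k: v.copy() for k, v in d.items()} for d in self.coords],
                        self.center, self.chain)

    @property
    def guide_atom(self) -> str:
        return "O" if self.resnames[self.center] == "GLY" else "CB"

    def guide_position(self) -> np.ndarray:
        return self.coords[self.center][self.guide_atom]

    def peptide_unit(self) -> PeptideUnit:
        k = self.center
        return PeptideUnit(np.stack([
            self.coords[k]["CA"], self.coords[k]["C"], self.coords[k]["O"],
            self.coords[k + 1]["N"], self.coords[k + 1]["CA"],
        ]))

    def backbone_rmsd(self, other: "Fragment") -> float:
        a = np.concatenate([np.stack(list(d.values())) for d in self.coords])
        b = np.concatenate([np.stack(list(d.values())) for d in other.coords])
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass
class BackboneCandidate:
    fragment: Fragment
    flip_state: str = "none"        # 'none' or a flip cluster name
    displacement: str = "none"      # 'none' or '+e1'...'-e3'
    converged: bool = True
    guide_error: float = 0.0


@dataclass
class CandidateConformer:
    """A full residue candidate: backbone provenance plus built sidechain."""
    backbone: BackboneCandidate
    resname: str
    rotamer: str | None = None
    chi: tuple[float, ...] = ()
    sidechain: list[tuple[str, str, np.ndarray]] = field(default_factory=list)

    def center_backbone(self) -> dict[str, np.ndarray]:
        return self.backbone.fragment.coords[self.backbone.fragment.center]

    def positions(self) -> dict[str, np.ndarray]:
        out = dict(self.center_backbone())
        for name, _el, pos in self.sidechain:
            out[name] = pos
        return out


def fragment_around(model: ProteinModel, chain: str, resseq: int,
                    half_width: int = 3) -> Fragment:
    """Extract the backbone fragment of length 2*half_width+1 centered on
    residue ``resseq`` (truncated at chain ends)."""
    residues = [r for r in model.chains()[chain] if not r.hetero]
    idx = next(i for i, r in enumerate(residues) if r.resseq == resseq)
    lo = max(0, idx - half_width)
    hi = min(len(residues), idx + half_width + 1)
    window = residues[lo:hi]
    coords = []
    for r in window:
        conf = r.primary()
        d = {}
        for name in ("N", "CA", "C", "O", "CB"):
            if conf.has(name):
                d[name] = conf.get(name).position.copy()
        coords.append(d)
    return Fragment([r.resseq for r in window], [r.name for r in window],
                    coords, idx - lo, chain)


# ---------------------------------------------------------------------------
# density moment tensor (guide-atom thermal ellipsoid surrogate)
# ---------------------------------------------------------------------------

def density_moment_tensor(dmap: DensityMap, position: np.ndarray,
                          radius: float) -> AnisoTensor:
    """Density-weighted second-moment tensor of the map within ``radius`` of
    ``position``, using positive density only.  Scale-invariant in the map
    values; serves as the anisotropic displacement surrogate steering
    guide-atom sampling."""
    from .density import build_mask

    mask = build_mask(dmap, position, radius)
    fallback = AnisoTensor(np.eye(3) * (radius / 2.0) ** 2)
    if len(mask) == 0:
        logger.warning("moment tensor: no voxels within %.1f A; isotropic fallback",
                       radius)
        return fallback
    vals = dmap.values_at(mask.indices)
    w = np.clip(vals, 0.0, None)
    if w.sum() <= 0:
        logger.warning("moment tensor: non-positive density; isotropic fallback")
        return fallback
    pts = dmap.voxel_centers(mask.indices)
    mean = (w[:, None] * pts).sum(axis=0) / w.sum()
    diff = pts - mean
    T = (w[:, None, None] * diff[:, :, None] * diff[:, None, :]).sum(axis=0) / w.sum()
    return AnisoTensor(T)


def sample_guide_displacements(tensor: AnisoTensor, cfg: SamplerConfig,
                               position: np.ndarray, rng=None) -> list[np.ndarray]:
    """Six guide-atom targets: ``position +/- mc_ampl * sqrt(lambda_j) * e_j``
    along the ellipsoid axes, magnitudes jittered uniformly by
    ``+/- jitter * sqrt(lambda_j)``."""
    rng = np.random.default_rng(rng)
    out = []
    for j in range(3):
        lam = np.sqrt(tensor.eigenvalues[j])
        ej = tensor.eigenvectors[:, j]
        for sign in (+1.0, -1.0):
            mag = cfg.mc_ampl * lam
            if cfg.jitter > 0:
                mag += rng.uniform(-cfg.jitter, cfg.jitter) * lam
            out.append(np.asarray(position, float) + sign * mag * ej)
    return out


# ---------------------------------------------------------------------------
# dihedral kinematics on a fragment
# ---------------------------------------------------------------------------

try:  # JIT kernels for the IK inner loops (plain-numpy fallback below)
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=False)
def _rebuild_kernel(base, theta, axis_p, axis_q, moved):
    """Apply dihedral offsets in chain order by rigid subtree rotation."""
    coords = base.copy()
    m = theta.shape[0]
    for j in range(m):
        th = theta[j]
        if abs(th) < 1e-12:
            continue
        px, py, pz = coords[axis_p[j], 0], coords[axis_p[j], 1], coords[axis_p[j], 2]
        ux = coords[axis_q[j], 0] - px
        uy = coords[axis_q[j], 1] - py
        uz = coords[axis_q[j], 2] - pz
        n = (ux * ux + uy * uy + uz * uz) ** 0.5
        ux, uy, uz = ux / n, uy / n, uz / n
        c = np.cos(th)
        s = np.sin(th)
        C = 1.0 - c
        r00 = c + ux * ux * C
        r01 = ux * uy * C - uz * s
        r02 = ux * uz * C + uy * s
        r10 = uy * ux * C + uz * s
        r11 = c + uy * uy * C
        r12 = uy * uz * C - ux * s
        r20 = uz * ux * C - uy * s
        r21 = uz * uy * C + ux * s
        r22 = c + uz * uz * C
        for a in range(coords.shape[0]):
            if moved[j, a]:
                dx = coords[a, 0] - px
                dy = coords[a, 1] - py
                dz = coords[a, 2] - pz
                coords[a, 0] = px + r00 * dx + r01 * dy + r02 * dz
                coords[a, 1] = py + r10 * dx + r11 * dy + r12 * dz
                coords[a, 2] = pz + r20 * dx + r21 * dy + r22 * dz
    return coords


@_njit(cache=False)
def _jacobian_kernel(coords, axis_p, axis_q, moved, rows):
    """d(position)/d(theta): u_j x (x_a - p_j) for moved atoms."""
    m = axis_p.shape[0]
    k = rows.shape[0]
    J = np.zeros((3 * k, m))
    for j in range(m):
        px, py, pz = coords[axis_p[j], 0], coords[axis_p[j], 1], coords[axis_p[j], 2]
        ux = coords[axis_q[j], 0] - px
        uy = coords[axis_q[j], 1] - py
        uz = coords[axis_q[j], 2] - pz
        n = (ux * ux + uy * uy + uz * uz) ** 0.5
        ux, uy, uz = ux / n, uy / n, uz / n
        for r in range(k):
            a = rows[r]
            if moved[j, a]:
                dx = coords[a, 0] - px
                dy = coords[a, 1] - py
                dz = coords[a, 2] - pz
                J[3 * r, j] = uy * dz - uz * dy
                J[3 * r + 1, j] = uz * dx - ux * dz
                J[3 * r + 2, j] = ux * dy - uy * dx
    return J


class _FragmentKinematics:
    """Phi/psi forward kinematics on a flattened fragment atom array."""

    def __init__(self, fragment: Fragment):
        self.base = fragment
        self.atom_index: list[tuple[int, str]] = []
        for i, d in enumerate(fragment.coords):
            for name in d:
                self.atom_index.append((i, name))
        self.lookup = {key: j for j, key in enumerate(self.atom_index)}
        self.base_coords = np.array(
            [fragment.coords[i][n] for i, n in self.atom_index])
        L = len(fragment)
        # DOFs in chain order: (residue, 'phi'|'psi') for interior residues
        self.dofs: list[tuple[int, str]] = []
        for i in range(1, L - 1):
            self.dofs.append((i, "phi"))
            self.dofs.append((i, "psi"))
        self.anchor_idx = [
            self.lookup[(0, n)] for n in ("N", "CA", "C")
        ] + [
            self.lookup[(L - 1, n)] for n in ("N", "CA", "C")
        ]
        self._moved_masks = [self._moved_mask(*dof) for dof in self.dofs]
        # packed arrays for the JIT kernels
        self._axis_p = np.array(
            [self.lookup[(r, "N" if w == "phi" else "CA")]
             for r, w in self.dofs], dtype=np.int64)
        self._axis_q = np.array(
            [self.lookup[(r, "CA" if w == "phi" else "C")]
             for r, w in self.dofs], dtype=np.int64)
        self._moved = (np.stack(self._moved_masks)
                       if self.dofs else
                       np.zeros((0, len(self.atom_index)), dtype=bool))

    def _moved_mask(self, res: int, which: str) -> np.ndarray:
        moved = np.zeros(len(self.atom_index), dtype=bool)
        for j, (i, name) in enumerate(self.atom_index):
            if i > res:
                moved[j] = True
            elif i == res:
                if which == "phi":
                    moved[j] = name in ("C", "O", "CB")
                else:  # psi moves the carbonyl O and everything downstream
                    moved[j] = name == "O"
        return moved

    def rebuild(self, theta: np.ndarray, base_coords: np.ndarray | None = None
                ) -> np.ndarray:
        """Apply dihedral offsets (radians) in chain order; exact rigid
        subtree rotations, so covalent geometry is preserved."""
        base = self.base_coords if base_coords is None else base_coords
        if not self.dofs:
            return base.copy()
        return _rebuild_kernel(np.ascontiguousarray(base),
                               np.asarray(theta, dtype=float),
                               self._axis_p, self._axis_q, self._moved)

    def jacobian(self, coords: np.ndarray, atom_rows: np.ndarray) -> np.ndarray:
        """d(position)/d(theta) for the given atom row indices; shape
        (3*len(atom_rows), n_dofs)."""
        return _jacobian_kernel(np.ascontiguousarray(coords),
                                self._axis_p, self._axis_q, self._moved,
                                np.asarray(atom_rows, dtype=np.int64))

    def to_fragment(self, coords: np.ndarray) -> Fragment:
        frag = self.base.copy()
        for j, (i, name) in enumerate(self.atom_index):
            frag.coords[i][name] = coords[j].copy()

        return frag


def _ik_solve(kin: _FragmentKinematics, targets: list[tuple[int, str, np.ndarray]],
              base_theta: np.ndarray | None = None,
              max_iter: int = 200, tol: float = 0.05,
              anchor_tol: float = 0.01, sv_cutoff: float = 1e-8,
              weights: np.ndarray | None = None
              ) -> tuple[np.ndarray, bool, float]:
    """Projected-gradient IK: pull target atoms toward their goals within
    the nullspace of the anchor Jacobian, with Gauss-Newton anchor
    correction after every accepted step.

    Returns (theta, converged, rms target error)."""
    n = len(kin.dofs)
    theta = np.zeros(n) if base_theta is None else base_theta.copy()
    rows = np.array([kin.lookup[(i, name)] for i, name, _ in targets])
    goals = np.array([t for _, _, t in targets])
    w = np.ones(len(targets)) if weights is None else np.asarray(weights, float)
    w3 = np.repeat(w, 3)
    anchor_goal = kin.base_coords[kin.anchor_idx].copy()

    anchor_rows = np.array(kin.anchor_idx)

    def anchor_correct(th):
        for _ in range(4):
            coords = kin.rebuild(th)
            err = (coords[anchor_rows] - anchor_goal).ravel()
            if float(err @ err) < 1e-6:
                break
            J = kin.jacobian(coords, anchor_rows)
            step, *_ = np.linalg.lstsq(J, -err, rcond=None)
            th = th + step
        return th

    def objective(th):
        coords = kin.rebuild(th)
        return float(np.sum(w[:, None] * (coords[rows] - goals) ** 2)), coords

    if base_theta is not None and np.any(base_theta):
        theta = anchor_correct(theta)
    f, coords = objective(theta)
    converged = False
    for _ in range(max_iter):
        rms = np.sqrt(f / len(targets))
        if rms < tol:
            converged = True
            break
        Ja = kin.jacobian(coords, np.array(kin.anchor_idx))
        U, s, Vt = np.linalg.svd(Ja)
        rank = int(np.sum(s > sv_cutoff * max(s[0], 1.0)))
        N = Vt[rank:].T                     # nullspace basis (n x m)
        if N.shape[1] == 0:
            break
        Jt = kin.jacobian(coords, rows)
        resid = (goals - coords[rows]).ravel()
        # Gauss-Newton step restricted to the anchor nullspace: the descent
        # direction is still the projected gradient direction family, but
        # curvature-scaled (with a small ridge) for fast, stable convergence
        sw = np.sqrt(w3)
        JN = (Jt @ N) * sw[:, None]
        rhs = resid * sw
        H = JN.T @ JN + 1e-3 * np.eye(JN.shape[1])
        c = np.linalg.solve(H, JN.T @ rhs)
        step = N @ c
        norm = np.linalg.norm(step)
        if norm < 1e-10:
            break
        if norm > 0.3:
            step *= 0.3 / norm              # cap step at 0.3 rad
        improved = False
        alpha = 1.0
        for _ in range(8):
            trial = anchor_correct(theta + alpha * step)
            f_t, coords_t = objective(trial)
            if f_t < f - 1e-12:
                theta, f, coords = trial, f_t, coords_t
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
    rms = np.sqrt(f / len(targets))
    if converged:
        final = kin.rebuild(theta)
        aerr = np.max(np.linalg.norm(final[kin.anchor_idx] - anchor_goal, axis=1))
        if aerr > anchor_tol:
            converged = False
    return theta, converged, float(rms)


def nullspace_ik_close(fragment: Fragment, guide_atom: str, target: np.ndarray,
                       tol: float = 0.05, max_iter: int = 200
                       ) -> tuple[Fragment, bool, float]:
    """Deform ``fragment`` by phi/psi moves so its center-residue
    ``guide_atom`` reaches ``target`` while the first/last-residue N, CA, C
    anchors stay fixed (< 0.01 A).  Guide-to-target distance is
    non-increasing across iterations (monotone line search).

    Returns (deformed fragment, converged flag, residual guide distance).
    """
    kin = _FragmentKinematics(fragment)
    k = fragment.center
    theta, ok, err = _ik_solve(kin, [(k, guide_atom, np.asarray(target, float))],
                               max_iter=max_iter, tol=tol)
    return kin.to_fragment(kin.rebuild(theta)), ok, err


def _realize_flip(fragment: Fragment, cluster: FlipCluster,
                  tol: float = 0.25) -> tuple[Fragment, bool, float]:
    """Realize a peptide-flip candidate as pure dihedral moves.

    The cluster centroid is rigidly mapped into the current peptide frame
    and the five peptide atoms are driven toward it by nullspace IK, so the
    flip geometry is approximated while covalent geometry stays exact.
    """
    unit = fragment.peptide_unit()
    target = apply_flip_centroid(unit, cluster)
    k = fragment.center
    targets = [
        (k, "CA", target.ca1), (k, "C", target.c1), (k, "O", target.o1),
        (k + 1, "N", target.n2), (k + 1, "CA", target.ca2),
    ]
    kin = _FragmentKinematics(fragment)
    rows = np.array([kin.lookup[(i, n)] for i, n, _ in targets])
    goals = np.array([t for _, _, t in targets])

    # A flip is, to first order, an anti-correlated psi(k)/phi(k+1)
    # crankshaft of the cluster's nominal rotation; seed the solver with the
    # best-scoring crankshaft to escape the unflipped local minimum.
    j_psi = kin.dofs.index((k, "psi")) if (k, "psi") in kin.dofs else None
    j_phi = kin.dofs.index((k + 1, "phi")) if (k + 1, "phi") in kin.dofs else None
    rho = np.deg2rad(cluster.rotation_class)
    seeds = [np.zeros(len(kin.dofs))]
    if j_psi is not None:
        for s in (+1.0, -1.0):
            th = np.zeros(len(kin.dofs))
            th[j_psi] = s * rho
            if j_phi is not None:
                th[j_phi] = -s * rho
            seeds.append(th)
    best = None
    for th in seeds:
        coords = kin.rebuild(th)
        f = float(np.sum((coords[rows] - goals) ** 2))
        if best is None or f < best[0]:
            best = (f, th)
    # Multi-start over target weightings: the landscape has competing basins
    # (plane-atom fit vs flanking-Ca placement), and which weighting finds
    # the better one depends on the backbone.  Keep the realization with
    # the lowest unweighted rms, preferring ones that are valid flips of
    # the starting peptide (the flip definition the candidates exist for).
    from .flips import detect_flip

    trials = []
    for wca in (0.4, 4.0):
        w = np.array([wca, 1.0, 1.0, 1.0, wca])
        theta, ok, _werr = _ik_solve(kin, targets, base_theta=best[1],
                                     tol=tol, weights=w)
        coords = kin.rebuild(theta)
        rms = float(np.sqrt(np.mean(
            np.sum((coords[rows] - goals) ** 2, axis=1))))
        frag_out = kin.to_fragment(coords)
        is_flip = detect_flip(unit, frag_out.peptide_unit()).is_flip
        trials.append((not is_flip, rms, frag_out, ok))
    trials.sort(key=lambda x: (x[0], x[1]))
    not_flip, rms, frag_out, ok = trials[0]
    return frag_out, ok and not not_flip, rms


def realize_flip_states(fragment: Fragment,
                        centroids: list[FlipCluster]
                        ) -> list[tuple[str, Fragment]]:
    """The four flip-realized variants of a fragment (flip-like ones only).
    Depends only on the fragment geometry, so callers may cache it across
    sampling configurations."""
    from .flips import detect_flip

    out: list[tuple[str, Fragment]] = []
    start_unit = fragment.peptide_unit()
    for c in centroids:
        flipped, _ok, err = _realize_flip(fragment, c)
        # keep a flip candidate iff the realized geometry is actually a
        # flip of the starting peptide (rotation >= 90 deg, carbonyls
        # apart, flanking Ca reconverged)
        if not detect_flip(start_unit, flipped.peptide_unit()).is_flip:
            logger.info("flip %s: realization not flip-like "
                        "(IK rms %.2f A), dropped", c.name, err)
            continue
        out.append((c.name, flipped))
    return out


def enumerate_backbones(fragment: Fragment, flips_allowed: bool,
                        tensor: AnisoTensor, cfg: SamplerConfig,
                        centroids: list[FlipCluster] | None = None,
                        rng=None,
                        flip_states: list[tuple[str, Fragment]] | None = None
                        ) -> list[BackboneCandidate]:
    """All backbone candidates for the fragment's center residue:
    (1 unflipped + 4 flipped when allowed) x (1 undisplaced + 6 ellipsoid
    displacements), each closed by nullspace IK.  The identity candidate is
    always present.  Non-converging candidates are dropped (logged)."""
    if centroids is None:
        from .flips import load_flip_centroids
        centroids = load_flip_centroids()
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)

    k = fragment.center
    L = len(fragment)
    # the first and last fragment residues are anchors: their atoms cannot
    # move, so a center residue at a chain end keeps only the identity
    if not (1 <= k <= L - 2):
        return [BackboneCandidate(fragment, "none", "none", True, 0.0)]
    states: list[tuple[str, Fragment]] = [("none", fragment)]
    # a flip moves atoms of residues k and k+1, so k+1 must be interior too
    can_flip = (flips_allowed and cfg.flips_enabled and k + 1 <= L - 2)
    if can_flip:
        if flip_states is None:
            flip_states = realize_flip_states(fragment, centroids)
        states.extend(flip_states)

    out: list[BackboneCandidate] = []
    labels = ("+e1", "-e1", "+e2", "-e2", "+e3", "-e3")
    for flip_name, frag in states:
        out.append(BackboneCandidate(frag, flip_name, "none", True, 0.0))
        guide = frag.guide_position()
        targets = sample_guide_displacements(tensor, cfg, guide, rng)
        for label, target in zip(labels, targets):
            closed, ok, err = nullspace_ik_close(frag, frag.guide_atom, target)
            if not ok and err > np.linalg.norm(target - guide):
                logger.info("displacement %s/%s: IK made no progress, dropped",
                            flip_name, label)
                continue
            out.append(BackboneCandidate(closed, flip_name, label, ok, err))
    return out


# ---------------------------------------------------------------------------
# sidechain decoration
# ---------------------------------------------------------------------------

_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90, "H": 1.20}


def _self_clash(candidate: CandidateConformer) -> bool:
    """True if any sidechain atom (beyond CB) overlaps the backbone of a
    different fragment residue worse than 0.4x the vdW radius sum."""
    frag = candidate.backbone.fragment
    k = frag.center
    sc = [(el, pos) for name, el, pos in candidate.sidechain if name != "CB"]
    if not sc:
        return False
    for i, d in enumerate(frag.coords):
        if i == k:
            continue
        for name, bbpos in d.items():
            el_bb = name[0]
            for el, pos in sc:
                lim = 0.4 * (_VDW.get(el.upper(), 1.7) + _VDW.get(el_bb, 1.7))
                if np.sum((pos - bbpos) ** 2) < lim * lim:
                    return True
    return False


def _chi_offset_grid(n_chi: int, offsets) -> list[tuple[float, ...]]:
    grids = [offsets] * n_chi
    out = [()]
    for g in grids:
        out = [t + (o,) for t in out for o in g]
    return out


def decorate_small_sidechain(backbones: list[BackboneCandidate], resname: str,
                             library: list[RotamerEntry]
                             ) -> list[CandidateConformer]:
    """Small-residue decoration: for each backbone x rotamer, chi offsets
    from the Cartesian product of {-20,-10,0,+10,+20} degrees per chi
    (proline: {-10,0,+10} to keep the ring closed)."""
    resname = resname.upper()
    if resname not in SMALL_SIDECHAINS and resname not in ("ALA", "GLY"):
        raise ValueError(f"{resname} is not a small-sidechain type")
    offsets = PRO_OFFSETS if resname == "PRO" else SMALL_OFFSETS
    rotamers = [e for e in library if e.residue == resname]
    out: list[CandidateConformer] = []
    for bb in backbones:
        backbone = bb.fragment.coords[bb.fragment.center]
        if resname in ("ALA", "GLY"):
            sc = build_sidechain(resname, backbone) if resname == "ALA" else []
            out.append(CandidateConformer(bb, resname, None, (), sc))
            continue
        for rot in rotamers:
            for off in _chi_offset_grid(len(rot.chi), offsets):
                chi = tuple(_wrap_chi(c + o) for c, o in zip(rot.chi, off))
                sc = build_sidechain(resname, backbone, chi)
                cand = CandidateConformer(bb, resname, rot.name, chi, sc)
                if not _self_clash(cand):
                    out.append(cand)
    return out


def _wrap_chi(x: float) -> float:
    y = (x + 180.0) % 360.0 - 180.0
    return 180.0 if y == -180.0 else y


def decorate_large_sidechain(backbones: list[BackboneCandidate], resname: str,
                             library: list[RotamerEntry], select_fn
                             ) -> list[CandidateConformer]:
    """Hierarchical decoration of large sidechains: at level l, each
    survivor of level l-1 is extended with 12 offsets of chi_l in a 50 deg
    window (4.5 deg steps); ``select_fn(candidates, level)`` returns the
    surviving indices (fitting the density up to the atoms built so far).
    Falls back to the best single candidate if a level empties."""
    resname = resname.upper()
    if resname not in LARGE_SIDECHAINS:
        raise ValueError(f"{resname} is not a large-sidechain type")
    n_chi = len(CHI_ATOMS[resname])
    rotamers = [e for e in library if e.residue == resname]

    survivors: list[tuple[BackboneCandidate, RotamerEntry, tuple[float, ...]]] = [
        (bb, rot, ()) for bb in backbones for rot in rotamers
    ]
    for level in range(n_chi):
        expanded: list[CandidateConformer] = []
        for bb, rot, prefix in survivors:
            backbone = bb.fragment.coords[bb.fragment.center]
            for off in LARGE_OFFSETS:
                chi = prefix + (_wrap_chi(rot.chi[level] + off),)
                sc = build_sidechain(resname, backbone, chi + rot.chi[level + 1:],
                                     through_chi=level + 1)
                cand = CandidateConformer(bb, resname, rot.name, chi, sc)
                if not _self_clash(cand):
                    expanded.append(cand)
        if not expanded:
            break
        keep = list(select_fn(expanded, level + 1))
        if not keep:
            keep = [0]
        survivors = [
            (expanded[i].backbone,
             next(r for r in rotamers if r.name == expanded[i].rotamer),
             expanded[i].chi)
            for i in keep
        ]
    out = []
    for bb, rot, chi in survivors:
        backbone = bb.fragment.coords[bb.fragment.center]
        sc = build_sidechain(resname, backbone, chi)
        out.append(CandidateConformer(bb, resname, rot.name, chi, sc))
    return out


def decorate(backbones, resname: str, library, select_fn=None):
    """Dispatch to the small or hierarchical-large decoration path."""
    resname = resname.upper()
    if resname in LARGE_SIDECHAINS:
        if select_fn is None:
            select_fn = lambda cands, level: range(len(cands))  # noqa: E731
        return decorate_large_sidechain(backbones, resname, library, select_fn)
    return decorate_small_sidechain(backbones, resname, library)


# ---------------------------------------------------------------------------
# secondary structure (flip suppression)
# ---------------------------------------------------------------------------

def secondary_structure(model: ProteinModel) -> dict[tuple, str]:
    """Assign 'H' (helix), 'E' (strand) or 'C' per residue from phi/psi.

    A simple dihedral-window heuristic: helical windows over runs of >= 4
    residues, extended/beta windows over runs of >= 3.  Residues assigned
    H or E skip peptide-flip sampling.
    """
    out: dict[tuple, str] = {}
    for chain, residues in model.chains().items():
        poly = [r for r in residues if not r.hetero]
        phipsi = []
        for i, r in enumerate(poly):
            phi = psi = None
            conf = r.primary()
            try:
                if i > 0 and poly[i - 1].resseq == r.resseq - 1:
                    prev = poly[i - 1].primary()
                    phi = dihedral(prev.get("C").position, conf.get("N").position,
                                   conf.get("CA").position, conf.get("C").position)
                if i + 1 < len(poly) and poly[i + 1].resseq == r.resseq + 1:
                    nxt = poly[i + 1].primary()
                    psi = dihedral(conf.get("N").position, conf.get("CA").position,
                                   conf.get("C").position, nxt.get("N").position)
            except KeyError:
                pass
            phipsi.append((phi, psi))

        def in_helix(pp):
            phi, psi = pp
            return (phi is not None and psi is not None
                    and -100 < phi < -30 and -80 < psi < -5)

        def in_strand(pp):
            phi, psi = pp
            return (phi is not None and psi is not None
                    and -180 <= phi < -90 and (90 < psi <= 180 or psi < -150))

        labels = ["C"] * len(poly)
        for pred, label, min_run in ((in_helix, "H", 4), (in_strand, "E", 3)):
            i = 0
            while i < len(poly):
                if pred(phipsi[i]) and labels[i] == "C":
                    j = i
                    while j < len(poly) and pred(phipsi[j]):
                        j += 1
                    if j - i >= min_run:
                        for m in range(i, j):
                            labels[m] = label
                    i = j
                else:
                    i += 1
        for r, lab in zip(poly, labels):
            out[r.key] = lab
    return out
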