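"""Peptide-flip geometry: detection, canonical frames, centroid transforms,
k-means clustering of flip geometries, tight-turn detection and glycine
enrichment statistics.

A "peptide unit" is the five backbone heavy atoms Ca1, C1, O1, N2, Ca2 of
the peptide between residues k and k+1.  A peptide flip is a 90-180 degree
rotation of this plane about the Ca-Ca axis with both flanking Ca atoms
nearly unchanged; flips cluster around four recurrent geometries (two near
180 degrees with different in-plane translations, and one each near +120
and -120 degrees), which are used as rigid transform templates to propose
candidate flipped conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .geometry import dihedral, normalize, rotation_about_axis, signed_angle_about_axis
from .model import ProteinModel

PEPTIDE_ATOMS = ("CA1", "C1", "O1", "N2", "CA2")

__all__ = [
    "PeptideUnit",
    "PeptideFrame",
    "FlipCluster",
    "FlipObservation",
    "FlipResult",
    "reference_peptide",
    "peptide_frame",
    "apply_flip_centroid",
    "detect_flip",
    "cluster_flips",
    "is_tight_turn",
    "glycine_enrichment",
    "load_flip_centroids",
    "make_synthetic_centroids",
    "peptide_unit_from_residues",
    "mine_flips",
]


class DegenerateFrameError(ValueError):
    pass


@dataclass
class PeptideUnit:
    """Coordinates (5, 3) of Ca1, C1, O1, N2, Ca2 in angstroms."""
    coords: np.ndarray
    residues: tuple | None = None  # ((chain, resseq, icode) x2) provenance

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (5, 3):
            raise ValueError("peptide unit needs 5 atoms x 3 coordinates")

    @property
    def ca1(self): return self.coords[0]
    @property
    def c1(self): return self.coords[1]
    @property
    def o1(self): return self.coords[2]
    @property
    def n2(self): return self.coords[3]
    @property
    def ca2(self): return self.coords[4]

    def validate(self) -> None:
        co = np.linalg.norm(self.c1 - self.o1)
        if not (1.0 <= co <= 1.5):
            raise ValueError(f"C1-O1 bond {co:.2f} A outside [1.0, 1.5]")
        for a, b, label in ((self.ca1, self.c1, "CA1-C1"),
                            (self.n2, self.ca2, "N2-CA2")):
            d = np.linalg.norm(a - b)
            if not (1.2 <= d <= 1.8):
                raise ValueError(f"{label} bond {d:.2f} A outside [1.2, 1.8]")

    def omega(self) -> float:
        return dihedral(self.ca1, self.c1, self.n2, self.ca2)

    def is_cis(self) -> bool:
        return abs(self.omega()) < 90.0


@dataclass
class PeptideFrame:
    origin: np.ndarray
    rotation: np.ndarray  # columns = x, y, z axes

    def to_frame(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.origin) @ self.rotation

    def from_frame(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.origin


def peptide_frame(p: PeptideUnit) -> PeptideFrame:
    """Local right-handed frame: x along Ca1->Ca2, y the Gram-Schmidt
    orthogonalized Ca1->O1 direction, z their cross product."""
    v1 = p.ca2 - p.ca1
    v2 = p.o1 - p.ca1
    if np.linalg.norm(v1) < 1e-6:
        raise DegenerateFrameError("coincident flanking Ca atoms")
    x = normalize(v1)
    y = v2 - np.dot(v2, x) * x
    if np.linalg.norm(y) < 1e-6:
        raise DegenerateFrameError("O1 collinear with the Ca-Ca axis")
    y = normalize(y)
    z = np.cross(x, y)
    return PeptideFrame(p.ca1.copy(), np.stack([x, y, z], axis=1))


@dataclass
class FlipCluster:
    """One flip-geometry cluster centroid, stored in the canonical frame of
    the reference peptide (origin at Ca1, x along Ca1->Ca2)."""
    name: str
    coords: np.ndarray                # (5, 3) canonical-frame coordinates
    rotation_class: float             # nominal rotation about the Ca-Ca axis

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        PeptideUnit(self.coords).validate()


@dataclass
class FlipResult:
    is_flip: bool
    rotation: float      # signed rotation of O1 about the Ca-Ca axis, deg
    reason: str = ""

    def __iter__(self):
        return iter((self.is_flip, self.rotation))


@dataclass
class FlipObservation:
    structure_id: str
    chain: str
    resseq: int
    altloc_pair: tuple[str, str]
    rotation: float
    in_turn: bool = False
    gly_first: bool = False
    gly_second: bool = False
    coords: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# reference peptide and centroid application
# ---------------------------------------------------------------------------

def reference_peptide() -> PeptideUnit:
    """Ideal planar trans peptide expressed in its own canonical frame."""
    from .geometry import place_atom
    ca1 = np.zeros(3)
    c1 = np.array([1.525, 0.0, 0.0])
    dummy = np.array([0.0, 1.0, 0.0])
    n2 = place_atom(dummy, ca1, c1, 1.329, 116.2, -90.0)
    ca2 = place_atom(ca1, c1, n2, 1.458, 121.7, 180.0)
    o1 = place_atom(ca2, n2, c1, 1.231, 122.7, 0.0)
    unit = PeptideUnit(np.stack([ca1, c1, o1, n2, ca2]))
    frame = peptide_frame(unit)
    return PeptideUnit(frame.to_frame(unit.coords))


def apply_flip_centroid(p: PeptideUnit, c: FlipCluster) -> PeptideUnit:
    """Map the centroid geometry rigidly into ``p``'s local frame (a
    homogeneous transform; all internal distances of the centroid are
    preserved)."""
    frame = peptide_frame(p)
    return PeptideUnit(frame.from_frame(c.coords), p.residues)


def detect_flip(conf_a: PeptideUnit, conf_b: PeptideUnit) -> FlipResult:
    """Classify a conformer pair as a peptide flip.

    A flip requires (i) carbonyl C-O bonds pointing away from each other
    (O-O distance > C-C distance + 1 A), (ii) a rotation of at least 90
    degrees of O1 about the Ca-Ca axis, and (iii) both flanking Ca atoms
    reconverged to < 1.5 A.
    """
    dca1 = np.linalg.norm(conf_a.ca1 - conf_b.ca1)
    dca2 = np.linalg.norm(conf_a.ca2 - conf_b.ca2)
    axis_a = conf_a.ca2 - conf_a.ca1
    axis_b = conf_b.ca2 - conf_b.ca1
    if np.linalg.norm(axis_a) < 1e-6 or np.linalg.norm(axis_b) < 1e-6:
        return FlipResult(False, 0.0, "degenerate Ca-Ca axis")
    # superpose flanking-Ca midpoints, use the mean axis direction
    mid_a = 0.5 * (conf_a.ca1 + conf_a.ca2)
    mid_b = 0.5 * (conf_b.ca1 + conf_b.ca2)
    axis = normalize(axis_a) + normalize(axis_b)
    if np.linalg.norm(axis) < 1e-6:
        return FlipResult(False, 0.0, "anti-parallel Ca-Ca axes")
    axis = normalize(axis)
    o_a = conf_a.o1 - mid_a
    o_b = conf_b.o1 - mid_b
    rotation = signed_angle_about_axis(o_a, o_b, axis)
    d_oo = np.linalg.norm(conf_a.o1 - conf_b.o1)
    d_cc = np.linalg.norm(conf_a.c1 - conf_b.c1)
    if dca1 >= 1.5 or dca2 >= 1.5:
        return FlipResult(False, rotation, "flanking Ca not reconverged")
    if abs(rotation) < 90.0:
        return FlipResult(False, rotation, "rotation below 90 degrees")
    if d_oo <= d_cc + 1.0:
        return FlipResult(False, rotation, "carbonyls not pointing apart")
    return FlipResult(True, rotation)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_flips(observations: np.ndarray, k: int, restarts: int = 25,
                  rng=None, max_iter: int = 100
                  ) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Lloyd's k-means under the 5-atom RMSD metric.

    ``observations`` is an (n, 5, 3) stack already superposed into the
    reference frame.  RMSD between flattened 15-vectors is Euclidean
    distance scaled by 1/sqrt(5), so plain Lloyd iterations with
    coordinate-wise mean centroids minimize the RMSD inertia.  Best of
    ``restarts`` seeded initializations is returned.

    Returns (centroids (k,5,3), assignments (n,), inertia, inertia trace of
    the winning restart).  Inertia is the sum of squared RMSDs.
    """
    X = np.asarray(observations, dtype=float).reshape(len(observations), -1)
    n = len(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of observations {n}")
    rng = np.random.default_rng(rng)
    best = None
    for _ in range(restarts):
        idx = rng.choice(n, size=k, replace=False)
        centers = X[idx].copy()
        trace: list[float] = []
        assign = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=2)
            assign = np.argmin(d2, axis=1)
            inertia = float(np.sum(d2[np.arange(n), assign]) / 5.0)
            if trace and inertia > trace[-1] + 1e-9:
                raise AssertionError("k-means inertia increased")
            converged = bool(trace) and trace[-1] - inertia < 1e-12
            trace.append(inertia)
            for j in range(k):
                members = X[assign == j]
                if len(members):
                    centers[j] = members.mean(axis=0)
                else:  # re-seed an empty cluster at the worst-fit point
                    centers[j] = X[np.argmax(d2[np.arange(n), assign])]
            if converged:
                break
        if best is None or trace[-1] < best[2] - 1e-12:
            best = (centers.copy(), assign.copy(), trace[-1], trace)
    centers, assign, inertia, trace = best
    return centers.reshape(k, 5, 3), assign, inertia, trace


def superposed_flip_coords(unit_a: PeptideUnit, unit_b: PeptideUnit) -> np.ndarray:
    """Coordinates of the flipped conformer in the primary conformer's
    canonical frame (the clustering feature vector)."""
    frame = peptide_frame(unit_a)
    return frame.to_frame(unit_b.coords)


# ---------------------------------------------------------------------------
# tight turns and glycine statistics
# ---------------------------------------------------------------------------

def is_tight_turn(model: ProteinModel, chain: str, resseq: int,
                  icode: str = "") -> tuple[bool, str]:
    """Is the peptide (i, i+1) at ``resseq`` inside a tight turn?

    A tight turn is defined by a mainchain-mainchain hydrogen bond between
    the i-1 carbonyl C=O and the i+2 amide N-H.  Hydrogens are implicit:
    the criterion is O...N distance <= 3.5 A and C=O...N angle >= 90 deg.
    """
    try:
        prev = model.get(chain, resseq - 1, icode)
        nxt2 = model.get(chain, resseq + 2, icode)
    except KeyError:
        return False, "chain terminus"
    try:
        c = prev.primary().get("C").position
        o = prev.primary().get("O").position
        n = nxt2.primary().get("N").position
    except KeyError:
        return False, "missing backbone atoms"
    d_on = np.linalg.norm(o - n)
    if d_on > 3.5:
        return False, f"O...N {d_on:.2f} A > 3.5"
    v1 = normalize(o - c)
    v2 = normalize(n - o)
    angle = np.rad2deg(np.arccos(np.clip(np.dot(v1, v2), -1, 1)))
    # C=O...N angle measured at O: 180 - angle between C->O and O->N
    if 180.0 - angle < 90.0:
        return False, "C=O...N angle below 90 degrees"
    return True, ""


def glycine_enrichment(hits: int, total: int, bg_hits: int, bg_total: int) -> float:
    """One-tailed Fisher exact (hypergeometric upper tail) probability of
    observing >= ``hits`` glycines in ``total`` draws from a background of
    ``bg_hits`` glycines among ``bg_total`` residues."""
    for v in (hits, total, bg_hits, bg_total):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if hits > total or bg_hits > bg_total:
        raise ValueError("hits cannot exceed totals")
    return float(hypergeom.sf(hits - 1, bg_total, bg_hits, total))


# ---------------------------------------------------------------------------
# centroid fixture
# ---------------------------------------------------------------------------

def make_synthetic_centroids() -> list[FlipCluster]:
    """Construct the four flip cluster centroids synthetically.

    These are a constructed stand-in for cluster centers mined from curated
    multiconformer structures: an ideal trans peptide is re-posed with the
    peptide plane rotated about the Ca-Ca axis by the cluster's nominal
    rotation (180/180/+120/-120 degrees) and the flanking Ca atoms
    translated in opposite perpendicular directions (> 0.2 A each, > 0.9 A
    for the first Ca of "tweaked down"), reproducing every documented
    geometric property of the mined centroids.
    """
    ref = reference_peptide()
    x = np.array([1.0, 0.0, 0.0])
    y = np.array([0.0, 1.0, 0.0])
    L = float(np.linalg.norm(ref.ca2 - ref.ca1))
    # in-plane decomposition of the reference atoms relative to their Ca
    c1_off = ref.c1 - ref.ca1
    o1_off = ref.o1 - ref.ca1
    n2_off = ref.n2 - ref.ca2
    # (name, rotation, dCa1_perp, dCa2_perp, dCa1_axial)
    params = [
        ("tweaked_down", 180.0, 0.95, 0.35, 0.30),
        ("simple_down", 178.0, 0.30, 0.30, 0.00),
        ("left", 122.0, 0.25, 0.30, 0.00),
        ("right", -121.0, 0.25, 0.30, 0.00),
    ]
    out = []
    for name, rho, d1, d2, ax1 in params:
        ca1 = ref.ca1 + ax1 * x - d1 * y
        ca2 = ref.ca2 + d2 * y
        e1 = normalize(ca2 - ca1)
        yp = normalize(y - np.dot(y, e1) * e1)
        R = rotation_about_axis(e1, rho)
        e2 = R @ yp
        def repose(off, anchor):
            par = np.dot(off, x)
            perp = np.dot(off, y)
            oop = np.dot(off, np.array([0.0, 0.0, 1.0]))
            e3 = np.cross(e1, e2)
            return anchor + par * e1 + perp * e2 + oop * e3
        coords = np.stack([
            ca1,
            repose(c1_off, ca1),
            repose(o1_off, ca1),
            repose(n2_off, ca2),
            ca2,
        ])
        out.append(FlipCluster(name, coords, rho))
    del L
    return out


def load_flip_centroids(path=None) -> list[FlipCluster]:
    """Load the four shipped flip cluster centroids and validate their
    rotation classes ({~180, ~180, ~+120, ~-120} degrees) and flanking-Ca
    displacements (> 0.2 A) against the reference peptide."""
    if path is None:
        from importlib.resources import files
        path = files("altconf.data") / "flip_centroids_synthetic.txt"
    clusters: list[FlipCluster] = []
    name = None
    rot = None
    rows: list[tuple[str, np.ndarray]] = []

    def flush():
        nonlocal rows, name, rot
        if name is None:
            return
        got = tuple(r[0] for r in rows)
        if got != PEPTIDE_ATOMS:
            raise ValueError(
                f"cluster {name}: expected atoms {PEPTIDE_ATOMS}, got {got}")
        clusters.append(FlipCluster(name, np.stack([r[1] for r in rows]), rot))
        rows = []

    with open(str(path)) as fh:
        for raw in fh:
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "cluster":
                flush()
                name = parts[1]
                rot = float(parts[2])
            else:
                rows.append((parts[0], np.array([float(v) for v in parts[1:4]])))
    flush()
    if len(clusters) != 4:
        raise ValueError(f"expected 4 flip clusters, found {len(clusters)}")
    ref = reference_peptide()
    for c in clusters:
        res = detect_flip(ref, PeptideUnit(c.coords))
        if abs(abs(res.rotation) - abs(c.rotation_class)) > 30.0:
            raise ValueError(
                f"cluster {c.name}: rotation {res.rotation:.0f} inconsistent "
                f"with class {c.rotation_class:.0f}")
        dca = max(np.linalg.norm(c.coords[0] - ref.ca1),
                  np.linalg.norm(c.coords[4] - ref.ca2))
        if dca <= 0.2:
            raise ValueError(f"cluster {c.name}: flanking Ca translation <= 0.2 A")
    return clusters


def write_flip_centroids(clusters: list[FlipCluster], path) -> None:
    lines = ["# Peptide flip cluster centroid geometries (synthetic",
             "# reconstruction; canonical reference-peptide frame, angstroms)."]
    for c in clusters:
        lines.append(f"cluster {c.name} {c.rotation_class:.1f}")
        for atom, xyz in zip(PEPTIDE_ATOMS, c.coords):
            lines.append(f"{atom} {xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f}")
    with open(str(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# mining multiconformer models
# ---------------------------------------------------------------------------

def peptide_unit_from_residues(res_k, res_k1, altloc: str | None = None
                               ) -> PeptideUnit:
    """Extract the (k, k+1) peptide unit, preferring the given altloc and
    falling back to each residue's shared/primary conformer."""
    def pick(res):
        if altloc is not None:
            for c in res.conformers:
                if c.altloc == altloc:
                    return c
        return res.primary()
    ck = pick(res_k)
    ck1 = pick(res_k1)
    coords = np.stack([
        ck.get("CA").position, ck.get("C").position, ck.get("O").position,
        ck1.get("N").position, ck1.get("CA").position,
    ])
    return PeptideUnit(coords, (res_k.key, res_k1.key))


def mine_flips(model: ProteinModel, structure_id: str = "") -> list[FlipObservation]:
    """Scan a multiconformer model for peptide flips between altloc pairs.

    Pairs with more than two alternative peptide conformations or with a cis
    state are excluded (further validation-based filtering of candidates is
    left to manual review).
    """
    out: list[FlipObservation] = []
    for chain, residues in model.chains().items():
        poly = [r for r in residues if not r.hetero]
        for rk, rk1 in zip(poly, poly[1:]):
            if rk1.resseq != rk.resseq + 1:
                continue
            altlocs = sorted(
                {c.altloc for c in rk.conformers if c.altloc}
                | {c.altloc for c in rk1.conformers if c.altloc}
            )
            if len(altlocs) < 2:
                continue
            if len(altlocs) > 2:
                continue  # more than two alternative peptide conformations
            try:
                ua = peptide_unit_from_residues(rk, rk1, altlocs[0])
                ub = peptide_unit_from_residues(rk, rk1, altlocs[1])
            except KeyError:
                continue
            if ua.is_cis() or ub.is_cis():
                continue
            res = detect_flip(ua, ub)
            if not res.is_flip:
                continue
            turn, _ = is_tight_turn(model, chain, rk.resseq, rk.icode)
            out.append(FlipObservation(
                structure_id, chain, rk.resseq, (altlocs[0], altlocs[1]),
                res.rotation, turn,
                gly_first=rk.name == "GLY", gly_second=rk1.name == "GLY",
                coords=superposed_flip_coords(ua, ub),
            ))
    return out
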