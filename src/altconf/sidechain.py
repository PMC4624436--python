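"""Sidechain construction from ideal residue templates and chi angles.

Templates (ideal heavy-atom coordinates and connectivity) come from the
chemical component dictionary shipped with biotite.  A sidechain is built by
superposing the template backbone (N, CA, C) onto the target backbone and
rotating the subtree distal to each chi bond so the chi dihedrals take the
requested values exactly.

Proline is special-cased: its ring forbids free chi rotations, so chi1 is
adjusted by rotating CG about the CB-CD axis (the ring "flap"), which
preserves all ring bond lengths while moving chi1 through its pucker range.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .geometry import dihedral, rotation_about_axis

#: chi dihedral definitions (atom name quadruplets, chi1..chi4)
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@lru_cache(maxsize=None)
def _template(resname: str):
    """Heavy-atom ideal template: (names, elements, coords, adjacency)."""
    import biotite.structure.info as info

    arr = info.residue(resname.upper())
    heavy = arr.element != "H"
    idx_map = {}
    names, elements, coords = [], [], []
    for i in np.nonzero(heavy)[0]:
        idx_map[int(i)] = len(names)
        names.append(str(arr.atom_name[i]))
        elements.append(str(arr.element[i]).capitalize())
        coords.append(arr.coord[i])
    adj: dict[int, set[int]] = {i: set() for i in range(len(names))}
    bonds = arr.bonds.as_array()
    for a, b, _ in bonds:
        if int(a) in idx_map and int(b) in idx_map:
            ia, ib = idx_map[int(a)], idx_map[int(b)]
            adj[ia].add(ib)
            adj[ib].add(ia)
    return names, elements, np.array(coords, dtype=float), adj


def _downstream(adj, names, b_name: str, c_name: str) -> list[int]:
    """Indices of the connected component containing c after cutting b-c."""
    b = names.index(b_name)
    c = names.index(c_name)
    seen = {b, c}
    stack = [c]
    out = [c]
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
                out.append(nb)
    return out


def sidechain_chis(resname: str, positions: dict[str, np.ndarray]) -> tuple[float, ...]:
    """Measure the chi dihedrals of a built residue."""
    out = []
    for quad in CHI_ATOMS[resname.upper()]:
        out.append(dihedral(*(positions[n] for n in quad)))
    return tuple(out)


def build_sidechain(resname: str, backbone: dict[str, np.ndarray],
                    chi: tuple[float, ...] = (),
                    through_chi: int | None = None
                    ) -> list[tuple[str, str, np.ndarray]]:
    """Build heavy sidechain atoms (CB and beyond) on the given backbone.

    ``backbone`` must contain N, CA, C positions.  Atoms are placed one by
    one (NeRF) using internal coordinates measured on the ideal template,
    with chi-defining torsions shifted to the requested ``chi`` values, so
    the built chi angles equal the request exactly (except proline, see
    module docstring).  ``through_chi`` limits the built atoms to those
    whose position is fixed once chi angles up to that level are set (the
    hierarchical-sampling partial build); None builds the full sidechain.

    Returns [(name, element, position), ...].
    """
    from .geometry import bond_angle, place_atom

    resname = resname.upper()
    names, elements, tcoords, adj = _template(resname)
    quads = CHI_ATOMS[resname]
    if chi and len(chi) != len(quads):
        raise ValueError(f"{resname} expects {len(quads)} chi angles")

    iN, iCA, iC = (names.index(n) for n in ("N", "CA", "C"))
    pos: dict[int, np.ndarray] = {
        iN: np.asarray(backbone["N"], float),
        iCA: np.asarray(backbone["CA"], float),
        iC: np.asarray(backbone["C"], float),
    }
    # spanning tree of the sidechain rooted at CA
    parent: dict[int, int] = {}
    order: list[int] = []
    placed = {iN, iCA, iC}
    queue = [iCA]
    while queue:
        cur = queue.pop(0)
        for nb in sorted(adj[cur]):
            if nb in placed or names[nb] in _BACKBONE:
                continue
            placed.add(nb)
            parent[nb] = cur
            order.append(nb)
            queue.append(nb)

    def grand(i: int) -> int:
        if i == iCA:
            return iN
        if i == iN:
            return iC
        return parent[i]

    # torsion offsets per chi axis (b, c)
    axis_delta: dict[tuple[int, int], float] = {}
    if chi and resname != "PRO":
        for quad, value in zip(quads, chi):
            qa, qb, qc, qd = (names.index(n) for n in quad)
            tchi = dihedral(tcoords[qa], tcoords[qb], tcoords[qc], tcoords[qd])
            axis_delta[(qb, qc)] = value - tchi

    for d in order:
        c = parent[d]
        b = grand(c)
        a = grand(b)
        bond = float(np.linalg.norm(tcoords[d] - tcoords[c]))
        ang = bond_angle(tcoords[b], tcoords[c], tcoords[d])
        tor = dihedral(tcoords[a], tcoords[b], tcoords[c], tcoords[d])
        tor += axis_delta.get((b, c), 0.0)
        pos[d] = place_atom(pos[a], pos[b], pos[c], bond, ang, tor)

    coords = np.array(tcoords, copy=True)
    for i, p in pos.items():
        coords[i] = p

    if resname == "PRO" and chi:
        coords = _set_proline_chi1(names, coords, chi[0])

    keep_drop = None
    if through_chi is not None and through_chi < len(quads):
        # drop atoms distal to the next chi bond
        nq = quads[through_chi]
        drop = set(_downstream(adj, names, nq[1], nq[2]))
        drop.discard(names.index(nq[2]))
        keep_drop = drop

    out = []
    for i, name in enumerate(names):
        if name in _BACKBONE:
            continue
        if keep_drop is not None and i in keep_drop:
            continue
        out.append((name, elements[i], coords[i].copy()))
    return out


def _set_proline_chi1(names, coords, chi1_target: float) -> np.ndarray:
    """Adjust proline chi1 by rotating CG about the CB-CD flap axis."""
    n, ca, cb, cg, cd = (names.index(x) for x in ("N", "CA", "CB", "CG", "CD"))

    def chi1_at(theta):
        rot = rotation_about_axis(coords[cd] - coords[cb], theta)
        g = (coords[cg] - coords[cb]) @ rot.T + coords[cb]
        return dihedral(coords[n], coords[ca], coords[cb], g), g

    best = None
    for theta in np.linspace(-80, 80, 321):
        val, g = chi1_at(theta)
        err = abs((val - chi1_target + 180) % 360 - 180)
        if best is None or err < best[0]:
            best = (err, g)
    new = coords.copy()
    new[cg] = best[1]
    return new
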