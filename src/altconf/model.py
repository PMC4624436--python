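"""Domain model for multiconformer protein structures and PDB-format I/O.

The unit of modeling is the :class:`ResidueEnsemble`: one residue carrying an
ordered list of alternative conformations ("conformers"), each tagged with an
altloc letter and an occupancy.  A deposited single-conformer residue is an
ensemble with one conformer whose altloc is ``''``.

The reader/writer speaks fixed-column PDB (ATOM/HETATM/ANISOU/TER/CRYST1)
and is lossless to output precision: coordinates to 1e-3 A, occupancies and
isotropic B to 1e-2.  Atoms with a blank altloc inside a partially split
residue follow the deposited-PDB convention: they are shared by every
conformer and are replicated into each one on read (flagged ``shared``) and
emitted once on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: number of chi dihedrals per chi-bearing residue type
CHI_COUNTS = {
    "ARG": 4, "LYS": 4,
    "GLU": 3, "GLN": 3, "MET": 3,
    "ASP": 2, "ASN": 2, "HIS": 2, "ILE": 2, "LEU": 2,
    "PHE": 2, "PRO": 2, "TRP": 2, "TYR": 2,
    "CYS": 1, "SER": 1, "THR": 1, "VAL": 1,
    "ALA": 0, "GLY": 0,
}

SMALL_SIDECHAINS = frozenset(
    {"ASN", "ASP", "CYS", "ILE", "LEU", "PRO", "SER", "THR", "VAL"}
)
LARGE_SIDECHAINS = frozenset(
    {"ARG", "GLU", "GLN", "HIS", "LYS", "MET", "PHE", "TRP", "TYR"}
)


class PDBFormatError(ValueError):
    """Malformed fixed-column PDB content; message names the line number."""


class DuplicateAtomError(PDBFormatError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0
    b_aniso: np.ndarray | None = None  # symmetric 3x3, A^2
    altloc: str = ""
    shared: bool = False  # blank-altloc atom replicated across conformers

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not (-1e-6 <= self.occupancy <= 1.0 + 1e-6):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_iso < 0:
            raise ValueError(f"negative b_iso {self.b_iso}")
        if self.b_aniso is not None:
            t = np.asarray(self.b_aniso, dtype=float)
            if not np.allclose(t, t.T, atol=1e-8):
                raise ValueError("b_aniso must be symmetric")
            if np.trace(t) <= 0:
                raise ValueError("b_aniso must have positive trace")
            self.b_aniso = t

    def copy(self) -> "Atom":
        a = replace(self)
        a.position = self.position.copy()
        if self.b_aniso is not None:
            a.b_aniso = self.b_aniso.copy()
        return a


@dataclass
class Conformer:
    altloc: str
    occupancy: float
    atoms: list[Atom] = field(default_factory=list)

    def get(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    def has(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self, names=None) -> np.ndarray:
        if names is None:
            return np.array([a.position for a in self.atoms])
        return np.array([self.get(n).position for n in names])

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}

    def copy(self) -> "Conformer":
        return Conformer(self.altloc, self.occupancy, [a.copy() for a in self.atoms])


@dataclass
class ResidueEnsemble:
    chain: str
    resseq: int
    icode: str
    name: str
    conformers: list[Conformer] = field(default_factory=list)
    hetero: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)

    def occupancy_sum(self) -> float:
        return sum(c.occupancy for c in self.conformers)

    def primary(self) -> Conformer:
        """Highest-occupancy conformer (ties broken by altloc order)."""
        return max(self.conformers, key=lambda c: (c.occupancy, -ord(c.altloc or " ")))

    def collapse_to_primary(self) -> "ResidueEnsemble":
        if len(self.conformers) > 1:
            logger.warning(
                "residue %s %s%d%s: collapsing %d input conformers to the "
                "highest-occupancy one before fitting",
                self.name, self.chain, self.resseq, self.icode, len(self.conformers),
            )
        best = self.primary().copy()
        best.altloc = ""
        best.occupancy = 1.0
        for a in best.atoms:
            a.altloc = ""
            a.occupancy = 1.0
            a.shared = False
        return ResidueEnsemble(self.chain, self.resseq, self.icode, self.name,
                               [best], self.hetero)

    def validate(self, threshold: float | None = None) -> None:
        if self.occupancy_sum() > 1.0 + 1e-6:
            raise ValueError(f"occupancies of {self.key} sum to {self.occupancy_sum()}")
        names = [c.atom_names() for c in self.conformers]
        if any(n != names[0] for n in names[1:]):
            raise ValueError(f"conformers of {self.key} carry different atom sets")
        if threshold is not None and len(self.conformers) > int(1.0 / threshold):
            raise ValueError(
                f"{len(self.conformers)} conformers exceeds cardinality "
                f"floor(1/{threshold})"
            )

    def copy(self) -> "ResidueEnsemble":
        return ResidueEnsemble(self.chain, self.resseq, self.icode, self.name,
                               [c.copy() for c in self.conformers], self.hetero)


@dataclass
class ProteinModel:
    residues: list[ResidueEnsemble] = field(default_factory=list)
    unit_cell: tuple[float, float, float, float, float, float] | None = None

    def chains(self) -> dict[str, list[ResidueEnsemble]]:
        out: dict[str, list[ResidueEnsemble]] = {}
        for r in self.residues:
            out.setdefault(r.chain, []).append(r)
        return out

    def get(self, chain: str, resseq: int, icode: str = "") -> ResidueEnsemble:
        for r in self.residues:
            if r.key == (chain, resseq, icode):
                return r
        raise KeyError((chain, resseq, icode))

    def polymer(self) -> list[ResidueEnsemble]:
        """Amino-acid residues only (ligands/waters carried as background)."""
        return [r for r in self.residues if r.name in CHI_COUNTS]

    def copy(self) -> "ProteinModel":
        return ProteinModel([r.copy() for r in self.residues], self.unit_cell)

    def validate(self) -> None:
        for ch, residues in self.chains().items():
            poly = [r for r in residues if r.name in CHI_COUNTS]
            nums = [(r.resseq, r.icode) for r in poly]
            if nums != sorted(nums):
                raise ValueError(f"residue numbering not increasing in chain {ch}")
            for r in poly:
                r.validate()


# ---------------------------------------------------------------------------
# PDB fixed-column I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple:
    try:
        serial = line[6:11]
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        b = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM/HETATM record at line {lineno}: {exc}")
    if not element:
        # fall back to the name convention: col 13 blank => 1-letter element
        element = name[:2].strip() if line[12] != " " else name[0]
        element = "".join(ch for ch in element if ch.isalpha())[:2]
    del serial
    return name, altloc, resname, chain, resseq, icode, np.array([x, y, z]), occ, b, element


def read_pdb(path) -> ProteinModel:
    """Read a (multi)conformer model from a fixed-column PDB file.

    Atoms sharing (chain, resseq, icode) are grouped into one
    :class:`ResidueEnsemble`; distinct altlocs become distinct conformers and
    blank-altloc atoms of a partially split residue are replicated into every
    conformer with ``shared=True``.  ANISOU records attach to the matching
    preceding ATOM.
    """
    unit_cell = None
    # residue key -> {altloc -> list[Atom]}, plus bookkeeping
    order: list[tuple] = []
    groups: dict[tuple, dict[str, list[Atom]]] = {}
    resnames: dict[tuple, str] = {}
    hetflags: dict[tuple, bool] = {}
    seen: set[tuple] = set()
    last_atom: Atom | None = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    unit_cell = tuple(
                        float(line[i:j]) for i, j in
                        ((6, 15), (15, 24), (24, 33), (33, 40), (40, 47), (47, 54))
                    )
                except ValueError as exc:
                    raise PDBFormatError(f"malformed CRYST1 at line {lineno}: {exc}")
            elif rec in ("ATOM  ", "HETATM"):
                (name, altloc, resname, chain, resseq, icode,
                 pos, occ, b, element) = _parse_atom_line(line, lineno)
                akey = (chain, resseq, icode, name, altloc)
                if akey in seen:
                    raise DuplicateAtomError(
                        f"duplicate atom {akey} at line {lineno}")
                seen.add(akey)
                rkey = (chain, resseq, icode)
                if rkey not in groups:
                    groups[rkey] = {}
                    order.append(rkey)
                    resnames[rkey] = resname
                    hetflags[rkey] = rec == "HETATM"
                atom = Atom(name, element, pos, occ, b, None, altloc)
                groups[rkey].setdefault(altloc, []).append(atom)
                last_atom = atom
            elif rec == "ANISOU":
                if last_atom is None:
                    raise PDBFormatError(f"ANISOU without ATOM at line {lineno}")
                try:
                    u = [int(line[28 + 7 * i:35 + 7 * i]) for i in range(6)]
                except ValueError as exc:
                    raise PDBFormatError(f"malformed ANISOU at line {lineno}: {exc}")
                f = 1e-4 * 8.0 * np.pi**2  # U (1e-4 A^2) -> B (A^2)
                t = np.array([[u[0], u[3], u[4]],
                              [u[3], u[1], u[5]],
                              [u[4], u[5], u[2]]], dtype=float) * f
                last_atom.b_aniso = t

    residues = []
    for rkey in order:
        by_altloc = groups[rkey]
        labeled = sorted(a for a in by_altloc if a)
        shared = by_altloc.get("", [])
        conformers: list[Conformer] = []
        if labeled:
            for al in labeled:
                atoms = [a.copy() for a in shared]
                for a in atoms:
                    a.shared = True
                atoms += by_altloc[al]
                occ = by_altloc[al][0].occupancy
                conformers.append(Conformer(al, occ, atoms))
        else:
            conformers.append(Conformer("", shared[0].occupancy if shared else 1.0,
                                        shared))
        residues.append(
            ResidueEnsemble(rkey[0], rkey[1], rkey[2], resnames[rkey],
                            conformers, hetflags[rkey])
        )
    return ProteinModel(residues, unit_cell)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def _atom_lines(atom: Atom, serial: int, res: ResidueEnsemble, altloc: str,
                hetero: bool) -> list[str]:
    rec = "HETATM" if hetero else "ATOM  "
    x, y, z = atom.position
    line = (
        f"{rec}{serial:5d} {_format_atom_name(atom.name, atom.element)}"
        f"{altloc or ' '}{res.name:>3s} {res.chain}{res.resseq:4d}"
        f"{res.icode or ' '}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_iso:6.2f}          "
        f"{atom.element:>2s}"
    )
    lines = [line]
    if atom.b_aniso is not None:
        f = 1.0 / (1e-4 * 8.0 * np.pi**2)
        t = atom.b_aniso * f
        u = [t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2]]
        lines.append(
            f"ANISOU{serial:5d} {_format_atom_name(atom.name, atom.element)}"
            f"{altloc or ' '}{res.name:>3s} {res.chain}{res.resseq:4d}"
            f"{res.icode or ' '} " + "".join(f"{int(round(v)):7d}" for v in u)
            + "      " + f"{atom.element:>2s}"
        )
    return lines


def write_pdb(model: ProteinModel, path) -> None:
    """Write ``model`` in fixed-column PDB format.

    Multiconformer residues are emitted with consecutive altloc letters
    'A', 'B', ...; ``shared`` atoms are emitted once with a blank altloc.
    """
    lines: list[str] = []
    if model.unit_cell is not None:
        a, b, c, al, be, ga = model.unit_cell
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1"
        )
    serial = 0
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    prev_chain = None
    for res in model.residues:
        if prev_chain is not None and res.chain != prev_chain:
            lines.append("TER")
        prev_chain = res.chain
        if len(res.conformers) == 1 and not any(
            a.shared for a in res.conformers[0].atoms
        ):
            conf = res.conformers[0]
            for atom in conf.atoms:
                serial += 1
                lines += _atom_lines(atom, serial, res, conf.altloc, res.hetero)
        else:
            if len(res.conformers) > len(letters):
                raise ValueError(
                    f"{len(res.conformers)} conformers exceeds supported "
                    f"altloc labels (26)"
                )
            shared_done = False
            for i, conf in enumerate(res.conformers):
                label = letters[i] if len(res.conformers) > 1 else (conf.altloc or "")
                for atom in conf.atoms:
                    if atom.shared:
                        if shared_done:
                            continue
                        serial += 1
                        lines += _atom_lines(atom, serial, res, "", res.hetero)
                    else:
                        serial += 1
                        lines += _atom_lines(atom, serial, res, label, res.hetero)
                shared_done = True
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Rotamer library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RotamerEntry:
    residue: str
    name: str
    chi: tuple[float, ...]

    def __post_init__(self):
        for c in self.chi:
            if not (-180.0 < c <= 180.0):
                raise ValueError(f"chi {c} outside (-180, 180]")
        if len(self.chi) != CHI_COUNTS[self.residue]:
            raise ValueError(
                f"{self.residue} expects {CHI_COUNTS[self.residue]} chi angles, "
                f"got {len(self.chi)}"
            )


def load_rotamer_library(path=None) -> list[RotamerEntry]:
    """Load the shipped rotamer table (whitespace-delimited, one rotamer
    per line: residue, rotamer name, chi1..chi4)."""
    if path is None:
        from importlib.resources import files
        path = files("altconf.data") / "rotamer_library.txt"
    entries: list[RotamerEntry] = []
    with open(str(path)) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            res = parts[0].upper()
            if res not in CHI_COUNTS:
                raise ValueError(f"unknown residue type {res!r} at line {lineno}")
            chi = tuple(float(x) for x in parts[2:])
            entries.append(RotamerEntry(res, parts[1], chi))
    return entries


def rotamers_for(library: list[RotamerEntry], residue: str) -> list[RotamerEntry]:
    return [e for e in library if e.residue == residue.upper()]
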