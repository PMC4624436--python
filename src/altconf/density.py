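"""Real-space electron density: model-to-map calculation, map scaling and
masking, background subtraction, synthetic-data generation, CCP4/MRC I/O.

Density is computed as a sum of isotropic Gaussians per atom using tabulated
5-term element form factors (four Gaussians plus a constant, the constant
treated as a zero-width Gaussian).  The atomic displacement parameter B
enters through the standard isotropic Debye-Waller broadening: each
reciprocal-space term ``a_k exp(-b_k s^2/4)`` becomes, in real space,

    rho_k(r) = a_k (4 pi / (b_k + B))^{3/2} exp(-4 pi^2 r^2 / (b_k + B))

so the map integral of one atom equals its electron count.

All maps live on orthogonal grids in a P1 box; the grid-to-Cartesian mapping
is the affine ``x = origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .model import Atom, ProteinModel

__all__ = [
    "DensityMap",
    "VoxelMask",
    "SyntheticSpec",
    "mask_radius",
    "calc_density",
    "density_at_points",
    "grid_for_atoms",
    "build_mask",
    "scale_obs_to_calc",
    "background_subtract",
    "generate_synthetic_dataset",
    "read_map",
    "write_map",
]

# minimum effective Gaussian width parameter (A^2); keeps the constant
# form-factor term finite for near-zero B
_B_FLOOR = 0.5


def mask_radius(d: float) -> float:
    """Resolution-dependent fitting-mask radius r(d) in angstroms:
    ``r = 0.7 + (d - 0.6)/3`` below 3 A resolution and ``0.5 d`` above."""
    if d <= 0:
        raise ValueError(f"resolution must be positive, got {d}")
    if d < 3.0:
        return 0.7 + (d - 0.6) / 3.0
    return 0.5 * d


@dataclass
class DensityMap:
    values: np.ndarray          # (nx, ny, nz)
    origin: np.ndarray          # Cartesian A of voxel (0,0,0)
    spacing: np.ndarray         # A per voxel along x,y,z
    resolution: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def index_of(self, point: np.ndarray) -> np.ndarray:
        return np.round((np.asarray(point) - self.origin) / self.spacing).astype(int)

    def values_at(self, indices: np.ndarray) -> np.ndarray:
        ix = np.asarray(indices)
        return self.values[ix[:, 0], ix[:, 1], ix[:, 2]]

    def like(self, values: np.ndarray | None = None) -> "DensityMap":
        v = np.zeros(self.shape) if values is None else values
        return DensityMap(v, self.origin.copy(), self.spacing.copy(), self.resolution)

    def copy(self) -> "DensityMap":
        return self.like(self.values.copy())


@dataclass
class VoxelMask:
    indices: np.ndarray                     # (N, 3) int voxel indices
    atoms: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    radius: float = 0.0

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# form factors
# ---------------------------------------------------------------------------

_FF_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _form_factor(element: str) -> tuple[np.ndarray, np.ndarray]:
    el = element.capitalize()
    if el not in _FF_CACHE:
        g = gemmi.Element(el)
        coef = g.it92
        if coef is None or g.atomic_number == 0:
            raise ValueError(f"no form-factor entry for element {element!r}")
        a = np.array(list(coef.a) + [coef.c])
        b = np.array(list(coef.b) + [0.0])
        _FF_CACHE[el] = (a, b)
    return _FF_CACHE[el]


def _atom_b(atom: Atom) -> float:
    if atom.b_aniso is not None:
        return float(np.trace(atom.b_aniso) / 3.0)
    return atom.b_iso


def density_at_points(atoms, points: np.ndarray, cutoff: float | None = None) -> np.ndarray:
    """Density of ``atoms`` evaluated at arbitrary Cartesian ``points``.

    Each atom contributes its occupancy-scaled, B-broadened Gaussian sum;
    contributions beyond ``cutoff`` (if given) are dropped.
    """
    pts = np.asarray(points, dtype=float)
    out = np.zeros(len(pts))
    for atom in atoms:
        if atom.occupancy <= 0.0:
            continue
        a, b = _form_factor(atom.element)
        beff = np.maximum(b + max(_atom_b(atom), 0.0), _B_FLOOR)
        d2 = np.sum((pts - atom.position) ** 2, axis=1)
        if cutoff is not None:
            sel = d2 <= cutoff * cutoff
            if not np.any(sel):
                continue
            d2s = d2[sel]
            contrib = np.zeros(len(pts))
            contrib[sel] = np.sum(
                atom.occupancy
                * a
                * (4.0 * np.pi / beff) ** 1.5
                * np.exp(-4.0 * np.pi**2 * d2s[:, None] / beff),
                axis=1,
            )
            out += contrib
        else:
            out += np.sum(
                atom.occupancy
                * a
                * (4.0 * np.pi / beff) ** 1.5
                * np.exp(-4.0 * np.pi**2 * d2[:, None] / beff),
                axis=1,
            )
    return out


def calc_density(atoms, grid: DensityMap, d: float | None = None) -> DensityMap:
    """Compute model density on the grid of ``grid`` (values ignored).

    Contributions are truncated beyond ``3 + r(d)`` angstroms of each atom
    (a generous envelope relative to typical atomic B); with ``d`` omitted
    the grid's own resolution is used, defaulting to no truncation.
    """
    if d is None:
        d = grid.resolution
    cutoff = (3.0 + mask_radius(d)) if d is not None else None
    out = grid.like()
    nx, ny, nz = out.shape
    for atom in atoms:
        if atom.occupancy <= 0.0:
            continue
        a, b = _form_factor(atom.element)
        beff = np.maximum(b + max(_atom_b(atom), 0.0), _B_FLOOR)
        rel = (atom.position - out.origin) / out.spacing
        if cutoff is None:
            lo = np.zeros(3, dtype=int)
            hi = np.array([nx, ny, nz])
        else:
            ext = cutoff / out.spacing
            lo = np.maximum(np.floor(rel - ext).astype(int), 0)
            hi = np.minimum(np.ceil(rel + ext).astype(int) + 1, [nx, ny, nz])
        if np.any(lo >= hi):
            continue
        ax = (np.arange(lo[0], hi[0]) * out.spacing[0] + out.origin[0]) - atom.position[0]
        ay = (np.arange(lo[1], hi[1]) * out.spacing[1] + out.origin[1]) - atom.position[1]
        az = (np.arange(lo[2], hi[2]) * out.spacing[2] + out.origin[2]) - atom.position[2]
        d2 = (
            ax[:, None, None] ** 2
            + ay[None, :, None] ** 2
            + az[None, None, :] ** 2
        )
        block = np.zeros(d2.shape)
        for ak, bk in zip(a, beff):
            block += atom.occupancy * ak * (4.0 * np.pi / bk) ** 1.5 * np.exp(
                -4.0 * np.pi**2 * d2 / bk
            )
        if cutoff is not None:
            block[d2 > cutoff * cutoff] = 0.0
        out.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += block
    return out


def grid_for_atoms(atoms, d: float, spacing: float | None = None,
                   pad: float | None = None) -> DensityMap:
    """Empty map whose P1 box comfortably encloses ``atoms``.

    Default spacing is d/4 (common crystallographic sampling); default
    padding is ``3 + r(d)`` so every atom's full density footprint and the
    fitting mask fit inside.
    """
    coords = np.array([a.position for a in atoms])
    if spacing is None:
        spacing = d / 4.0
    if pad is None:
        pad = 3.0 + mask_radius(d)
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    return DensityMap(np.zeros(shape), lo, np.full(3, spacing), d)


def build_mask(grid: DensityMap, positions: np.ndarray, radius: float) -> VoxelMask:
    """Union of voxel spheres of ``radius`` around ``positions``."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    nx, ny, nz = grid.shape
    hit: set[tuple[int, int, int]] = set()
    for p in pos:
        rel = (p - grid.origin) / grid.spacing
        ext = radius / grid.spacing
        lo = np.maximum(np.floor(rel - ext).astype(int), 0)
        hi = np.minimum(np.ceil(rel + ext).astype(int) + 1, [nx, ny, nz])
        if np.any(lo >= hi):
            continue
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]), indexing="ij",
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        centers = grid.voxel_centers(idx)
        ok = np.sum((centers - p) ** 2, axis=1) <= radius * radius
        for t in idx[ok]:
            hit.add((int(t[0]), int(t[1]), int(t[2])))
    indices = np.array(sorted(hit), dtype=int).reshape(-1, 3)
    return VoxelMask(indices, pos, radius)


# ---------------------------------------------------------------------------
# scaling / background subtraction
# ---------------------------------------------------------------------------

def scale_obs_to_calc(obs: DensityMap, calc: DensityMap, mask: VoxelMask
                      ) -> tuple[DensityMap, float, float]:
    """Put the observed map on the calculated map's scale.

    A linear model ``obs = gain * calc + offset`` is fit by least squares
    over the masked voxels; the returned map is ``(obs - offset) / gain``.
    """
    if len(mask) < 10:
        raise ValueError(f"degenerate mask of {len(mask)} voxels (< 10)")
    o = obs.values_at(mask.indices)
    c = calc.values_at(mask.indices)
    A = np.stack([c, np.ones_like(c)], axis=1)
    (gain, offset), *_ = np.linalg.lstsq(A, o, rcond=None)
    if abs(gain) < 1e-12:
        raise ValueError("zero gain between observed and calculated density")
    scaled = obs.like((obs.values - offset) / gain)
    return scaled, float(gain), float(offset)


def _model_atoms(model: ProteinModel):
    """Flat atom list with shared atoms emitted once per residue."""
    out = []
    for res in model.residues:
        shared_done = False
        for conf in res.conformers:
            for a in conf.atoms:
                if a.shared:
                    if shared_done:
                        continue
                    out.append(a)
                else:
                    out.append(a)
            shared_done = True
    return out


def background_subtract(obs: DensityMap, model: ProteinModel,
                        selection, d: float) -> DensityMap:
    """Residual map ``obs - calc(all atoms not in selection)``.

    ``selection`` is a set of ``(chain, resseq, icode, atom_name)`` tuples
    naming the atoms to be rebuilt; their density stays in the residual and
    becomes the fitting target for candidate conformers.
    """
    selection = set(selection)
    if not selection:
        raise ValueError("empty rebuild selection")
    background = []
    for res in model.residues:
        shared_done = False
        for conf in res.conformers:
            for a in conf.atoms:
                if a.shared and shared_done:
                    continue
                if (res.chain, res.resseq, res.icode, a.name) not in selection:
                    background.append(a)
            shared_done = True
    bg = calc_density(background, obs, d)
    return obs.like(obs.values - bg.values)


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Protocol for one synthetic dataset.

    B-factors are inflated by ``b_inflation_rate`` (A^2 per A of resolution
    lost relative to ``original_resolution``), the model is placed in a P1
    box, density is computed, band-limited at 1/d, and zero-mean complex
    Gaussian noise with sigma = ``noise_fraction`` x mean structure-factor
    amplitude is added in reciprocal space.
    """
    model: ProteinModel
    resolution: float                     # target d, A
    original_resolution: float = 0.9      # d0, A
    b_inflation_rate: float = 10.0        # A^2 per A of resolution lost
    noise_fraction: float = 0.10
    noise_mode: str = "global"            # 'global' | 'proportional'
    bulk_solvent: bool = False
    k_sol: float = 0.4
    b_sol: float = 45.0
    spacing: float | None = None

    def __post_init__(self):
        if self.resolution < self.original_resolution:
            raise ValueError(
                f"target resolution {self.resolution} better than original "
                f"{self.original_resolution}"
            )
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")


def generate_synthetic_dataset(spec: SyntheticSpec, rng=None
                               ) -> tuple[ProteinModel, DensityMap]:
    """Generate (ground-truth model, observed map) per the synthetic protocol."""
    rng = np.random.default_rng(rng)
    d = spec.resolution
    truth = spec.model.copy()
    dB = spec.b_inflation_rate * (d - spec.original_resolution)
    for res in truth.residues:
        for conf in res.conformers:
            for a in conf.atoms:
                if a.b_aniso is not None:
                    a.b_iso = float(np.trace(a.b_aniso) / 3.0)
                    a.b_aniso = None
                a.b_iso += dB

    atoms = _model_atoms(truth)
    grid = grid_for_atoms(atoms, d, spacing=spec.spacing)
    calc = calc_density(atoms, grid, d)
    values = calc.values

    F = np.fft.rfftn(values)
    nx, ny, nz = values.shape
    fx = np.fft.fftfreq(nx, d=grid.spacing[0])
    fy = np.fft.fftfreq(ny, d=grid.spacing[1])
    fz = np.fft.rfftfreq(nz, d=grid.spacing[2])
    s2 = (fx[:, None, None] ** 2 + fy[None, :, None] ** 2
          + fz[None, None, :] ** 2)
    keep = s2 <= (1.0 / d) ** 2

    if spec.bulk_solvent:
        # flat solvent in the region > 2 A from any atom, blurred by b_sol
        coords = np.array([a.position for a in atoms])
        solv = np.ones(values.shape)
        m = build_mask(grid, coords, 2.0)
        solv[m.indices[:, 0], m.indices[:, 1], m.indices[:, 2]] = 0.0
        Fs = np.fft.rfftn(spec.k_sol * solv) * np.exp(-spec.b_sol * s2 / 4.0)
        F = F + Fs

    F[~keep] = 0.0
    if spec.noise_fraction > 0:
        amp = np.abs(F)
        nonzero = keep.copy()
        nonzero[0, 0, 0] = False
        if spec.noise_mode == "global":
            sigma = spec.noise_fraction * amp[nonzero].mean()
            sig = np.where(nonzero, sigma, 0.0)
        elif spec.noise_mode == "proportional":
            sig = np.where(nonzero, spec.noise_fraction * amp, 0.0)
        else:
            raise ValueError(f"unknown noise mode {spec.noise_mode!r}")
        noise = (rng.standard_normal(F.shape) + 1j * rng.standard_normal(F.shape))
        F = F + sig * noise / np.sqrt(2.0)

    obs_values = np.fft.irfftn(F, s=values.shape, axes=(0, 1, 2))
    obs = grid.like(obs_values)
    return truth, obs


# ---------------------------------------------------------------------------
# CCP4/MRC I/O
# ---------------------------------------------------------------------------

def write_map(dmap: DensityMap, path) -> None:
    """Write a mode-2 CCP4/MRC map; the Cartesian origin goes into the
    MRC2014 ORIGIN header words."""
    g = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    nx, ny, nz = dmap.shape
    g.set_unit_cell(gemmi.UnitCell(
        nx * dmap.spacing[0], ny * dmap.spacing[1], nz * dmap.spacing[2],
        90.0, 90.0, 90.0,
    ))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for i, v in enumerate(dmap.origin):
        m.set_header_float(50 + i, float(v))
    m.write_ccp4_map(str(path))


def read_map(path, resolution: float | None = None) -> DensityMap:
    """Read a CCP4/MRC map, normalizing axis order to fast->slow = x,y,z."""
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise ValueError("non-orthogonal unit cell is unsupported (P1-box scope)")
    values = np.array(m.grid, copy=True).astype(float)
    nx, ny, nz = values.shape
    spacing = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    origin = np.array([m.header_float(50 + i) for i in range(3)])
    if np.allclose(origin, 0.0):
        start = np.array([m.header_i32(5 + i) for i in range(3)], dtype=float)
        origin = start * spacing
    return DensityMap(values, origin, spacing, resolution)
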