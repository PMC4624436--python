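"""Density computation, scaling, masking, synthetic data and map I/O."""

import numpy as np
import pytest

from altconf.density import (
    DensityMap, SyntheticSpec, background_subtract, build_mask, calc_density,
    density_at_points, generate_synthetic_dataset, grid_for_atoms, mask_radius,
    read_map, scale_obs_to_calc, write_map,
)
from altconf.model import Atom


def _grid(spacing=0.4, extent=12.0, d=1.5):
    n = int(extent / spacing)
    return DensityMap(np.zeros((n, n, n)), np.zeros(3), np.full(3, spacing), d)


class TestMaskRadius:
    @pytest.mark.parametrize("d,r", [(1.5, 1.0), (3.0, 1.5), (4.0, 2.0)])
    def test_formula_values(self, d, r):
        assert mask_radius(d) == pytest.approx(r, abs=1e-12)

    def test_branch_continuity_and_monotonicity(self):
        ds = np.linspace(0.5, 6.0, 200)
        rs = np.array([mask_radius(d) for d in ds])
        assert np.all(np.diff(rs) >= -1e-12)
        assert mask_radius(3.0 - 1e-9) == pytest.approx(mask_radius(3.0), abs=1e-6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            mask_radius(0.0)


class TestCalcDensity:
    def test_zero_occupancy_contributes_nothing(self):
        g = _grid()
        atom = Atom("C", "C", [6, 6, 6], occupancy=0.0, b_iso=15.0)
        assert np.all(calc_density([atom], g).values == 0.0)

    def test_linearity_in_occupancy(self):
        g = _grid()
        a1 = Atom("C", "C", [6, 6, 6], occupancy=0.4, b_iso=15.0)
        a2 = Atom("C", "C", [6, 6, 6], occupancy=0.8, b_iso=15.0)
        v1 = calc_density([a1], g).values
        v2 = calc_density([a2], g).values
        assert np.allclose(v2, 2.0 * v1, rtol=1e-12, atol=1e-15)

    def test_additivity_over_atoms(self):
        g = _grid()
        a = Atom("C", "C", [5, 6, 6], 1.0, 12.0)
        b = Atom("O", "O", [7, 6, 6], 1.0, 18.0)
        both = calc_density([a, b], g).values
        sep = calc_density([a], g).values + calc_density([b], g).values
        assert np.allclose(both, sep, atol=1e-12)

    def test_carbon_integral_matches_electron_count(self):
        # integral of one atom's density ~ Z (6 for carbon) within 2%
        d = 1.5
        atom = Atom("C", "C", [8, 8, 8], 1.0, 20.0)
        g = grid_for_atoms([atom], d, spacing=d / 4, pad=6.0)
        total = calc_density([atom], g, d=None).values.sum() * np.prod(g.spacing)
        assert total == pytest.approx(6.0, rel=0.02)

    def test_unknown_element_rejected(self):
        g = _grid()
        with pytest.raises(ValueError):
            calc_density([Atom("X", "Xx", [6, 6, 6], 1.0, 10.0)], g)

    def test_points_evaluation_matches_grid(self):
        g = _grid()
        atom = Atom("N", "N", [6.1, 5.9, 6.0], 1.0, 14.0)
        dm = calc_density([atom], g, d=None)
        idx = np.array([[10, 12, 15], [15, 15, 15], [20, 10, 14]])
        pts = g.voxel_centers(idx)
        assert np.allclose(density_at_points([atom], pts),
                           dm.values_at(idx), rtol=1e-10)


class TestScaling:
    def test_exact_linear_recovery(self):
        g = _grid()
        atom = Atom("C", "C", [6, 6, 6], 1.0, 15.0)
        calc = calc_density([atom], g)
        obs = calc.like(2.0 * calc.values + 1.0)
        mask = build_mask(g, np.array([[6, 6, 6.0]]), 2.5)
        scaled, gain, offset = scale_obs_to_calc(obs, calc, mask)
        assert gain == pytest.approx(2.0, abs=1e-9)
        assert offset == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(scaled.values_at(mask.indices),
                           calc.values_at(mask.indices), atol=1e-9)

    def test_identity_scaling(self):
        g = _grid()
        calc = calc_density([Atom("C", "C", [6, 6, 6], 1.0, 15.0)], g)
        mask = build_mask(g, np.array([[6, 6, 6.0]]), 2.5)
        _, gain, offset = scale_obs_to_calc(calc, calc, mask)
        assert gain == pytest.approx(1.0, abs=1e-12)
        assert offset == pytest.approx(0.0, abs=1e-12)

    def test_noisy_gain_recovered_within_1pct(self, rng):
        g = _grid(spacing=0.3)
        calc = calc_density([Atom("C", "C", [6, 6, 6], 1.0, 15.0)], g)
        mask = build_mask(g, np.array([[6, 6, 6.0]]), 3.0)
        assert len(mask) >= 1000
        noise = 0.01 * rng.standard_normal(len(mask))
        obs = calc.copy()
        obs.values[mask.indices[:, 0], mask.indices[:, 1], mask.indices[:, 2]] = (
            1.7 * calc.values_at(mask.indices) + noise)
        _, gain, _ = scale_obs_to_calc(obs, calc, mask)
        assert gain == pytest.approx(1.7, rel=0.01)

    def test_degenerate_mask_rejected(self):
        g = _grid()
        calc = calc_density([Atom("C", "C", [6, 6, 6], 1.0, 15.0)], g)
        tiny = build_mask(g, np.array([[6, 6, 6.0]]), 0.3)
        with pytest.raises(ValueError):
            scale_obs_to_calc(calc, calc, tiny)


class TestBackgroundSubtract:
    def test_full_selection_returns_obs(self, loop_chain):
        atoms = [a for r in loop_chain.residues
                 for a in r.conformers[0].atoms]
        g = grid_for_atoms(atoms, 2.0, spacing=0.5, pad=3.0)
        obs = calc_density(atoms, g)
        sel = {(r.chain, r.resseq, r.icode, a.name)
               for r in loop_chain.residues for a in r.conformers[0].atoms}
        residual = background_subtract(obs, loop_chain, sel, 2.0)
        assert np.allclose(residual.values, obs.values, atol=1e-12)

    def test_residual_equals_selected_atom_density(self, loop_chain):
        atoms = [a for r in loop_chain.residues for a in r.conformers[0].atoms]
        g = grid_for_atoms(atoms, 1.5, spacing=0.4, pad=3.5)
        obs = calc_density(atoms, g)
        res4 = loop_chain.get("A", 4)
        sel = {("A", 4, "", a.name) for a in res4.conformers[0].atoms}
        residual = background_subtract(obs, loop_chain, sel, 1.5)
        expected = calc_density(res4.conformers[0].atoms, g)
        peak = expected.values.max()
        rms = np.sqrt(np.mean((residual.values - expected.values) ** 2))
        assert rms < 0.01 * peak

    def test_locality_of_disjoint_selections(self, loop_chain):
        atoms = [a for r in loop_chain.residues for a in r.conformers[0].atoms]
        g = grid_for_atoms(atoms, 1.5, spacing=0.4, pad=3.5)
        obs = calc_density(atoms, g)
        sel2 = {("A", 2, "", a.name)
                for a in loop_chain.get("A", 2).conformers[0].atoms}
        sel6 = {("A", 6, "", a.name)
                for a in loop_chain.get("A", 6).conformers[0].atoms}
        r2 = background_subtract(obs, loop_chain, sel2, 1.5)
        r6 = background_subtract(obs, loop_chain, sel6, 1.5)
        diff = np.abs(r2.values - r6.values)
        pos2 = loop_chain.get("A", 2).conformers[0].coords()
        pos6 = loop_chain.get("A", 6).conformers[0].coords()
        near = np.concatenate([pos2, pos6])
        idx = np.argwhere(diff > 1e-6)
        pts = g.voxel_centers(idx)
        dmin = np.min(np.linalg.norm(pts[:, None, :] - near[None, :, :],
                                     axis=2), axis=1)
        assert np.all(dmin <= 2 * mask_radius(1.5) + 3.0)

    def test_empty_selection_rejected(self, loop_chain):
        g = _grid()
        with pytest.raises(ValueError):
            background_subtract(g, loop_chain, set(), 1.5)


class TestSyntheticData:
    def test_b_inflation_zero_at_original_resolution(self, loop_chain):
        spec = SyntheticSpec(loop_chain, 0.9, original_resolution=0.9,
                             noise_fraction=0.0, spacing=0.5)
        truth, _ = generate_synthetic_dataset(spec, rng=0)
        b0 = loop_chain.residues[0].conformers[0].atoms[0].b_iso
        assert truth.residues[0].conformers[0].atoms[0].b_iso == b0

    def test_b_inflation_ten_per_angstrom(self, loop_chain):
        spec = SyntheticSpec(loop_chain, 2.0, original_resolution=1.2,
                             noise_fraction=0.0, spacing=0.6)
        truth, _ = generate_synthetic_dataset(spec, rng=0)
        for r_in, r_out in zip(loop_chain.residues, truth.residues):
            for a_in, a_out in zip(r_in.conformers[0].atoms,
                                   r_out.conformers[0].atoms):
                assert a_out.b_iso == pytest.approx(a_in.b_iso + 8.0, abs=1e-9)

    def test_worse_target_than_original_rejected(self, loop_chain):
        with pytest.raises(ValueError):
            SyntheticSpec(loop_chain, 0.8, original_resolution=1.0)

    def test_zero_noise_equals_bandlimited_calc(self, loop_chain):
        d = 1.5
        spec = SyntheticSpec(loop_chain, d, original_resolution=0.9,
                             noise_fraction=0.0, spacing=d / 4)
        truth, obs = generate_synthetic_dataset(spec, rng=5)
        atoms = [a for r in truth.residues for a in r.conformers[0].atoms]
        calc = calc_density(atoms, obs, d)
        # independent band-limit oracle
        F = np.fft.rfftn(calc.values)
        nx, ny, nz = calc.values.shape
        fx = np.fft.fftfreq(nx, obs.spacing[0])
        fy = np.fft.fftfreq(ny, obs.spacing[1])
        fz = np.fft.rfftfreq(nz, obs.spacing[2])
        s2 = fx[:, None, None] ** 2 + fy[None, :, None] ** 2 + fz[None, None, :] ** 2
        F[s2 > 1.0 / d ** 2] = 0.0
        expected = np.fft.irfftn(F, s=calc.values.shape, axes=(0, 1, 2))
        assert np.allclose(obs.values, expected, atol=1e-6)

    def test_zero_noise_is_seed_independent(self, loop_chain):
        spec = SyntheticSpec(loop_chain, 1.5, original_resolution=0.9,
                             noise_fraction=0.0, spacing=0.5)
        _, obs1 = generate_synthetic_dataset(spec, rng=1)
        _, obs2 = generate_synthetic_dataset(spec, rng=99)
        assert np.array_equal(obs1.values, obs2.values)

    def test_correlation_decreases_with_noise(self, loop_chain):
        d = 1.5
        corrs = []
        for frac in (0.0, 0.1, 0.3):
            vals = []
            for seed in range(5):
                spec = SyntheticSpec(loop_chain, d, original_resolution=0.9,
                                     noise_fraction=frac, spacing=0.5)
                _, obs = generate_synthetic_dataset(spec, rng=seed)
                atoms = [a for r in spec.model.residues
                         for a in r.conformers[0].atoms]
                # compare against the noiseless generator output
                clean_spec = SyntheticSpec(loop_chain, d,
                                           original_resolution=0.9,
                                           noise_fraction=0.0, spacing=0.5)
                _, clean = generate_synthetic_dataset(clean_spec, rng=seed)
                vals.append(np.corrcoef(obs.values.ravel(),
                                        clean.values.ravel())[0, 1])
            corrs.append(np.mean(vals))
        assert corrs[0] > corrs[1] > corrs[2]


class TestMapIO:
    def test_round_trip_values_origin_spacing(self, tmp_path):
        rng = np.random.default_rng(0)
        dmap = DensityMap(rng.standard_normal((6, 8, 10)),
                          np.array([1.25, -2.5, 3.0]),
                          np.array([0.5, 0.5, 0.5]), 1.5)
        path = tmp_path / "m.ccp4"
        write_map(dmap, path)
        back = read_map(path, resolution=1.5)
        assert np.allclose(back.values, dmap.values, atol=1e-6)  # float32
        assert np.allclose(back.origin, dmap.origin)
        assert np.allclose(back.spacing, dmap.spacing)
        assert back.resolution == 1.5

    def test_permuted_axis_order_normalized(self, tmp_path):
        import gemmi

        rng = np.random.default_rng(1)
        values = rng.standard_normal((4, 6, 8)).astype(np.float32)
        # write with axis order z,y,x (mapc=3, mapr=2, maps=1)
        g = gemmi.FloatGrid(np.ascontiguousarray(values.transpose(2, 1, 0)))
        g.set_unit_cell(gemmi.UnitCell(4 * 0.5, 6 * 0.5, 8 * 0.5, 90, 90, 90))
        m = gemmi.Ccp4Map()
        m.grid = g
        m.update_ccp4_header()
        m.set_header_i32(17, 3)
        m.set_header_i32(18, 2)
        m.set_header_i32(19, 1)
        path = tmp_path / "perm.ccp4"
        m.write_ccp4_map(str(path))
        back = read_map(path)
        assert back.values.shape == (4, 6, 8)
        assert np.allclose(back.values, values, atol=1e-6)
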