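"""Backbone candidate generation, nullspace IK and sidechain decoration."""

import numpy as np
import pytest

from altconf.benchmark import build_backbone_chain
from altconf.density import DensityMap, calc_density, grid_for_atoms
from altconf.model import Atom, load_rotamer_library
from altconf.sampling import (
    AnisoTensor, BackboneCandidate, SamplerConfig, decorate,
    decorate_large_sidechain, decorate_small_sidechain, density_moment_tensor,
    enumerate_backbones, fragment_around, nullspace_ik_close,
    sample_guide_displacements, secondary_structure, LARGE_OFFSETS,
    SMALL_OFFSETS,
)
from altconf.sidechain import CHI_ATOMS, build_sidechain, sidechain_chis


def _wrap(x):
    return (np.asarray(x) + 180.0) % 360.0 - 180.0


class TestMomentTensor:
    def test_spherical_blob_is_isotropic(self):
        g = grid_for_atoms([Atom("C", "C", [5, 5, 5], 1.0, 25.0)], 2.0,
                           spacing=0.4, pad=4.0)
        dmap = calc_density([Atom("C", "C", [5, 5, 5], 1.0, 25.0)], g)
        t = density_moment_tensor(dmap, np.array([5.0, 5, 5]), 2.0)
        assert t.eigenvalues[0] / t.eigenvalues[2] < 1.1

    def test_two_blobs_major_axis_along_displacement(self):
        atoms = [Atom("C", "C", [4.3, 5, 5], 1.0, 15.0),
                 Atom("C", "C", [5.7, 5, 5], 1.0, 15.0)]
        g = grid_for_atoms(atoms, 2.0, spacing=0.35, pad=4.0)
        dmap = calc_density(atoms, g)
        t = density_moment_tensor(dmap, np.array([5.0, 5, 5]), 2.2)
        angle = np.rad2deg(np.arccos(abs(t.eigenvectors[0, 0])))
        assert angle < 5.0

    def test_invariant_under_positive_rescaling(self):
        atoms = [Atom("C", "C", [5, 5, 5], 1.0, 20.0)]
        g = grid_for_atoms(atoms, 2.0, spacing=0.4, pad=4.0)
        dmap = calc_density(atoms, g)
        t1 = density_moment_tensor(dmap, np.array([5.0, 5, 5]), 2.0)
        t2 = density_moment_tensor(dmap.like(7.3 * dmap.values),
                                   np.array([5.0, 5, 5]), 2.0)
        assert np.allclose(t1.tensor, t2.tensor, atol=1e-12)

    def test_nonpositive_density_falls_back_isotropic(self):
        g = DensityMap(-np.ones((10, 10, 10)), np.zeros(3),
                       np.full(3, 0.5), 2.0)
        t = density_moment_tensor(g, np.array([2.5, 2.5, 2.5]), 1.5)
        assert t.eigenvalues[0] == pytest.approx(t.eigenvalues[2])


class TestGuideDisplacements:
    def test_exactly_six_targets(self):
        t = AnisoTensor(np.diag([0.09, 0.04, 0.01]))
        cfg = SamplerConfig(mc_ampl=0.2, jitter=0.05)
        out = sample_guide_displacements(t, cfg, np.zeros(3), rng=0)
        assert len(out) == 6

    def test_isotropic_zero_jitter_equal_magnitudes(self):
        t = AnisoTensor(np.eye(3) * 0.25)
        cfg = SamplerConfig(mc_ampl=0.3, jitter=0.0)
        out = sample_guide_displacements(t, cfg, np.zeros(3), rng=0)
        mags = [np.linalg.norm(p) for p in out]
        assert np.allclose(mags, 0.3 * 0.5, atol=1e-12)

    def test_magnitudes_scale_linearly_with_mc_ampl(self):
        t = AnisoTensor(np.diag([0.16, 0.09, 0.04]))
        mags = {}
        for mc in (0.1, 0.2, 0.3):
            cfg = SamplerConfig(mc_ampl=mc, jitter=0.0)
            out = sample_guide_displacements(t, cfg, np.zeros(3), rng=0)
            mags[mc] = np.array([np.linalg.norm(p) for p in out])
        assert np.allclose(mags[0.2] / mags[0.1], 2.0, atol=1e-9)
        assert np.allclose(mags[0.3] / mags[0.1], 3.0, atol=1e-9)


class TestNullspaceIK:
    def test_target_at_current_guide_is_identity(self, loop_chain):
        frag = fragment_around(loop_chain, "A", 4, 3)
        out, ok, err = nullspace_ik_close(frag, "CB", frag.guide_position())
        assert ok
        assert frag.backbone_rmsd(out) == 0.0

    def test_anchors_fixed_and_distance_reduced(self, loop_chain, rng):
        frag = fragment_around(loop_chain, "A", 4, 3)
        g0 = frag.guide_position().copy()
        n_converged = 0
        for _ in range(20):
            target = g0 + rng.uniform(-0.35, 0.35, 3)
            out, ok, err = nullspace_ik_close(frag, "CB", target)
            final = np.linalg.norm(out.guide_position() - target)
            assert final <= np.linalg.norm(target - g0) + 1e-9
            if ok:
                n_converged += 1
                assert final < 0.05 + 1e-6
                for idx in (0, len(frag) - 1):
                    for name in ("N", "CA", "C"):
                        moved = np.linalg.norm(out.coords[idx][name]
                                               - frag.coords[idx][name])
                        assert moved < 0.01
        assert n_converged >= 15  # typical small displacements close fine

    def test_matches_constrained_minimization_oracle(self, loop_chain, rng):
        # oracle: generic nonlinear minimization over the same dihedrals
        # with a stiff anchor penalty
        from scipy.optimize import minimize

        from altconf.sampling import _FragmentKinematics

        frag = fragment_around(loop_chain, "A", 4, 3)
        kin = _FragmentKinematics(frag)
        row = kin.lookup[(frag.center, "CB")]
        anchor_rows = np.array(kin.anchor_idx)
        anchor_goal = kin.base_coords[anchor_rows]
        g0 = frag.guide_position().copy()
        for _ in range(5):
            target = g0 + rng.uniform(-0.3, 0.3, 3)

            def objective(theta):
                coords = kin.rebuild(theta)
                f = np.sum((coords[row] - target) ** 2)
                pen = np.sum((coords[anchor_rows] - anchor_goal) ** 2)
                return f + 1e4 * pen

            res = minimize(objective, np.zeros(len(kin.dofs)),
                           method="Powell",
                           options={"maxiter": 4000, "xtol": 1e-8})
            oracle_err = np.sqrt(max(res.fun, 0.0))
            out, ok, err = nullspace_ik_close(frag, "CB", target)
            ours = np.linalg.norm(out.guide_position() - target)
            assert ours <= oracle_err + 0.05

    def test_bond_geometry_preserved(self, loop_chain, rng):
        frag = fragment_around(loop_chain, "A", 4, 3)
        target = frag.guide_position() + np.array([0.3, -0.2, 0.15])
        out, _, _ = nullspace_ik_close(frag, "CB", target)
        for i in range(len(frag) - 1):
            d_in = np.linalg.norm(frag.coords[i]["C"] - frag.coords[i + 1]["N"])
            d_out = np.linalg.norm(out.coords[i]["C"] - out.coords[i + 1]["N"])
            assert abs(d_out - d_in) / d_in < 0.10
        for i in range(len(frag)):
            for a, b in (("N", "CA"), ("CA", "C"), ("C", "O")):
                d_in = np.linalg.norm(frag.coords[i][a] - frag.coords[i][b])
                d_out = np.linalg.norm(out.coords[i][a] - out.coords[i][b])
                assert abs(d_out - d_in) < 1e-9  # dihedral moves are rigid


class TestEnumerateBackbones:
    def _tensor(self):
        return AnisoTensor(np.diag([0.16, 0.09, 0.04]))

    def test_loop_residue_yields_35_candidates(self, loop_chain, centroids):
        frag = fragment_around(loop_chain, "A", 4, 3)
        cands = enumerate_backbones(frag, True, self._tensor(),
                                    SamplerConfig(seed=0), centroids, rng=0)
        assert len(cands) == 35
        flips = {c.flip_state for c in cands}
        assert flips == {"none", "tweaked_down", "simple_down", "left", "right"}

    def test_flip_suppression_yields_7(self, loop_chain, centroids):
        frag = fragment_around(loop_chain, "A", 4, 3)
        cands = enumerate_backbones(frag, False, self._tensor(),
                                    SamplerConfig(seed=0), centroids, rng=0)
        assert len(cands) == 7
        assert all(c.flip_state == "none" for c in cands)

    def test_glycine_uses_backbone_O_guide(self, centroids):
        model = build_backbone_chain(["ALA"] * 3 + ["GLY"] + ["ALA"] * 3,
                                     [(-80.0, 130.0)] * 7)
        frag = fragment_around(model, "A", 4, 3)
        assert frag.guide_atom == "O"
        cands = enumerate_backbones(frag, True, self._tensor(),
                                    SamplerConfig(seed=0), centroids, rng=0)
        assert len(cands) == 35

    def test_identity_candidate_always_present(self, loop_chain, centroids):
        frag = fragment_around(loop_chain, "A", 4, 3)
        cands = enumerate_backbones(frag, True, self._tensor(),
                                    SamplerConfig(seed=0), centroids, rng=0)
        identity = [c for c in cands
                    if c.flip_state == "none" and c.displacement == "none"]
        assert len(identity) == 1
        assert frag.backbone_rmsd(identity[0].fragment) == 0.0

    def test_chain_terminal_residue_identity_only(self, loop_chain, centroids):
        frag = fragment_around(loop_chain, "A", 1, 3)
        cands = enumerate_backbones(frag, True, self._tensor(),
                                    SamplerConfig(seed=0), centroids, rng=0)
        assert len(cands) == 1

    def test_helix_detected_and_suppresses_flips(self, helix_chain, loop_chain):
        ss = secondary_structure(helix_chain)
        inner = [ss[("A", i, "")] for i in range(3, 8)]
        assert all(s == "H" for s in inner)
        ss_loop = secondary_structure(loop_chain)
        assert all(v != "H" for v in ss_loop.values())


class TestSidechainDecoration:
    def _one_backbone(self, loop_chain):
        frag = fragment_around(loop_chain, "A", 4, 3)
        return [BackboneCandidate(frag)]

    def test_ser_candidate_count_525_over_35_backbones(self, loop_chain,
                                                       centroids, library):
        frag = fragment_around(loop_chain, "A", 4, 3)
        backbones = enumerate_backbones(
            frag, True, AnisoTensor(np.diag([0.09, 0.04, 0.01])),
            SamplerConfig(seed=0), centroids, rng=0)
        assert len(backbones) == 35
        cands = decorate_small_sidechain(backbones, "SER", library)
        # 3 rotamers x 5 offsets x 35 backbones (minus any clash-filtered)
        assert len(cands) == 3 * 5 * 35

    def test_small_offsets_are_exact_grid(self, loop_chain, library):
        cands = decorate_small_sidechain(self._one_backbone(loop_chain),
                                         "SER", library)
        p_rot = [e for e in library if e.residue == "SER" and e.name == "p"][0]
        offs = sorted(round(float(_wrap(c.chi[0] - p_rot.chi[0])), 6)
                      for c in cands if c.rotamer == "p")
        assert offs == sorted(SMALL_OFFSETS)

    def test_built_chi_equals_rotamer_plus_offset(self, loop_chain, library):
        cands = decorate_small_sidechain(self._one_backbone(loop_chain),
                                         "LEU", library)
        for c in cands[:10]:
            pos = c.positions()
            built = sidechain_chis("LEU", pos)
            assert np.allclose(_wrap(np.array(built) - np.array(c.chi)), 0.0,
                               atol=1e-6)

    def test_large_offsets_are_12_values_in_50_degree_window(self):
        assert len(LARGE_OFFSETS) == 12
        assert LARGE_OFFSETS[0] == -25.0
        assert LARGE_OFFSETS[-1] == pytest.approx(24.5)
        assert np.allclose(np.diff(LARGE_OFFSETS), 4.5)

    def test_hierarchical_counts_with_keep_all(self, loop_chain):
        # 2 rotamers, 4-chi residue, keep-all selection: 2*12 at level 1,
        # then x12 per level
        from altconf.model import RotamerEntry

        lib = [RotamerEntry("ARG", "a", (-67.0, 177.0, 180.0, 180.0)),
               RotamerEntry("ARG", "b", (-177.0, 177.0, 180.0, 180.0))]
        seen = []

        def keep_all(cands, level):
            seen.append(len(cands))
            return range(len(cands))

        out = decorate_large_sidechain(self._one_backbone(loop_chain), "ARG",
                                       lib, keep_all)
        assert seen[0] <= 2 * 12
        for prev, nxt in zip(seen, seen[1:]):
            assert nxt <= prev * 12
        assert len(out) == seen[-1]

    def test_large_residue_hierarchy_converges_with_select(self, loop_chain,
                                                           library):
        def keep_best_two(cands, level):
            return range(min(2, len(cands)))

        out = decorate_large_sidechain(self._one_backbone(loop_chain), "GLU",
                                       library, keep_best_two)
        assert 1 <= len(out) <= 2 * 12
        for c in out:
            assert len(c.chi) == len(CHI_ATOMS["GLU"])
            names = {n for n, _, _ in c.sidechain}
            assert {"CB", "CG", "CD", "OE1", "OE2"} <= names

    def test_ala_and_gly_decorate_trivially(self, loop_chain, library):
        bb = self._one_backbone(loop_chain)
        ala = decorate(bb, "ALA", library)
        assert len(ala) == 1 and [n for n, _, _ in ala[0].sidechain] == ["CB"]
        gly = decorate(bb, "GLY", library)
        assert len(gly) == 1 and gly[0].sidechain == []

    def test_candidate_count_closed_forms(self, loop_chain, library):
        bb = self._one_backbone(loop_chain)
        for res in ("SER", "CYS", "THR", "VAL"):
            cands = decorate_small_sidechain(bb, res, library)
            n_rot = len([e for e in library if e.residue == res])
            assert len(cands) == n_rot * 5
        ile = decorate_small_sidechain(bb, "ILE", library)
        n_rot = len([e for e in library if e.residue == "ILE"])
        assert len(ile) <= n_rot * 25
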