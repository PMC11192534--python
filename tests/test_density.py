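"""Forward density model, synthetic-map generator, and map I/O."""

import math

import gemmi
import numpy as np
import pytest

import mcbuild as mc
from mcbuild.density import DensityMap, density_columns, resolution_blur_b
from mcbuild.structure import Atom, Conformer


def carbon_grid(spacing=0.25, half=6.0, resolution=1.0, mode="xray"):
    n = int(2 * half / spacing)
    geom = DensityMap(
        np.zeros((n, n, n)), origin=[-half] * 3, spacing=spacing,
        resolution=resolution, mode=mode,
    )
    atom = Atom("C", "C", [0.0, 0.0, 0.0], b_iso=15.0)
    return geom, Conformer("ALA", [atom])


class TestForwardModel:
    def test_zero_weight_gives_zero_density(self):
        geom, conf = carbon_grid()
        rho = mc.compute_density([conf], geom, weights=[0.0], with_background=False)
        assert np.all(rho == 0.0)

    def test_linearity_in_weight(self):
        geom, conf = carbon_grid()
        rho1 = mc.compute_density([conf], geom, weights=[1.0], with_background=False)
        rho2 = mc.compute_density([conf], geom, weights=[2.0], with_background=False)
        assert np.allclose(rho2, 2.0 * rho1)

    def test_carbon_integral_matches_scattering_sum(self):
        """Analytic Gaussian integral: sum(rho)*voxvol == total scattering."""
        geom, conf = carbon_grid()
        rho = mc.compute_density([conf], geom, with_background=False)
        it = gemmi.Element("C").it92
        expected = sum(it.a) + it.c
        assert rho.sum() * geom.voxel_volume == pytest.approx(expected, rel=0.02)

    def test_em_mode_uses_electron_factors(self):
        geom, conf = carbon_grid(mode="em")
        rho = mc.compute_density([conf], geom, with_background=False, mode="em")
        expected = sum(gemmi.Element("C").c4322.a)
        assert rho.sum() * geom.voxel_volume == pytest.approx(expected, rel=0.02)

    def test_background_only_in_xray_mode(self):
        geom, conf = carbon_grid()
        far_corner = (0, 0, 0)  # ~10 A from the atom, outside any mask
        center = tuple(s // 2 for s in geom.shape)
        x = mc.compute_density([conf], geom, weights=[0.0], with_background=True)
        assert x[far_corner] == 0.0
        assert x[center] == pytest.approx(0.3)
        e = mc.compute_density(
            [conf], geom, weights=[0.0], mode="em", with_background=None
        )
        assert np.all(e == 0.0)

    def test_unknown_element_rejected(self):
        geom, _ = carbon_grid()
        bad = Conformer("ALA", [Atom("XX", "Xx", [0, 0, 0])])
        with pytest.raises(ValueError, match="element"):
            mc.compute_density([bad], geom, with_background=False)

    def test_density_columns_match_full_grid(self):
        geom, conf = carbon_grid()
        other = conf.copy()
        other.atoms[0].pos = np.array([1.5, 0.0, 0.0])
        cols, active = density_columns([conf, other], geom)
        full0 = mc.compute_density([conf], geom, with_background=False).ravel()
        full1 = mc.compute_density([other], geom, with_background=False).ravel()
        assert np.allclose(cols[:, 0], full0[active])
        assert np.allclose(cols[:, 1], full1[active])
        # the active set covers everything nonzero
        assert full0[np.setdiff1d(np.arange(full0.size), active)].max() == 0.0


class TestSubgrid:
    def test_values_preserved_index_by_index(self, tripeptide):
        spec = mc.SyntheticSpec(target_resolution=1.5, seed=0)
        dmap, ref = mc.make_synthetic_map(tripeptide, spec)
        sub = mc.extract_residue_subgrid(dmap, ref.residues[1], padding=3.0)
        i0 = np.round((sub.origin - dmap.origin) / dmap.spacing).astype(int)
        sl = tuple(slice(i0[d], i0[d] + sub.shape[d]) for d in range(3))
        assert np.array_equal(sub.values, dmap.values[sl])
        assert sub.spacing == dmap.spacing

    def test_clipped_at_map_edge(self, tripeptide):
        spec = mc.SyntheticSpec(target_resolution=1.5, seed=0)
        dmap, ref = mc.make_synthetic_map(tripeptide, spec)
        sub = mc.extract_residue_subgrid(dmap, ref.residues[0], padding=50.0)
        assert sub.shape == dmap.shape  # clipped, no wrap

    def test_residue_outside_map_rejected(self, tripeptide):
        geom = DensityMap(
            np.zeros((8, 8, 8)), origin=[500.0, 500, 500], spacing=0.5,
            resolution=2.0,
        )
        with pytest.raises(ValueError, match="outside"):
            mc.extract_residue_subgrid(geom, tripeptide.residues[0])


class TestShakeAndInflate:
    def test_zero_rmse_identity(self, tripeptide):
        shaken = mc.shake_coordinates(tripeptide, 0.0, seed=1)
        for r0, r1 in zip(tripeptide.residues, shaken.residues):
            assert np.allclose(r0.conformers[0].coords, r1.conformers[0].coords)

    def test_rms_displacement_matches_request(self):
        """Monte Carlo: over ~1e4 atoms the RMS shift is within 5% of rmse."""
        big = mc.build_ideal_peptide(["ALA"] * 40)
        atoms0 = np.array([a.pos for a in big.all_atoms()])
        reps = []
        for seed in range(50):
            shaken = mc.shake_coordinates(big, 0.4, seed=seed)
            atoms1 = np.array([a.pos for a in shaken.all_atoms()])
            reps.append(np.sum((atoms1 - atoms0) ** 2, axis=1))
        rms = math.sqrt(np.mean(np.concatenate(reps)))
        assert rms == pytest.approx(0.4, rel=0.05)

    def test_negative_rmse_rejected(self, tripeptide):
        with pytest.raises(ValueError):
            mc.shake_coordinates(tripeptide, -0.1, seed=0)

    @pytest.mark.parametrize(
        "base,target,delta",
        [(0.8, 0.8, 0.0), (0.8, 1.8, 10.0), (0.77, 3.0, 22.3)],
    )
    def test_bfactor_inflation_rule(self, tripeptide, base, target, delta):
        inflated = mc.inflate_bfactors(tripeptide, base, target)
        b0 = tripeptide.all_atoms()[0].b_iso
        for atom in inflated.all_atoms():
            assert atom.b_iso == pytest.approx(b0 + delta, abs=1e-9)

    def test_inflation_target_below_base_rejected(self, tripeptide):
        with pytest.raises(ValueError):
            mc.inflate_bfactors(tripeptide, 2.0, 1.0)


@pytest.fixture(scope="module")
def sf(tripeptide):
    return mc.compute_structure_factors(tripeptide, d_min=2.0, mode="em")


class TestStructureFactors:

    def test_dc_term_equals_density_sum(self, tripeptide, sf):
        spacing = 2.0 / 4.0
        from mcbuild.density import _p1_box

        origin, shape = _p1_box(tripeptide, 10.0, spacing)
        geom = DensityMap(np.zeros(shape), origin, spacing, 2.0, "em")
        confs = [c for r in tripeptide.residues for c in r.conformers]
        rho = mc.compute_density(confs, geom, mode="em", with_background=False)
        dc = sf.amplitude[np.all(sf.hkl == 0, axis=1)][0]
        assert dc == pytest.approx(rho.sum() * geom.voxel_volume, rel=0.01)

    def test_translation_changes_phases_not_amplitudes(self, tripeptide, sf):
        moved = tripeptide.copy()
        for atom in moved.all_atoms():
            atom.pos = atom.pos + np.array([1.0, 0.0, 0.0])
        # same box: translate origin back so the grid is identical
        sf2 = mc.compute_structure_factors(moved, d_min=2.0, mode="em")
        assert np.allclose(sf2.amplitude, sf.amplitude, rtol=1e-6, atol=1e-9)

    def test_halving_occupancies_halves_amplitudes(self, tripeptide, sf):
        half = tripeptide.copy()
        for res in half.residues:
            for conf in res.conformers:
                conf.set_occupancy(0.5)
        sf2 = mc.compute_structure_factors(half, d_min=2.0, mode="em")
        assert np.allclose(sf2.amplitude, 0.5 * sf.amplitude, atol=1e-9)

    def test_resolution_cutoff_respected(self, sf):
        inv_d = np.sqrt(np.sum((sf.hkl / sf.cell) ** 2, axis=1))
        assert np.all(inv_d <= 1.0 / sf.d_min + 1e-9)


class TestAmplitudeNoise:
    def test_zero_scale_identity(self, tripeptide):
        sf = mc.compute_structure_factors(tripeptide, d_min=2.5)
        noisy = mc.add_structure_factor_noise(sf, 2.5, 0.0, seed=4)
        assert np.array_equal(noisy.amplitude, sf.amplitude)
        assert np.array_equal(noisy.phase, sf.phase)

    def test_zero_amplitude_stays_zero(self):
        sf = mc.StructureFactors(
            hkl=np.array([[1, 0, 0]]), amplitude=np.array([0.0]),
            phase=np.array([0.3]), d_min=2.0, cell=np.array([10.0, 10, 10]),
            grid_shape=(10, 10, 10),
        )
        noisy = mc.add_structure_factor_noise(sf, 2.0, 0.5, seed=0)
        assert noisy.amplitude[0] == 0.0

    def test_noise_moments_match_formula(self):
        """F=100, d=2.0, scale 0.5: mean stays 100, SD = sqrt(100)*1.0 = 10."""
        n = 100_000
        sf = mc.StructureFactors(
            hkl=np.zeros((n, 3), dtype=int), amplitude=np.full(n, 100.0),
            phase=np.zeros(n), d_min=2.0, cell=np.array([50.0, 50, 50]),
            grid_shape=(2, 2, 2),
        )
        noisy = mc.add_structure_factor_noise(sf, 2.0, 0.5, seed=11)
        assert noisy.amplitude.mean() == pytest.approx(100.0, rel=0.01)
        assert noisy.amplitude.std() == pytest.approx(10.0, rel=0.05)

    def test_deterministic_per_seed(self, tripeptide):
        sf = mc.compute_structure_factors(tripeptide, d_min=2.5)
        a = mc.add_structure_factor_noise(sf, 2.5, 0.5, seed=7)
        b = mc.add_structure_factor_noise(sf, 2.5, 0.5, seed=7)
        assert np.array_equal(a.amplitude, b.amplitude)


class TestSyntheticMap:
    def test_noise_free_map_matches_forward_density(self, tripeptide):
        """Band-limited inversion reproduces the smooth forward model."""
        spec = mc.SyntheticSpec(
            target_resolution=1.5, shake_scale=0.0, noise_scale=0.0, seed=0,
            mode="em",
        )
        dmap, ref = mc.make_synthetic_map(tripeptide, spec)
        confs = [c for r in ref.residues for c in r.conformers]
        direct = mc.compute_density(confs, dmap)
        corr = np.corrcoef(direct.ravel(), dmap.values.ravel())[0, 1]
        assert corr > 0.999

    def test_noise_free_xray_map_close_despite_mask_edges(self, tripeptide):
        spec = mc.SyntheticSpec(
            target_resolution=1.5, shake_scale=0.0, noise_scale=0.0, seed=0
        )
        dmap, ref = mc.make_synthetic_map(tripeptide, spec)
        confs = [c for r in ref.residues for c in r.conformers]
        direct = mc.compute_density(confs, dmap)
        assert np.corrcoef(direct.ravel(), dmap.values.ravel())[0, 1] > 0.99

    def test_deterministic_per_seed(self, tripeptide):
        spec = mc.SyntheticSpec(target_resolution=2.0, seed=5)
        m1, _ = mc.make_synthetic_map(tripeptide, spec)
        m2, _ = mc.make_synthetic_map(tripeptide, spec)
        assert np.array_equal(m1.values, m2.values)

    def test_reference_keeps_unshaken_coordinates(self, tripeptide):
        spec = mc.SyntheticSpec(target_resolution=2.0, seed=5)
        _, ref = mc.make_synthetic_map(tripeptide, spec)
        for r0, r1 in zip(tripeptide.residues, ref.residues):
            assert np.allclose(r0.conformers[0].coords, r1.conformers[0].coords)
            # but B was inflated: (2.0 - 0.8) / 0.1 = 12 A^2
            assert r1.conformers[0].atoms[0].b_iso == pytest.approx(
                r0.conformers[0].atoms[0].b_iso + 12.0
            )


class TestMapIO:
    def test_round_trip_float32(self, tmp_path, tripeptide):
        spec = mc.SyntheticSpec(target_resolution=2.0, seed=2)
        dmap, _ = mc.make_synthetic_map(tripeptide, spec)
        path = tmp_path / "m.ccp4"
        mc.write_map(dmap, path)
        back = mc.read_map(path, resolution=2.0)
        assert np.allclose(back.values, dmap.values.astype(np.float32))
        assert np.allclose(back.origin, dmap.origin, atol=1e-4)
        assert back.spacing == pytest.approx(dmap.spacing, abs=1e-6)

    def test_permuted_axis_order_normalized(self, tmp_path):
        """A map stored with Z as the fast axis is re-indexed to X,Y,Z."""
        rng = np.random.default_rng(0)
        values = rng.normal(size=(6, 8, 10))
        path = str(tmp_path / "perm.ccp4")
        arr_t = np.ascontiguousarray(values.transpose(2, 1, 0), dtype=np.float32)
        grid = gemmi.FloatGrid(*arr_t.shape)
        np.asarray(grid)[...] = arr_t
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        m.set_header_i32(17, 3)  # MAPC = Z
        m.set_header_i32(18, 2)  # MAPR = Y
        m.set_header_i32(19, 1)  # MAPS = X
        m.set_header_float(11, 3.0)  # cell along crystal X,Y,Z
        m.set_header_float(12, 4.0)
        m.set_header_float(13, 5.0)
        m.set_header_i32(8, 6)  # sampling along X,Y,Z
        m.set_header_i32(9, 8)
        m.set_header_i32(10, 10)
        m.write_ccp4_map(path)
        back = mc.read_map(path, resolution=2.0)
        assert back.values.shape == (6, 8, 10)
        assert np.allclose(back.values, values.astype(np.float32))

    def test_unsupported_mode_word_rejected(self, tmp_path):
        ref = DensityMap(np.zeros((4, 4, 4)), [0, 0, 0], 0.5, 2.0)
        path = tmp_path / "m.ccp4"
        mc.write_map(ref, path)
        m = gemmi.read_ccp4_map(str(path))
        m.set_header_i32(4, 1)
        m.write_ccp4_map(str(path))
        with pytest.raises(ValueError, match="mode"):
            mc.read_map(path, resolution=2.0)

    def test_anisotropic_voxels_rejected(self, tmp_path):
        ref = DensityMap(np.zeros((4, 4, 4)), [0, 0, 0], 0.5, 2.0)
        path = tmp_path / "m.ccp4"
        mc.write_map(ref, path)
        m = gemmi.read_ccp4_map(str(path))
        m.set_header_float(11, 5.0)  # stretch the cell along a only
        m.write_ccp4_map(str(path))
        with pytest.raises(ValueError, match="spacing mismatch"):
            mc.read_map(path, resolution=2.0)
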