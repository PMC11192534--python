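"""Candidate enumeration: counts, geometry preservation, pruning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mcbuild as mc
from mcbuild.geometry import bond_angle, dihedral
from mcbuild.sampling import (
    SamplingConfig,
    measure_chi,
    sample_proline_pucker,
    set_chi,
)
from mcbuild.structure import conformer_rmsd


@pytest.fixture(scope="module")
def peptide():
    return mc.build_ideal_peptide(["GLY", "SER", "TYR", "LEU", "PRO", "ALA"])


def _pairwise_distances(conf):
    c = conf.coords
    return np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)


class TestBackbone:
    def test_zero_amplitude_identity_only(self, peptide):
        cfg = SamplingConfig(bb_amplitude=0.0)
        out = mc.sample_backbone(peptide.get("A", 2), cfg)
        assert len(out) == 1

    def test_default_count_is_nineteen(self, peptide):
        """3 axes x 3 magnitudes x 2 signs + identity."""
        out = mc.sample_backbone(peptide.get("A", 2), SamplingConfig())
        assert len(out) == 19
        coords = np.array([c.coords for c in out])
        assert len({tuple(np.round(c.ravel(), 6)) for c in coords}) == 19

    def test_translations_preserve_internal_geometry(self, peptide):
        ref = peptide.get("A", 3).conformers[0]
        d0 = _pairwise_distances(ref)
        for cand in mc.sample_backbone(peptide.get("A", 3), SamplingConfig()):
            assert np.allclose(_pairwise_distances(cand), d0, atol=1e-9)

    def test_glycine_uses_virtual_cbeta_axes(self, peptide):
        out = mc.sample_backbone(peptide.get("A", 1), SamplingConfig())
        assert len(out) == 19

    def test_anisotropic_cbeta_guides_axes(self, peptide):
        res = peptide.get("A", 2).copy()
        cb = res.conformers[0].atom("CB")
        cb.u_aniso = np.diag([0.4, 0.1, 0.1])  # principal axis along x
        out = mc.sample_backbone(res, SamplingConfig())
        shifts = [c.atom("CA").pos - res.conformers[0].atom("CA").pos for c in out[1:]]
        # one third of the displacements must be along the x eigenvector
        along_x = sum(
            1 for s in shifts if abs(abs(s / np.linalg.norm(s)) @ [1, 0, 0] - 1) < 1e-9
        )
        assert along_x == 6

    def test_missing_backbone_atom_rejected(self, peptide):
        res = peptide.get("A", 2).copy()
        res.conformers[0].atoms = [
            a for a in res.conformers[0].atoms if a.name != "O"
        ]
        with pytest.raises(ValueError, match="backbone"):
            mc.sample_backbone(res, SamplingConfig())


class TestAromaticAngle:
    def test_five_conformations_for_tyr(self, peptide):
        conf = peptide.get("A", 3).conformers[0]
        out = mc.sample_aromatic_angle(conf, SamplingConfig())
        assert len(out) == 5

    def test_non_aromatic_returned_unchanged(self, peptide):
        conf = peptide.get("A", 4).conformers[0]  # LEU
        out = mc.sample_aromatic_angle(conf, SamplingConfig())
        assert len(out) == 1 and out[0] is conf

    def test_angle_offsets_applied_exactly(self, peptide):
        conf = peptide.get("A", 3).conformers[0]
        base = bond_angle(
            conf.atom("CA").pos, conf.atom("CB").pos, conf.atom("CG").pos
        )
        out = mc.sample_aromatic_angle(conf, SamplingConfig())
        measured = sorted(
            bond_angle(c.atom("CA").pos, c.atom("CB").pos, c.atom("CG").pos)
            for c in out
        )
        expected = sorted(base + off for off in (-7.5, -3.75, 0.0, 3.75, 7.5))
        assert np.allclose(measured, expected, atol=1e-6)

    def test_ring_geometry_rigid(self, peptide):
        conf = peptide.get("A", 3).conformers[0]
        ring = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"]
        d0 = np.linalg.norm(conf.atom("CZ").pos - conf.atom("CG").pos)
        for cand in mc.sample_aromatic_angle(conf, SamplingConfig()):
            assert np.linalg.norm(
                cand.atom("CZ").pos - cand.atom("CG").pos
            ) == pytest.approx(d0, abs=1e-9)


class TestChiSweep:
    def test_count_three_rotamers_times_nine(self, peptide, library):
        conf = peptide.get("A", 2).conformers[0]  # SER: 3 rotamers
        out = mc.sample_chi([conf], 1, library, SamplingConfig())
        assert len(out) == 3 * 9

    def test_gly_ala_no_chi(self, peptide, library):
        assert mc.sample_chi(
            [peptide.get("A", 6).conformers[0]], 1, library, SamplingConfig()
        ) == []

    def test_chi_values_hit_targets(self, peptide, library):
        """Measured chi equals mode + offset via the independent four-atom
        signed-angle formula."""
        conf = peptide.get("A", 2).conformers[0]
        out = mc.sample_chi([conf], 1, library, SamplingConfig())
        expected = sorted(
            (m + off + 180) % 360 - 180
            for _, m in library.modal_values("SER", 1)
            for off in range(-24, 25, 6)
        )
        measured = sorted(
            dihedral(
                c.atom("N").pos, c.atom("CA").pos, c.atom("CB").pos, c.atom("OG").pos
            )
            for c in out
        )
        assert np.allclose(measured, expected, atol=1e-6)

    def test_chi_index_beyond_count_rejected(self, peptide, library):
        with pytest.raises(IndexError):
            mc.sample_chi(
                [peptide.get("A", 2).conformers[0]], 2, library, SamplingConfig()
            )

    def test_untouched_geometry_preserved(self, peptide, library):
        conf = peptide.get("A", 4).conformers[0]  # LEU
        for cand in mc.sample_chi([conf], 2, library, SamplingConfig()):
            # chi2 rotation must not move CB-CG bond length or chi1
            assert np.linalg.norm(
                cand.atom("CG").pos - cand.atom("CB").pos
            ) == pytest.approx(
                np.linalg.norm(conf.atom("CG").pos - conf.atom("CB").pos), abs=1e-9
            )
            assert measure_chi(cand, 1) == pytest.approx(
                measure_chi(conf, 1), abs=1e-6
            )


class TestProlinePucker:
    def test_candidate_count_and_closure(self, peptide):
        conf = peptide.get("A", 5).conformers[0]
        out = sample_proline_pucker(conf, SamplingConfig())
        assert 0 < len(out) <= 18
        for cand in out:
            d = np.linalg.norm(cand.atom("CD").pos - cand.atom("N").pos)
            assert abs(d - 1.474) <= 0.1

    def test_both_pucker_families_present(self, peptide):
        conf = peptide.get("A", 5).conformers[0]
        out = sample_proline_pucker(conf, SamplingConfig())
        signs = {np.sign(measure_chi(c, 1)) for c in out}
        assert signs == {-1.0, 1.0}

    def test_non_proline_rejected(self, peptide):
        with pytest.raises(ValueError):
            sample_proline_pucker(peptide.get("A", 2).conformers[0], SamplingConfig())


class TestPrune:
    def test_duplicates_deduplicated(self, peptide):
        conf = peptide.get("A", 2).conformers[0]
        out = mc.prune_candidates([conf.copy(), conf.copy()], SamplingConfig())
        assert len(out) == 1

    def test_self_clash_removed(self, peptide):
        conf = peptide.get("A", 2).conformers[0].copy()
        conf.atom("OG").pos = conf.atom("N").pos + np.array([0.5, 0.0, 0.0])
        out = mc.prune_candidates([conf], SamplingConfig())
        assert out == []

    def test_survivors_pairwise_distinct(self, peptide, library):
        """Brute-force check: every surviving pair is >= the redundancy RMSD."""
        cfg = SamplingConfig(chi_step=0.002, chi_range=0.008)
        conf = peptide.get("A", 2).conformers[0]
        cands = mc.sample_chi([conf], 1, library, cfg)
        out = mc.prune_candidates(cands, cfg)
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert conformer_rmsd(out[i], out[j]) >= cfg.redundancy_rmsd

    def test_idempotent(self, peptide, library):
        cfg = SamplingConfig()
        cands = mc.sample_chi(
            [peptide.get("A", 2).conformers[0]], 1, library, cfg
        )
        once = mc.prune_candidates(cands, cfg)
        twice = mc.prune_candidates(once, cfg)
        assert len(once) == len(twice)


class TestBFactors:
    def test_default_six_variants(self, peptide):
        conf = peptide.get("A", 2).conformers[0]
        out, parents = mc.sample_bfactors([conf], SamplingConfig())
        assert len(out) == 6
        assert parents == [0] * 6
        ratios = sorted(a.atoms[0].b_iso / conf.atoms[0].b_iso for a in out)
        assert np.allclose(ratios, [0.5, 0.7, 0.9, 1.1, 1.3, 1.5])

    def test_coordinates_untouched(self, peptide):
        confs = [peptide.get("A", i).conformers[0] for i in (1, 2, 3)]
        out, parents = mc.sample_bfactors(confs, SamplingConfig())
        assert len(out) == 18
        for variant, parent in zip(out, parents):
            assert np.array_equal(variant.coords, confs[parent].coords)

    def test_identity_multiplier_when_configured(self, peptide):
        cfg = SamplingConfig(b_multipliers=(1.0,))
        conf = peptide.get("A", 2).conformers[0]
        out, _ = mc.sample_bfactors([conf], cfg)
        assert out[0].atoms[0].b_iso == conf.atoms[0].b_iso

    def test_non_positive_multiplier_rejected(self, peptide):
        cfg = SamplingConfig(b_multipliers=(0.5, -1.0))
        with pytest.raises(ValueError):
            mc.sample_bfactors([peptide.get("A", 2).conformers[0]], cfg)


class TestSetChi:
    @settings(max_examples=25, deadline=None)
    @given(target=st.floats(min_value=-179.9, max_value=180.0))
    def test_set_then_measure_round_trip(self, target):
        pep = mc.build_ideal_peptide(["ALA", "MET", "ALA"])
        conf = pep.get("A", 2).conformers[0]
        for chi_index in (1, 2, 3):
            set_chi(conf, chi_index, target)
            assert measure_chi(conf, chi_index) == pytest.approx(target, abs=1e-6)
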