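"""Segment identification, assembly, altloc relabeling, expansion."""

import itertools
import warnings

import numpy as np
import pytest

import mcbuild as mc
from mcbuild.segments import (
    Segment,
    _pair_clashes,
    find_segments,
    occupancy_groups,
    relabel_altlocs,
    segment_only_expand,
)
from mcbuild.structure import StructureModel


def shift_conformer(conf, dx, altloc="", occ=1.0):
    new = conf.copy()
    for atom in new.atoms:
        atom.pos = atom.pos + np.array([dx, 0.0, 0.0])
    new.altloc = altloc
    new.set_occupancy(occ)
    return new


def make_multibackbone(model, seq_ids, dx=0.2):
    """Give listed residues two backbone-shifted conformers (0.5/0.5)."""
    out = model.copy()
    for seq_id in seq_ids:
        res = out.get("A", seq_id)
        base = res.conformers[0]
        a = shift_conformer(base, 0.0, "A", 0.5)
        b = shift_conformer(base, dx, "B", 0.5)
        res.conformers = [a, b]
    return out


@pytest.fixture(scope="module")
def hexapeptide():
    return mc.build_ideal_peptide(["ALA"] * 6)


class TestFindSegments:
    def test_all_single_gives_empty(self, hexapeptide):
        assert find_segments(hexapeptide) == []

    def test_pattern_s_mm_s_m_s(self, hexapeptide):
        model = make_multibackbone(hexapeptide, [2, 3, 5])
        segments = find_segments(model)
        assert [[r.seq_id for r in s.residues] for s in segments] == [[2, 3], [5]]

    def test_two_adjacent_multibackbone_one_segment(self, hexapeptide):
        model = make_multibackbone(hexapeptide, [3, 4])
        segments = find_segments(model)
        assert len(segments) == 1
        assert len(segments[0]) == 2
        combos = list(
            itertools.product(*(r.conformers for r in segments[0].residues))
        )
        assert len(combos) == 4

    def test_same_backbone_multi_sidechain_is_delimiter(self):
        pep = mc.build_ideal_peptide(["ALA", "SER", "ALA"])
        res = pep.get("A", 2)
        a = res.conformers[0].copy()
        b = res.conformers[0].copy()
        from mcbuild.sampling import set_chi

        set_chi(b, 1, -65.0)  # side chain moves, backbone identical
        a.altloc, b.altloc = "A", "B"
        a.set_occupancy(0.5)
        b.set_occupancy(0.5)
        res.conformers = [a, b]
        assert find_segments(pep) == []

    def test_segments_disjoint_and_ordered(self, hexapeptide):
        model = make_multibackbone(hexapeptide, [1, 2, 4, 5, 6])
        segments = find_segments(model)
        seen = [r.seq_id for s in segments for r in s.residues]
        assert seen == sorted(set(seen))


class TestAssembleSegment:
    def test_coupled_backbone_recovery(self):
        """A 2-residue segment with coupled A/B backbones at 0.6/0.4 comes
        back with shared occupancies within 0.1 of truth."""
        pep = mc.build_ideal_peptide(["ALA", "ALA", "ALA", "ALA"])
        truth = pep.copy()
        for seq_id in (2, 3):
            res = truth.get("A", seq_id)
            base = res.conformers[0]
            res.conformers = [
                shift_conformer(base, 0.0, "A", 0.6),
                shift_conformer(base, 0.7, "B", 0.4),
            ]
        dmap, ref = mc.make_synthetic_map(
            truth, mc.SyntheticSpec(target_resolution=1.0, seed=2,
                                    shake_scale=0.05, noise_scale=0.2)
        )
        segment = find_segments(ref)[0]
        context = [
            c
            for r in ref.residues
            if r.seq_id in (1, 4)
            for c in r.conformers
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assembled = mc.assemble_segment(
                segment, dmap, mc.SamplingConfig(), context=context
            )
        for res in assembled.residues:
            assert len(res.conformers) == 2
            occs = sorted(c.occupancy for c in res.conformers)
            assert occs[1] == pytest.approx(0.6, abs=0.1)
        # backbone-connected conformers share occupancy exactly
        r2, r3 = assembled.residues
        for c2, c3 in zip(r2.conformers, r3.conformers):
            assert c2.occupancy == pytest.approx(c3.occupancy, abs=1e-6)

    def test_single_residue_segment_reduces_to_residue_pass(self):
        pep = mc.build_ideal_peptide(["ALA", "ALA", "ALA"])
        truth = pep.copy()
        res = truth.get("A", 2)
        base = res.conformers[0]
        res.conformers = [
            shift_conformer(base, 0.0, "A", 0.7),
            shift_conformer(base, 0.8, "B", 0.3),
        ]
        dmap, ref = mc.make_synthetic_map(
            truth, mc.SyntheticSpec(target_resolution=1.0, seed=4,
                                    shake_scale=0.0, noise_scale=0.0)
        )
        segment = find_segments(ref)[0]
        assert len(segment) == 1
        context = [
            c for r in ref.residues if r.seq_id != 2 for c in r.conformers
        ]
        assembled = mc.assemble_segment(
            segment, dmap, mc.SamplingConfig(), context=context
        )
        occs = sorted(c.occupancy for c in assembled.residues[0].conformers)
        assert occs == pytest.approx([0.3, 0.7], abs=0.05)

    def test_occupancy_sums_bounded(self):
        pep = mc.build_ideal_peptide(["ALA", "ALA", "ALA"])
        model = make_multibackbone(pep, [2])
        dmap, ref = mc.make_synthetic_map(
            model, mc.SyntheticSpec(target_resolution=1.5, seed=0)
        )
        segment = find_segments(ref)[0]
        assembled = mc.assemble_segment(segment, dmap, mc.SamplingConfig())
        for res in assembled.residues:
            assert res.occupancy_sum <= 1.0 + 1e-6


class TestRelabel:
    def _clashing_pair(self):
        """Two Ser residues 8 A apart whose inward-pointing conformers clash
        when they share a letter; swapping one residue's labels is clash-free."""
        pep = mc.build_ideal_peptide(["SER"])
        base1 = pep.get("A", 1).conformers[0]
        base2 = base1.copy()
        for atom in base2.atoms:
            atom.pos = atom.pos + np.array([8.0, 0.0, 0.0])

        def with_sidechain(base, cb, og, altloc):
            conf = base.copy()
            conf.atom("CB").pos = np.array(cb, float)
            conf.atom("OG").pos = np.array(og, float)
            conf.altloc = altloc
            conf.set_occupancy(0.5)
            return conf

        r1 = mc.ResidueModel(
            "A",
            1,
            [
                with_sidechain(base1, base1.atom("CB").pos, base1.atom("OG").pos, "A"),
                with_sidechain(base1, [3.4, 0, 0], [4.1, 0, 0], "B"),
            ],
        )
        r2 = mc.ResidueModel(
            "A",
            3,
            [
                with_sidechain(base2, base2.atom("CB").pos, base2.atom("OG").pos, "A"),
                # inward conformer shares letter B with residue 1's inward one
                with_sidechain(base2, [5.9, 0, 0], [5.2, 0, 0], "B"),
            ],
        )
        return StructureModel([r1, r2])

    def test_swap_relieves_clash(self):
        model = self._clashing_pair()
        r1 = model.get("A", 1)
        r3 = model.get("A", 3)
        assert _pair_clashes(r1.conformers[1], r3.conformers[1], False, 0.75) > 0
        out = relabel_altlocs(model, seed=0)
        o1 = out.get("A", 1)
        o3 = out.get("A", 3)
        for c1 in o1.conformers:
            for c3 in o3.conformers:
                if c1.altloc == c3.altloc:
                    assert _pair_clashes(c1, c3, False, 0.75) == 0

    def test_no_contacts_keeps_labels(self):
        pep = mc.build_ideal_peptide(["SER"])
        res = pep.get("A", 1)
        base = res.conformers[0]
        a = base.copy()
        a.altloc = "A"
        b = base.copy()
        b.altloc = "B"
        res.conformers = [a, b]
        out = relabel_altlocs(pep, seed=1)
        assert [c.altloc for c in out.get("A", 1).conformers] == ["A", "B"]

    def test_matches_exhaustive_search(self):
        """Best labeling energy equals brute force over all letter choices."""
        model = self._clashing_pair()
        out = relabel_altlocs(model, seed=2)

        def labeling_energy(model, flips):
            multi = [r for r in model.residues if len(r.conformers) > 1]
            energy = 0
            for i in range(len(multi)):
                for j in range(i + 1, len(multi)):
                    ci = multi[i].conformers
                    cj = multi[j].conformers
                    for letter in range(2):
                        a = ci[letter ^ flips[i]]
                        b = cj[letter ^ flips[j]]
                        energy += _pair_clashes(a, b, False, 0.75)
            return energy

        best_brute = min(
            labeling_energy(model, flips)
            for flips in itertools.product([0, 1], repeat=2)
        )
        multi = [r for r in out.residues if len(r.conformers) > 1]
        achieved = 0
        for i in range(len(multi)):
            for j in range(i + 1, len(multi)):
                for a in multi[i].conformers:
                    for b in multi[j].conformers:
                        if a.altloc == b.altloc:
                            achieved += _pair_clashes(a, b, False, 0.75)
        assert achieved == best_brute

    def test_deterministic_per_seed(self):
        model = self._clashing_pair()
        o1 = relabel_altlocs(model, seed=3)
        o2 = relabel_altlocs(model, seed=3)
        for r1, r2 in zip(o1.residues, o2.residues):
            assert [c.altloc for c in r1.conformers] == [
                c.altloc for c in r2.conformers
            ]


class TestSegmentOnlyExpand:
    def _ragged_segment(self):
        pep = mc.build_ideal_peptide(["ALA", "ALA", "ALA", "ALA"])
        model = pep.copy()
        res2 = model.get("A", 2)
        base = res2.conformers[0]
        res2.conformers = [
            shift_conformer(base, 0.05 * i, "ABCD"[i], occ)
            for i, occ in enumerate([0.4, 0.3, 0.2, 0.1])
        ]
        res3 = model.get("A", 3)
        base = res3.conformers[0]
        res3.conformers = [
            shift_conformer(base, 0.0, "A", 0.6),
            shift_conformer(base, 0.1, "B", 0.4),
        ]
        return model

    def test_duplication_to_max_count(self):
        out = segment_only_expand(self._ragged_segment())
        assert len(out.get("A", 2).conformers) == 4
        assert len(out.get("A", 3).conformers) == 4

    def test_occupancy_sums_preserved(self):
        out = segment_only_expand(self._ragged_segment())
        for seq_id in (2, 3):
            assert out.get("A", seq_id).occupancy_sum == pytest.approx(1.0, abs=1e-6)

    def test_uniform_segment_unchanged(self):
        pep = mc.build_ideal_peptide(["ALA", "ALA", "ALA"])
        model = make_multibackbone(pep, [2])
        out = segment_only_expand(model)
        assert len(out.get("A", 2).conformers) == 2

    def test_over_budget_rejected(self):
        model = self._ragged_segment()
        res = model.get("A", 2)
        extra = res.conformers[0].copy()
        extra.altloc = "E"
        res.conformers = res.conformers + [extra]
        for c in res.conformers:
            c.set_occupancy(0.2)
        res3 = model.get("A", 3)
        # force a 6-high target by adding a fifth and sixth to residue 2
        extra2 = res.conformers[0].copy()
        extra2.altloc = "F"
        res.conformers.append(extra2)
        for c in res.conformers:
            c.set_occupancy(1.0 / 6)
        with pytest.raises(ValueError, match="altloc budget|conformers"):
            segment_only_expand(model)


class TestOccupancyGroups:
    def test_groups_listed_per_slot(self, hexapeptide):
        model = make_multibackbone(hexapeptide, [2, 3])
        groups = occupancy_groups(model)
        assert len(groups) == 2
        assert {g["altloc"] for g in groups} == {"A", "B"}
        assert all(g["start"] == 2 and g["end"] == 3 for g in groups)
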