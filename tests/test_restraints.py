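"""Restraint generation, the Geman-McClure loss, metal links, torsion flips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsfit import (
    GMDistanceRestraint,
    apply_jed_flip,
    build_standard_restraints,
    generate_self_gm_restraints,
    gm_residual,
    make_ideal_polypeptide,
    metal_link_restraints,
    torsion_flip_deltas,
)
from rsfit.dictionary import MissingDictionaryError, TorsionTemplate
from rsfit.model import Atom, LinkRecord, Residue, Structure


class TestStandardRestraints:
    def test_dipeptide_has_peptide_bond_restraint(self, dictionary):
        s = make_ideal_polypeptide("AA", "helix")
        rset = build_standard_restraints(s, dictionary)
        peptide = [b for b in rset.bonds
                   if b.atoms[0][3] == "C" and b.atoms[1][3] == "N"
                   and b.atoms[0][1] != b.atoms[1][1]]
        assert len(peptide) == 1
        assert peptide[0].target == pytest.approx(1.33, abs=0.005)

    def test_single_gly_has_no_sidechain_torsions(self, dictionary):
        s = make_ideal_polypeptide("G", "helix")
        rset = build_standard_restraints(s, dictionary)
        assert rset.torsions == []
        assert all(len(r.atoms) == 0 or True for r in rset.torsions)

    def test_unknown_residue_type_named_in_error(self, dictionary):
        s = make_ideal_polypeptide("A", "helix")
        s.chain("A")[0].res_type = "XYZ"
        with pytest.raises(MissingDictionaryError, match="XYZ"):
            build_standard_restraints(s, dictionary)

    def test_nonbonded_excludes_covalent_neighbours(self, dictionary):
        s = make_ideal_polypeptide("AAA", "helix")
        rset = build_standard_restraints(s, dictionary)
        bonded = {frozenset(b.atoms) for b in rset.bonds}
        for nb in rset.nonbonded:
            assert frozenset(nb.atoms) not in bonded


class TestGMResidual:
    def test_zero_at_target(self):
        r = GMDistanceRestraint((("A", 1, "", "CA"), ("A", 2, "", "CA")),
                                target=3.8, sigma=0.1, alpha=0.02)
        e, g = gm_residual(3.8, r)
        assert e == 0.0 and g == 0.0

    def test_alpha_zero_is_harmonic(self):
        r = GMDistanceRestraint((("A", 1, "", "CA"), ("A", 2, "", "CA")),
                                target=2.0, sigma=0.5, alpha=0.0)
        for d in np.linspace(0.5, 3.5, 13):
            z = (d - 2.0) / 0.5
            e, _g = gm_residual(d, r)
            assert e == pytest.approx(z * z, abs=1e-12)

    def test_energy_bounded_by_inverse_alpha(self):
        alpha = 0.05
        r = GMDistanceRestraint((("A", 1, "", "CA"), ("A", 2, "", "CA")),
                                target=1.0, sigma=0.1, alpha=alpha)
        e_far, _ = gm_residual(1e6, r)
        assert e_far < 1.0 / alpha
        assert e_far == pytest.approx(1.0 / alpha, rel=1e-3)

    @given(z=st.floats(-5, 5), alpha=st.floats(0.0, 0.5))
    @settings(max_examples=200, deadline=None)
    def test_gm_never_exceeds_harmonic(self, z, alpha):
        sigma, target = 0.2, 2.0
        r = GMDistanceRestraint((("A", 1, "", "X"), ("A", 2, "", "Y")),
                                target=target, sigma=sigma, alpha=alpha)
        d = target + z * sigma
        if d < 0:
            return
        e, _ = gm_residual(d, r)
        assert e <= z * z + 1e-9
        if alpha * z * z == 0:
            assert e == pytest.approx(z * z, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.01, 0.2])
    @pytest.mark.parametrize("z", [-3.0, -0.7, 0.4, 2.5])
    def test_gradient_matches_finite_differences(self, alpha, z):
        sigma, target = 0.15, 2.5
        r = GMDistanceRestraint((("A", 1, "", "X"), ("A", 2, "", "Y")),
                                target=target, sigma=sigma, alpha=alpha)
        d = target + z * sigma
        h = 1e-7
        _e, g = gm_residual(d, r)
        num = (gm_residual(d + h, r)[0] - gm_residual(d - h, r)[0]) / (2 * h)
        assert g == pytest.approx(num, rel=1e-6, abs=1e-9)

    def test_nonpositive_sigma_rejected(self):
        r = GMDistanceRestraint((("A", 1, "", "X"), ("A", 2, "", "Y")),
                                target=1.0, sigma=0.0)
        with pytest.raises(ValueError):
            gm_residual(1.0, r)


class TestSelfGMGeneration:
    @pytest.mark.parametrize("limit", [4.2, 6.0, 7.0])
    def test_matches_brute_force_oracle(self, mixed_helix, limit):
        from rsfit.restraints import covalent_graph

        rs = generate_self_gm_restraints(mixed_helix, limit=limit)
        # brute force: all O(n^2) pairs within limit, minus 1-2/1-3
        keys, xyz = [], []
        for r in mixed_helix.residues():
            for a in r.atoms:
                keys.append((r.chain_id, r.seqnum, r.inscode, a.name))
                xyz.append(a.pos)
        xyz = np.array(xyz)
        graph = covalent_graph(mixed_helix)
        expected = {}
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                d = np.linalg.norm(xyz[i] - xyz[j])
                if d > limit:
                    continue
                nbrs = graph[keys[i]]
                second = set().union(*(graph[n] for n in nbrs)) if nbrs else set()
                if keys[j] in nbrs or keys[j] in second:
                    continue
                expected[frozenset((keys[i], keys[j]))] = d
        got = {frozenset(r.atoms): r.target for r in rs}
        assert set(got) == set(expected)
        for k, d in expected.items():
            assert got[k] == pytest.approx(d, abs=1e-9)

    def test_longer_limit_is_superset(self, mixed_helix):
        short = {frozenset(r.atoms)
                 for r in generate_self_gm_restraints(mixed_helix, limit=4.2)}
        long = {frozenset(r.atoms)
                for r in generate_self_gm_restraints(mixed_helix, limit=6.0)}
        assert short <= long

    def test_directly_bonded_pair_excluded(self, mixed_helix):
        rs = generate_self_gm_restraints(mixed_helix, limit=4.2)
        pairs = {frozenset((a[3], a[1]) for a in r.atoms) for r in rs}
        res1 = mixed_helix.chain("A")[0]
        key = frozenset({("N", res1.seqnum), ("CA", res1.seqnum)})
        assert key not in pairs


def zinc_structure(ligand_atom="NE2", ligand_element="N"):
    his = Residue("A", 10, "HIS")
    his.atoms.append(Atom("N", "N", [0.0, 0.0, 0.0]))
    his.atoms.append(Atom(ligand_atom, ligand_element, [2.0, 0.0, 0.0]))
    zn = Residue("A", 90, "ZN")
    zn.atoms.append(Atom("ZN", "ZN", [4.0, 0.0, 0.0]))
    return Structure(
        [("A", [his, zn])],
        links=[LinkRecord(("A", 10, "", ligand_atom), ("A", 90, "", "ZN"))])


class TestMetalLinks:
    def test_zn_his_gives_bond_and_suppression(self):
        s = zinc_structure()
        bonds, suppressed = metal_link_restraints(s)
        assert len(bonds) == 1
        assert bonds[0].target == pytest.approx(2.08, abs=0.2)  # Zn-N
        assert frozenset((("A", 10, "", "NE2"), ("A", 90, "", "ZN"))) in suppressed

    def test_metal_to_carbon_ignored(self):
        s = zinc_structure(ligand_atom="CD2", ligand_element="C")
        bonds, suppressed = metal_link_restraints(s)
        assert bonds == [] and suppressed == set()

    def test_dangling_link_warns_and_skips(self):
        s = zinc_structure()
        s.links.append(LinkRecord(("B", 1, "", "O"), ("A", 90, "", "ZN")))
        with pytest.warns(UserWarning, match="dangling"):
            bonds, _sup = metal_link_restraints(s)
        assert len(bonds) == 1

    def test_suppressed_pair_absent_from_nonbonded(self, dictionary):
        s = zinc_structure()
        # HIS entry needs full atoms; restrict to a dictionary-free check
        rset = build_standard_restraints(
            make_ideal_polypeptide("AA", "helix"), dictionary)
        bonds, suppressed = metal_link_restraints(s)
        pair = next(iter(suppressed))
        assert all(frozenset(nb.atoms) != pair for nb in rset.nonbonded)


class TestTorsionFlips:
    @pytest.mark.parametrize("period,expected", [
        (3, {120.0, -120.0}),
        (2, {180.0}),
        (1, {180.0}),
        (4, {90.0, -90.0, 180.0}),
        (6, {60.0, -60.0, 120.0, -120.0, 180.0}),
    ])
    def test_deltas_from_period(self, period, expected):
        t = TorsionTemplate("t", "A", "B", "C", "D", 60.0, 10.0, period)
        assert set(torsion_flip_deltas(t)) == expected

    @given(period=st.integers(3, 12))
    @settings(max_examples=20, deadline=None)
    def test_deltas_closed_under_negation(self, period):
        t = TorsionTemplate("t", "A", "B", "C", "D", 0.0, 10.0, period)
        deltas = set(torsion_flip_deltas(t))
        for d in deltas:
            if abs(d) != 180.0:
                assert -d in deltas

    def test_invalid_period_rejected(self):
        t = TorsionTemplate("t", "A", "B", "C", "D", 0.0, 10.0, 0)
        with pytest.raises(ValueError):
            torsion_flip_deltas(t)


class TestJedFlip:
    @staticmethod
    def ligand_structure(toy_ligand):
        return Structure([("L", [toy_ligand.copy()])])

    def test_ring_flip_swaps_meta_chlorine(self, toy_ligand):
        s = self.ligand_structure(toy_ligand)
        bond = (("L", 1, "", "C1"), ("L", 1, "", "C7"))
        # the ring is the larger side, so reverse moves it
        out = apply_jed_flip(s, bond, 180.0, reverse=True)
        res0 = s.chain("L")[0]
        res1 = out.chain("L")[0]
        # chlorine must move; the bond axis atoms stay put
        assert np.linalg.norm(res1.pos("CL1") - res0.pos("CL1")) > 2.0
        assert np.allclose(res1.pos("C1"), res0.pos("C1"))
        assert np.allclose(res1.pos("C7"), res0.pos("C7"))
        # intra-ring distances preserved
        ring = ["C1", "C2", "C3", "C4", "C5", "C6", "CL1"]
        for i, a in enumerate(ring):
            for b in ring[i + 1:]:
                d0 = np.linalg.norm(res0.pos(a) - res0.pos(b))
                d1 = np.linalg.norm(res1.pos(a) - res1.pos(b))
                assert d1 == pytest.approx(d0, abs=1e-9)

    def test_default_moves_smaller_side(self, toy_ligand):
        s = self.ligand_structure(toy_ligand)
        bond = (("L", 1, "", "C1"), ("L", 1, "", "C7"))
        out = apply_jed_flip(s, bond, 180.0)
        res0 = s.chain("L")[0]
        res1 = out.chain("L")[0]
        # tail (C8, C9) is smaller than ring side: chlorine must NOT move
        assert np.allclose(res1.pos("CL1"), res0.pos("CL1"))
        assert np.linalg.norm(res1.pos("C9") - res0.pos("C9")) > 0.5

    def test_delta_360_is_identity(self, toy_ligand):
        s = self.ligand_structure(toy_ligand)
        bond = (("L", 1, "", "C1"), ("L", 1, "", "C7"))
        out = apply_jed_flip(s, bond, 360.0)
        assert np.allclose(out.coords(), s.coords(), atol=1e-9)

    def test_flip_then_inverse_restores(self, toy_ligand):
        s = self.ligand_structure(toy_ligand)
        bond = (("L", 1, "", "C1"), ("L", 1, "", "C7"))
        out = apply_jed_flip(apply_jed_flip(s, bond, 120.0), bond, -120.0)
        assert np.allclose(out.coords(), s.coords(), atol=1e-9)

    def test_ring_bond_refused(self, toy_ligand):
        s = self.ligand_structure(toy_ligand)
        bond = (("L", 1, "", "C1"), ("L", 1, "", "C2"))
        with pytest.raises(ValueError, match="ring"):
            apply_jed_flip(s, bond, 120.0)
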