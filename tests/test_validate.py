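"""Validation suite: Ramachandran/Kleywegt, rotamers, B stats, density fit,
ligand distortion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsfit import (
    b_factor_stats,
    density_fit_graph,
    kleywegt_compare,
    ligand_distortion,
    make_ideal_polypeptide,
    phi_psi,
    rama_report,
    rotamer_analysis,
    synthesize_map,
)
from rsfit.geometry import dihedral_deg, wrap_degrees
from rsfit.model import Atom, Structure
from rsfit.validate import RamaTables, rama_class


class TestPhiPsi:
    def test_roundtrip_of_generator_angles(self):
        for conf, (phi0, psi0) in [("helix", (-57.0, -47.0)),
                                   ("strand", (-120.0, 120.0))]:
            s = make_ideal_polypeptide("A" * 6, conf)
            for res in s.chain("A")[1:-1]:
                phi, psi = phi_psi(s, res)
                assert phi == pytest.approx(phi0, abs=0.1)
                assert psi == pytest.approx(psi0, abs=0.1)

    def test_termini_undefined(self):
        s = make_ideal_polypeptide("AAAA", "helix")
        assert phi_psi(s, s.chain("A")[0]) is None
        assert phi_psi(s, s.chain("A")[-1]) is None

    def test_dihedral_sign_convention_hand_case(self):
        # four points with a known +90 degree dihedral, worked by hand:
        # b0=(0,1,0) projected, b2=(0,0,1): cross/atan2 gives +90
        a = np.array([0.0, 1.0, 0.0])
        b = np.array([0.0, 0.0, 0.0])
        c = np.array([1.0, 0.0, 0.0])
        d = np.array([1.0, 0.0, 1.0])
        assert dihedral_deg(a, b, c, d) == pytest.approx(90.0)
        assert dihedral_deg(d, c, b, a) == pytest.approx(90.0)
        d2 = np.array([1.0, 0.0, -1.0])
        assert dihedral_deg(a, b, c, d2) == pytest.approx(-90.0)


class TestRamaReport:
    def test_ideal_helix_all_preferred_general(self, helix20):
        points, summary = rama_report(helix20)
        assert summary["n"] == 18
        assert all(p.rama_class == "general" for p in points)
        assert summary["percent"]["preferred"] == 100.0

    def test_pre_pro_takes_precedence_over_ile_val(self):
        s = make_ideal_polypeptide("AIPA", "helix")
        chain = s.chain("A")
        assert rama_class(chain[1], chain[2]) == "pre_pro"  # ILE before PRO
        assert rama_class(chain[1], chain[0]) == "ile_val"

    def test_class_assignment(self):
        s = make_ideal_polypeptide("AGAPVA", "helix")
        chain = s.chain("A")
        assert rama_class(chain[1], chain[2]) == "gly"
        assert rama_class(chain[2], chain[3]) == "pre_pro"  # precedes PRO
        assert rama_class(chain[3], chain[4]) == "pro"
        assert rama_class(chain[4], chain[5]) == "ile_val"
        assert rama_class(chain[5], None) == "general"

    def test_outliers_only_filters(self, helix20):
        points, _summary = rama_report(helix20, outliers_only=True)
        assert points == []

    def test_category_counts_cover_defined_residues(self, mixed_helix):
        points, summary = rama_report(mixed_helix)
        assert sum(summary["counts"].values()) == summary["n"] == len(points)

    def test_markers(self):
        s = make_ideal_polypeptide("AGPA", "helix")
        points, _ = rama_report(s)
        markers = {p.res_type: p.marker for p in points}
        assert markers["GLY"] == "triangle"
        assert markers["PRO"] == "square"

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            RamaTables(preferred_min=0.001, allowed_min=0.01)


def two_chain_structure(n=100, shift_psi=None):
    a = make_ideal_polypeptide("A" * n, "helix", chain_id="A")
    b = make_ideal_polypeptide("A" * n, "helix", chain_id="B")
    s = Structure(a.chains + b.chains)
    if shift_psi:
        seqnum, delta = shift_psi
        # rotate everything after residue seqnum's C about the CA-C bond
        from rsfit.geometry import rotation_about_axis

        res = s.chain("B")[seqnum - 1]
        R, t = rotation_about_axis(res.pos("CA"), res.pos("C") - res.pos("CA"),
                                   delta)
        started = False
        for r in s.chain("B"):
            for atom in r.atoms:
                if r.seqnum > seqnum or (r.seqnum == seqnum and atom.name == "O"):
                    atom.pos = R @ atom.pos + t
        del started
    return s


class TestKleywegt:
    def test_identical_chains_all_zero(self):
        s = two_chain_structure(100)
        pairs = kleywegt_compare(s, "A", s, "B")
        assert len(pairs) == 50  # default top-50
        assert all(p.torus_distance == pytest.approx(0.0, abs=1e-9)
                   for p in pairs)

    def test_psi_shift_ranks_first(self):
        s = two_chain_structure(30, shift_psi=(15, 30.0))
        pairs = kleywegt_compare(s, "A", s, "B", top_n=5)
        assert pairs[0].residue_b[1] == 15
        assert pairs[0].torus_distance == pytest.approx(30.0, abs=0.5)

    def test_wraparound_of_angle_differences(self):
        assert wrap_degrees(350.0) == pytest.approx(-10.0)
        assert abs(wrap_degrees(185.0 - (-175.0))) == pytest.approx(0.0)

    def test_symmetric_distances(self):
        s = two_chain_structure(20, shift_psi=(10, 25.0))
        ab = {p.residue_a[1]: p.torus_distance
              for p in kleywegt_compare(s, "A", s, "B", top_n=100)}
        ba = {p.residue_b[1]: p.torus_distance
              for p in kleywegt_compare(s, "B", s, "A", top_n=100)}
        for k in ab:
            assert ab[k] == pytest.approx(ba[k], abs=1e-9)

    def test_shifted_numbering_paired_by_alignment(self):
        a = make_ideal_polypeptide("ASLKDE", "helix", chain_id="A")
        b = make_ideal_polypeptide("ASLKDE", "helix", chain_id="B",
                                   start_seqnum=100)
        s = Structure(a.chains + b.chains)
        pairs = kleywegt_compare(s, "A", s, "B")
        assert len(pairs) == 4  # interior residues with defined phi/psi
        assert all(p.torus_distance < 1e-6 for p in pairs)

    def test_no_comparable_residues_raises(self):
        # two-residue chains have no residue with defined phi/psi
        a = make_ideal_polypeptide("AA", "helix", chain_id="A")
        b = make_ideal_polypeptide("AA", "helix", chain_id="B")
        s = Structure(a.chains + b.chains)
        with pytest.raises(ValueError):
            kleywegt_compare(s, "A", s, "B")

    @given(st.tuples(st.floats(-180, 179.9), st.floats(-180, 179.9),
                     st.floats(-180, 179.9)),
           st.tuples(st.floats(-180, 179.9), st.floats(-180, 179.9),
                     st.floats(-180, 179.9)))
    @settings(max_examples=100, deadline=None)
    def test_torus_distance_triangle_inequality(self, phis, psis):
        def dist(p1, s1, p2, s2):
            return np.hypot(wrap_degrees(p1 - p2), wrap_degrees(s1 - s2))

        a, b, c = zip(phis, psis)
        assert dist(*a, *b) + dist(*b, *c) >= dist(*a, *c) - 1e-9


class TestRotamerAnalysis:
    def test_exact_library_conformation_found(self, rotamer_library):
        s = make_ideal_polypeptide("ALA", "helix")
        df = rotamer_analysis(s)
        row = df[df.res_type == "LEU"].iloc[0]
        assert row.chi_distance == pytest.approx(0.0, abs=1e-6)
        assert row.rotamer == rotamer_library.rotamers("LEU")[0].name

    def test_gly_and_ala_skipped(self):
        s = make_ideal_polypeptide("GAL", "helix")
        df = rotamer_analysis(s)
        assert set(df.res_type) == {"LEU"}

    def test_tie_goes_to_more_probable_rotamer(self, rotamer_library):
        # SER chi1 exactly between p (62) and m (-65): at 178.5 both are
        # 116.5 away -- but t (-177) is nearer; construct midpoint of p/m
        s = make_ideal_polypeptide("ASA", "helix")
        res = s.chain("A")[1]
        from rsfit.backrub import Rotamer, place_rotamer_side_chain

        mid = Rotamer("SER", "mid", 1.0, (-1.5,))  # equidistant from 62/-65
        for name, p in place_rotamer_side_chain(res, mid).items():
            res.atom(name).pos = p
        df = rotamer_analysis(s)
        assert df.iloc[0].rotamer == "p"  # library order = probability order


class TestBFactorStats:
    def test_uniform_b(self, helix20):
        mean, median, _df = b_factor_stats(helix20)
        assert mean == 20.0 and median == 20.0

    def test_median_robust_to_one_extreme_water(self):
        atoms99 = Structure()
        from rsfit.model import Residue

        residues = []
        for i in range(99):
            r = Residue("A", i + 1, "HOH")
            r.atoms.append(Atom("O", "O", [float(i), 0.0, 0.0], b=20.0))
            residues.append(r)
        extreme = Residue("A", 100, "HOH")
        extreme.atoms.append(Atom("O", "O", [99.0, 0.0, 0.0], b=200.0))
        residues.append(extreme)
        s = Structure([("A", residues)])
        mean, median, _df = b_factor_stats(s)
        assert median == 20.0
        assert mean == pytest.approx(21.8)

    def test_per_residue_means_consistent_with_global(self, mixed_helix):
        mean, _median, df = b_factor_stats(mixed_helix)
        weighted = (df.mean_b * df.n_atoms).sum() / df.n_atoms.sum()
        assert weighted == pytest.approx(mean)

    def test_empty_selection_rejected(self, helix20):
        with pytest.raises(ValueError):
            b_factor_stats(helix20, sel="//Z")


class TestDensityFitGraph:
    def test_residue_outside_map_scores_zero(self, helix20, helix20_map):
        s = helix20.copy()
        for a in s.chain("A")[0].atoms:
            a.pos = a.pos + 500.0
        df = density_fit_graph(s, helix20_map)
        assert df.iloc[0].fit == 0.0

    def test_truth_model_every_residue_positive(self, helix20, helix20_map):
        df = density_fit_graph(helix20, helix20_map)
        assert (df.fit > 0).all()

    def test_removing_sidechain_density_is_local(self):
        s = make_ideal_polypeptide("ALLA", "helix")
        m_full = synthesize_map(s)
        bare = s.copy()
        res = bare.chain("A")[1]
        res.atoms = [a for a in res.atoms
                     if a.name in ("N", "CA", "C", "O", "CB")]
        m_bare = synthesize_map(bare, like=m_full)
        # evaluate the same model against both maps
        df_full = density_fit_graph(s, m_full)
        df_bare = density_fit_graph(s, m_bare)
        drop = df_full.fit - df_bare.fit
        assert drop.iloc[1] == drop.max()
        assert drop.iloc[1] > 5 * abs(drop.iloc[3])


class TestLigandDistortion:
    def test_ideal_ligand_all_zero(self, toy_ligand):
        df, summary = ligand_distortion(toy_ligand)
        assert np.abs(df.z).max() < 1e-9
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in summary.values())

    def test_stretched_bond_z_is_two(self, toy_ligand):
        res = toy_ligand.copy()
        # stretch the C8-C9 terminal bond by 2 sigma (sigma 0.02)
        v = res.pos("C9") - res.pos("C8")
        res.atom("C9").pos = res.pos("C8") + v * (1.0 + 0.04 / np.linalg.norm(v))
        df, _summary = ligand_distortion(res)
        z = df[(df["class"] == "bond") & (df.atoms == "C8-C9")].iloc[0].z
        assert z == pytest.approx(2.0, abs=0.01)

    def test_torsion_periodicity(self, toy_ligand):
        df, _ = ligand_distortion(toy_ligand)
        tor = df[df["class"] == "torsion"]
        assert np.abs(tor.z).max() < 1e-9  # targets hit modulo period

    def test_invariant_under_rigid_motion(self, toy_ligand, rng):
        from rsfit.geometry import rotation_about_axis

        res = toy_ligand.copy()
        R, t = rotation_about_axis([1.0, 2.0, 3.0], [0.3, -0.5, 0.81], 77.0)
        for a in res.atoms:
            a.pos = R @ a.pos + t + np.array([5.0, -2.0, 1.0])
        df0, sum0 = ligand_distortion(toy_ligand)
        df1, sum1 = ligand_distortion(res)
        assert np.allclose(df0.z, df1.z, atol=1e-8)

    def test_missing_dictionary_entry(self, toy_ligand):
        from rsfit.dictionary import MissingDictionaryError

        res = toy_ligand.copy()
        res.res_type = "QQQ"
        with pytest.raises(MissingDictionaryError):
            ligand_distortion(res)
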