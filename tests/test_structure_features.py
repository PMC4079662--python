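"""Structure parsing, SASA and the 89 protein-level features."""

import numpy as np
import pytest

from crystalgp import synthetic as syn
from crystalgp.pdb import parse_structure
from crystalgp.protein_features import (
    feature_names,
    isoelectric_point,
    neighbor_pair_fractions,
    protein_feature_vector,
    radius_of_gyration,
    scale_average,
    surface_residues,
    _net_charge,
)
from crystalgp.sasa import atom_sasa, compute_sasa, sphere_points
from crystalgp.scales import AMINO_ACIDS, CATEGORIES, CATEGORY_PAIRS, residue_category


class TestScales:
    def test_category_partition_covers_all_residues_once(self):
        by_cat = {c: [] for c in CATEGORIES}
        for aa in AMINO_ACIDS:
            by_cat[residue_category(aa)].append(aa)
        assert sorted(by_cat["S"]) == ["A", "G"]
        assert sorted(by_cat["+"]) == ["H", "K", "R"]
        assert sorted(by_cat["-"]) == ["D", "E"]
        assert sorted(by_cat["P"]) == ["C", "N", "Q", "S", "T"]
        assert sorted(by_cat["H"]) == ["F", "I", "L", "M", "P", "V", "W", "Y"]
        assert sum(len(v) for v in by_cat.values()) == 20

    def test_pair_symbols_unordered(self):
        assert len(CATEGORY_PAIRS) == 15
        from crystalgp.scales import category_pair

        assert category_pair("-", "+") == category_pair("+", "-") == "+-"


class TestParseStructure:
    def test_round_trip_toy_peptide(self):
        txt = syn.generate_toy_structure(syn.ToyLayout([("GLY", (0, 0, 0)), ("LYS", (4, 0, 0))]))
        s = parse_structure(txt)
        assert len(s.residues) == 2
        assert [r.name3 for r in s.residues] == ["GLY", "LYS"]
        assert not s.symmetry_ops and s.cell is None

    def test_no_atoms_rejected(self):
        with pytest.raises(ValueError, match="no ATOM records"):
            parse_structure("HEADER  nothing\nEND\n")

    def test_malformed_coordinate_names_line(self):
        bad = (
            "ATOM      1  CA  GLY A   1      bad.000   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(ValueError, match="line 1"):
            parse_structure(bad)

    def test_altloc_highest_occupancy_tie_goes_to_A(self):
        line = (
            "ATOM      1  CA {alt}GLY A   1    {x:8.3f}   0.000   0.000{occ:6.2f}  0.00           C"
        )
        # B has higher occupancy → B wins
        txt = "\n".join(
            [line.format(alt="A", x=0.0, occ=0.4), line.format(alt="B", x=9.0, occ=0.6)]
        )
        s = parse_structure(txt)
        assert s.coords[0, 0] == pytest.approx(9.0)
        # occupancy tie → 'A' wins
        txt = "\n".join(
            [line.format(alt="B", x=9.0, occ=0.5), line.format(alt="A", x=0.0, occ=0.5)]
        )
        s = parse_structure(txt)
        assert s.coords[0, 0] == pytest.approx(0.0)

    def test_agrees_with_gemmi_on_toy_structure(self):
        gemmi = pytest.importorskip("gemmi")
        txt = syn.generate_toy_structure(
            syn.ToyLayout([("GLY", (0, 0, 0)), ("LYS", (4, 0, 0))],
                          cell=(10.0, 12.0, 14.0, 90.0, 90.0, 90.0))
        )
        ours = parse_structure(txt)
        theirs = gemmi.read_pdb_string(txt)
        g_atoms = [a for model in theirs for chain in model for res in chain for a in res]
        assert len(g_atoms) == ours.n_atoms
        g_xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in g_atoms])
        np.testing.assert_allclose(np.sort(g_xyz, axis=0), np.sort(ours.coords, axis=0),
                                   atol=1e-6)
        cell = theirs.cell
        assert (cell.a, cell.b, cell.c) == pytest.approx(ours.cell[:3])

    def test_smtry_operator_count_matches_fixture(self):
        ops = [
            (np.eye(3), np.zeros(3)),
            (np.diag([-1.0, -1.0, 1.0]), np.array([0.0, 0.0, 5.0])),
            (np.diag([1.0, -1.0, -1.0]), np.array([5.0, 0.0, 0.0])),
        ]
        lay = syn.ToyLayout([("ALA", (0, 0, 0))], cell=(10, 10, 10, 90, 90, 90), symmetry_ops=ops)
        s = parse_structure(syn.generate_toy_structure(lay))
        assert len(s.symmetry_ops) == 3
        np.testing.assert_allclose(s.symmetry_ops[1].rotation, np.diag([-1, -1, 1]))
        np.testing.assert_allclose(s.symmetry_ops[1].translation, [0, 0, 5])


class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        # closed form: 4π(r_vdw + r_probe)²
        area = atom_sasa(np.zeros((1, 3)), np.array([1.7]), 1.4, 960)[0]
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(area - exact) / exact < 0.01

    def test_far_apart_atoms_additive(self):
        one = atom_sasa(np.zeros((1, 3)), np.array([1.7]))[0]
        two = atom_sasa(np.array([[0.0, 0, 0], [50.0, 0, 0]]), np.array([1.7, 1.7]))
        assert two.sum() == pytest.approx(2 * one, rel=1e-12)

    def test_caged_atom_has_zero_area(self):
        # surround a small atom with a tight shell of large spheres
        shell = 2.2 * sphere_points(200)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.concatenate([[0.5], np.full(200, 1.7)])
        areas = atom_sasa(coords, radii, probe_radius=1.4, n_points=500)
        assert areas[0] == 0.0

    def test_quadrature_converges_on_fixture(self, helix_structure):
        a = sum(compute_sasa(helix_structure, n_points=480).values())
        b = sum(compute_sasa(helix_structure, n_points=960).values())
        assert abs(a - b) / b < 0.005


class TestSurfaceAndPairs:
    def test_threshold_boundary_inclusive(self):
        assert surface_residues({0: 2.5, 1: 2.49}, threshold=2.5) == {0}
        assert surface_residues({0: 0.0, 1: 0.0}) == set()

    def test_two_glycines_all_small_pair(self):
        txt = syn.generate_toy_structure(syn.ToyLayout([("GLY", (0, 0, 0)), ("GLY", (4, 0, 0))]))
        s = parse_structure(txt)
        frac, _, has = neighbor_pair_fractions(s, {0, 1}, cutoff=5.0)
        assert has and frac["SS"] == 1.0 and frac.sum() == 1.0

    def test_gke_triplet_three_pair_categories(self):
        txt = syn.generate_toy_structure(
            syn.ToyLayout([("GLY", (0, 0, 0)), ("LYS", (3, 0, 0)), ("GLU", (1.5, 2.5, 0))])
        )
        s = parse_structure(txt)
        frac, _, has = neighbor_pair_fractions(s, {0, 1, 2}, cutoff=5.0)
        assert has
        # G(S)-K(+), G(S)-E(-), K(+)-E(-) → S+, S-, +- each 1/3
        for sym in ("S+", "S-", "+-"):
            assert frac[sym] == pytest.approx(1 / 3)

    def test_tiny_cutoff_flags_no_pairs(self):
        txt = syn.generate_toy_structure(syn.ToyLayout([("GLY", (0, 0, 0)), ("GLY", (4, 0, 0))]))
        s = parse_structure(txt)
        frac, _, has = neighbor_pair_fractions(s, {0, 1}, cutoff=0.1)
        assert not has and frac.sum() == 0.0


class TestScalarFeatures:
    def test_polyglycine_gravy_is_kyte_doolittle_value(self):
        assert scale_average(list("GGGG"), "gravy") == pytest.approx(-0.4)

    def test_single_residue_identity_and_mixture(self):
        assert scale_average(["K"], "sce") == pytest.approx(1.94)
        got = scale_average(["G", "A"], "gravy")
        assert got == pytest.approx((-0.4 + 1.8) / 2)

    def test_pi_is_a_charge_zero(self):
        for seq in ("GGKGG", "DDKEE", "ACDEFGHIKLMNPQRSTVWY"):
            pi = isoelectric_point(seq)
            assert abs(_net_charge(seq, pi)) < 1e-3

    def test_pi_ordering_basic_vs_acidic(self):
        assert isoelectric_point("KKKKK") > isoelectric_point("EEEEE")

    def test_pi_matches_brute_force_scan(self):
        seq = "GGKGG"
        charges = np.array([_net_charge(seq, p) for p in np.linspace(0, 14, 57)])
        # brute bisection oracle at much finer tolerance
        lo, hi = 0.0, 14.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if _net_charge(seq, mid) > 0:
                lo = mid
            else:
                hi = mid
        assert isoelectric_point(seq, tol=1e-6) == pytest.approx((lo + hi) / 2, abs=1e-4)
        assert charges[0] > 0 > charges[-1]  # sanity: charge decreases with pH

    def test_radius_of_gyration_analytic_cases(self):
        def rg_of(coords):
            from crystalgp.pdb import Structure

            n = len(coords)
            return radius_of_gyration(
                Structure(
                    residues=[__import__("crystalgp.pdb", fromlist=["Residue"]).Residue("A", 1, "GLY")],
                    coords=np.asarray(coords, dtype=float),
                    elements=["C"] * n,
                    atom_residue=np.zeros(n, dtype=int),
                    het_mask=np.zeros(n, dtype=bool),
                )
            )

        assert rg_of([[1.0, 2.0, 3.0]]) == 0.0
        assert rg_of([[0, 0, 0], [2.0, 0, 0]]) == pytest.approx(1.0)
        cube = [[x, y, z] for x in (0, 2.0) for y in (0, 2.0) for z in (0, 2.0)]
        assert rg_of(cube) == pytest.approx(np.sqrt(3.0))


class TestFeatureVector:
    def test_schema_has_89_features(self):
        assert len(feature_names()) == 89

    def test_simplex_invariants_and_consistency(self, helix_structure):
        v = protein_feature_vector(helix_structure)
        assert sum(v[f"frac_{aa}"] for aa in AMINO_ACIDS) == pytest.approx(1.0, abs=1e-9)
        assert sum(v[f"w_frac_{aa}"] for aa in AMINO_ACIDS) == pytest.approx(1.0, abs=1e-9)
        assert sum(v[f"pair_{p}"] for p in CATEGORY_PAIRS) == pytest.approx(1.0, abs=1e-9)
        # sGRAVY/sSCE/sPOL are coverage-weighted scale means (exact identity)
        from crystalgp.scales import residue_scale

        for key, scale in (("sGRAVY", "gravy"), ("sSCE", "sce"), ("sPOL", "pol")):
            expect = sum(v[f"frac_{aa}"] * residue_scale(scale)[aa] for aa in AMINO_ACIDS)
            assert v[key] == pytest.approx(expect, abs=1e-10)

    def test_helix_terminal_residues_more_exposed(self, helix_structure):
        sasa = compute_sasa(helix_structure)
        n = len(helix_structure.residues)
        terminal = (sasa[0] + sasa[n - 1]) / 2
        central = (sasa[n // 2] + sasa[n // 2 - 1]) / 2
        assert terminal > central
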