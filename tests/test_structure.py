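"""Structure I/O, SASA/BSA, accessible-volume clouds and FRET prediction."""

import numpy as np
import pytest

import protconf as pc

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.919   6.877  -5.041  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA  ALA A   2       5.000   0.000   0.000  1.00  0.00           C
END
"""


def atoms(xyz, radius=1.7, names=None):
    n = len(xyz)
    return pc.StructureModel(
        element=np.full(n, "C", dtype=object),
        name=np.array(names if names is not None else ["CA"] * n, dtype=object),
        resnum=np.arange(1, n + 1),
        chain=np.full(n, "A", dtype=object),
        xyz=np.asarray(xyz, float),
        radius=np.full(n, radius),
    )


class TestReadStructure:
    def test_minimal_pdb(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        st = pc.read_structure(path)
        assert len(st) == 3
        i = st.find_atom(1, "CA")
        assert st.xyz[i] == pytest.approx([11.639, 6.071, -5.147], abs=1e-3)

    def test_round_trip_coordinates(self, tmp_path, toy_dumbbell):
        path = tmp_path / "toy.pdb"
        toy_dumbbell.to_pdb(path)
        st = pc.read_structure(path)
        assert len(st) == len(toy_dumbbell)
        assert np.allclose(np.sort(st.xyz, axis=0),
                           np.sort(toy_dumbbell.xyz, axis=0), atol=1e-3)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        st = pc.read_structure(path)
        assert len(st) == 2  # one altloc dropped
        i = st.find_atom(1, "CA")
        assert st.xyz[i][0] == pytest.approx(1.0, abs=1e-3)

    def test_missing_file(self, tmp_path):
        with pytest.raises(Exception):
            pc.read_structure(tmp_path / "nope.pdb")


class TestDistances:
    def test_same_residue_zero(self, toy_dumbbell):
        assert pc.ca_distance(toy_dumbbell, 3, 3) == 0.0

    def test_constructed_separation(self):
        st = pc.generate_toy_structure(1, 1.0, 51.0)
        assert pc.ca_distance(st, 1, 2) == 51.0

    def test_missing_residue_named_in_error(self, toy_dumbbell):
        with pytest.raises(KeyError, match="999"):
            pc.ca_distance(toy_dumbbell, 1, 999)


class TestSASA:
    def test_single_atom_closed_form(self):
        st = atoms([[0, 0, 0]])
        total = pc.sasa(st).sum()
        assert total == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=0.01)

    def test_far_apart_atoms_additive(self):
        st = atoms([[0, 0, 0], [50, 0, 0]])
        per_atom = pc.sasa(st)
        single = 4 * np.pi * (1.7 + 1.4) ** 2
        assert per_atom == pytest.approx([single, single], rel=0.01)

    def test_overlapping_spheres_match_cap_formula(self):
        d = 2.0
        st = atoms([[0, 0, 0], [d, 0, 0]])
        r = 1.7 + 1.4
        h = r - d / 2
        analytic = 2 * (4 * np.pi * r * r - 2 * np.pi * r * h)
        assert pc.sasa(st).sum() == pytest.approx(analytic, rel=0.02)


class TestBuriedSurfaceArea:
    def test_zero_when_far_apart(self):
        st = pc.generate_toy_structure(5, 3.0, 60.0, seed=2)
        assert pc.buried_surface_area(st, (1, 5), (6, 10)) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_dimer_buries_equally(self):
        # mirror-symmetric contact: each side buries half the total
        xyz_a = [[0, 0, 0], [-3, 1, 0], [-3, -1, 0]]
        xyz_b = [[2.5, 0, 0], [5.5, 1, 0], [5.5, -1, 0]]
        st = atoms(xyz_a + xyz_b)
        total = pc.buried_surface_area(st, (1, 3), (4, 6))
        assert total > 0
        side_a = (pc.sasa(st.subset(st.residue_mask(1, 3))).sum()
                  - pc.sasa(st)[st.residue_mask(1, 3)].sum())
        # sphere-point discretization is not reflection-invariant: ~1%
        assert side_a == pytest.approx(total / 2, rel=0.02)

    def test_symmetric_in_group_order(self, toy_dumbbell):
        st = pc.generate_toy_structure(10, 6.0, 10.0, seed=5)
        ab = pc.buried_surface_area(st, (1, 10), (11, 20))
        ba = pc.buried_surface_area(st, (11, 20), (1, 10))
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_overlapping_groups_rejected(self, toy_dumbbell):
        with pytest.raises(ValueError):
            pc.buried_surface_area(toy_dumbbell, (1, 41), (41, 80))


class TestAccessibleVolume:
    def test_free_site_fills_sphere(self):
        st = atoms([[0, 0, 0]])
        av = pc.compute_av(st, 1, atom="CA")
        # centroid at the attachment within one grid spacing
        assert np.linalg.norm(av.centroid) < av.grid_spacing
        r = np.linalg.norm(av.points, axis=1)
        assert r.max() <= 20.0 + 1e-6
        # lattice metric shaves the outer shell only slightly
        ball = 4 / 3 * np.pi * 20.0 ** 3
        assert len(av) * av.grid_spacing ** 3 > 0.7 * ball

    def test_wall_confines_to_half_space(self):
        # slab of atoms in the y-z plane through the attachment point
        ys, zs = np.meshgrid(np.arange(-24, 25, 1.5), np.arange(-24, 25, 1.5))
        wall = np.column_stack((np.zeros(ys.size), ys.ravel(), zs.ravel()))
        site = np.array([[2.5, 0.0, 0.0]])
        st = atoms(np.vstack((site, wall)))
        av = pc.compute_av(st, 1, atom="CA")
        assert np.all(av.points[:, 0] > 0)       # free half-space only
        assert av.centroid[0] > 2.0              # pushed along the free normal

    def test_cloud_shrinks_with_dye_radius(self):
        st = pc.generate_toy_structure(30, 8.0, 20.0, seed=3)
        small = pc.compute_av(st, 1, params=pc.DyeParams(dye_radius=3.0))
        large = pc.compute_av(st, 1, params=pc.DyeParams(dye_radius=4.5))
        pts_small = {tuple(np.round(p, 6)) for p in small.points}
        pts_large = {tuple(np.round(p, 6)) for p in large.points}
        assert pts_large < pts_small  # strict set inclusion

    def test_cloud_file_outputs(self, tmp_path):
        st = atoms([[0, 0, 0]])
        av = pc.compute_av(st, 1, atom="CA",
                           params=pc.DyeParams(linker_length=6.0))
        xyz_path = tmp_path / "av.xyz"
        dx_path = tmp_path / "av.dx"
        av.to_xyz(xyz_path)
        av.to_dx(dx_path)
        assert int(xyz_path.read_text().splitlines()[0]) == len(av)
        header = dx_path.read_text().splitlines()[0]
        assert header.startswith("object 1 class gridpositions")

    def test_occluded_site_raises(self):
        # attachment atom fully caged by a dense shell
        from itertools import product
        shell = [np.array(p) for p in product((-2.0, 0.0, 2.0), repeat=3)
                 if any(p)]
        st = atoms([[0.0, 0.0, 0.0]] + shell)
        with pytest.raises(ValueError, match="residue 1"):
            pc.compute_av(st, 1, atom="CA",
                          params=pc.DyeParams(linker_length=8.0))


class TestMeanFret:
    def test_efficiency_half_at_forster_radius(self):
        d = pc.AVCloud(np.zeros((1, 3)), np.zeros(3), 0.9)
        a = pc.AVCloud(np.array([[51.0, 0, 0]]), np.zeros(3), 0.9)
        assert pc.mean_fret(d, a, r0=51.0).mean_e == 0.5

    def test_closed_form_at_three_r0(self):
        d = pc.AVCloud(np.zeros((1, 3)), np.zeros(3), 0.9)
        a = pc.AVCloud(np.array([[153.0, 0, 0]]), np.zeros(3), 0.9)
        assert pc.mean_fret(d, a, r0=51.0).mean_e == pytest.approx(1 / 730, rel=1e-12)

    def test_matches_exhaustive_nine_pair_average(self):
        rng = np.random.default_rng(0)
        pd_ = rng.normal(0, 5, (3, 3))
        pa = rng.normal(40, 5, (3, 3))
        d = pc.AVCloud(pd_, np.zeros(3), 0.9)
        a = pc.AVCloud(pa, np.zeros(3), 0.9)
        got = pc.mean_fret(d, a, r0=51.0)
        es = []
        for i in range(3):
            for j in range(3):
                r = np.linalg.norm(pd_[i] - pa[j])
                es.append(1 / (1 + (r / 51.0) ** 6))
        assert got.mean_e == pytest.approx(np.mean(es), abs=1e-12)
        assert got.n_pairs == 9

    def test_symmetric_in_clouds(self):
        rng = np.random.default_rng(1)
        d = pc.AVCloud(rng.normal(0, 4, (20, 3)), np.zeros(3), 0.9)
        a = pc.AVCloud(rng.normal(45, 4, (20, 3)), np.zeros(3), 0.9)
        assert (pc.mean_fret(d, a, r0=51.0).mean_e
                == pytest.approx(pc.mean_fret(a, d, r0=51.0).mean_e, rel=1e-12))

    def test_decreasing_under_dilation(self):
        rng = np.random.default_rng(2)
        pts_d = rng.normal(0, 3, (15, 3))
        pts_a = rng.normal(40, 3, (15, 3))
        es = []
        for scale in (1.0, 1.3, 1.8):
            d = pc.AVCloud(pts_d * scale, np.zeros(3), 0.9)
            a = pc.AVCloud(pts_a * scale, np.zeros(3), 0.9)
            es.append(pc.mean_fret(d, a, r0=51.0).mean_e)
        assert es[0] > es[1] > es[2]

    def test_monte_carlo_close_to_exhaustive(self):
        rng = np.random.default_rng(3)
        pts_d = rng.normal(0, 5, (60, 3))
        pts_a = rng.normal(48, 5, (60, 3))
        d = pc.AVCloud(pts_d, np.zeros(3), 0.9)
        a = pc.AVCloud(pts_a, np.zeros(3), 0.9)
        exact = pc.mean_fret(d, a, r0=51.0, n_samples=10_000)  # 3600 pairs: exhaustive
        n_mc = 2000
        mc = pc.mean_fret(d, a, r0=51.0, n_samples=n_mc, seed=4)
        # per-pair E values have sd < 0.5; 3 sigma/sqrt(n) envelope
        assert abs(mc.mean_e - exact.mean_e) < 3 * 0.5 / np.sqrt(n_mc)
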