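import numpy as np
import pytest

from ensitemap.mapping import (
    SceneStyle,
    centroid_color,
    emit_scene,
    map_sites_to_reference,
    parse_scene,
    region_report,
    select_residues,
    style_spheres,
)
from ensitemap.pocket_grid import PocketSite
from ensitemap.probe_consensus import ProbePose, build_consensus_sites, cluster_probe_poses
from ensitemap.structure_io import Ensemble
from ensitemap.synthetic import make_toy_protein

from conftest import random_rigid_transform


def cs_at(center, rank=1, n_clusters=1):
    poses = [ProbePose("EOH", np.asarray(center, float).reshape(1, 3), score=1.0)]
    sites = build_consensus_sites(cluster_probe_poses(poses))
    sites[0].rank = rank
    return sites[0]


def pocket_at(points, rank=1):
    points = np.atleast_2d(np.asarray(points, float))
    return PocketSite(
        points=points, point_count=len(points), volume=float(len(points)),
        centroid=points.mean(axis=0), rank=rank,
    )


def rigid_copy_ensemble(base, n, seed):
    rng = np.random.default_rng(seed)
    members = [base]
    transforms = [(np.eye(3), np.zeros(3))]
    for i in range(1, n):
        R, t = random_rigid_transform(rng)
        m = base.with_coords(base.coords() @ R.T + t)
        m.model_id = i + 1
        members.append(m)
        transforms.append((R, t))
    return Ensemble(members=members), transforms


class TestMapToReference:
    def test_homologous_sites_coincide_after_mapping(self, toy_protein):
        """Rigid copies each carry the 'same' site in their own frame; mapping
        back to the reference collapses them onto one point."""
        anchor = np.array([5.0, 2.0, 3.0])
        ens, transforms = rigid_copy_ensemble(toy_protein, 4, seed=10)
        member_cs = []
        for R, t in transforms:
            member_cs.append([cs_at(R @ anchor + t)])
        mapped = map_sites_to_reference(ens, member_cs, [[] for _ in range(4)],
                                        reference_index=0, fit_sel="name CA")
        centers = np.array([s.center for s in mapped.consensus])
        np.testing.assert_allclose(centers, np.tile(anchor, (4, 1)), atol=1e-6)

    def test_reference_sites_unchanged_exactly(self, toy_protein):
        ens, _ = rigid_copy_ensemble(toy_protein, 3, seed=11)
        anchor = np.array([1.0, 2.0, 3.0])
        member_cs = [[cs_at(anchor)], [], []]
        mapped = map_sites_to_reference(ens, member_cs, [[], [], []],
                                        reference_index=0, fit_sel="name CA")
        ref_sites = [s for s in mapped.consensus if s.member_index == 0]
        np.testing.assert_array_equal(ref_sites[0].center, anchor)

    def test_hinge_site_spread_matches_analytic_displacement(self, toy_protein):
        """A site riding the mobile domain spreads by the hinge chord length
        when members are fitted on the fixed domain only."""
        theta = np.deg2rad(20.0)
        coords = toy_protein.coords()
        from ensitemap.structure_io import select_atoms

        dom2 = select_atoms(toy_protein, "resseq 13-24")
        pivot = coords[select_atoms(toy_protein, "name CA and resseq 13")][0]
        Rz = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        moved = coords.copy()
        moved[dom2] = (coords[dom2] - pivot) @ Rz.T + pivot
        hinged = toy_protein.with_coords(moved)
        hinged.model_id = 2
        ens = Ensemble(members=[toy_protein, hinged])
        site = pivot + np.array([4.0, 0.0, 0.0])  # rides domain 2, off-axis
        site_moved = (site - pivot) @ Rz.T + pivot
        mapped = map_sites_to_reference(
            ens, [[cs_at(site)], [cs_at(site_moved)]], [[], []],
            reference_index=0, fit_sel="name CA and resseq 1-12",
        )
        centers = [s.center for s in mapped.consensus]
        spread = np.linalg.norm(centers[1] - centers[0])
        expected = 2.0 * np.sin(theta / 2.0) * 4.0  # chord at radius 4 Å
        assert spread == pytest.approx(expected, abs=1e-6)

    def test_pocket_points_transform_with_member(self, toy_protein):
        ens, transforms = rigid_copy_ensemble(toy_protein, 2, seed=12)
        R, t = transforms[1]
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        member_pockets = [[], [pocket_at(pts @ R.T + t)]]
        mapped = map_sites_to_reference(ens, [[], []], member_pockets,
                                        reference_index=0, fit_sel="name CA")
        np.testing.assert_allclose(mapped.pockets[0].points, pts, atol=1e-6)


class TestStyling:
    def test_paper_rule_largest_sphere_equals_n_displayed(self):
        """With 5 spheres displayed the rank-1 sphere has radius 5 Å."""
        style = SceneStyle(n_spheres_displayed=5)
        glyphs = style_spheres([cs_at([0, 0, 0], rank=1)], style, 1, 10)
        assert glyphs[0].radius == pytest.approx(5.0)

    def test_linear_decrement_to_rank_five(self):
        style = SceneStyle(n_spheres_displayed=5)
        sites = [cs_at([float(i), 0, 0], rank=i) for i in range(1, 6)]
        glyphs = style_spheres(sites, style, 1, 2)
        assert [g.radius for g in glyphs] == [5.0, 4.0, 3.0, 2.0, 1.0]

    def test_radius_floor(self):
        style = SceneStyle(n_spheres_displayed=12)
        glyphs = style_spheres([cs_at([0, 0, 0], rank=12)], style, 1, 1)
        assert glyphs[0].radius == pytest.approx(12 - 11 * 1.0)
        style2 = SceneStyle(n_spheres_displayed=3, largest_sphere_radius=1.0)
        glyphs2 = style_spheres([cs_at([0, 0, 0], rank=3)], style2, 1, 1)
        assert glyphs2[0].radius == pytest.approx(0.5)  # floored

    def test_ranks_beyond_display_count_hidden(self):
        style = SceneStyle(n_spheres_displayed=2)
        sites = [cs_at([float(i), 0, 0], rank=i) for i in range(1, 6)]
        assert len(style_spheres(sites, style, 1, 1)) == 2

    def test_centroid_colors_red_to_blue(self):
        assert centroid_color(1, 10) == (1.0, 0.0, 0.0)
        assert centroid_color(10, 10) == (0.0, 0.0, 1.0)
        mid = centroid_color(5, 9)
        assert mid == pytest.approx((0.5, 0.0, 0.5))
        assert centroid_color(1, 1) == (1.0, 0.0, 0.0)


class TestSelectResidues:
    def test_atom_within_cutoff_selected(self, toy_protein):
        # residue 1 has its N atom at (-1.2, 0, 0.9): within 3 Å of the origin
        sel = select_residues([toy_protein], [[cs_at([0.0, 0.0, 0.0])]], [[]], cutoff=3.0)
        assert ("A", 1, "", "ALA") in sel.probe_only

    def test_one_angstrom_cutoff_selects_nothing(self, toy_protein):
        """All toy atoms sit more than 1 Å from the site by construction."""
        sel = select_residues([toy_protein], [[cs_at([0.0, 2.5, 0.0])]], [[]], cutoff=1.0)
        assert sel.probe_only == set()

    def test_cutoffs_nest(self, toy_protein):
        sets = []
        for cutoff in (1.0, 2.0, 3.0, 4.0):
            sel = select_residues(
                [toy_protein], [[cs_at([0.0, 2.5, 0.0])]], [[]], cutoff=cutoff
            )
            sets.append(sel.probe_only)
        for small, large in zip(sets, sets[1:]):
            assert small <= large

    def test_duplicates_removed_across_identical_members(self, toy_protein):
        cs = [cs_at([0.0, 0.0, 0.0])]
        one = select_residues([toy_protein], [cs], [[]], cutoff=3.0)
        many = select_residues(
            [toy_protein] * 5, [cs] * 5, [[]] * 5, cutoff=3.0
        )
        assert many.probe_only == one.probe_only

    def test_both_is_intersection(self, toy_protein):
        cs = [cs_at([0.0, 0.0, 0.0])]
        pockets = [pocket_at([[0.0, 0.0, 0.0], [20.0, 10.0, 0.0]])]
        sel = select_residues([toy_protein], [cs], [pockets], cutoff=3.0)
        assert sel.both == sel.probe_only & sel.pocket_only
        assert sel.pocket_only >= sel.probe_only  # pocket points include the CS spot


class TestScene:
    def _mapped(self, toy_protein):
        ens, transforms = rigid_copy_ensemble(toy_protein, 2, seed=13)
        member_cs = [
            [cs_at([0.0, 0.0, 0.0], rank=1), cs_at([8.0, 0.0, 0.0], rank=2)], []
        ]
        member_pockets = [[], [pocket_at([[1.0, 1.0, 1.0], [1.0, 1.0, 2.0]])]]
        return map_sites_to_reference(ens, member_cs, member_pockets,
                                      reference_index=0, fit_sel="name CA")

    def test_element_count(self, toy_protein, tmp_path):
        mapped = self._mapped(toy_protein)
        scene_path, _ = emit_scene(mapped, SceneStyle(), tmp_path)
        elements = parse_scene(scene_path)
        assert len(elements) == 3  # 2 consensus spheres + 1 pocket surface

    def test_rerun_byte_identical(self, toy_protein, tmp_path):
        mapped = self._mapped(toy_protein)
        style = SceneStyle()
        p1, t1 = emit_scene(mapped, style, tmp_path / "a")
        p2, t2 = emit_scene(mapped, style, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()
        assert t1.read_bytes() == t2.read_bytes()

    def test_roundtrip_matches_style_spheres(self, toy_protein, tmp_path):
        mapped = self._mapped(toy_protein)
        style = SceneStyle(n_spheres_displayed=5)
        scene_path, _ = emit_scene(mapped, style, tmp_path)
        spheres = [e for e in parse_scene(scene_path) if e["element"] == "sphere"]
        expected = style_spheres(
            [s for s in mapped.consensus], style, 1, mapped.n_centroids
        )
        assert len(spheres) == len(expected)
        for got, want in zip(spheres, expected):
            assert got["radius"] == pytest.approx(want.radius, abs=1e-3)
            assert got["rgb"] == pytest.approx(want.rgb, abs=1e-3)


class TestRegionReport:
    def test_two_distant_pockets_make_two_regions(self, toy_protein):
        cs = [cs_at([0.0, 0.0, 0.0]), cs_at([26.0, 10.0, 0.0])]
        sel = select_residues([toy_protein], [cs], [[]], cutoff=3.5)
        df = region_report(sel, toy_protein, which="probe", link_cutoff=8.0)
        regions = df["region"].unique().tolist()
        assert len(regions) == 2
        lists = [set(df[df["region"] == r]["residues"].iloc[0].split(", "))
                 for r in regions]
        assert lists[0].isdisjoint(lists[1])

    def test_empty_selection_empty_table(self, toy_protein):
        sel = select_residues([toy_protein], [[]], [[]], cutoff=3.0)
        df = region_report(sel, toy_protein, which="both")
        assert len(df) == 0

    def test_single_blob_single_region(self, toy_protein):
        cs = [cs_at([0.0, 0.0, 0.0])]
        sel = select_residues([toy_protein], [cs], [[]], cutoff=4.0)
        df = region_report(sel, toy_protein, which="probe", link_cutoff=10.0)
        assert df["region"].nunique() == 1
        assert df["region"].iloc[0] == "A"
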