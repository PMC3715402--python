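import numpy as np
import pytest

from ensitemap.pocket_grid import (
    Grid,
    RetentionParams,
    SitePointSet,
    build_grid,
    characterize_site,
    export_density_grid,
    export_sites_pdb,
    find_pockets,
    group_site_points,
    retain_site_points,
)
from ensitemap.structure_io import AtomRecord, Structure, assign_vdw_radii, read_pdb
from ensitemap.synthetic import make_toy_protein

from conftest import random_rigid_transform


def atom(x, y, z, element="C", radius=None, name="C", resname="ALA", resseq=1,
         serial=1):
    defaults = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
    return AtomRecord(
        serial=serial, name=name, altloc="", resname=resname, chain="A",
        resseq=resseq, icode="", x=x, y=y, z=z, element=element,
        vdw_radius=radius if radius is not None else defaults[element],
    )


def single_point_grid(x, y, z):
    return Grid(origin=np.array([x, y, z]), spacing=1.0, dims=(1, 1, 1))


def retention_oracle(grid, s, params):
    """Brute force: every grid point against every atom, no spatial index."""
    pts = grid.points()
    coords = s.coords()
    radii = s.vdw_radii()
    retained = []
    for i, p in enumerate(pts):
        d = np.linalg.norm(coords - p, axis=1)
        if np.any(d <= radii):
            continue
        if params.mode == "nearest":
            j = int(np.argmin(d))
            ok = d[j] ** 2 < params.ratio_max * radii[j] ** 2
        else:
            ok = bool(np.any(d**2 < params.ratio_max * radii**2))
        if ok:
            retained.append(i)
    return retained


def bfs_components(mask, connectivity):
    """Breadth-first-search connected components on a boolean 3D mask."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    dims = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            cur = queue.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= nb[a] < dims[a] for a in range(3)) and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


class TestBuildGrid:
    def test_covers_vdw_envelope_plus_padding(self):
        s = Structure(atoms=[atom(0.0, 0.0, 0.0)])  # carbon, r = 1.7
        g = build_grid(s, spacing=1.0, padding=2.0)
        lo = g.origin
        hi = g.origin + g.spacing * (np.array(g.dims) - 1)
        assert np.all(lo <= -3.7 + 1e-9)
        assert np.all(hi >= 3.7 - 1e-9)

    def test_halving_spacing_roughly_doubles_dims(self, toy_protein):
        s = assign_vdw_radii(toy_protein)
        g1 = build_grid(s, spacing=1.0, padding=2.0)
        g2 = build_grid(s, spacing=0.5, padding=2.0)
        for a, b in zip(g1.dims, g2.dims):
            assert abs(b - 2 * a) <= 2

    def test_empty_structure_and_bad_spacing_raise(self):
        with pytest.raises(ValueError):
            build_grid(Structure(atoms=[]), spacing=1.0)
        with pytest.raises(ValueError):
            build_grid(Structure(atoms=[atom(0, 0, 0)]), spacing=0.0)


class TestRetention:
    def test_sheltered_point_near_carbon_retained(self):
        s = Structure(atoms=[atom(0.0, 0.0, 0.0)])
        sp = retain_site_points(single_point_grid(2.0, 0.0, 0.0), s)
        assert sp.n_retained == 1  # 4.00 / 2.89 = 1.384 < 2.5

    def test_exposed_point_eliminated(self):
        s = Structure(atoms=[atom(0.0, 0.0, 0.0)])
        sp = retain_site_points(single_point_grid(3.0, 0.0, 0.0), s)
        assert sp.n_retained == 0  # 9.00 / 2.89 = 3.114 >= 2.5

    def test_point_inside_vdw_sphere_eliminated(self):
        s = Structure(atoms=[atom(0.0, 0.0, 0.0)])
        sp = retain_site_points(single_point_grid(1.0, 0.0, 0.0), s)
        assert sp.n_retained == 0

    @pytest.mark.parametrize("ratio,expected", [(2.49, 1), (2.50, 0), (2.51, 0)])
    def test_ratio_boundary_is_strict(self, ratio, expected):
        """d chosen so d²/r² hits exactly 2.49 / 2.50 / 2.51; only < 2.5 survives."""
        r = 1.70
        d = np.sqrt(ratio) * r
        s = Structure(atoms=[atom(0.0, 0.0, 0.0)])
        sp = retain_site_points(single_point_grid(d, 0.0, 0.0), s)
        assert sp.n_retained == expected

    @pytest.mark.parametrize("mode", ["nearest", "any"])
    def test_matches_brute_force_oracle(self, mode):
        rng = np.random.default_rng(2024)
        params = RetentionParams(mode=mode, min_site_points=1)
        for case in range(50):
            n_atoms = int(rng.integers(2, 8))
            atoms = [
                atom(*rng.uniform(-3, 3, 3), radius=float(rng.uniform(1.2, 2.0)),
                     serial=i + 1, resseq=i + 1)
                for i in range(n_atoms)
            ]
            s = Structure(atoms=atoms)
            g = build_grid(s, spacing=0.9, padding=1.5)
            sp = retain_site_points(g, s, params)
            assert list(sp.retained) == retention_oracle(g, s, params)

    def test_nearest_atom_annotation(self):
        s = Structure(atoms=[atom(0.0, 0.0, 0.0), atom(10.0, 0.0, 0.0, serial=2, resseq=2)])
        sp = retain_site_points(single_point_grid(8.0, 0.0, 0.0), s)
        assert sp.n_retained == 1
        assert sp.nearest_atom[0] == 1
        assert sp.nearest_dist[0] == pytest.approx(2.0)


class TestGrouping:
    @staticmethod
    def _point_set(mask):
        grid = Grid(origin=np.zeros(3), spacing=1.0, dims=mask.shape)
        flat = np.nonzero(mask.ravel())[0]
        return SitePointSet(
            grid=grid, retained=flat,
            nearest_atom=np.zeros(len(flat), dtype=int),
            nearest_dist=np.zeros(len(flat)),
        )

    def test_two_separated_blobs_make_two_sites(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[0:2, 0:2, 0:2] = True
        mask[6:8, 6:8, 6:8] = True
        sites = group_site_points(self._point_set(mask), RetentionParams(min_site_points=1))
        assert len(sites) == 2
        assert all(s.point_count == 8 for s in sites)

    def test_single_point_site_volume(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        sp = self._point_set(mask)
        sites = group_site_points(sp, RetentionParams(min_site_points=1))
        assert len(sites) == 1
        assert sites[0].volume == pytest.approx(sp.grid.spacing**3)

    def test_min_site_points_drops_small_components(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0:3, 0:3, 0:3] = True  # 27 points
        mask[6, 6, 6] = True        # singleton
        sites = group_site_points(self._point_set(mask), RetentionParams(min_site_points=5))
        assert len(sites) == 1
        assert sites[0].point_count == 27

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_bfs_oracle(self, connectivity):
        rng = np.random.default_rng(555)
        params = RetentionParams(min_site_points=1, connectivity=connectivity)
        n_cases = 100 if connectivity == 26 else 20
        for _ in range(n_cases):
            mask = rng.random((10, 10, 10)) < 0.12
            sites = group_site_points(self._point_set(mask), params)
            got = {
                frozenset(
                    tuple(np.round((p - 0.0)).astype(int)) for p in s.points
                )
                for s in sites
            }
            assert got == bfs_components(mask, connectivity)

    def test_sites_ordered_by_size_then_centroid(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[0:3, 0:3, 0:3] = True   # 27
        mask[8:10, 8:10, 8:10] = True  # 8
        sites = group_site_points(self._point_set(mask), RetentionParams(min_site_points=1))
        assert [s.point_count for s in sites] == [27, 8]
        assert [s.rank for s in sites] == [1, 2]


class TestCharacterize:
    def test_planted_lining_composition(self, hinge_fixture, hinge_fixture_radii):
        """Open pocket lined by 3 LEU + 1 SER -> hydrophobic fraction 0.75."""
        s = hinge_fixture_radii[0]
        sites = find_pockets(s, contact_cutoff=4.0)
        anchor = hinge_fixture.pocket_anchor
        pocket = min(
            sites, key=lambda x: np.linalg.norm(x.points - anchor, axis=1).min()
        )
        # keep only the points in the planted cavity to isolate its lining
        near = pocket.points[np.linalg.norm(pocket.points - anchor, axis=1) <= 2.0]
        from ensitemap.pocket_grid import PocketSite

        cavity = PocketSite(points=near, point_count=len(near),
                            volume=len(near) * 0.35**3, centroid=near.mean(axis=0))
        characterize_site(cavity, s, contact_cutoff=4.0)
        resnames = sorted(c[3] for c in cavity.contact_residues)
        assert resnames == ["LEU", "LEU", "LEU", "SER"]
        assert cavity.hydrophobic_fraction == pytest.approx(0.75)

    def test_no_contacts_flagged(self, toy_protein):
        from ensitemap.pocket_grid import PocketSite

        s = assign_vdw_radii(toy_protein)
        far = np.array([[200.0, 200.0, 200.0]])
        site = PocketSite(points=far, point_count=1, volume=1.0, centroid=far[0])
        characterize_site(site, s, contact_cutoff=4.0)
        assert site.no_contacts
        assert site.hydrophobic_fraction == 0.0
        assert site.contact_residues == []

    def test_doubling_cutoff_grows_contact_set(self, hinge_fixture_radii):
        s = hinge_fixture_radii[0]
        sites = find_pockets(s)
        small = set(map(tuple, characterize_site(sites[0], s, 3.0).contact_residues))
        large = set(map(tuple, characterize_site(sites[0], s, 6.0).contact_residues))
        assert small <= large


class TestRigidInvariance:
    def test_transforming_receptor_transforms_sites(self):
        rng = np.random.default_rng(31)
        s = assign_vdw_radii(make_toy_protein(n_residues=10, seed=5))
        R, t = random_rigid_transform(rng)
        s_rot = s.with_coords(s.coords() @ R.T + t)
        params = RetentionParams(min_site_points=5)
        sites = find_pockets(s, spacing=0.5, params=params)
        sites_rot = find_pockets(s_rot, spacing=0.5, params=params)
        n = sum(x.point_count for x in sites)
        n_rot = sum(x.point_count for x in sites_rot)
        assert abs(n_rot - n) <= max(0.02 * n, 2)  # grid-discretization tolerance
        # the dominant site's centroid moves with the receptor
        np.testing.assert_allclose(
            R @ sites[0].centroid + t, sites_rot[0].centroid, atol=0.5
        )


class TestTransientPocket:
    def test_pocket_found_exactly_in_open_members(self, hinge_fixture, hinge_fixture_radii):
        """The ensemble-only detection mechanism: a cavity present in a subset
        of conformations yields a site at the anchor only in that subset."""
        anchor = hinge_fixture.pocket_anchor
        detected = []
        for i, s in enumerate(hinge_fixture_radii):
            sites = find_pockets(s)
            hit = any(
                np.linalg.norm(site.points - anchor, axis=1).min() <= 2.0
                for site in sites
            )
            detected.append(i if hit else None)
        assert [i for i in detected if i is not None] == list(hinge_fixture.open_members)


class TestExports:
    def test_sites_pdb_roundtrip(self, tmp_path, hinge_fixture_radii):
        s = hinge_fixture_radii[0]
        sites = find_pockets(s, params=RetentionParams(min_site_points=15))
        path = tmp_path / "merged.pdb"
        export_sites_pdb(sites, s, path)
        back = read_pdb(path).members[0]
        het = [a for a in back.atoms if a.het]
        assert len(het) == sum(x.point_count for x in sites)
        assert {a.resname for a in het} == {"SIT"}
        all_points = np.vstack([x.points for x in sites])
        np.testing.assert_allclose(
            np.array([a.coords for a in het]), all_points, atol=1e-3
        )

    def test_zero_sites_receptor_only(self, tmp_path, toy_protein):
        s = assign_vdw_radii(toy_protein)
        path = tmp_path / "none.pdb"
        export_sites_pdb([], s, path)
        back = read_pdb(path).members[0]
        assert back.n_atoms == s.n_atoms

    def test_density_grid_export(self, tmp_path):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        sp = TestGrouping._point_set(mask)
        path = tmp_path / "density.txt"
        export_density_grid(sp, path)
        lines = path.read_text().splitlines()
        header = [ln for ln in lines if ln.startswith("#")]
        values = [int(ln) for ln in lines if not ln.startswith("#")]
        assert any("isovalue 0.5" in h for h in header)
        assert sum(values) == 1
        assert len(values) == 27
        assert values[13] == 1  # (1,1,1) in C order
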