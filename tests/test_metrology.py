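"""Vessel metrology: centerlines, diameters, selection and inter-vessel distance."""

import numpy as np
import pytest
from scipy import ndimage

import choroid3d as c3
from choroid3d import metrology as vm
from choroid3d.errors import ValidationError

from conftest import SP, VOXEL_DIAG, two_tube_spec


class TestExtractComponents:
    def test_single_tube_radius_profile(self, single_tube_phantom):
        _, _, _, comps = single_tube_phantom
        assert len(comps) == 1
        median_r = float(np.median(comps[0].radius_profile_um))
        assert abs(median_r - 100.0) <= VOXEL_DIAG

    def test_two_disjoint_tubes_give_two_components(self):
        _, gt = c3.generate_phantom(two_tube_spec(gap_um=300.0))
        vlv = c3.label_components(gt.luminal_mask)
        comps = c3.extract_components(vlv, SP)
        assert len(comps) == 2
        paths = [set(map(tuple, c.path)) for c in comps]
        assert not (paths[0] & paths[1])

    def test_digital_ball_edt_matches_brute_force(self):
        # isotropic 1 µm grid; compare scipy's EDT maximum against a direct
        # min-distance-to-background computation
        from skimage.morphology import ball

        m = np.pad(ball(5).astype(bool), 3)
        edt = ndimage.distance_transform_edt(m, sampling=(1.0, 1.0, 1.0))
        bg = np.argwhere(~m)
        center = np.array(m.shape) // 2
        brute = np.min(np.linalg.norm(bg - center, axis=1))
        assert edt[tuple(center)] == pytest.approx(brute, abs=1e-9)
        assert edt.max() == pytest.approx(brute, abs=1e-9)

    def test_components_in_excluded_columns_are_dropped(self, single_tube_phantom):
        _, gt, vlv, _ = single_tube_phantom
        ny, nx = gt.luminal_mask.shape[:2]
        disc = np.zeros((ny, nx), bool)
        disc[:, :] = True
        grid = c3.build_sector_grid(
            (ny, nx), SP[:2], (ny // 2, nx // 2), "OD", disc=c3.DiscMask(disc)
        )
        assert c3.extract_components(vlv, SP, grid) == []


class TestRepresentativeDiameter:
    def test_uniform_tube_sites_near_design(self, single_tube_phantom):
        _, _, _, comps = single_tube_phantom
        sites, d, flags = c3.representative_diameter(comps[0])
        assert flags == []
        assert len(sites) == 3
        for s in sites:
            assert abs(s - 200.0) <= max(0.1 * 200.0, VOXEL_DIAG)
        assert abs(d - 200.0) <= max(0.1 * 200.0, VOXEL_DIAG)

    def test_tapering_tube_sites_are_ordered(self):
        # cone from 200 µm down to 100 µm on a fine isotropic grid
        pts = tuple((128.0, x, 240.0) for x in np.linspace(100.0, 1100.0, 26))
        # piecewise-constant approximation of a taper: stack tubes of
        # decreasing diameter
        specs = []
        for i in range(25):
            dia = 200.0 - 100.0 * (i + 0.5) / 25
            specs.append(
                c3.VesselSpec(centerline=(pts[i], pts[i + 1]), diameter=dia)
            )
        spec = c3.PhantomSpec(
            grid_shape=(64, 320, 128),
            spacing=(4.0, 4.0, 4.0),
            inner_depth=60.0,
            choroid_thickness=380.0,
            vessels=tuple(specs),
        )
        _, gt = c3.generate_phantom(spec)
        vlv = c3.label_components(gt.luminal_mask)
        comps = c3.extract_components(vlv, (4.0, 4.0, 4.0))
        assert len(comps) == 1  # segments merge into one tapered vessel
        sites, d, _ = c3.representative_diameter(comps[0])
        ordered = list(sites)
        assert ordered == sorted(ordered) or ordered == sorted(ordered, reverse=True)
        assert d == pytest.approx(150.0, rel=0.15)

    def test_single_voxel_component_flagged(self):
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        comps = c3.extract_components(c3.label_components(m), (1.0, 1.0, 1.0))
        sites, d, flags = c3.representative_diameter(comps[0])
        assert "short_skeleton" in flags
        assert len(set(np.round(sites, 9))) == 1


class TestSelection:
    def _ladder_components(self, ladder_components):
        return ladder_components

    def test_three_largest_selected_from_ladder(self, ladder_components):
        _, comps = ladder_components
        selected, flags = c3.select_three_largest(comps, sector=None)
        assert flags == []
        est = [c3.representative_diameter(c)[1] for c in selected]
        assert est[0] > est[1] > est[2]
        assert est[0] == pytest.approx(300.0, abs=max(30.0, VOXEL_DIAG))
        assert est[2] == pytest.approx(200.0, abs=max(20.0, VOXEL_DIAG))

    def test_sub_floor_vessels_yield_empty_selection(self):
        spec = c3.PhantomSpec(
            grid_shape=(96, 192, 192), spacing=SP, inner_depth=100.0, choroid_thickness=520.0,
            vessels=(
                c3.straight_tube(384.0, 360.0, 90.0, 200.0, 2000.0),
                c3.straight_tube(768.0, 360.0, 95.0, 200.0, 2000.0),
            ),
        )
        _, gt = c3.generate_phantom(spec)
        comps = c3.extract_components(c3.label_components(gt.luminal_mask), SP)
        selected, flags = c3.select_three_largest(comps, sector=None)
        assert selected == []
        assert "insufficient_vessels" in flags

    def test_exactly_three_qualifying_all_selected(self):
        spec = c3.PhantomSpec(
            grid_shape=(128, 160, 192), spacing=SP, inner_depth=100.0, choroid_thickness=520.0,
            vessels=tuple(
                c3.straight_tube(300.0 + 400.0 * i, 360.0, d, 200.0, 1700.0)
                for i, d in enumerate((150.0, 200.0, 250.0))
            ),
        )
        _, gt = c3.generate_phantom(spec)
        comps = c3.extract_components(c3.label_components(gt.luminal_mask), SP)
        selected, flags = c3.select_three_largest(comps, sector=None)
        assert len(selected) == 3
        assert flags == []


class TestIVD:
    @pytest.mark.parametrize("gap", [150.0, 300.0])
    def test_parallel_tubes_recover_designed_gap(self, gap):
        _, gt = c3.generate_phantom(two_tube_spec(gap_um=gap))
        vlv = c3.label_components(gt.luminal_mask)
        comps = c3.extract_components(vlv, SP)
        selected, _ = c3.select_three_largest(comps, None)
        ivds, flags, _ = c3.compute_ivd(selected, comps, vlv, SP)
        assert flags == []
        for v in ivds:
            assert abs(v - gap) <= VOXEL_DIAG

    def test_single_vessel_reports_missing_never_zero(self, single_tube_phantom):
        _, _, vlv, comps = single_tube_phantom
        selected, _ = c3.select_three_largest(comps, None)
        ivds, flags, _ = c3.compute_ivd(selected, comps, vlv, SP)
        assert ivds == []
        assert "no_neighbor" in flags

    def test_site_values_match_brute_force_surface_distance(self):
        # two parallel tubes: every site's IVD equals the brute-force minimum
        # distance between the two components' surface voxel sets
        _, gt = c3.generate_phantom(two_tube_spec(gap_um=200.0))
        vlv = c3.label_components(gt.luminal_mask)
        comps = c3.extract_components(vlv, SP)
        selected, _ = c3.select_three_largest(comps, None)
        ivds, _, _ = c3.compute_ivd(selected, comps, vlv, SP)

        sp = np.asarray(SP)
        surfs = []
        for cid in (1, 2):
            m = vlv.labels == cid
            er = ndimage.binary_erosion(m)
            surfs.append((np.argwhere(m & ~er) + 0.5) * sp)
        from scipy.spatial import cKDTree

        brute = float(cKDTree(surfs[1]).query(surfs[0])[0].min())
        for v in ivds:
            assert v == pytest.approx(brute, abs=VOXEL_DIAG)

    def test_nearest_neighbor_differs_per_site(self):
        # long tube A with neighbors B (left end) and C (right end) at
        # different designed gaps: end sites must see different distances
        vessels = (
            c3.straight_tube(600.0, 360.0, 160.0, 200.0, 2000.0),  # A
            c3.straight_tube(880.0, 360.0, 120.0, 200.0, 600.0),   # B near left end
            c3.straight_tube(1100.0, 360.0, 120.0, 1600.0, 2000.0),  # C near right end
        )
        spec = c3.PhantomSpec(
            grid_shape=(128, 192, 192), spacing=SP, inner_depth=100.0,
            choroid_thickness=520.0, vessels=vessels,
        )
        _, gt = c3.generate_phantom(spec)
        vlv = c3.label_components(gt.luminal_mask)
        comps = c3.extract_components(vlv, SP)
        a = next(c for c in comps if c.size == max(x.size for x in comps))
        ivds, _, recs = c3.compute_ivd([a], comps, vlv, SP)
        assert len(ivds) == 3
        gap_ab = 880.0 - 600.0 - 80.0 - 60.0  # 140 µm
        gap_ac = 1100.0 - 600.0 - 80.0 - 60.0  # 360 µm
        assert min(ivds) == pytest.approx(gap_ab, abs=2 * VOXEL_DIAG)
        assert max(ivds) <= gap_ac + 2 * VOXEL_DIAG


class TestMeasureSector:
    def test_three_equal_tubes_mean_of_nine(self):
        spec = c3.PhantomSpec(
            grid_shape=(128, 160, 192), spacing=SP, inner_depth=100.0, choroid_thickness=520.0,
            vessels=tuple(
                c3.straight_tube(300.0 + 400.0 * i, 360.0, 200.0, 200.0, 1700.0)
                for i in range(3)
            ),
        )
        _, gt = c3.generate_phantom(spec)
        vlv = c3.label_components(gt.luminal_mask)
        comps = c3.extract_components(vlv, SP)
        m = c3.measure_sector(None, comps, vlv, SP)
        assert len(m.diameters_um) == 9
        assert m.mchvd_um == pytest.approx(200.0, abs=max(0.1 * 200, VOXEL_DIAG))
        assert m.mchvd_um == pytest.approx(np.mean(m.diameters_um))

    def test_empty_sector_all_missing_with_flags(self):
        m = c3.measure_sector(None, [], c3.label_components(np.zeros((4, 4, 4), bool)), SP)
        assert np.isnan(m.mchvd_um) and np.isnan(m.ivd_um)
        assert "insufficient_vessels" in m.flags

    def test_mean_of_nine_equals_mean_of_vessel_means(self, ladder_components):
        vlv, comps = ladder_components
        m = c3.measure_sector(None, comps, vlv, SP)
        per_vessel = [
            c3.representative_diameter(c)[1]
            for c in comps
            if c.id in m.vessel_ids
        ]
        assert m.mchvd_um == pytest.approx(np.mean(per_vessel), abs=1e-9)

    def test_measurements_are_deterministic(self, ladder_components):
        vlv, comps = ladder_components
        a = c3.measure_sector(None, comps, vlv, SP)
        b = c3.measure_sector(None, comps, vlv, SP)
        assert a.vessel_ids == b.vessel_ids
        assert a.diameters_um == b.diameters_um
        assert a.ivds_um == b.ivds_um


def test_orientation_invariance_of_diameter():
    # the same tube along x and along y must measure alike (discretization only)
    base = dict(inner_depth=100.0, choroid_thickness=520.0, spacing=SP)
    along_x = c3.PhantomSpec(
        grid_shape=(64, 160, 192),
        vessels=(c3.straight_tube(384.0, 360.0, 200.0, 200.0, 1700.0),), **base,
    )
    along_y = c3.PhantomSpec(
        grid_shape=(160, 64, 192),
        vessels=(
            c3.VesselSpec(centerline=((200.0, 384.0, 360.0), (1700.0, 384.0, 360.0)), diameter=200.0),
        ),
        **base,
    )
    results = []
    for spec in (along_x, along_y):
        _, gt = c3.generate_phantom(spec)
        comps = c3.extract_components(c3.label_components(gt.luminal_mask), SP)
        results.append(c3.representative_diameter(comps[0])[1])
    assert abs(results[0] - results[1]) / results[0] < 0.05


def test_mchvd_strictly_monotone_on_ladder(ladder_components):
    _, comps = ladder_components
    est = [c3.representative_diameter(c)[1] for c in comps]
    assert all(a < b for a, b in zip(est, est[1:]))
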