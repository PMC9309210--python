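import numpy as np
import pytest

from tmsdose import efield as ef
from tmsdose import headmodel as hm
from tmsdose import synthdata as sd


def line_current_primary(placement, dIdt, pts_mm, wing_radius=27.0, sep=40.0,
                         n_seg=720):
    """Independent oracle: E_p of two opposite-sense circular line currents
    via the Biot-Savart-type integral for the vector potential rate."""
    Rf = ef._coil_frame(placement)
    E = np.zeros((len(pts_mm), 3))
    for cx, sgn in [(sep / 2, +1.0), (-sep / 2, -1.0)]:
        t = 2 * np.pi * (np.arange(n_seg) + 0.5) / n_seg
        ring = np.stack([cx + wing_radius * np.cos(t),
                         wing_radius * np.sin(t),
                         np.zeros_like(t)], axis=1)
        world = placement.center + ring @ Rf
        nxt = np.roll(world, -1, axis=0)
        dl = (nxt - world) * 1e-3 * sgn
        mid = 0.5 * (world + nxt) * 1e-3
        d = pts_mm[:, None, :] * 1e-3 - mid[None, :, :]
        inv = 1.0 / np.linalg.norm(d, axis=2)
        E += -1e-7 * dIdt * np.einsum("pk,kj->pj", inv, dl)
    return E


@pytest.fixture(scope="module")
def placement(head):
    s = head.surfaces[sd.M1]
    target = s.vertices[hm.nearest_vertex(s, np.array([0.0, 0.0, 85.0]))]
    return hm.place_coil(head, target, 45.0)


class TestCoilModel:
    def test_single_dipole_per_wing(self):
        c = ef.build_figure8_coil(dipoles_per_wing=1, rings_per_wing=1)
        assert len(c.positions_mm) == 2
        assert np.allclose(c.moments[0], -c.moments[1])

    def test_total_moment_vanishes(self):
        c = ef.build_figure8_coil()
        assert np.abs(c.moments.sum(axis=0)).max() < 1e-12

    def test_doubling_dipoles_changes_field_little(self, head, placement):
        c1 = ef.build_figure8_coil(dipoles_per_wing=8, rings_per_wing=4)
        c2 = ef.build_figure8_coil(dipoles_per_wing=16, rings_per_wing=8)
        pt = np.array([[5.0, 3.0, 70.0]])
        e1 = ef.primary_field(c1, placement, ef.DIDT_PER_PCT_MSO, pt)
        e2 = ef.primary_field(c2, placement, ef.DIDT_PER_PCT_MSO, pt)
        assert np.linalg.norm(e1 - e2) / np.linalg.norm(e2) < 0.02

    def test_rejects_degenerate_geometry(self):
        with pytest.raises(ValueError):
            ef.build_figure8_coil(wing_radius_mm=-1.0)
        with pytest.raises(ValueError):
            ef.build_figure8_coil(dipoles_per_wing=0)


class TestPrimaryField:
    def test_zero_on_single_dipole_axis(self, placement):
        coil = ef.CoilModel(positions_mm=np.zeros((1, 3)),
                            moments=np.array([[0.0, 0.0, 1e-4]]),
                            calibration_constant=1.0)
        axis_pt = placement.center + 30.0 * placement.normal
        E = ef.primary_field(coil, placement, 1e6, axis_pt[None, :])
        assert np.abs(E).max() < 1e-12

    def test_zero_didt_gives_zero_field(self, coil, placement):
        E = ef.primary_field(coil, placement, 0.0, np.array([[0.0, 0.0, 70.0]]))
        assert np.all(E == 0)

    def test_matches_line_current_oracle(self, head, placement):
        coil = ef.build_figure8_coil(calibration_constant=1.0)
        pts = head.surfaces[sd.M1].vertices[::29]
        Ed = ef.primary_field(coil, placement, ef.DIDT_PER_PCT_MSO, pts)
        El = line_current_primary(placement, ef.DIDT_PER_PCT_MSO, pts)
        assert np.linalg.norm(Ed - El) / np.linalg.norm(El) < 0.05

    def test_point_on_dipole_rejected(self, coil, placement):
        pos, _ = ef._world_dipoles(coil, placement)
        with pytest.raises(ValueError):
            ef.primary_field(coil, placement, 1e6, pos[:1])


class TestTotalField:
    def test_interior_field_is_tangential(self, coil, head, placement):
        pts = head.surfaces[sd.M1].vertices[::11]
        E = ef.total_field(coil, placement, head, pts)
        r_hat = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        radial = np.abs(np.einsum("ij,ij->i", E, r_hat))
        assert radial.max() / np.abs(E).max() < 1e-3

    def test_exact_linearity_in_drive(self, coil, head, placement):
        pts = head.surfaces[sd.M1].vertices[::101]
        E1 = ef.total_field(coil, placement, head, pts, dIdt=ef.DIDT_PER_PCT_MSO)
        E4 = ef.total_field(coil, placement, head, pts, dIdt=4 * ef.DIDT_PER_PCT_MSO)
        assert np.array_equal(E4, 4 * E1)     # power-of-two factor: bit exact
        E7 = ef.total_field(coil, placement, head, pts, dIdt=7 * ef.DIDT_PER_PCT_MSO)
        assert np.allclose(E7, 7 * E1, rtol=1e-15, atol=0)

    def test_spectral_gradient_matches_finite_differences(self, coil, placement):
        """Dual route: the pole-safe spectral gradient of the secondary
        potential vs central differences of the potential itself."""
        L = 16
        blm = ef._neumann_coefficients(coil, placement, ef.DIDT_PER_PCT_MSO, 85.0, L)
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 60.0
        h = 1e-3
        fd = np.empty((len(pts), 3))
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            fd[:, ax] = (ef._phi_eval(blm, 85.0, pts + e)
                         - ef._phi_eval(blm, 85.0, pts - e)) / (2 * h)
        sp = ef._grad_phi(blm, 85.0, pts)
        assert np.abs(sp - fd).max() / np.abs(fd).max() < 1e-6

    def test_invalid_expansion_order(self, coil, head, placement):
        with pytest.raises(ValueError):
            ef.total_field(coil, placement, head, np.array([[0, 0, 70.0]]), L=0)

    def test_points_outside_scalp_rejected(self, coil, head, placement):
        with pytest.raises(ValueError):
            ef.total_field(coil, placement, head, np.array([[0, 0, 90.0]]))

    def test_180_degree_rotation_negates_axis_field(self, coil, head):
        s = head.surfaces[sd.M1]
        target = s.vertices[hm.nearest_vertex(s, np.array([0.0, 0.0, 85.0]))]
        a = hm.place_coil(head, target, 30.0)
        b = hm.place_coil(head, target, 210.0)
        axis = a.center / np.linalg.norm(a.center)
        pts = np.outer(np.linspace(60, 77, 5), axis)
        Ea = ef.total_field(coil, a, head, pts)
        Eb = ef.total_field(coil, b, head, pts)
        assert np.abs(Ea + Eb).max() / np.abs(Ea).max() < 1e-9


class TestDecompose:
    def test_pythagorean_example(self):
        et, etan, eperp = ef.decompose(np.array([[3.0, 4.0, 0.0]]),
                                       np.array([[0.0, 0.0, 1.0]]))
        assert (et[0], etan[0], eperp[0]) == (5.0, 5.0, 0.0)

    def test_field_parallel_to_normal(self):
        et, etan, eperp = ef.decompose(np.array([[0.0, 0.0, -2.5]]),
                                       np.array([[0.0, 0.0, 1.0]]))
        assert etan[0] == pytest.approx(0.0, abs=1e-15)
        assert eperp[0] == pytest.approx(-2.5)
        assert et[0] == pytest.approx(2.5)

    def test_identity_on_random_vectors(self):
        rng = np.random.default_rng(1)
        E = rng.normal(size=(200, 3))
        n = rng.normal(size=(200, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        et, etan, eperp = ef.decompose(E, n)
        assert np.allclose(et**2, etan**2 + eperp**2, rtol=1e-12, atol=1e-12)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError):
            ef.decompose(np.array([[1.0, 0, 0]]), np.array([[0, 0, 2.0]]))


class TestRoiStats:
    def test_nearest_rank_percentile(self):
        assert ef.nearest_rank_percentile(np.arange(1, 1001), 99.9) == 999

    def test_uniform_field_mean_equals_robust_max(self, head):
        s = head.surfaces[sd.M1]
        n = s.n_vertices
        em = ef.EFieldMap(vectors=np.zeros((n, 3)), e_total=np.full(n, 3.25),
                          e_t=np.full(n, 3.25), e_perp=np.zeros(n), pct_mso=1.0)
        st = ef.roi_stats(em, s, 0, radius_mm=10.0)
        assert st.mean_e_total == pytest.approx(3.25)
        assert st.robust_max_e_total == pytest.approx(3.25)
        assert st.robust_max_e_total >= st.mean_e_total

    def test_tiny_radius_keeps_only_center(self, head):
        s = head.surfaces[sd.M1]
        n = s.n_vertices
        vals = np.arange(n, dtype=float)
        em = ef.EFieldMap(vectors=np.zeros((n, 3)), e_total=vals, e_t=vals,
                          e_perp=np.zeros(n), pct_mso=1.0)
        st = ef.roi_stats(em, s, 17, radius_mm=0.4)
        assert st.n_vertices == 1
        assert st.mean_e_total == pytest.approx(17.0)

    def test_empty_roi_rejected(self, head):
        s = head.surfaces[sd.M1]
        em = ef.EFieldMap(vectors=np.zeros((2, 3)), e_total=np.zeros(2),
                          e_t=np.zeros(2), e_perp=np.zeros(2), pct_mso=1.0)
        with pytest.raises(ValueError):
            ef.roi_stats(em, s, 0, radius_mm=10.0,
                         vertex_indices=np.array([s.n_vertices - 1,
                                                  s.n_vertices - 2]))


class TestAngleSweep:
    def test_default_sweep_has_twelve_rows(self, coil, head):
        s = head.surfaces[sd.M1]
        target = s.vertices[hm.nearest_vertex(s, np.array([0.0, 0.0, 85.0]))]
        df, _ = ef.angle_sweep(coil, head, sd.M1, target, L=24)
        assert len(df) == 12
        assert list(df.angle_deg) == [0, 15, 30, 45, 60, 75, 90, 105, 120, 135, 150, 165]

    def test_unfolded_sphere_is_rotation_invariant(self, coil):
        params = sd.HeadParams(85.0, 78.0, {
            sd.M1: sd.RegionSpec(12.0, 0.0, (0.0, 0.0, 1.0))})
        head = hm.build_head(params)
        s = head.surfaces[sd.M1]
        target = s.vertices[np.argmax(s.vertices[:, 2])]
        df, _ = ef.angle_sweep(coil, head, sd.M1, target, L=24)
        v = df.mean_e_total.to_numpy()
        assert (v.max() - v.min()) / v.mean() < 0.01

    def test_optimal_angle_near_45_on_default_m1(self, coil, head):
        s = head.surfaces[sd.M1]
        target = s.vertices[hm.nearest_vertex(s, np.array([0.0, 0.0, 85.0]))]
        _, optimal = ef.angle_sweep(coil, head, sd.M1, target)
        assert abs(optimal - 45.0) <= 15.0


class TestIntensityScaling:
    def test_linear_scaling_examples(self):
        em = ef.EFieldMap(vectors=np.ones((4, 3)), e_total=np.full(4, 2.0),
                          e_t=np.full(4, 2.0), e_perp=np.zeros(4), pct_mso=1.0)
        assert ef.scale_to_intensity(em, 60.0).e_total[0] == pytest.approx(120.0)
        assert ef.scale_to_intensity(em, 1.0).e_total[0] == pytest.approx(2.0)
        assert ef.scale_to_intensity(em, 75.0).e_total[0] == pytest.approx(150.0)

    def test_rejects_out_of_range_intensity(self):
        em = ef.EFieldMap(vectors=np.ones((1, 3)), e_total=np.ones(1),
                          e_t=np.ones(1), e_perp=np.zeros(1), pct_mso=1.0)
        for bad in (0.0, -5.0, 101.0):
            with pytest.raises(ValueError):
                ef.scale_to_intensity(em, bad)

    def test_match_efield_intensity(self):
        assert ef.match_efield_intensity(2.5, 140.0) == pytest.approx(56.0)
        assert ef.match_efield_intensity(3.0, 3.0) == pytest.approx(1.0)
        # round trip reproduces the target exactly
        pct = ef.match_efield_intensity(2.0, 140.0)
        assert 2.0 * pct == pytest.approx(140.0, abs=1e-9)
        with pytest.raises(ValueError):
            ef.match_efield_intensity(2.0, -1.0)


class TestExports:
    def test_field_map_ply_and_csv(self, coil, head, m1_placement, tmp_path):
        import trimesh
        surf = head.surfaces[sd.M1]
        em = ef.field_map(coil, m1_placement, head, surf, L=16)
        ply = tmp_path / "map.ply"
        ef.export_field_map_ply(em, surf, ply)
        back = trimesh.load(ply, process=False)
        raw = back.metadata["_ply_raw"]["vertex"]["data"]
        assert np.allclose(raw["e_total"], em.e_total, atol=1e-4)
        csv = tmp_path / "map.csv"
        ef.export_field_map_csv(em, surf, csv)
        import pandas as pd
        df = pd.read_csv(csv)
        assert len(df) == surf.n_vertices
        assert np.allclose(df.e_total, em.e_total, rtol=1e-9)


class TestRegionContrast:
    def test_m1_like_roi_mean_exceeds_dlpfc_like_across_cohort(self, coil):
        """Sign test over 8 synthetic participants at matched drive: the
        deep-narrow broad-crowned M1-like region sees the stronger mean
        field (one-sided binomial p < 0.05 requires >= 7/8)."""
        wins = 0
        for p in sd.sample_cohort(8, seed=11):
            head = hm.build_head(p.head_params)
            means = {}
            pl_m1 = None
            for region in (sd.M1, sd.DLPFC):
                s = head.surfaces[region]
                if region == sd.M1:
                    cdir = np.asarray(s.spec.patch_center_direction, float)
                    tgt = s.vertices[hm.nearest_vertex(s, 85.0 * cdir)]
                    pl_m1 = hm.place_coil(head, tgt, 45.0)
                else:
                    tgt = hm.apply_5cm_rule(head, pl_m1)
                pl = hm.place_coil(head, tgt, 45.0)
                rc = hm.nearest_vertex(s, pl.center)
                mem = ef.roi_members(s, rc, 10.0)
                em = ef.field_map(coil, pl, head, s, vertex_indices=mem, L=36)
                means[region] = ef.roi_stats(em, s, rc, 10.0,
                                             vertex_indices=mem).mean_e_total
            wins += means[sd.M1] > means[sd.DLPFC]
        assert wins >= 7
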