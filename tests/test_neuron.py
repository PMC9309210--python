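import numpy as np
import pytest
from scipy.integrate import quad

from tmsdose import neuron as nr
from tests.conftest import uniform_psi


def single_compartment(area_cm2=1e-4):
    return nr.CompartmentTree(
        parent=np.array([-1]), length_um=np.array([100.0]),
        diam_um=np.array([10.0]), midpoint_um=np.zeros((1, 3)),
        area_cm2=np.array([area_cm2]), g_axial_uS=np.array([0.0]),
        region=np.array([nr.R_SOMA]), path_dist_um=np.array([0.0]))


def passive_biophys(gl=0.05):
    return nr.BiophysSpec(g_na=(0,) * 5, g_kdr=(0,) * 5, g_km=(0,) * 5,
                          g_ca_hva=(0,) * 5, g_leak=(gl,) * 5,
                          cm_uf_cm2=(1.0,) * 5)


class TestMorphology:
    def test_apical_extent_within_budget(self, morphology):
        apical = morphology.xyz[morphology.types == nr.SWC_APICAL]
        assert np.linalg.norm(apical, axis=1).max() <= 1200.0

    def test_deterministic_given_seed(self):
        a = nr.generate_reduced_l5_morphology(seed=4)
        b = nr.generate_reduced_l5_morphology(seed=4)
        assert np.array_equal(a.xyz, b.xyz) and np.array_equal(a.parent, b.parent)

    def test_infeasible_extent_rejected(self):
        with pytest.raises(ValueError):
            nr.generate_reduced_l5_morphology(apical_trunk_um=1100.0,
                                              tuft_branch_um=300.0)

    def test_swc_roundtrip_identical(self, morphology, tmp_path):
        p = tmp_path / "cell.swc"
        nr.write_swc(morphology, p)
        back = nr.read_swc(p)
        assert np.allclose(back.xyz, morphology.xyz, atol=1e-6)
        assert np.array_equal(back.parent, morphology.parent)
        assert np.array_equal(back.types, morphology.types)
        # writer is canonical: a second write round is bit-identical
        p2 = tmp_path / "cell2.swc"
        nr.write_swc(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_minimal_three_point_file(self, tmp_path):
        p = tmp_path / "mini.swc"
        p.write_text("# soma + two children\n"
                     "1 1 0 0 0 5 -1\n2 3 10 0 0 1 1\n3 3 -10 0 0 1 1\n")
        m = nr.read_swc(p)
        assert m.n_nodes == 3
        leaves = set(m.ids) - set(m.parent)
        assert len(leaves) == 2

    def test_cycle_reported_with_node(self, tmp_path):
        p = tmp_path / "cyc.swc"
        p.write_text("1 1 0 0 0 5 2\n2 3 1 0 0 1 1\n")
        with pytest.raises(ValueError, match="cyclic"):
            nr.read_swc(p)

    def test_unknown_type_code_reports_line(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 9 1 0 0 1 1\n")
        with pytest.raises(ValueError, match=":2"):
            nr.read_swc(p)


class TestDiscretize:
    def test_segment_count_for_simple_cable(self, tmp_path):
        p = tmp_path / "cable.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 0 0 100 0.5 1\n")
        tree = nr.discretize(nr.read_swc(p), max_seg_len_um=20.0)
        assert tree.n == 1 + 5   # soma + 100/20 segments

    def test_area_conserved_under_refinement(self, morphology):
        a = nr.discretize(morphology, 20.0).total_area_cm2
        b = nr.discretize(morphology, 10.0).total_area_cm2
        assert a == pytest.approx(b, rel=1e-9)
        assert a == pytest.approx(nr.discretize(morphology, 40.0).total_area_cm2,
                                  rel=0.01)

    def test_axial_resistance_closed_form(self, tmp_path):
        """End-to-end resistance of a 100 um, 1 um diameter cable at
        Ra = 150 Ohm cm is 4*Ra*L/(pi*d^2) = 1.91e8 Ohm."""
        p = tmp_path / "thin.swc"
        p.write_text("1 3 0 0 0 0.5 -1\n2 3 0 0 100 0.5 1\n")
        tree = nr.discretize(nr.read_swc(p), max_seg_len_um=10.0, ra_ohm_cm=150.0)
        r_total_ohm = 4 * (150.0 * 1e4) * 100.0 / (np.pi * 1.0**2)   # Ohm
        assert r_total_ohm == pytest.approx(1.9099e8, rel=1e-4)
        # each interior center-to-center coupling spans one 10 um segment
        r_seg_mohm = r_total_ohm / 10 / 1e6
        for i in range(2, tree.n):
            assert 1.0 / tree.g_axial_uS[i] == pytest.approx(r_seg_mohm, rel=1e-9)

    def test_positive_couplings(self, tree):
        assert np.all(tree.g_axial_uS[1:] > 0)
        assert np.all(tree.parent[1:] < np.arange(1, tree.n))


class TestQuasipotentials:
    def test_uniform_field_line_integral(self, tmp_path):
        p = tmp_path / "xcable.swc"
        p.write_text("1 3 0 0 0 0.5 -1\n2 3 100 0 0 0.5 1\n")
        tree = nr.discretize(nr.read_swc(p), max_seg_len_um=10.0)
        psi = uniform_psi(tree, (1.0, 0.0, 0.0), magnitude=100.0)
        # compartment 0.1 mm along +x from the root midpoint: psi = -10 mV
        x_mm = tree.midpoint_um[:, 0] * 1e-3
        expected = -100.0 * (x_mm - x_mm[0])
        assert np.allclose(psi.psi_mv, expected, atol=1e-9)
        assert psi.psi_mv[0] == 0.0

    def test_perpendicular_field_gives_zero(self, tmp_path):
        p = tmp_path / "xcable.swc"
        p.write_text("1 3 0 0 0 0.5 -1\n2 3 100 0 0 0.5 1\n")
        tree = nr.discretize(nr.read_swc(p), max_seg_len_um=10.0)
        psi = uniform_psi(tree, (0.0, 0.0, 1.0), magnitude=100.0)
        assert np.abs(psi.psi_mv).max() < 1e-12

    def test_branched_tree_path_independence(self, tree):
        """In a uniform field, psi depends only on position, not branch
        order: psi_i = -E . (x_i - x_root)."""
        E = np.array([3.0, -2.0, 1.5])
        psi = nr.quasipotentials(tree, lambda p: np.tile(E, (len(p), 1)))
        pos_mm = tree.midpoint_um * 1e-3
        expected = -(pos_mm - pos_mm[0]) @ E
        assert np.allclose(psi.psi_mv, expected, atol=1e-9)

    def test_undefined_sampler_raises_with_position(self, tree):
        def bad(p):
            out = np.tile([1.0, 0, 0], (len(p), 1))
            out[0] = np.nan
            return out
        with pytest.raises(ValueError, match="position"):
            nr.quasipotentials(tree, bad)


class TestBiphasicWaveform:
    def test_starts_at_peak_one(self, waveform):
        assert waveform.values[0] == pytest.approx(1.0)
        assert np.abs(waveform.values).max() == pytest.approx(1.0)

    def test_biphasic_sign_change(self, waveform):
        assert np.any(waveform.values > 0) and np.any(waveform.values < 0)

    def test_charge_near_balance(self, waveform):
        """Damped cosine over one period: |integral w| < 0.25 integral |w|
        (quadrature oracle)."""
        f, tau = waveform.carrier_khz, waveform.damping_ms
        w = lambda t: np.cos(2 * np.pi * f * t) * np.exp(-t / tau)
        num, _ = quad(w, 0, 1 / f, limit=200)
        den, _ = quad(lambda t: abs(w(t)), 0, 1 / f, limit=200)
        assert abs(num) < 0.25 * den
        # the sampled waveform matches the closed form it claims
        assert np.allclose(waveform(waveform.times_ms), waveform.values, atol=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            nr.biphasic_waveform(dt_ms=0.0)
        with pytest.raises(ValueError):
            nr.biphasic_waveform(carrier_khz=-3.0)


class TestSimulate:
    def test_passive_steady_state_ohms_law(self):
        tree = single_compartment()
        bio = passive_biophys(gl=0.05)   # R = 1/(0.05 mS/cm2 * 1e-4 cm2) = 200 MOhm
        tr = nr.simulate(tree, bio, None, None, 0.0, duration_ms=400.0,
                         iclamp=(0, 0.05, 50.0, 400.0))
        assert tr.vm_mv[-1] - bio.v_rest_mv == pytest.approx(0.05 * 200.0, rel=0.005)

    def test_passive_membrane_time_constant(self):
        tree = single_compartment()
        bio = passive_biophys(gl=0.05)   # tau = Cm/gl = 20 ms
        tr = nr.simulate(tree, bio, None, None, 0.0, duration_ms=400.0,
                         iclamp=(0, 0.05, 50.0, 400.0))
        dv = tr.vm_mv - bio.v_rest_mv
        vss = dv[-1]
        i0 = np.searchsorted(tr.t_ms, 50.0)
        i63 = i0 + np.argmax(dv[i0:] >= 0.632 * vss)
        assert tr.t_ms[i63] - 50.0 == pytest.approx(20.0, rel=0.02)

    def test_resting_stability(self, tree, biophys):
        tr = nr.simulate(tree, biophys, None, None, 0.0, duration_ms=100.0)
        assert np.abs(tr.vm_mv - biophys.v_rest_mv).max() < 0.5
        assert len(tr.ap_times_ms) == 0

    def test_deterministic(self, tree, biophys, waveform):
        psi = uniform_psi(tree, (0, 0, 1.0))
        a = nr.simulate(tree, biophys, psi, waveform, 80.0, duration_ms=15.0)
        b = nr.simulate(tree, biophys, psi, waveform, 80.0, duration_ms=15.0)
        assert np.array_equal(a.vm_mv, b.vm_mv)

    def test_dt_refinement_changes_peak_little(self, tree, biophys, waveform):
        psi = uniform_psi(tree, (0, 0, 1.0))
        a = nr.simulate(tree, biophys, psi, waveform, 70.0, duration_ms=15.0)
        b = nr.simulate(tree, biophys, psi, waveform, 70.0, duration_ms=15.0,
                        dt_ms=0.0125, fine_dt_ms=0.0025)
        assert abs(a.vm_mv.max() - b.vm_mv.max()) / abs(b.vm_mv.max()) < 0.01

    def test_calcium_nonnegative_and_bounded_under_fuzzed_drives(self, tree, biophys,
                                                                 waveform):
        rng = np.random.default_rng(5)
        for _ in range(5):
            d = rng.normal(size=3)
            s = float(rng.uniform(10, 150))
            psi = uniform_psi(tree, d)
            tr = nr.simulate(tree, biophys, psi, waveform, s, duration_ms=40.0)
            assert np.all(tr.ca_mm >= 0)
            assert np.all(np.isfinite(tr.vm_mv))
            assert np.abs(tr.vm_mv).max() <= 200.0

    def test_gate_tables_stay_in_unit_interval(self):
        xinf, q = nr._cached_gate_tables((0.025, 0.005))
        assert np.all((xinf >= 0) & (xinf <= 1))
        assert np.all((q >= 0) & (q <= 1))

    def test_divergence_is_flagged_with_time(self, tree, biophys, waveform):
        psi = uniform_psi(tree, (0, 0, 1.0))
        with pytest.raises(nr.SolverDivergence):
            nr.simulate(tree, biophys, psi, waveform, 50000.0, duration_ms=10.0)

    def test_direction_sensitivity_axis_easier_than_perpendicular(
            self, tree, biophys, waveform):
        """Uniform field parallel to the somato-dendritic axis activates at
        lower strength than the perpendicular direction."""
        def fires(psi, s):
            try:
                tr = nr.simulate(tree, biophys, psi, waveform, s, duration_ms=15.0)
            except nr.SolverDivergence:
                return True   # drive far beyond physiological range
            return bool(tr.time_locked_flags.any())

        def threshold(direction):
            lo, hi = 4.0, 800.0
            psi = uniform_psi(tree, direction)
            if not fires(psi, hi):
                return np.inf
            while hi - lo > 2.0:
                mid = 0.5 * (lo + hi)
                if fires(psi, mid):
                    hi = mid
                else:
                    lo = mid
            return hi
        parallel = min(threshold((0, 0, 1.0)), threshold((0, 0, -1.0)))
        perpendicular = min(threshold((1.0, 0, 0)), threshold((0, 1.0, 0)))
        assert parallel < perpendicular


class TestEventDetection:
    def test_flat_trace_has_no_aps(self):
        t = np.arange(0, 100, 0.1)
        assert len(nr.detect_aps(t, np.full_like(t, -70.0))) == 0

    def test_two_separated_bumps(self):
        t = np.arange(0, 30, 0.1)
        v = np.full_like(t, -70.0)
        v[(t > 5) & (t < 6)] = 20.0
        v[(t > 15) & (t < 16)] = 20.0
        assert len(nr.detect_aps(t, v)) == 2

    def test_refractory_merges_close_crossings(self):
        t = np.arange(0, 10, 0.1)
        v = np.full_like(t, -70.0)
        v[(t > 5.0) & (t < 5.3)] = 20.0
        v[(t > 6.0) & (t < 6.3)] = 20.0   # 1 ms later, inside refractory
        assert len(nr.detect_aps(t, v, refractory_ms=2.0)) == 1

    def test_time_locked_window(self):
        flags = nr.time_locked(np.array([8.0]), np.array([5.0]), window_ms=5.0)
        assert flags.tolist() == [True]
        flags = nr.time_locked(np.array([12.0]), np.array([5.0]), window_ms=5.0)
        assert flags.tolist() == [False]
        flags = nr.time_locked(np.array([]), np.array([5.0, 105.0]), window_ms=5.0)
        assert flags.tolist() == [False, False]

    def test_ca_events(self):
        t = np.arange(0, 100, 0.5)
        rest, delta = 1e-4, 5e-4
        ca = np.full_like(t, rest)
        assert len(nr.detect_ca_events(t, ca, rest, delta)) == 0
        ca[(t > 20) & (t < 30)] = 1e-3
        assert len(nr.detect_ca_events(t, ca, rest, delta)) == 1
        ca2 = np.full_like(t, rest)
        ca2[(t > 20) & (t < 22)] = 1e-3
        ca2[(t > 27) & (t < 29)] = 1e-3   # 5 ms gap < 20 ms separation
        assert len(nr.detect_ca_events(t, ca2, rest, delta,
                                       min_separation_ms=20.0)) == 1


class TestTraceExport:
    def test_trace_and_events_roundtrip(self, tree, biophys, waveform, tmp_path):
        psi = uniform_psi(tree, (0, 0, -1.0))
        tr = nr.simulate(tree, biophys, psi, waveform, 150.0, duration_ms=30.0)
        out = tmp_path / "trace.csv"
        nr.save_trace_csv(tr, out)
        import pandas as pd
        df = pd.read_csv(out)
        assert list(df.columns) == ["time_ms", "vm_mv", "ca_mm"]
        ev = pd.read_csv(tmp_path / "trace_events.csv")
        assert len(ev[ev.event == "ap"]) == len(tr.ap_times_ms)


class TestSynapse:
    def test_zero_before_first_event(self):
        spec = nr.SynapseSpec(weight_us=0.5, event_times_ms=(10.0,))
        assert nr.synapse_conductance(spec, 9.99) == 0.0

    def test_peak_equals_weight(self):
        spec = nr.SynapseSpec(weight_us=0.5, event_times_ms=(0.0,))
        t = np.linspace(0, 20, 40001)
        assert nr.synapse_conductance(spec, t).max() == pytest.approx(0.5, abs=1e-6)

    def test_peak_time_closed_form(self):
        """argmax t = tau1 tau2/(tau2-tau1) ln(tau2/tau1) = 0.549 ms for the
        default 0.2 / 2.5 ms time constants."""
        spec = nr.SynapseSpec(weight_us=1.0, event_times_ms=(0.0,))
        t = np.linspace(0, 5, 500001)
        tp = t[np.argmax(nr.synapse_conductance(spec, t))]
        expected = 0.2 * 2.5 / (2.5 - 0.2) * np.log(2.5 / 0.2)
        assert expected == pytest.approx(0.549, abs=5e-4)
        assert tp == pytest.approx(expected, abs=1e-3)

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            nr.SynapseSpec(tau1_ms=2.5, tau2_ms=0.2)
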