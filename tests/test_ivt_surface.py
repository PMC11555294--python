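"""IV-curve measurement, surface assembly, projections, component
surfaces and persistence."""

import numpy as np
import pytest

from ivtsurf.ivt_surface import (
    build_surface,
    component_surface,
    load_surface_h5,
    measure_iv_curve,
    project,
    save_surface_h5,
    surface_to_csv,
)


class TestMeasureIVCurve:
    def test_toy_curve_is_analytic_polynomial_at_any_tvc(self, toy_cubic):
        from ivtsurf.protocols import StimulusSpec, simulate_ap

        traj = simulate_ap(toy_cubic.initial_state(), toy_cubic,
                           StimulusSpec(0.0, 0.5), duration=80.0)
        V = np.arange(-100.0, 51.0, 2.0)
        for tvc in (0.01, 1.0, 5.0):
            curve = measure_iv_curve(traj, 20.0, tvc, V)
            np.testing.assert_allclose(curve.I_total, toy_cubic.iv(V), atol=1e-9)

    def test_t_beyond_trajectory_errors(self, toy_traj):
        with pytest.raises(ValueError):
            measure_iv_curve(toy_traj, 1e5, 1.0)

    def test_ap_point_is_read_from_unperturbed_trajectory(self, ord_traj):
        curve = measure_iv_curve(ord_traj, 50.0, 1.0, np.arange(-40.0, 45.0, 2.0))
        v_ap, i_ap = curve.ap_point
        assert v_ap == pytest.approx(ord_traj.V_at(50.0))
        assert i_ap == pytest.approx(ord_traj.i_ion_at(50.0))

    def test_delta_i_monotone_in_tvc_during_plateau(self, ord_traj):
        """The gating increment accumulated during the clamp grows with the
        clamp duration (the AP state drops below long-t_vc surfaces)."""
        v_ap = ord_traj.V_at(100.0)
        grid = np.arange(v_ap - 6.0, v_ap + 6.1, 2.0)
        deltas = [abs(measure_iv_curve(ord_traj, 100.0, tvc, grid).delta_I)
                  for tvc in (0.001, 0.1, 1.0, 5.0)]
        assert all(b >= a - 1e-3 for a, b in zip(deltas, deltas[1:]))

    def test_ical_activation_deflection_at_plateau(self, ord_traj):
        """At T = 200 ms the quasi-instantaneous curve deflects downward at
        depolarized voltages because I_CaL activates there."""
        curve = measure_iv_curve(ord_traj, 200.0, 1.0, np.arange(-30.0, 31.0, 2.0))
        assert curve.components["I_CaL"].min() < -0.5


class TestBuildSurface:
    def test_toy_surface_time_invariant_outer_product(self, toy_cubic):
        from ivtsurf.protocols import StimulusSpec, simulate_ap

        traj = simulate_ap(toy_cubic.initial_state(), toy_cubic,
                           StimulusSpec(0.0, 0.5), duration=80.0)
        V = np.arange(-100.0, 51.0, 10.0)
        surf = build_surface(traj, T_grid=np.arange(0.0, 60.0, 20.0), t_vc=1.0, V_grid=V)
        for row in surf.I:
            np.testing.assert_allclose(row, toy_cubic.iv(V), atol=1e-9)

    def test_resting_surface_is_cylindrical(self, ord_traj):
        """Once the AP has settled into diastole the surface is T-invariant
        on the subthreshold limb: neighbouring isochrones agree cell-wise
        within 0.05 A/F.  (At suprathreshold voltages sodium availability
        keeps recovering for hundreds of ms, so the full grid is excluded
        by design.)"""
        t99 = ord_traj.repol_time(0.99)
        Tg = np.arange(t99 + 60.0, t99 + 81.0, 10.0)
        surf = build_surface(ord_traj, T_grid=Tg, t_vc=1.0,
                             V_grid=np.arange(-100.0, -69.0, 5.0),
                             record_components=False)
        assert np.max(surf.I.max(axis=0) - surf.I.min(axis=0)) < 0.05

    def test_metadata_records_reproducibility_info(self, ord_surf5):
        meta = ord_surf5.metadata
        assert meta["model"] == "ord" and meta["t_vc"] == 5.0
        assert meta["params"]["C_m_pF"] == 200.0

    def test_ap_curve_lies_on_surface_during_plateau(self, ord_surf1):
        """For t_vc <= 2 ms the AP's (I,V,T) states lie on the surface:
        |delta_I| <= 0.05 A/F through the plateau."""
        sel = (ord_surf1.T_grid >= 20.0) & (ord_surf1.T_grid <= 150.0)
        deltas = [abs(ord_surf1.curve_at(T).delta_I) for T in ord_surf1.T_grid[sel]]
        assert max(deltas) <= 0.05


class TestProjections:
    def test_vt_projection_equals_simulated_ap(self, ord_surf1, ord_traj):
        proj = project(ord_surf1)
        v_direct = np.array([ord_traj.V_at(T) for T in ord_surf1.T_grid])
        np.testing.assert_allclose(proj["V_of_T"], v_direct, atol=1e-6)

    def test_current_projection_integrates_to_net_charge(self, ord_surf1, ord_traj):
        """Trapezoid integral of I_ion(T) from just after the upstroke to
        the APD equals the net voltage drop (per-capacitance charge
        conservation; x C_m for pC).  The sub-millisecond sodium spike is
        excluded: it is unresolvable on a 2-ms T grid by construction."""
        proj = project(ord_surf1)
        sel = (ord_surf1.T_grid >= 4.0) & (ord_surf1.T_grid <= ord_traj.APD)
        integral = np.trapezoid(proj["I_of_T"][sel], ord_surf1.T_grid[sel])
        dv = ord_traj.V_at(float(ord_surf1.T_grid[sel][0])) - ord_traj.V_at(
            float(ord_surf1.T_grid[sel][-1]))
        assert integral == pytest.approx(dv, rel=0.02)

    def test_offset_traces_near_symmetric_where_quasi_ohmic(self, ord_surf1):
        """+/-10 mV displacements during the early plateau produce nearly
        symmetric current deflections (quasi-ohmic membrane)."""
        proj = project(ord_surf1)
        k = int(np.argmin(np.abs(ord_surf1.T_grid - 100.0)))
        up = proj["I_offset_plus"][k] - ord_surf1.ap_I[k]
        down = proj["I_offset_minus"][k] - ord_surf1.ap_I[k]
        assert up > 0 > down
        assert 0.5 < abs(up / down) < 2.0


class TestComponentSurfaces:
    def test_components_sum_to_total(self, ord_surf1):
        total = sum(ord_surf1.components.values())
        np.testing.assert_allclose(total, ord_surf1.I, atol=1e-8)

    def test_unknown_component_errors(self, ord_surf1):
        with pytest.raises(KeyError):
            component_surface(ord_surf1, "I_funny")

    def test_ina_component_zero_in_absolute_refractory_window(self, ord_surf1):
        sub = component_surface(ord_surf1, "I_Na")
        k = int(np.argmin(np.abs(sub.T_grid - 100.0)))
        assert np.max(np.abs(sub.I[k])) < 0.05

    def test_ik1_dominates_late_hill_slope(self, ord_surf1):
        """Near the slope-sign transition the total isochronal slope at the
        AP state has the same sign as the I_K1 component's slope."""
        from ivtsurf.surface_analysis import _local_slope

        k = int(np.argmin(np.abs(ord_surf1.T_grid - 256.0)))
        v_ap = ord_surf1.ap_V[k]
        s_total = _local_slope(ord_surf1.V_grid, ord_surf1.I[k], v_ap)
        s_k1 = _local_slope(ord_surf1.V_grid, ord_surf1.components["I_K1"][k], v_ap)
        assert np.sign(s_total) == np.sign(s_k1)


class TestPersistence:
    def _small_surface(self, ord_traj):
        return build_surface(ord_traj, T_grid=np.array([40.0, 60.0]), t_vc=1.0,
                             V_grid=np.arange(-80.0, 1.0, 20.0))

    def test_hdf5_roundtrip_bit_exact(self, ord_traj, tmp_path):
        surf = self._small_surface(ord_traj)
        p = tmp_path / "s.h5"
        save_surface_h5(surf, p)
        back = load_surface_h5(p)
        np.testing.assert_array_equal(back.I, surf.I)
        np.testing.assert_array_equal(back.T_grid, surf.T_grid)
        np.testing.assert_array_equal(back.ap_V, surf.ap_V)
        assert back.metadata == surf.metadata
        assert set(back.components) == set(surf.components)

    def test_identical_builds_export_identical_csv(self, ord_traj, tmp_path):
        a = self._small_surface(ord_traj)
        b = self._small_surface(ord_traj)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        surface_to_csv(a, pa)
        surface_to_csv(b, pb)
        assert pa.read_bytes() == pb.read_bytes()
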