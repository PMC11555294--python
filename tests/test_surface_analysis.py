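"""Equilibria, SRR transitions, region segmentation, membrane resistance,
refractoriness and AP-type classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivtsurf.ivt_surface import IVCurve, build_surface
from ivtsurf.pipeline import random_cubics
from ivtsurf.surface_analysis import (
    classify_ap_type,
    detect_srr_transition,
    find_equilibria,
    find_srr_minima,
    membrane_resistance,
    membrane_time_constant,
    refractory_window,
    rm_from_slope,
    segment_regions,
    slope_sign_transition,
)

V_GRID = np.arange(-100.0, 51.0, 2.0)


def _cubic_curve(a, r1, r2, r3, ap_v=None):
    I = a * (V_GRID - r1) * (V_GRID - r2) * (V_GRID - r3)
    ap = None if ap_v is None else (ap_v, float(np.interp(ap_v, V_GRID, I)))
    return IVCurve(T=0.0, t_vc=5.0, V_grid=V_GRID, I_total=I, ap_point=ap)


def _brute_force_roots(fn, lo=-100.0, hi=50.0, step=0.01):
    v = np.arange(lo, hi, step)
    I = fn(v)
    roots = []
    for k in np.flatnonzero(np.sign(I[:-1]) * np.sign(I[1:]) < 0):
        frac = I[k] / (I[k] - I[k + 1])
        roots.append(v[k] + frac * step)
    return np.array(roots)


class TestEquilibria:
    def test_linear_iv_single_stable_equilibrium(self):
        I = 0.1 * (V_GRID + 85.0)
        curve = IVCurve(T=0.0, t_vc=1.0, V_grid=V_GRID, I_total=I, ap_point=(-85.0, 0.0))
        eqs = find_equilibria(curve)
        assert len(eqs) == 1
        assert eqs[0].stability == "stable"
        assert eqs[0].V == pytest.approx(-85.0, abs=1e-9)

    def test_200_random_cubics_match_dense_scan_oracle(self):
        """The grid-based finder recovers every root of 200 random N-shaped
        cubics within 0.1 mV of a 0.01 mV brute-force scan, with matching
        stability labels (stable-unstable-stable alternation)."""
        fixtures = random_cubics(seed=0, n=200)
        for _, row in fixtures.iterrows():
            a, r1, r2, r3 = row["a"], row["r1"], row["r2"], row["r3"]
            curve = _cubic_curve(a, r1, r2, r3, ap_v=r1)
            eqs = find_equilibria(curve)
            oracle = _brute_force_roots(lambda v: a * (v - r1) * (v - r2) * (v - r3))
            oracle = oracle[oracle < V_GRID[-1]]
            assert len(eqs) == len(oracle)
            for e, r in zip(eqs, oracle):
                assert abs(e.V - r) < 0.1
            labels = [e.stability for e in eqs]
            assert labels == ["stable", "unstable", "stable"][: len(labels)]

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        r1=st.floats(-95.0, -75.0),
        gap1=st.floats(6.0, 40.0),
        gap2=st.floats(6.0, 80.0),
        loga=st.floats(-5.0, -3.0),
    )
    def test_cubic_equilibria_property(self, r1, gap1, gap2, loga):
        a = 10.0 ** loga
        r2, r3 = r1 + gap1, r1 + gap1 + gap2
        eqs = find_equilibria(_cubic_curve(a, r1, r2, r3, ap_v=r1))
        expected = [r for r in (r1, r2, r3) if r < V_GRID[-1]]
        assert len(eqs) == len(expected)
        for e, r in zip(eqs, expected):
            assert abs(e.V - r) < 0.1

    def test_regenerative_direction_relative_to_ap_state(self):
        eqs = find_equilibria(_cubic_curve(1e-4, -85.0, -55.0, 30.0, ap_v=-85.0))
        unstable = [e for e in eqs if e.stability == "unstable"]
        assert unstable[0].regenerative_direction == "depolarizing"
        # same curve seen from a plateau AP state: the crossing below is AONR
        eqs2 = find_equilibria(_cubic_curve(1e-4, -85.0, -55.0, 30.0, ap_v=10.0))
        unstable2 = [e for e in eqs2 if e.stability == "unstable"]
        assert unstable2[0].regenerative_direction == "repolarizing"
        assert unstable2[0].kind == "AONR"


class TestSRRMinima:
    def test_monotone_curve_has_no_minima(self):
        I = 0.05 * (V_GRID + 80.0)
        curve = IVCurve(T=0.0, t_vc=5.0, V_grid=V_GRID, I_total=I, ap_point=(40.0, 6.0))
        assert find_srr_minima(curve) == []

    def test_quadratic_refinement_within_one_grid_step(self):
        v_min_true = -33.3
        I = 0.4 + 1e-3 * (V_GRID - v_min_true) ** 2
        curve = IVCurve(T=0.0, t_vc=5.0, V_grid=V_GRID, I_total=I, ap_point=(30.0, 5.0))
        mins = find_srr_minima(curve)
        assert len(mins) == 1
        assert abs(mins[0].V - v_min_true) < 2.0
        assert mins[0].I == pytest.approx(0.4, abs=1e-3)

    def test_minima_must_be_positive_and_below_ap(self):
        v_min_true = -33.3
        I = -0.2 + 1e-3 * (V_GRID - v_min_true) ** 2  # dips below zero
        curve = IVCurve(T=0.0, t_vc=5.0, V_grid=V_GRID, I_total=I, ap_point=(30.0, 5.0))
        assert find_srr_minima(curve) == []


class TestSRRTransition:
    def _profile(self, v_trans=-30.0, noise=0.0, seed=0):
        V = np.arange(-100.0, 51.0, 2.0)
        D = np.where(V >= v_trans, 0.02 * (V + 100.0), -1.5)  # abrupt drop
        if noise:
            D = D + np.random.default_rng(seed).normal(0.0, noise, V.size)
        return V, D

    def test_abrupt_drop_located(self):
        V, D = self._profile(-30.0)
        tr = detect_srr_transition(V, D)
        assert tr is not None
        assert abs(tr.V - (-30.0)) <= 2.0

    def test_flat_profile_gives_no_transition(self):
        V = np.arange(-100.0, 51.0, 2.0)
        assert detect_srr_transition(V, np.zeros_like(V)) is None
        assert detect_srr_transition(V, 0.01 * (V + 100.0)) is None

    def test_robust_to_small_noise(self):
        V, D = self._profile(-30.0, noise=0.02)
        tr = detect_srr_transition(V, D)
        assert tr is not None and abs(tr.V - (-30.0)) <= 4.0


class TestMembraneResistance:
    def test_ohmic_toy_closed_forms(self, toy_ohmic, toy_traj):
        """g = 0.1 mS/uF: absolute R_m = 1/(g C_m) = 50 MOhm at C_m = 200 pF;
        reporting-convention R_m = 10; tau = R_m C_m = 10 ms."""
        surf = build_surface(toy_traj, T_grid=np.arange(0.0, 40.0, 10.0), t_vc=1.0,
                             V_grid=np.arange(-100.0, 51.0, 2.0))
        prof = membrane_resistance(surf, C_m_pF=200.0)
        np.testing.assert_allclose(prof.R_m_abs, 50.0, rtol=1e-6)
        np.testing.assert_allclose(prof.R_m, 10.0, rtol=1e-6)
        # unit-consistency invariant: R_m[Ohm] * g'[S/F] * C_m[F] = 1
        assert prof.R_m_abs[0] * 1e6 * prof.slope[0] * 200e-12 == pytest.approx(1.0)

    def test_flat_slope_reports_signed_infinity(self):
        assert math.isinf(rm_from_slope(0.0))
        assert rm_from_slope(1e-9) > 0
        assert rm_from_slope(-1e-9) < 0

    def test_toy_has_no_slope_sign_transition(self, toy_ohmic, toy_traj):
        surf = build_surface(toy_traj, T_grid=np.arange(0.0, 40.0, 10.0), t_vc=1.0,
                             V_grid=np.arange(-100.0, 51.0, 2.0))
        with pytest.raises(ValueError):
            slope_sign_transition(surf)

    def test_negative_rm_window_during_late_repolarization(self, ord_surf1):
        """R_m is positive during the early plateau, negative on the late
        negative-slope limb (around T = 180-220 ms), and positive at rest."""
        prof = membrane_resistance(ord_surf1)
        def rm_at(T):
            return prof.R_m[int(np.argmin(np.abs(prof.T - T)))]
        assert rm_at(50.0) > 0 and rm_at(100.0) > 0
        assert rm_at(180.0) < 0 and rm_at(220.0) < 0
        assert rm_at(prof.T[-1]) > 0

    def test_slope_agrees_with_two_point_clamp_pair(self, ord_model, ord_traj):
        """Quadratic-fit slope vs a +/-2 mV clamp-pair secant within 5%."""
        from ivtsurf.ivt_surface import measure_iv_curve
        from ivtsurf.surface_analysis import _local_slope

        T = 180.0
        v_ap = float(ord_traj.V_at(T))
        curve = measure_iv_curve(ord_traj, T, 1.0, v_ap + np.arange(-4.0, 4.1, 2.0),
                                 record_components=False)
        fit = _local_slope(curve.V_grid, curve.I_total, v_ap)
        secant = (curve.I_total[3] - curve.I_total[1]) / 4.0
        assert fit == pytest.approx(secant, rel=0.05)


class TestRefractoryWindow:
    def test_toy_without_sodium_current_spans_entire_grid(self, toy_ohmic, toy_traj):
        surf = build_surface(toy_traj, T_grid=np.arange(0.0, 40.0, 10.0), t_vc=1.0,
                             V_grid=np.arange(-100.0, 51.0, 10.0))
        lo, hi = refractory_window(surf)
        assert lo == surf.T_grid[0] and hi == surf.T_grid[-1]

    def test_floor_halving_moves_endpoints_within_two_grid_steps(self, ord_surf1):
        """Sodium availability recovers exponentially, so halving the
        absence floor shifts the window end by less than two T-grid steps."""
        w1 = refractory_window(ord_surf1, eps=0.05)
        w2 = refractory_window(ord_surf1, eps=0.025)
        assert abs(w1[1] - w2[1]) <= 4.0
        assert abs(w1[0] - w2[0]) <= 4.0

    def test_relative_floor_end_matches_slope_sign_transition(self, ord_surf1, ord_surf5):
        """With the rendering-resolution (relative) floor, the absolute
        refractory window ends where the isochronal slope at the AP state
        turns positive -- the convergence of the two markers."""
        w = refractory_window(ord_surf1, eps=0.01, eps_mode="relative")
        t_star = slope_sign_transition(ord_surf5)
        assert abs(w[1] - t_star) <= 4.0


class TestClassification:
    def test_canonical_ap_is_sodium_driven(self, ord_traj):
        assert classify_ap_type(ord_traj) == "sodium_driven"

    def test_subthreshold_response_is_passive(self, ord_model, ord_rest):
        from ivtsurf.protocols import StimulusSpec, simulate_ap

        traj = simulate_ap(ord_rest, ord_model, StimulusSpec(-20.0, 0.5), 300.0)
        assert classify_ap_type(traj) == "passive"

    def test_calcium_driven_ap_in_region_three(self, ord_model, ord_traj):
        """A strong cathodal pulse during region III (sodium unavailable)
        elicits a slow calcium-driven AP."""
        from ivtsurf.protocols import StimulusSpec, simulate_ap

        tr = simulate_ap(ord_traj.state_at(230.0), ord_model,
                         StimulusSpec(-120.0, 0.5), 400.0)
        assert classify_ap_type(tr) == "calcium_driven"

    def test_classification_stable_under_amplitude_jitter(self, ord_model, ord_rest):
        from ivtsurf.protocols import StimulusSpec, simulate_ap

        for amp in (-72.0, -80.0, -88.0):
            traj = simulate_ap(ord_rest, ord_model, StimulusSpec(amp, 0.5), 300.0)
            assert classify_ap_type(traj) == "sodium_driven"


class TestTimeConstant:
    def test_toy_rc_product_exact(self, toy_ohmic):
        tau = membrane_time_constant(toy_ohmic, toy_ohmic.initial_state())
        assert tau == pytest.approx(10.0, rel=0.01)

    def test_fit_consistent_with_resting_slope(self, ord_model, ord_rest):
        """Dual-estimator consistency: the exponential-fit tau agrees with
        the reciprocal resting IV slope (per-capacitance units) within 15%."""
        from ivtsurf.protocols import clamp_step
        from ivtsurf.surface_analysis import _local_slope

        tau_fit = membrane_time_constant(ord_model, ord_rest)
        offs = np.arange(-4.0, 4.1, 2.0)
        I = np.array([clamp_step(ord_rest, ord_model, ord_rest[0] + o, 1.0,
                                 n_samples=2).breakdown.I_ion for o in offs])
        slope = _local_slope(ord_rest[0] + offs, I, ord_rest[0])  # (A/F)/mV
        tau_slope = 1.0 / slope
        assert tau_fit == pytest.approx(tau_slope, rel=0.15)


class TestRegions:
    def test_toy_surface_has_no_threshold_regions(self, toy_cubic):
        from ivtsurf.protocols import StimulusSpec, simulate_ap

        traj = simulate_ap(toy_cubic.initial_state(), toy_cubic,
                           StimulusSpec(0.0, 0.5), duration=80.0)
        surf = build_surface(traj, T_grid=np.arange(0.0, 60.0, 20.0), t_vc=5.0)
        rmap = segment_regions(surf)
        kinds = {e.kind for pts in rmap.annotations.values()
                 for e in pts if hasattr(e, "kind")}
        assert "Ca_threshold" not in kinds and "Na_threshold" not in kinds
        assert "AONR" not in kinds
        assert rmap.bistable_window is None

    def test_ord_region_structure(self, ord_surf5):
        """Canonical ordering of the four repolarization regions with a
        bistable window at the region III/IV border."""
        rmap = segment_regions(ord_surf5)
        assert 120.0 <= rmap.I_end <= 180.0
        assert rmap.I_end <= rmap.II_end <= rmap.III_end
        assert rmap.III_end >= rmap.IV_start - 10.0  # III and IV may overlap slightly
        assert rmap.bistable_window is not None
        lo, hi = rmap.bistable_window
        assert rmap.III_end - 20.0 <= lo <= hi <= rmap.III_end + 2.0

    def test_region_boundaries_stable_on_refined_T_grid(self, ord_traj):
        """Halving the T step around the region III lower boundary moves it
        by at most one coarse step."""
        Tg2 = np.arange(190.0, 215.0, 2.0)
        Tg1 = np.arange(190.0, 215.0, 1.0)
        s2 = build_surface(ord_traj, T_grid=Tg2, t_vc=5.0)
        s1 = build_surface(ord_traj, T_grid=Tg1, t_vc=5.0)
        def iii_start(surf):
            from ivtsurf.surface_analysis import find_equilibria
            for T in surf.T_grid:
                if any(e.kind == "Ca_threshold" for e in find_equilibria(surf.curve_at(T))):
                    return T
            return None
        a, b = iii_start(s2), iii_start(s1)
        assert a is not None and b is not None
        assert abs(a - b) <= 2.0
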