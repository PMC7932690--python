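"""Unit tests of the reaction-diffusion sensor core."""

import math
import warnings

import numpy as np
import pytest

import choxamp as cx
from choxamp.sensor import CURRENT_PA_FACTOR


def make_state(coating, grid, kinetics):
    return cx.init_state(coating, grid, kinetics)


class TestInitState:
    def test_geometry_and_initial_profiles(self, kinetics, grid, coating):
        st = make_state(coating, grid, kinetics)
        assert st.r.size == 31
        assert st.r[0] == pytest.approx(8.5)
        assert st.r[-1] == pytest.approx(38.5)
        assert np.allclose(st.E, 263.0)
        for arr in (st.ch, st.o2, st.h2o2, st.ECh, st.EredBA, st.EoxBA,
                    st.EredGB, st.EoxGB):
            assert np.all(arr == 0.0)

    def test_stability_number_quarter_accepted(self, kinetics):
        # alpha*D_O2*dt/dr^2 = 0.8*2500*1e-4/1 = 0.2 for the O2 coefficient;
        # the binding constraint uses max(D) = 2500 -> 0.25 with dt=1.25e-4
        coat = cx.CoatingSpec(thickness=10.0, d_ch=100.0, d_o2=2500.0,
                              d_h2o2=100.0, alpha=0.8)
        grid = cx.GridSpec(dt=1.25e-4, dr=1.0)
        assert grid.stability_number(coat) == pytest.approx(0.25)
        cx.init_state(coat, grid, kinetics)  # accepted

    def test_stability_violation_rejected(self, kinetics, coating):
        with pytest.raises(cx.NumericsError):
            cx.init_state(coating, cx.GridSpec(dt=5e-4), kinetics)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            cx.CoatingSpec(thickness=-1.0)
        with pytest.raises(ValueError):
            cx.CoatingSpec(thickness=10.0, e0=-1.0)
        with pytest.raises(ValueError):
            cx.CoatingSpec(thickness=10.0, alpha=1.5)
        with pytest.raises(ValueError):
            cx.KineticConstants(k2=0.0)
        # thickness below 2*dr
        with pytest.raises(ValueError):
            cx.GridSpec(dr=8.0).check(cx.CoatingSpec(thickness=10.0))


class TestStepState:
    def test_zero_state_is_fixed_point(self, kinetics, grid, coating):
        st = make_state(coating, grid, kinetics)
        out = cx.step_state(st, (0.0, 0.0), coating, grid, kinetics)
        assert np.array_equal(out.ch, st.ch)
        assert np.array_equal(out.enzymes, st.enzymes)

    def test_no_o2_no_h2o2_no_current(self, kinetics, grid, coating):
        """Both oxidation steps need O2: Ch alone never yields product."""
        st = make_state(coating, grid, kinetics)
        proto = cx.BulkProtocol.constant(5.0, 0.0, 0.5)
        tr = cx.run_protocol(proto, coating, grid, kinetics, state=st,
                             keep_snapshots=True, plateau_warn=False)
        assert np.all(tr.current == 0.0)
        assert np.all(tr.snapshots[-1].h2o2 == 0.0)
        assert tr.snapshots[-1].ch[1] > 0  # Ch did diffuse in

    def test_single_step_matches_scalar_rhs(self, kinetics, grid, coating):
        """One explicit update equals the hand-evaluated reaction RHS where
        profiles are uniform (diffusion term vanishes)."""
        st = make_state(coating, grid, kinetics)
        st.enzymes[0] = 163.0
        st.enzymes[2] = 100.0          # EredBA
        st.o2[:] = 5.0
        out = cx.step_state(st, (0.0, 5.0), coating, grid, kinetics)
        # scalar forward-Euler at an interior node, plain python floats
        k2 = 8.64e4 * 1e-6
        k3 = 135.0
        d_eoba = k2 * 100.0 * 5.0 - k3 * 0.0
        assert out.EoxBA[5] == pytest.approx(grid.dt * d_eoba, rel=1e-12)
        d_erba = -k2 * 100.0 * 5.0
        assert out.EredBA[5] - 100.0 == pytest.approx(grid.dt * d_erba, rel=1e-12)
        # O2 consumed identically at interior nodes (uniform -> no diffusion)
        d_o2 = -k2 * 100.0 * 5.0
        assert out.o2[5] - 5.0 == pytest.approx(grid.dt * d_o2, rel=1e-10)

    def test_interior_diffusion_matches_manual_laplacian(self, kinetics, grid,
                                                         coating):
        """Non-uniform inert profile: update equals the conservative
        spherical operator evaluated by hand at one node."""
        st = make_state(coating, grid, kinetics)
        st.enzymes[:] = 0.0            # no enzyme, pure diffusion
        st.ch[:] = st.r - st.r[0]      # linear profile
        out = cx.step_state(st, (30.0, 0.0), coating, grid, kinetics)
        i = 7
        r = st.r[i]
        dr = 1.0
        lap = (((r + 0.5) ** 2 * (st.ch[i + 1] - st.ch[i])
                - (r - 0.5) ** 2 * (st.ch[i] - st.ch[i - 1]))
               / (r**2 * dr**2))
        expect = st.ch[i] + grid.dt * coating.d_ch_eff * lap
        assert out.ch[i] == pytest.approx(expect, rel=1e-12)

    def test_negative_bulk_rejected(self, kinetics, grid, coating):
        st = make_state(coating, grid, kinetics)
        with pytest.raises(ValueError):
            cx.step_state(st, (-1.0, 0.0), coating, grid, kinetics)


class TestElectrodeCurrent:
    def test_unit_conversion_two_point(self, coating):
        """Independent dimensional analysis: a 1 uM/um gradient at re=8.5 um
        with D_eff = 0.8*1830 um^2/s gives 2*F*pi*re^2*D*slope converted to
        pA: uM/um = 1e-21 mol/um^4, times um^2 * um^2/s = 1e-21 mol/s,
        times 2*96485.33212 C/mol = C/s, times 1e12 -> pA."""
        n = 5
        r = 8.5 + np.arange(n, dtype=float)
        st = cx.FieldState(r, np.zeros(n), np.zeros(n), 1.0 * (r - 8.5),
                           np.zeros((6, n)))
        expected = 2.0 * 96485.33212 * math.pi * 8.5**2 * (0.8 * 1830.0) * 1e-21 * 1e12
        got = cx.electrode_current(st, coating, gradient="two_point")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_area_scaling_two_point(self, coating):
        n = 5
        r = 8.5 + np.arange(n, dtype=float)
        st = cx.FieldState(r, np.zeros(n), np.zeros(n), 1.0 * (r - 8.5),
                           np.zeros((6, n)))
        big = cx.CoatingSpec(thickness=coating.thickness, radius=17.0)
        r2 = 17.0 + np.arange(n, dtype=float)
        st2 = cx.FieldState(r2, np.zeros(n), np.zeros(n), 1.0 * (r2 - 17.0),
                            np.zeros((6, n)))
        i1 = cx.electrode_current(st, coating, gradient="two_point")
        i2 = cx.electrode_current(st2, big, gradient="two_point")
        assert i2 / i1 == pytest.approx(4.0, rel=1e-12)

    def test_spherical_estimator_exact_on_source_free_profile(self, coating):
        """H = A(1/a - 1/r) carries flux 4*pi*D*A through every shell; the
        default estimator recovers 2*F*pi*a^2*D*A/a^2 to O(dr^2)."""
        a = coating.radius
        r = a + np.arange(31, dtype=float)
        A = 50.0
        st = cx.FieldState(r, np.zeros(31), np.zeros(31), A * (1 / a - 1 / r),
                           np.zeros((6, 31)))
        true = CURRENT_PA_FACTOR * coating.d_h2o2_eff * A
        got = cx.electrode_current(st, coating)
        assert got == pytest.approx(true, rel=5e-3)

    def test_zero_h2o2_zero_current(self, kinetics, grid, coating):
        st = make_state(coating, grid, kinetics)
        assert cx.electrode_current(st, coating) == 0.0


class TestRunProtocol:
    def test_no_enzyme_zero_current_and_linear_delta_o2(self, kinetics, grid):
        coat = cx.CoatingSpec(thickness=20.0, e0=0.0)
        proto = cx.BulkProtocol.standard_calibration(ch=5.0, o2_step=5.0,
                                                     o2_max=15.0, hold=10.0,
                                                     pre_hold=10.0)
        tr = cx.run_protocol(proto, coat, grid, kinetics, keep_snapshots=False,
                             plateau_warn=False)
        assert np.all(tr.current == 0.0)
        # identical bulk steps through an inert coating give identical DO2
        d = cx.compute_delta_o2(tr, lag=0.3)
        assert d.size == 3
        assert np.allclose(d, d[0], rtol=1e-6)
        assert np.all(cx.compute_delta_o2(tr, lag=0.0) == 0.0)

    def test_no_choline_zero_current(self, kinetics, grid, coating):
        proto = cx.BulkProtocol(np.array([0.0, 5.0]), np.array([0.0, 0.0]),
                                np.array([0.0, 10.0]), 10.0)
        tr = cx.run_protocol(proto, coating, grid, kinetics,
                             keep_snapshots=False, plateau_warn=False)
        assert np.all(tr.current == 0.0)

    def test_enzyme_conservation_and_nonnegativity(self, short_staircase,
                                                   coating):
        _, tr = short_staircase
        worst = 0.0
        for snap in tr.snapshots:
            worst = max(worst, np.abs(snap.total_enzyme() - coating.e0).max())
            assert snap.ch.min() >= -1e-9
            assert snap.o2.min() >= -1e-9
            assert snap.h2o2.min() >= -1e-9
            assert snap.h2o2[0] == 0.0 and snap.h2o2[-1] == 0.0
        assert worst / coating.e0 < 1e-9
        assert tr.current.min() >= -1e-9

    def test_overshoot_then_plateau_high_loading(self, kinetics, grid):
        """5 uM O2 steps on a heavily loaded coating: transient peak above
        the subsequent plateau at every step."""
        coat = cx.CoatingSpec(thickness=30.0, e0=560.0)
        proto = cx.BulkProtocol.standard_calibration(hold=20.0, pre_hold=120.0,
                                                     o2_max=10.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tr = cx.run_protocol(proto, coat, grid, kinetics,
                                 keep_snapshots=False)
        from choxamp.calibration import step_responses_from_trace
        sr = step_responses_from_trace(tr)
        assert np.all(sr.phasic > 0)

    def test_plateau_warning_on_short_hold(self, kinetics, grid, coating):
        proto = cx.BulkProtocol.standard_calibration(hold=2.0, pre_hold=2.0,
                                                     o2_max=10.0)
        with pytest.warns(RuntimeWarning, match="not plateaued"):
            cx.run_protocol(proto, coating, grid, kinetics,
                            keep_snapshots=False)

    def test_flux_balance_at_plateau(self, short_staircase, coating, kinetics):
        _, tr = short_staircase
        fb = cx.h2o2_flux_balance(tr.snapshots[-1], coating, kinetics)
        assert fb["rel_err"] < 0.01
        assert fb["flux_inner"] > 0 and fb["flux_outer"] > 0

    def test_delta_o2_grows_across_steps_high_loading(self, kinetics, grid):
        """Reduced-intermediate depletion sharpens the surface DO2 rise."""
        coat = cx.CoatingSpec(thickness=30.0, e0=560.0)
        proto = cx.BulkProtocol.standard_calibration(hold=20.0, pre_hold=120.0,
                                                     o2_max=20.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tr = cx.run_protocol(proto, coat, grid, kinetics,
                                 keep_snapshots=False)
        d = cx.compute_delta_o2(tr, lag=0.3)
        assert d[-1] > d[0]

    def test_delta_o2_requires_fine_record(self, kinetics, grid):
        coat = cx.CoatingSpec(thickness=20.0, e0=0.0)
        proto = cx.BulkProtocol.standard_calibration(hold=5.0, pre_hold=5.0,
                                                     o2_max=10.0)
        tr = cx.run_protocol(proto, coat, grid, kinetics, output_dt=0.5,
                             keep_snapshots=False, plateau_warn=False)
        with pytest.raises(ValueError, match="cadence"):
            cx.compute_delta_o2(tr)


class TestBulkProtocol:
    def test_validation(self):
        with pytest.raises(ValueError):
            cx.BulkProtocol(np.array([0.0, 1.0, 1.0]), np.zeros(3),
                            np.zeros(3), 5.0)
        with pytest.raises(ValueError):
            cx.BulkProtocol(np.array([0.0]), np.array([-1.0]),
                            np.array([0.0]), 5.0)

    def test_standard_calibration_shape(self):
        p = cx.BulkProtocol.standard_calibration()
        assert np.all(p.ch == 5.0)
        assert np.array_equal(p.o2, [0, 5, 10, 15, 20, 25, 30])
        assert np.all(np.diff(p.o2) == 5.0)
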