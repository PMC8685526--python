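"""Monodomain solver: geometry, Rush-Larsen, diffusion sanity, CV scaling."""

import math

import numpy as np
import pytest

from afpom import cell_model as cm
from afpom import synthetic_data as sd
from afpom import tissue_sim as ts
from afpom.cell_model import IonicProfile
from afpom.errors import PropagationError, RangeError, StabilityError


class TestGeometry:
    def test_named_planes(self):
        normal = ts.build_geometry("normal")
        assert (normal.nx, normal.ny, normal.dx) == (400, 400, 0.01)
        assert normal.area == pytest.approx(16.0)
        dilated = ts.build_geometry("dilated")
        assert (dilated.nx, dilated.ny) == (450, 450)
        assert dilated.area == pytest.approx(20.25)

    def test_reference_spacing_from_side_length(self):
        # 4 cm side over 400 nodes
        assert math.sqrt(16.0) / 400 == pytest.approx(ts.DX_REFERENCE)

    def test_unknown_label(self):
        with pytest.raises(RangeError):
            ts.build_geometry("giant")

    def test_desk_geometry_preserves_area(self):
        g = ts.desk_geometry("dilated", 100)
        assert g.area == pytest.approx(20.25)


class TestRushLarsen:
    def test_fixed_point(self):
        assert ts.rush_larsen_step(0.4, 0.4, 7.0, 0.5) == pytest.approx(0.4)

    def test_small_dt_limit(self):
        w = ts.rush_larsen_step(0.2, 0.9, 5.0, 1e-9)
        assert w == pytest.approx(0.2, abs=1e-9)

    def test_closed_form_value(self):
        assert ts.rush_larsen_step(0.0, 1.0, 1.0, 1.0) == pytest.approx(
            1.0 - math.exp(-1.0), abs=1e-12)

    def test_matches_analytic_relaxation(self, rng):
        for _ in range(1000):
            w = rng.uniform(0.0, 1.0)
            w_inf = rng.uniform(0.0, 1.0)
            tau = rng.uniform(0.05, 500.0)
            dt = rng.uniform(1e-4, 5.0)
            expected = w_inf + (w - w_inf) * math.exp(-dt / tau)
            assert ts.rush_larsen_step(w, w_inf, tau, dt) == pytest.approx(
                expected, abs=1e-12)
            assert 0.0 <= ts.rush_larsen_step(w, w_inf, tau, dt) <= 1.0

    def test_invalid_tau(self):
        with pytest.raises(RangeError):
            ts.rush_larsen_step(0.5, 0.5, 0.0, 0.1)


class TestStepMonodomain:
    def test_stability_refusal_suggests_dt(self):
        geom = ts.TissueGeometry(16, 16, 0.01)
        state = ts.init_tissue(geom, "surrogate")
        with pytest.raises(StabilityError, match="use dt <="):
            ts.step_monodomain(state, D_eff=0.01, dt=0.1)

    def test_uniform_field_diffusion_free(self, surrogate):
        geom = ts.TissueGeometry(24, 24, 0.04)
        state = ts.init_tissue(geom, "surrogate", sparams=surrogate)
        before = state.Vm.copy()
        for _ in range(50):
            ts.step_monodomain(state, D_eff=0.005, dt=0.05)
        after = state.Vm
        assert np.allclose(after, after[0, 0])  # stays uniform
        assert np.allclose(after, before, atol=0.5)

    def test_resting_plane_stays_at_rest_for_one_second(self, surrogate):
        geom = ts.TissueGeometry(16, 16, 0.04)
        state = ts.init_tissue(geom, "surrogate", sparams=surrogate)
        rest = state.Vm.copy()
        ts.advance(state, D_eff=0.005, dt=0.05, n_steps=20000)
        assert np.max(np.abs(state.Vm - rest)) < 0.5

    def test_surrogate_decoupling_matches_isolated_cell(self, surrogate):
        """D = 0: every tissue node integrates exactly like the single cell."""
        geom = ts.TissueGeometry(8, 8, 0.04)
        state = ts.init_tissue(geom, "surrogate", sparams=surrogate)
        dt, t_end = 0.05, 200.0
        stim = np.full((8, 8), 0.3)
        n_on = int(3.0 / dt)
        ts.advance(state, 0.0, dt, n_on, stim)
        ts.advance(state, 0.0, dt, int(t_end / dt) - n_on)
        tt = np.empty(4)
        vv = np.empty(4)
        v_cell, h_cell, _ = sd.ms_integrate_cell(
            0.0, 1.0, surrogate.tau_in, surrogate.tau_out, surrogate.tau_open,
            surrogate.tau_close, surrogate.v_gate, t_end, dt,
            np.array([0.0]), 3.0, 0.3, 1e9, tt, vv)
        assert np.allclose(state.v, v_cell, atol=1e-9)
        assert np.allclose(state.h, h_cell, atol=1e-9)

    def test_ionic_decoupling_matches_isolated_cell(self, caf_params, caf_rest):
        geom = ts.TissueGeometry(8, 8, 0.01)
        state = ts.init_tissue(geom, "ionic", params=caf_params,
                               resting_state=caf_rest)
        dt, t_end, amp = 0.02, 100.0, 20.0
        stim = np.full((8, 8), amp)
        n_on = int(3.0 / dt)
        ts.advance(state, 0.0, dt, n_on, stim)
        ts.advance(state, 0.0, dt, int(t_end / dt) - n_on)
        s = caf_rest.copy()
        tt = np.empty(4)
        vv = np.empty(4)
        cm._integrate_cell(s, caf_params.as_array(), 0.0, t_end, dt,
                           np.array([0.0]), 3.0, amp, 1e9, tt, vv)
        assert np.allclose(state.S[3, 5], s, atol=1e-9)

    def test_mirror_symmetry_preserved(self, surrogate):
        geom = ts.TissueGeometry(32, 32, 0.04)
        state = ts.init_tissue(geom, "surrogate", sparams=surrogate)
        stim = np.zeros((32, 32))
        stim[:, 14:18] = 0.4  # symmetric about the vertical midline
        stim += stim[:, ::-1]
        stim *= 0.5
        ts.advance(state, 0.005, 0.05, 60, stim)
        for _ in range(100):
            ts.step_monodomain(state, 0.005, 0.05)
        assert np.allclose(state.Vm, state.Vm[:, ::-1], atol=1e-9)

    def test_nan_reported_with_location(self, surrogate):
        geom = ts.TissueGeometry(8, 8, 0.04)
        state = ts.init_tissue(geom, "surrogate", sparams=surrogate)
        state.v[3, 4] = np.nan
        with pytest.raises(Exception, match="row=3, col=4"):
            state.check_finite()


class TestConductionVelocity:
    def test_sqrt2_scaling(self, surrogate):
        geom = ts.TissueGeometry(300, 8, 0.01, "strip")
        cv1 = ts.measure_cv(geom, ts.D_BASELINE, sparams=surrogate)
        cv2 = ts.measure_cv(geom, 2 * ts.D_BASELINE, sparams=surrogate)
        assert cv2 / cv1 == pytest.approx(math.sqrt(2.0), rel=0.05)

    def test_baseline_cv_in_config_band(self, surrogate):
        geom = ts.TissueGeometry(300, 8, 0.01, "strip")
        cv = ts.measure_cv(geom, ts.D_BASELINE, sparams=surrogate)
        assert cv == pytest.approx(40.0, rel=0.10)

    def test_no_diffusion_no_propagation(self, surrogate):
        geom = ts.TissueGeometry(300, 8, 0.01, "strip")
        with pytest.raises(PropagationError):
            ts.measure_cv(geom, 0.0, sparams=surrogate)


class TestS1S2:
    def test_movie_contract_and_quiescent_outcome(self, surrogate):
        geom = ts.desk_geometry("normal", 100)
        prof = IonicProfile("quiet")
        proto = ts.StimulusProtocol(observation=500.0, s2_coupling=2000.0)
        res = ts.run_s1s2(prof, geom, None, proto, model="surrogate", dt=0.1)
        assert res.dt_out == 1.0
        assert res.movie.shape[1:] == (100, 100)
        # S2 long after repolarization: a plain planar beat, then quiescence
        tail = res.movie[-100:]
        assert tail.max() < -60.0

    def test_zero_amplitude_s2_leaves_no_activity(self, surrogate):
        geom = ts.desk_geometry("normal", 100)
        prof = IonicProfile("p")
        proto = ts.StimulusProtocol(observation=400.0, amplitude=0.0)
        res = ts.run_s1s2(prof, geom, None, proto, model="surrogate", dt=0.1)
        assert res.movie[-50:].max() < -60.0

    def test_movie_hdf5_round_trip(self, tmp_path, surrogate):
        geom = ts.TissueGeometry(20, 20, 0.04)
        prof = IonicProfile("rt")
        proto = ts.StimulusProtocol(n_s1=1, observation=100.0,
                                    s2_coupling=300.0)
        res = ts.run_s1s2(prof, geom, None, proto, model="surrogate", dt=0.1)
        path = tmp_path / "movie.h5"
        ts.save_movie(res, path)
        back = ts.load_movie(path)
        assert back.movie.shape == res.movie.shape
        assert np.allclose(back.movie, res.movie)
        assert back.s2_time == res.s2_time
        assert back.geometry.dx == geom.dx

    def test_dt_refinement_changes_apd_under_one_percent(self, caf_params,
                                                         caf_rest,
                                                         caf_threshold):
        from afpom.population import compute_biomarkers

        amp = 2 * caf_threshold
        apds = []
        for dt in (0.02, 0.01):
            tr = cm.run_paced_cell(caf_params, 3, 1000.0, stim_amplitude=amp,
                                   dt=dt, initial_state=caf_rest)
            apds.append(compute_biomarkers(tr.t, tr.Vm, tr.stim_times, 1).APD90)
        assert abs(apds[0] - apds[1]) / apds[1] < 0.01
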