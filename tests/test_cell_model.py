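"""Ionic cell model: remodeling arithmetic, pacing behavior, refractoriness."""

import dataclasses

import numpy as np
import pytest

from afpom import cell_model as cm
from afpom.errors import InvalidParameterError, NumericalStateError, RangeError
from afpom.population import compute_biomarkers


class TestRemodeling:
    def test_remodeling_scalars(self):
        base = cm.BaselineParameters()
        out = cm.apply_caf_remodeling(base)
        assert out.gCaL == pytest.approx(base.gCaL * 0.45)
        assert out.gto == pytest.approx(base.gto * 0.38)
        assert out.gKur == pytest.approx(base.gKur * 0.62)
        assert out.gK1 == pytest.approx(base.gK1 * 1.62)
        assert out.gNCX_scale == pytest.approx(1.50)
        assert out.serca_scale == pytest.approx(0.84)
        assert out.plb_scale == pytest.approx(1.18)
        assert out.sln_scale == pytest.approx(0.60)

    def test_remodeling_leaves_other_fields(self):
        base = cm.BaselineParameters(Na_o=130.0)
        out = cm.apply_caf_remodeling(base)
        assert out.Na_o == 130.0
        assert out.gNa == base.gNa
        assert out.Cm == base.Cm

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            cm.BaselineParameters(gNa=0.0)
        with pytest.raises(InvalidParameterError):
            cm.BaselineParameters(K_o=-5.4)


class TestScaleProfile:
    def test_identity_profile(self, caf_params):
        prof = cm.IonicProfile("ones")
        assert cm.scale_profile(caf_params, prof) == caf_params

    def test_multiplier_application(self, caf_params):
        prof = cm.IonicProfile("p", m_gNa=0.5, m_gK1=1.0912)
        out = cm.scale_profile(caf_params, prof)
        assert out.gNa == pytest.approx(caf_params.gNa * 0.5)
        assert out.gK1 == pytest.approx(caf_params.gK1 * 1.0912)
        assert out.K_o == caf_params.K_o

    def test_out_of_range_multiplier(self):
        with pytest.raises(RangeError):
            cm.IonicProfile("bad", m_gCaL=2.5)
        with pytest.raises(RangeError):
            cm.IonicProfile("bad", m_D=0.4)

    def test_deterministic_and_bit_stable(self, caf_params):
        prof = cm.IonicProfile("ones")
        a = cm.scale_profile(cm.apply_caf_remodeling(cm.BaselineParameters()), prof)
        b = cm.scale_profile(cm.apply_caf_remodeling(cm.BaselineParameters()), prof)
        assert a.as_array().tobytes() == b.as_array().tobytes()


class TestDerivatives:
    def test_resting_drift_small(self, caf_params, caf_rest):
        state = cm.CellState.from_array(caf_rest)
        dv, gate_rates, dconc = cm.cell_derivatives(state, caf_params, 0.0)
        assert abs(dv) <= 0.01  # mV/ms after equilibration

    def test_gate_at_steady_state_is_fixed_point(self, caf_params, caf_rest):
        state = cm.CellState.from_array(caf_rest)
        _, gate_rates, _ = cm.cell_derivatives(state, caf_params, 0.0)
        # drive each gate to its own w_inf: the Rush-Larsen update is then the identity
        for k, (w_inf, tau) in enumerate(gate_rates):
            relaxed = w_inf + (w_inf - w_inf) * np.exp(-0.02 / tau)
            assert relaxed == pytest.approx(w_inf)
            assert 0.0 <= w_inf <= 1.0
            assert tau > 0.0

    def test_depolarizing_stimulus_sign(self, caf_params, caf_rest):
        state = cm.CellState.from_array(caf_rest)
        dv, _, _ = cm.cell_derivatives(state, caf_params, 30.0)
        assert dv > 0.0

    def test_nan_state_names_variable(self, caf_params, caf_rest):
        bad = caf_rest.copy()
        bad[12] = np.nan  # Ca_i
        with pytest.raises(NumericalStateError, match="Ca_i"):
            cm.cell_derivatives(cm.CellState.from_array(bad), caf_params)


class TestPacing:
    def test_no_stimulus_no_aps(self, caf_params, caf_rest):
        tr = cm.run_paced_cell(caf_params, 2, 600.0, stim_amplitude=0.0,
                               initial_state=caf_rest)
        assert tr.Vm.max() - tr.Vm.min() < 5.0

    def test_fifteen_beats_fifteen_upstrokes(self, caf_params, caf_rest,
                                             caf_threshold):
        tr = cm.run_paced_cell(caf_params, 15, 1000.0,
                               stim_amplitude=2 * caf_threshold,
                               initial_state=caf_rest)
        assert cm.count_upstrokes(tr.t, tr.Vm) == 15
        assert not tr.repolarization_failure
        # gating variables stay in [0, 1] through the whole train
        gates = tr.final_state[cm.GATE_SLICE]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)

    def test_threshold_bisection_separates(self, caf_params, caf_rest,
                                           caf_threshold):
        hi = cm.run_paced_cell(caf_params, 1, 600.0,
                               stim_amplitude=2 * caf_threshold,
                               initial_state=caf_rest)
        lo = cm.run_paced_cell(caf_params, 1, 600.0,
                               stim_amplitude=0.5 * caf_threshold,
                               initial_state=caf_rest)
        assert cm.count_upstrokes(hi.t, hi.Vm) == 1
        assert cm.count_upstrokes(lo.t, lo.Vm) == 0

    def test_invalid_args(self, caf_params):
        with pytest.raises(RangeError):
            cm.run_paced_cell(caf_params, 0, 1000.0)
        with pytest.raises(RangeError):
            cm.run_paced_cell(caf_params, 1, 2.0, stim_duration=3.0)


class TestRefractoriness:
    def test_early_s2_blocked_late_s2_captures(self, caf_params, caf_rest,
                                               caf_threshold):
        amp = 2 * caf_threshold
        # S2 10 ms after the S1 upstroke: absolutely refractory
        t, v, _ = cm.run_stimulus_sequence(caf_params, [10.0, 20.0],
                                           stim_amplitude=amp,
                                           initial_state=caf_rest, t_end=900.0)
        assert cm.count_upstrokes(t, v) == 1
        # S2 well after full repolarization: captures again
        t, v, _ = cm.run_stimulus_sequence(caf_params, [10.0, 610.0],
                                           stim_amplitude=amp,
                                           initial_state=caf_rest, t_end=1200.0)
        assert cm.count_upstrokes(t, v) == 2


class TestAPDMonotonicity:
    @staticmethod
    def _apd90(params, rest, amp):
        tr = cm.run_paced_cell(params, 4, 1000.0, stim_amplitude=amp,
                               initial_state=rest)
        bm = compute_biomarkers(tr.t, tr.Vm, tr.stim_times, n_last=2)
        return bm.APD90

    def test_gcal_and_gk1_monotonicity(self, caf_params, caf_rest,
                                       caf_threshold):
        amp = 2 * caf_threshold
        ref = self._apd90(caf_params, caf_rest, amp)
        half_cal = dataclasses.replace(caf_params, gCaL=caf_params.gCaL * 0.5)
        assert self._apd90(half_cal, caf_rest, amp) < ref
        apds = []
        for m in (0.5, 1.0, 2.0):
            p = dataclasses.replace(caf_params, gK1=caf_params.gK1 * m)
            apds.append(self._apd90(p, caf_rest, amp))
        assert apds[0] > apds[1] > apds[2]
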