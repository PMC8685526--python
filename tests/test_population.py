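"""LHS sampling, biomarker extraction, and strip calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afpom import population as pop
from afpom import synthetic_data as sd
from afpom.cell_model import IonicProfile, MULTIPLIER_NAMES
from afpom.errors import NoAPError, RangeError


class TestLHS:
    def test_shape_and_range(self):
        m = pop.lhs_sample(500, 9, seed=7)
        assert m.shape == (500, 9)
        assert m.min() >= 0.5 and m.max() <= 2.0

    def test_single_row(self):
        m = pop.lhs_sample(1, 9, seed=0)
        assert m.shape == (1, 9)
        assert np.all((m >= 0.5) & (m <= 2.0))

    def test_stratum_occupancy(self):
        n, dims = 16, 3
        m = pop.lhs_sample(n, dims, seed=3)
        edges = np.linspace(0.5, 2.0, n + 1)
        for d in range(dims):
            counts, _ = np.histogram(m[:, d], bins=edges)
            assert np.all(counts == 1)

    def test_seed_reproducibility(self):
        a = pop.lhs_sample(64, 9, seed=11)
        b = pop.lhs_sample(64, 9, seed=11)
        c = pop.lhs_sample(64, 9, seed=12)
        assert a.tobytes() == b.tobytes()
        assert a.tobytes() != c.tobytes()

    def test_invalid_n(self):
        with pytest.raises(RangeError):
            pop.lhs_sample(0, 9, seed=1)


class TestBiomarkers:
    def test_piecewise_linear_closed_form(self):
        t, v, stim, analytic = sd.gen_ap_trace(rest=-80.0, peak=20.0,
                                               apd90=270.0, shape="linear")
        bm = pop.compute_biomarkers(t, v, stim, n_last=1)
        assert bm.APA == pytest.approx(100.0, abs=1.0)
        assert bm.APD90 == pytest.approx(270.0, abs=1.0)
        assert bm.APD50 == pytest.approx(150.0, abs=1.0)
        assert bm.APD20 == pytest.approx(60.0, abs=1.0)
        assert bm.RMP == pytest.approx(-80.0, abs=0.5)
        assert bm.V20 == pytest.approx(0.0, abs=1.0)

    def test_constant_trace_raises_no_ap(self):
        t = np.arange(0.0, 1000.0)
        v = np.full_like(t, -80.0)
        with pytest.raises(NoAPError):
            pop.compute_biomarkers(t, v, [10.0], n_last=1)

    def test_identical_beats_average_equals_single(self):
        t, v, stim, _ = sd.gen_ap_trace(n_beats=2, cl=1000.0)
        two = pop.compute_biomarkers(t, v, stim, n_last=2)
        one = pop.compute_biomarkers(t, v, stim, n_last=1)
        for name in ("APD20", "APD50", "APD90", "APA", "RMP", "V20"):
            assert getattr(two, name) == pytest.approx(getattr(one, name), abs=1e-9)

    def test_n_last_validation(self):
        t, v, stim, _ = sd.gen_ap_trace()
        with pytest.raises(RangeError):
            pop.compute_biomarkers(t, v, stim, n_last=2)


class TestConstraints:
    def test_min_above_max_rejected(self):
        with pytest.raises(RangeError):
            pop.BiomarkerConstraints({"APD90": (300.0, 200.0)})

    def test_unknown_biomarker_rejected(self):
        with pytest.raises(RangeError):
            pop.BiomarkerConstraints({"APD95": (0.0, 1.0)})

    @given(
        apd90=st.floats(50, 500), widen=st.floats(0, 200),
        lo=st.floats(100, 300))
    @settings(max_examples=50, deadline=None)
    def test_widening_is_monotone(self, apd90, widen, lo):
        """If a biomarker set passes a box, it passes every wider box."""
        bm = pop.APBiomarkers(10.0, 20.0, apd90, 100.0, -80.0, 0.0)
        tight = pop.BiomarkerConstraints({"APD90": (lo, lo + 100.0)})
        wide = pop.BiomarkerConstraints({"APD90": (lo - widen, lo + 100.0 + widen)})
        if tight.contains(bm):
            assert wide.contains(bm)

    def test_csv_round_trip(self, tmp_path):
        box = sd.gen_constraint_box()
        path = tmp_path / "c.csv"
        box.to_csv(path)
        loaded = pop.BiomarkerConstraints.from_csv(path)
        assert dict(loaded.bounds) == {k: tuple(v) for k, v in box.bounds.items()}


class TestCalibration:
    def test_probe_index_convention(self):
        assert pop.probe_rc(500) == (1, 244)
        assert pop.probe_rc(620) == (2, 108)
        assert pop.probe_rc(748) == (2, 236)

    def test_invalid_probe_rejected(self):
        with pytest.raises(RangeError):
            pop.calibrate_population([IonicProfile("x")],
                                     sd.gen_constraint_box(),
                                     probe_cells=[99999])

    def test_all_ones_accepted_in_default_box(self):
        """Self-consistency: the unmodified surrogate lands inside the
        stand-in constraint box at every probe cell."""
        recs = pop.calibrate_population([IonicProfile("ones")],
                                        sd.gen_constraint_box(),
                                        model="surrogate", dx=0.04)
        assert len(recs) == 1 and recs[0].accepted
        for bm in recs[0].biomarkers.values():
            assert bm.APD20 <= bm.APD50 <= bm.APD90
            assert bm.APA > 0

    def test_wide_and_impossible_boxes(self):
        profs = [IonicProfile("a"), IonicProfile("b", m_gCaL=1.3)]
        wide = pop.BiomarkerConstraints(
            {k: (-1e9, 1e9) for k in pop.BIOMARKER_NAMES})
        recs = pop.calibrate_population(profs, wide, model="surrogate",
                                        n_beats=6, dx=0.04)
        assert [r.accepted for r in recs] == [True, True]
        assert [r.profile.profile_id for r in recs] == ["a", "b"]
        impossible = pop.BiomarkerConstraints({"APD90": (1e6, 2e6)})
        recs = pop.calibrate_population(profs, impossible, model="surrogate",
                                        n_beats=6, dx=0.04)
        assert not any(r.accepted for r in recs)
        assert all(r.reason == "constraints" for r in recs)
        # biomarkers are still recorded for rejected candidates
        assert all(np.isfinite(r.biomarkers[620].APD90) for r in recs)

    def test_unexcitable_candidate_marked_not_crashing(self):
        # gNa halved and outward currents doubled: the surrogate cannot fire
        dead = IonicProfile("dead", m_gNa=0.5, m_gK1=2.0, m_gKur=2.0)
        recs = pop.calibrate_population([dead, IonicProfile("ok")],
                                        sd.gen_constraint_box(variant="surrogate"),
                                        model="surrogate", n_beats=6, dx=0.04)
        assert recs[0].accepted is False
        assert recs[1].accepted is True

    def test_population_table_schema(self):
        recs = pop.calibrate_population([IonicProfile("ones")],
                                        sd.gen_constraint_box(),
                                        model="surrogate", n_beats=6, dx=0.04)
        table = pop.population_table(recs)
        for name in MULTIPLIER_NAMES:
            assert name in table.columns
        assert "cell620_APD90" in table.columns
        assert table.loc[0, "profile_id"] == "ones"
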