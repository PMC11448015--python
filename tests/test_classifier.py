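import numpy as np
import pandas as pd
import pytest

import pvasync as pv
from pvasync.classifier import (
    ClassifierParams,
    compute_aix,
    count_flow_peaks,
    detect_efforts,
    segment_cycles,
    summarize_group,
)
from pvasync.record import WaveformRecord


def make_record(flow_ls, paw=None, peso=None, fs=100.0):
    n = len(flow_ls)
    return WaveformRecord(
        fs=fs,
        t=np.arange(n) / fs,
        flow=np.asarray(flow_ls) * 60.0,
        paw=np.full(n, 10.0) if paw is None else np.asarray(paw),
        peso=np.full(n, 5.0) if peso is None else np.asarray(peso),
    )


class TestSegmentation:
    def test_flat_record_has_no_cycles(self):
        rec = make_record(np.zeros(2000))
        assert segment_cycles(rec) == []

    def test_square_wave_cycle_count_and_ti(self):
        # +-0.5 L/s square wave, period 2 s, 60 s -> 30 cycles of Ti 1 s
        t = np.arange(6000) / 100.0
        flow = np.where((t % 2.0) < 1.0, 0.5, -0.5)
        cycles = segment_cycles(make_record(flow))
        assert len(cycles) == 30
        assert all(abs(c.ti - 1.0) < 0.05 for c in cycles)
        assert all(abs(c.vt_insp - 0.5) < 0.02 for c in cycles)

    def test_simulated_passive_run_cycle_count(self):
        subject = pv.SubjectParams(effort_amplitude_Pmax=0.0)
        vent = pv.VentSettings(mode=pv.Mode.PC_AC, rr_set=30.0)
        res = pv.run_experiment(subject, vent, None, 600.0, seed=1)
        cycles = segment_cycles(res.record)
        assert abs(len(cycles) - 300) <= 1

    def test_low_rate_rejected(self):
        rec = make_record(np.zeros(100))
        with pytest.raises(ValueError):
            segment_cycles(rec, fs=20.0)


class TestEffortDetection:
    def test_constant_peso_no_efforts(self):
        assert detect_efforts(np.full(3000, 5.0), 100.0) == []

    def test_synthetic_dip_detected_with_magnitude(self):
        # 5 cmH2O dip lasting ~400 ms
        peso = np.full(3000, 5.0)
        peso[1000:1010] = np.linspace(5, 0, 10)
        peso[1010:1040] = 0.0
        peso[1040:1050] = np.linspace(0, 5, 10)
        events = detect_efforts(peso, 100.0)
        assert len(events) == 1
        assert events[0].magnitude == pytest.approx(5.0, abs=0.3)
        assert events[0].onset == pytest.approx(10.05, abs=0.2)

    def test_cardiac_oscillation_rejected(self):
        # 1 cmH2O peak-to-peak cardiac artifact stays below theta_dip
        t = np.arange(3000) / 100.0
        peso = 5.0 + 0.5 * np.sin(2 * np.pi * 1.5 * t)
        assert detect_efforts(peso, 100.0) == []

    def test_brief_dip_rejected(self):
        peso = np.full(3000, 5.0)
        peso[1000:1006] = 0.0  # 60 ms < 100 ms minimum
        assert detect_efforts(peso, 100.0) == []


class TestFlowPeaks:
    def _cycle_and_record(self, flow, paw=None):
        rec = make_record(flow, paw=paw)
        cycles = segment_cycles(rec)
        assert len(cycles) == 1
        return cycles[0], rec

    def test_monotone_rise_fall_is_one_peak(self):
        flow = np.concatenate([np.zeros(50), np.linspace(0, 1, 50),
                               np.linspace(1, 0, 100), np.zeros(100)])
        c, rec = self._cycle_and_record(flow)
        assert count_flow_peaks(c, rec) == 1

    def test_m_shape_is_two_peaks(self):
        # two flow humps while the airway pressure is still ramping
        hump = lambda n, h: h * np.sin(np.linspace(0, np.pi, n))
        flow = np.concatenate([np.zeros(50), hump(60, 1.0), hump(60, 0.6),
                               np.zeros(130)])
        paw = np.full(300, 10.0)
        paw[50:170] = np.linspace(10.0, 20.0, 120)  # slow ramp under both humps
        paw[170:185] = 20.0
        c, rec = self._cycle_and_record(flow, paw=paw)
        assert count_flow_peaks(c, rec) == 2

    def test_ripple_below_prominence_ignored(self):
        base = np.sin(np.linspace(0, np.pi, 200))
        ripple = 0.03 * np.sin(np.linspace(0, 20 * np.pi, 200))
        flow = np.concatenate([np.zeros(50), base + ripple, np.zeros(50)])
        c, rec = self._cycle_and_record(flow)
        assert count_flow_peaks(c, rec) == 1


class TestAixArithmetic:
    def _annotations(self, labels):
        return pd.DataFrame({"label": labels})

    def test_quarter(self):
        rep = compute_aix(self._annotations(["IE"] * 10 + ["NORMAL"] * 30))
        assert rep.aix == pytest.approx(0.25)
        assert rep.incidence["IE"] == pytest.approx(0.25)

    def test_all_normal(self):
        rep = compute_aix(self._annotations(["NORMAL"] * 20))
        assert rep.aix == 0.0

    def test_dt_cluster_counts_every_cycle(self):
        rep = compute_aix(self._annotations(["NORMAL"] * 97 + ["DT"] * 3))
        assert rep.aix == pytest.approx(0.03)
        assert rep.incidence["DT"] == pytest.approx(0.03)

    def test_incidences_sum_to_aix(self):
        rep = compute_aix(self._annotations(["IE", "AT", "DT", "NORMAL", "OTHER"] * 8))
        assert sum(rep.incidence.values()) == pytest.approx(rep.aix)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_aix(self._annotations([]))


class TestSummaries:
    def test_median_and_iqr_interpolation(self):
        out = summarize_group([10.0, 20.0, 30.0])
        row = out.iloc[0]
        assert row["median"] == 20.0
        assert row["q1"] == 15.0 and row["q3"] == 25.0

    def test_single_value_degenerate(self):
        row = summarize_group([42.0]).iloc[0]
        assert row["median"] == row["q1"] == row["q3"] == 42.0

    def test_grouped(self):
        rows = [{"value": v, "arm": a} for v, a in
                [(25, "ASY"), (27, "ASY"), (0, "SYN"), (2, "SYN")]]
        out = summarize_group(rows, group_keys=["arm"]).set_index("arm")
        assert out.loc["ASY", "median"] == 26.0
        assert out.loc["SYN", "median"] == 1.0


class TestClassification:
    def test_requires_peso(self):
        rec = make_record(np.zeros(1000))
        rec.peso = None
        with pytest.raises(ValueError):
            pv.classify_record(rec)

    def test_deterministic(self, study_asy_run):
        res, table, _ = study_asy_run
        table2, _ = pv.classify_record(res.record)
        assert table.equals(table2)

    def test_null_specificity_exact(self, study_syn_run):
        _, _, report = study_syn_run
        assert report.aix == 0.0

    def test_one_label_per_cycle(self, study_asy_run):
        _, table, _ = study_asy_run
        assert table["cycle_index"].is_unique
        assert table["label"].isin(["NORMAL", "IE", "AT", "DT", "OTHER"]).all()

    def test_pinsp_zero_regression_is_not_ie(self):
        # setting the inspiratory pressure to PEEP leaves a full flow
        # cycle driven by the subject (pressure compensation) -> no IE
        res = pv.run_scenario(pv.make_scenario("bench_ie_pinsp_zero"),
                              duration=300, seed=1)
        _, report = pv.classify_record(res.record)
        assert report.counts["IE"] == 0
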