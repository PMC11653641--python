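"""Neural-mass-model unit tests: kernel, sigmoid, dynamics, classification,
grid exploration and bank balancing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ictalesi import nmm


class TestPSPKernel:
    def test_zero_at_origin(self):
        assert nmm.psp_kernel(3.25, 0.1, 0.0) == 0.0

    def test_peak_at_inverse_rate(self):
        Q, q = 7.0, 0.05
        t = np.linspace(0, 200, 20001)
        h = nmm.psp_kernel(Q, q, t)
        assert t[np.argmax(h)] == pytest.approx(1 / q, rel=1e-3)
        assert h.max() == pytest.approx(Q / np.e, rel=1e-6)

    def test_linear_in_gain(self):
        t = np.linspace(0, 50, 100)
        np.testing.assert_allclose(
            nmm.psp_kernel(2 * 3.3, 0.1, t), 2 * nmm.psp_kernel(3.3, 0.1, t)
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            nmm.psp_kernel(1.0, 0.1, -1.0)

    @given(st.floats(0.5, 50), st.floats(0.01, 2.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_nonnegative_and_integral_closed_form(self, Q, q):
        # numerical quadrature oracle: the kernel integrates to Q/q
        # (equal to the gain Q exactly when q = 1)
        t = np.linspace(0, 500 / q, 101)
        assert np.all(nmm.psp_kernel(Q, q, t) >= 0)
        integral, _ = quad(lambda x: nmm.psp_kernel(Q, q, x), 0, np.inf)
        assert integral == pytest.approx(Q / q, rel=1e-6)


class TestSigmoid:
    def test_midpoint_half_max(self):
        s = nmm.SigmoidParams()
        assert nmm.sigmoid_rate(s.v0, s) == pytest.approx(s.e0)

    def test_asymptotes(self):
        s = nmm.SigmoidParams()
        assert nmm.sigmoid_rate(1e4, s) == pytest.approx(2 * s.e0)
        assert nmm.sigmoid_rate(-1e4, s) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value_at_zero(self):
        # S(0) = 5 / (1 + e^(0.56 * 6)) = 5 / (1 + e^3.36)
        s = nmm.SigmoidParams(e0=2.5, v0=6.0, r=0.56)
        assert nmm.sigmoid_rate(0.0, s) == pytest.approx(5.0 / (1 + np.exp(3.36)))

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, v1, v2):
        s = nmm.SigmoidParams()
        lo, hi = sorted([v1, v2])
        r1, r2 = nmm.sigmoid_rate(lo, s), nmm.sigmoid_rate(hi, s)
        assert 0 < r1 <= r2 < 2 * s.e0 or lo == hi


class TestSimulate:
    def test_bit_reproducible(self):
        p = nmm.NMMParams()
        t1 = nmm.simulate_nmm(p, duration=2.1, seed=42)
        t2 = nmm.simulate_nmm(p, duration=2.1, seed=42)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_deterministic_without_noise(self):
        p = nmm.NMMParams(p_sd=0.0)
        t1 = nmm.simulate_nmm(p, duration=2.1, seed=1)
        t2 = nmm.simulate_nmm(p, duration=2.1, seed=999)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_trace_length_and_finiteness(self):
        tr = nmm.simulate_nmm(nmm.NMMParams(), duration=3.0, sample_rate=250.0)
        assert tr.values.size == 750
        assert np.all(np.isfinite(tr.values))

    def test_classic_alpha_regime(self):
        # three-population reduction (fast loop off) with the classic
        # 120-320 pulses/s drive shows the well-known ~10 Hz limit cycle
        p = nmm.NMMParams(A=3.25, B=22.0, G=1.0, a=0.1, b=0.05, g=0.5,
                          c5=0.0, c6=0.0, c7=0.0, p_mean=220.0, p_sd=30.0)
        tr = nmm.simulate_nmm(p, duration=5.0, seed=1)
        f = nmm.waveform_features(tr)
        assert 8.0 <= f.major_frequency <= 13.0

    def test_ictal_family_produces_distinct_regimes(self):
        # the printed example family: A=5.5, B=14, G=4, g=0.5, (a, b) swept
        params = [
            nmm.NMMParams(A=5.5, B=14.0, G=4.0, a=float(a), b=float(b), g=0.5)
            for a in (0.05, 0.1, 0.15) for b in (0.025, 0.05, 0.075)
        ]
        traces, _ = nmm.simulate_nmm_batch(params, seeds=range(len(params)))
        labels = {
            nmm.classify_regime(nmm.waveform_features(t, 500.0)).label
            for t in traces
        }
        assert len(labels - {1}) >= 2

    def test_switch_is_continuous_and_changes_dynamics(self):
        p1 = nmm.NMMParams(A=5.5, B=14.0, G=4.0, a=0.1, b=0.05, g=0.5)
        p2 = nmm.NMMParams(A=5.5, B=40.0, G=4.0, a=0.05, b=0.025, g=0.2)
        traces, _ = nmm.simulate_nmm_switch([p1], [p2], [1.0], duration=2.5,
                                            seeds=[3])
        tr = traces[0]
        # no discontinuity at the switch sample beyond the regular step scale
        step = np.abs(np.diff(tr))
        assert step[499] < 50 * np.median(step) + 1.0
        assert np.std(tr[600:]) != pytest.approx(np.std(tr[:400]), rel=0.0)


class TestFeaturesAndClassifier:
    def test_pure_sinusoid_major_frequency(self):
        t = np.arange(0, 4, 1 / 500)
        f = nmm.waveform_features(np.sin(2 * np.pi * 8 * t), 500.0)
        assert f.major_frequency == pytest.approx(8.0, abs=0.5)

    def test_constant_trace(self):
        f = nmm.waveform_features(np.full(1000, 3.7), 500.0)
        assert f.line_length == 0.0
        assert np.isnan(f.major_frequency)
        assert nmm.classify_regime(f).label == 1

    def test_line_length_of_sinusoid(self):
        # total variation of a unit sinusoid is 4 per cycle -> 4 f mV/s
        fs, freq = 5000.0, 3.0
        t = np.arange(0, 4, 1 / fs)
        f = nmm.waveform_features(np.sin(2 * np.pi * freq * t), fs)
        assert f.line_length == pytest.approx(4 * freq, rel=1e-3)

    def test_quasi_sinusoid_is_type6(self):
        t = np.arange(0, 4, 1 / 500)
        x = 10.0 * np.sin(2 * np.pi * 6 * t)
        lab = nmm.classify_regime(nmm.waveform_features(x, 500.0))
        assert lab.label == 6

    def test_fast_low_voltage_is_type5(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 4, 1 / 500)
        x = 3.0 * np.sin(2 * np.pi * 20 * t) + 0.5 * rng.standard_normal(t.size)
        lab = nmm.classify_regime(nmm.waveform_features(x, 500.0))
        assert lab.label == 5

    def test_sporadic_spikes_are_type2(self):
        # two transient discharges on a smooth aperiodic background; the
        # 3-MAD peak rule must find exactly the transients (rate 0.5 Hz)
        fs = 500.0
        t = np.arange(0, 4, 1 / fs)
        x = 0.4 * np.sin(2 * np.pi * 1.3 * t) + 0.4 * np.sin(2 * np.pi * 3.7 * t)
        kernel = nmm.psp_kernel(40.0, 0.03, np.arange(200, dtype=float))
        for start in (300, 1400):
            x[start:start + 200] += kernel
        f = nmm.waveform_features(x, fs)
        assert 0 < f.spike_rate < 2.0
        assert nmm.classify_regime(f).label == 2

    def test_classifier_total_function(self):
        # every finite or non-finite feature tuple receives exactly one label
        for feat in [
            nmm.WaveformFeatures(0, np.nan, 0, 0, 0),
            nmm.WaveformFeatures(1e3, 30.0, 0, 0.99, 50.0),
            nmm.WaveformFeatures(1e3, 5.0, 0, 0.99, 50.0),
            nmm.WaveformFeatures(1e3, 5.0, 0, 0.1, 50.0, 1.0, 0.1),
            nmm.WaveformFeatures(1e3, 5.0, 0, 0.1, 50.0, 3.0, 0.1),
            nmm.WaveformFeatures(1e3, 5.0, 0, 0.1, 50.0, 3.0, 2.0),
        ]:
            assert nmm.classify_regime(feat).label in range(1, 7)

    @given(st.floats(0, 100), st.floats(0.5, 45), st.floats(0, 1),
           st.floats(0, 60), st.floats(0, 10), st.floats(0, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_classifier_deterministic_total(self, ll, mf, conc, amp, rate, cv):
        feat = nmm.WaveformFeatures(ll, mf, 0.0, conc, amp, rate, cv)
        l1 = nmm.classify_regime(feat).label
        l2 = nmm.classify_regime(feat).label
        assert l1 == l2 and l1 in range(1, 7)


class TestGridAndBank:
    def test_full_grid_axis_counts(self):
        assert nmm.GridSpec().shape == (30, 15, 11, 11, 8)

    def test_singleton_grid(self):
        grid = nmm.GridSpec(B=(14.0, 14.0, 2.0), G=(4.0, 4.0, 2.0),
                            a=(0.05, 0.05, 0.01), b=(0.025, 0.025, 0.005),
                            g=(0.5, 0.5, 0.2))
        bank = nmm.explore_parameter_grid(grid, seed=0)
        assert len(bank) == 1

    def test_prescreen_drops_normal_pairs(self):
        grid = nmm.GridSpec().thin(6)
        bank = nmm.explore_parameter_grid(grid, seed=0)
        pairs = {(e.params.B, e.params.G) for e in bank.entries}
        assert len(pairs) < len(grid.values("B")) * len(grid.values("G"))

    def test_balance_counts_exact(self, tiny_bank):
        labels = tiny_bank.labels()
        assert len(tiny_bank) == 20
        for t in nmm.ICTAL_TYPES:
            assert (labels == t).sum() == 4
        assert len(tiny_bank.subset("train")) == 16
        assert len(tiny_bank.subset("test")) == 4

    def test_balance_deterministic_and_disjoint(self, reduced_bank):
        bank = reduced_bank
        b1 = nmm.balance_parameter_sets(bank, 20, 80, 20, seed=5)
        b2 = nmm.balance_parameter_sets(bank, 20, 80, 20, seed=5)
        assert b1.to_frame().equals(b2.to_frame())
        train = {tuple(r) for r in b1.to_frame().query("split=='train'")
                 [["A", "B", "G", "a", "b", "g", "seed"]].values}
        test = {tuple(r) for r in b1.to_frame().query("split=='test'")
                [["A", "B", "G", "a", "b", "g", "seed"]].values}
        # with-replacement duplicates aside, no identical entry in both splits
        assert not (train & test)

    def test_missing_type_raises(self):
        feat = nmm.WaveformFeatures(1, 5, 0, 0.1, 10)
        entries = [nmm.BankEntry(nmm.NMMParams(), nmm.RegimeLabel(4, feat), 0)]
        bank = nmm.ParameterBank(entries)
        with pytest.raises(ValueError, match="absent"):
            nmm.balance_parameter_sets(bank, 2, 8, 2)

    def test_bank_roundtrip(self, tiny_bank, tmp_path):
        path = tmp_path / "bank.csv"
        tiny_bank.save(path)
        loaded = nmm.ParameterBank.load(path)
        assert loaded.to_frame().equals(tiny_bank.to_frame())
        assert loaded.thresholds == tiny_bank.thresholds
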