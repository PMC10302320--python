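"""Circuit model: capacitance formula, cut-off, transfer function, filtering."""

import numpy as np
import pytest

from aisqa.circuit_sim import (
    CircuitParams,
    ElectrodeGeometry,
    InvalidParameterError,
    highpass_cutoff,
    morphology_sweep,
    simulate_measurement,
    stratum_corneum_capacitance,
    transfer_function,
)


def capacitance_by_hand(eps_r, d_sc, l_elec=0.045, d_elec=0.011):
    # independent hand evaluation of the cylindrical-capacitor formula
    eps_0 = 8.8541878128e-12
    return 2 * np.pi * eps_0 * eps_r * l_elec / np.log((d_elec + d_sc) / d_elec)


class TestStratumCorneumCapacitance:
    @pytest.mark.parametrize(
        "eps_r,d_sc",
        [(1e3, 800e-6), (1e4, 100e-6), (1e5, 10e-6), (5e3, 300e-6)],
    )
    def test_matches_hand_evaluation(self, eps_r, d_sc):
        geom = ElectrodeGeometry(eps_r=eps_r, d_sc=d_sc)
        expected = capacitance_by_hand(eps_r, d_sc)
        assert stratum_corneum_capacitance(geom) == pytest.approx(expected, rel=1e-12)

    def test_reference_magnitudes(self):
        dry = ElectrodeGeometry(eps_r=1e3, d_sc=800e-6)
        humid = ElectrodeGeometry(eps_r=1e4, d_sc=100e-6)
        assert stratum_corneum_capacitance(dry) == pytest.approx(3.57e-8, rel=5e-3)
        assert stratum_corneum_capacitance(humid) == pytest.approx(2.77e-6, rel=5e-3)

    def test_linear_in_permittivity(self):
        a = ElectrodeGeometry(eps_r=2e3, d_sc=200e-6)
        b = ElectrodeGeometry(eps_r=4e3, d_sc=200e-6)
        ratio = stratum_corneum_capacitance(b) / stratum_corneum_capacitance(a)
        assert ratio == pytest.approx(2.0, rel=1e-12)

    def test_strictly_decreasing_in_thickness(self):
        grid = np.linspace(10e-6, 800e-6, 40)
        caps = [
            stratum_corneum_capacitance(ElectrodeGeometry(d_sc=d)) for d in grid
        ]
        assert np.all(np.diff(caps) < 0)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(l_elec=-1.0), dict(d_sc=0.0), dict(eps_r=0.5), dict(d_sc=0.02)],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ElectrodeGeometry(**kwargs)


class TestHighpassCutoff:
    @pytest.mark.parametrize(
        "c_cpl,expected,rel",
        [
            (0.3e-12, 10.6, 1e-2),    # printed as 10.6 Hz
            (100e-12, 0.032, 1e-2),   # printed as 0.032 Hz
            (0.1e-12, 32.0, 1e-2),    # printed as 32 Hz
            (1.0 / (2 * np.pi) / 50e9, 1.0, 1e-9),  # unit normalization
        ],
    )
    def test_cutoff_values(self, c_cpl, expected, rel):
        params = CircuitParams(C_cpl=c_cpl)
        assert highpass_cutoff(params) == pytest.approx(expected, rel=rel)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidParameterError):
            CircuitParams(C_cpl=-1e-12)


class TestTransferFunction:
    def test_dc_gain_zero(self):
        gain = transfer_function(CircuitParams(), [0.0])
        assert gain[0] == 0

    def test_passband_gain_near_unity(self):
        params = CircuitParams(C_cpl=100e-12)  # fc = 0.032 Hz
        fc = highpass_cutoff(params)
        gain = transfer_function(params, [1000 * fc])
        assert abs(gain[0]) == pytest.approx(1.0, abs=1e-2)

    def test_matches_one_pole_highpass_with_negligible_skin(self):
        params = CircuitParams(R_sc=1e-3, C_sc=1.0, C_cpl=10e-12)
        fc = highpass_cutoff(params)
        freqs = np.logspace(-2, 2, 200)
        mag = np.abs(transfer_function(params, freqs))
        analytic = freqs / np.sqrt(freqs**2 + fc**2)
        assert np.max(np.abs(mag - analytic) / analytic) < 1e-6

    def test_negative_frequency_rejected(self):
        with pytest.raises(InvalidParameterError):
            transfer_function(CircuitParams(), [-1.0])


class TestSimulateMeasurement:
    def test_constant_input_decays_to_zero(self):
        fs = 200.0
        x = np.ones(int(60 * fs))
        sim = simulate_measurement(x, fs, CircuitParams(C_cpl=10e-12))
        assert abs(sim.output_signal[-1]) < 1e-3
        assert np.mean(np.abs(sim.output_signal[-1000:])) < 1e-6

    def test_sinusoid_at_cutoff_attenuated_3db(self):
        params = CircuitParams(C_cpl=3.18e-12)
        fc = highpass_cutoff(params)
        fs = 200.0
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * fc * t)
        sim = simulate_measurement(x, fs, params)
        # steady-state amplitude after the transient settles
        tail = sim.output_signal[len(t) // 2 :]
        assert np.max(np.abs(tail)) == pytest.approx(1 / np.sqrt(2), rel=2e-2)

    def test_output_power_bounded_by_input(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=4000)
        sim = simulate_measurement(x, 200.0, CircuitParams())
        assert np.mean(sim.output_signal**2) <= np.mean(x**2) * (1 + 1e-9)

    def test_t_wave_acquires_negative_lobe_under_strong_coupling(self):
        # strong high-pass (0.3 pF): the late T region of the mean cycle
        # swings negative relative to the clean input
        from aisqa.synthetic_ecg import TEMPLATE_N_POINTS, generate_template

        fs, rr = 200.0, 1.0
        tmpl = generate_template()
        grid = np.arange(TEMPLATE_N_POINTS + 1) / TEMPLATE_N_POINTS
        t = np.arange(int(60 * fs)) / fs
        clean = np.interp((t % rr) / rr, grid, np.append(tmpl, tmpl[0]))
        sim = simulate_measurement(clean, fs, CircuitParams(C_cpl=0.3e-12))
        cyc = int(fs * rr)
        in_cycle = clean[5 * cyc : 6 * cyc]
        out_cycle = sim.output_signal[5 * cyc : 6 * cyc]
        t_window = slice(int(0.30 * cyc), int(0.45 * cyc))
        # relative to each cycle's own baseline (median), the filtered late-T
        # region dips clearly negative while the clean input does not
        in_rel = in_cycle[t_window].min() - np.median(in_cycle)
        out_rel = out_cycle[t_window].min() - np.median(out_cycle)
        assert out_rel < in_rel - 0.02
        assert out_rel < -0.02

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            simulate_measurement(np.array([]), 200.0)

    def test_deterministic(self):
        x = np.sin(np.arange(4000) * 0.1)
        a = simulate_measurement(x, 200.0).output_signal
        b = simulate_measurement(x, 200.0).output_signal
        assert np.array_equal(a, b)


class TestMorphologySweep:
    def _clean_ecg(self, duration=60.0, fs=200.0, rr=0.9):
        from aisqa.synthetic_ecg import TEMPLATE_N_POINTS, generate_template

        tmpl = generate_template()
        grid = np.arange(TEMPLATE_N_POINTS + 1) / TEMPLATE_N_POINTS
        t = np.arange(int(duration * fs)) / fs
        return np.interp((t % rr) / rr, grid, np.append(tmpl, tmpl[0]))

    def test_correlation_increases_with_coupling_capacitance(self):
        from aisqa.morphology import average_morphology, segment_beats
        from aisqa.preprocessing import detect_r_peaks

        fs = 200.0
        clean = self._clean_ecg(fs=fs)
        peaks = detect_r_peaks(clean, fs)
        ref = average_morphology(segment_beats(clean, peaks.indices)).cycle
        grid = [0.3e-12, 1e-12, 10e-12, 100e-12]
        cycles = morphology_sweep(clean, fs, grid)
        assert all(c is not None for c in cycles)
        corrs = [np.corrcoef(c, ref)[0, 1] for c in cycles]
        assert all(c2 > c1 for c1, c2 in zip(corrs, corrs[1:]))

    def test_destructive_coupling_entry_flagged_not_fatal(self):
        # fc = 32 Hz wipes out the waveform; the entry is flagged and the
        # sweep continues with the remaining grid points
        fs = 200.0
        clean = self._clean_ecg(fs=fs)
        cycles = morphology_sweep(clean, fs, [0.1e-12, 100e-12])
        assert cycles[0] is None
        assert cycles[1] is not None

    def test_large_coupling_recovers_clean_morphology(self):
        from aisqa.morphology import average_morphology, segment_beats
        from aisqa.preprocessing import detect_r_peaks

        fs = 200.0
        clean = self._clean_ecg(fs=fs)
        peaks = detect_r_peaks(clean, fs)
        ref = average_morphology(segment_beats(clean, peaks.indices)).cycle
        (cycle,) = morphology_sweep(clean, fs, [1e-6])  # fc ~ 3e-9 Hz
        assert np.corrcoef(cycle, ref)[0, 1] > 0.99

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            morphology_sweep(np.zeros(12000), 200.0, [])
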