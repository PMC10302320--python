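"""Generator: template, RR models, recordings, labels, device stand-in."""

import numpy as np
import pytest

from aisqa.synthetic_ecg import (
    DEFAULT_LABEL_MIX,
    P_PHASE_WINDOW,
    TEMPLATE_N_POINTS,
    SyntheticConfig,
    UndecidedError,
    generate_dataset,
    generate_rr_series,
    generate_template,
    quality_label_rule,
    simulate_device_decision,
    synthesize_recording,
)


class TestTemplate:
    def test_maximum_at_r_phase(self):
        tmpl = generate_template()
        assert np.argmax(tmpl) == 0  # R-peak anchored at phase 0

    def test_zero_p_amplitude_flattens_p_region(self):
        tmpl = generate_template(p_amp=0.0)
        lo, hi = (int(p * TEMPLATE_N_POINTS) for p in P_PHASE_WINDOW)
        baseline = np.median(tmpl)
        assert np.max(np.abs(tmpl[lo:hi] - baseline)) < 0.02

    def test_deterministic(self):
        assert np.array_equal(generate_template(), generate_template())

    def test_requires_positive_qrs(self):
        with pytest.raises(ValueError):
            generate_template(qrs_amp=0.0)


class TestRRSeries:
    def test_zero_variability_gives_constant_rr(self):
        rr = generate_rr_series("NSR", 60.0, 0.0, 60.0, seed=1)
        assert np.allclose(rr, 1.0)

    def test_af_much_more_irregular_than_nsr(self):
        rr_af = generate_rr_series("AF", 70.0, 0.03, 10000.0, seed=2)
        rr_nsr = generate_rr_series("NSR", 70.0, 0.03, 10000.0, seed=2)
        cv = lambda x: np.std(x) / np.mean(x)  # noqa: E731
        assert cv(rr_af) > 3 * cv(rr_nsr)
        assert cv(rr_af) >= 0.15

    def test_af_has_no_serial_correlation(self):
        rr = generate_rr_series("AF", 70.0, 0.03, 5000.0, seed=3)
        r = np.corrcoef(rr[:-1], rr[1:])[0, 1]
        assert abs(r) < 0.05

    def test_seed_reproducibility(self):
        a = generate_rr_series("AF", 80.0, 0.03, 60.0, seed=7)
        b = generate_rr_series("AF", 80.0, 0.03, 60.0, seed=7)
        assert np.array_equal(a, b)

    def test_covers_duration(self):
        rr = generate_rr_series("NSR", 45.0, 0.05, 60.0, seed=4)
        assert rr.sum() >= 60.0


class TestQualityLabelRule:
    @pytest.mark.parametrize(
        "snr,art,expected",
        [
            (np.inf, 0.0, 0),
            (25.0, 0.0, 0),
            (15.0, 0.0, 1),
            (25.0, 0.05, 1),
            (8.0, 0.0, 2),
            (25.0, 0.3, 2),
            (3.0, 0.0, 3),
            (25.0, 0.5, 3),
            (3.0, 0.5, 3),
        ],
    )
    def test_rule_table(self, snr, art, expected):
        assert quality_label_rule(snr, art) == expected

    def test_monotone_in_snr(self):
        snrs = np.linspace(0, 30, 100)
        labels = [quality_label_rule(s, 0.0) for s in snrs]
        assert np.all(np.diff(labels) <= 0)


class TestSynthesizeRecording:
    def test_noise_free_artifact_free_is_excellent(self):
        cfg = SyntheticConfig(seed=5, snr_db=np.inf, powerline_amp=0.0)
        _, truth = synthesize_recording(cfg)
        assert truth.quality_label == 0

    def test_leading_artifact_scenario(self):
        # motion artifact during the first three seconds of the recording
        cfg = SyntheticConfig(seed=6, artifact_spec=[(0.0, 3.0, "burst")])
        _, truth = synthesize_recording(cfg)
        assert truth.artifact_windows == [(0, 600)]

    def test_inversion_flips_amplitude_asymmetry(self):
        # the device-oriented trace satisfies mean < median; held upside
        # down, the dominant deflections flip and the inequality reverses
        flipped = 0
        for seed in range(100):
            rec, truth = synthesize_recording(SyntheticConfig(seed=seed, inverted=True))
            if np.mean(rec.samples) > np.median(rec.samples):
                flipped += 1
        assert flipped == 100

    def test_af_suppresses_p_wave_energy(self, clean_af_recording, clean_recording):
        from aisqa.morphology import average_morphology, segment_beats
        from aisqa.preprocessing import correct_inversion, detect_r_peaks

        for (rec, truth), is_af in [(clean_af_recording, True), (clean_recording, False)]:
            s, _ = correct_inversion(rec.samples)
            peaks = detect_r_peaks(s, rec.fs)
            morph = average_morphology(segment_beats(s, peaks.indices))
            lo, hi = (int(p * morph.cycle.size) for p in P_PHASE_WINDOW)
            r_amp = np.max(np.abs(morph.cycle))
            baseline = np.median(morph.cycle)
            p_energy = np.mean(np.abs(morph.cycle[lo:hi] - baseline)) / r_amp
            if is_af:
                assert p_energy < 0.05
            else:
                assert p_energy > 0.02

    def test_seed_determinism(self):
        cfg = SyntheticConfig(seed=9, artifact_spec=[(10.0, 5.0, "saturation")])
        r1, t1 = synthesize_recording(cfg)
        r2, t2 = synthesize_recording(cfg)
        assert np.array_equal(r1.samples, r2.samples)
        assert np.array_equal(t1.r_peaks, t2.r_peaks)

    def test_label_monotone_in_snr(self):
        labels = []
        for snr in [30.0, 15.0, 8.0, 2.0]:
            _, truth = synthesize_recording(SyntheticConfig(seed=10, snr_db=snr))
            labels.append(truth.quality_label)
        assert labels == sorted(labels)

    def test_unknown_artifact_kind_rejected(self):
        cfg = SyntheticConfig(seed=11, artifact_spec=[(0.0, 5.0, "gremlin")])
        with pytest.raises(ValueError):
            synthesize_recording(cfg)


class TestGenerateDataset:
    def test_degenerate_mix(self):
        data = generate_dataset(20, label_mix=(1.0, 0.0, 0.0, 0.0), seed=1)
        assert all(t.quality_label == 0 for _, t in data)

    def test_default_mix_frequencies(self):
        data = generate_dataset(4000, seed=2)
        labels = np.array([t.quality_label for _, t in data])
        freqs = np.bincount(labels, minlength=4) / len(labels)
        assert np.all(np.abs(freqs - np.asarray(DEFAULT_LABEL_MIX)) < 0.02)

    def test_seed_determinism(self):
        a = generate_dataset(10, seed=3)
        b = generate_dataset(10, seed=3)
        for (ra, ta), (rb, tb) in zip(a, b):
            assert np.array_equal(ra.samples, rb.samples)
            assert ta.quality_label == tb.quality_label

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_dataset(0)
        with pytest.raises(ValueError):
            generate_dataset(5, label_mix=(0.5, 0.5, 0.5, 0.5))


class TestDeviceDecision:
    def test_constant_rr_is_normal(self):
        assert simulate_device_decision(np.full(20, 0.8)) == "normal"

    def test_af_generator_detected(self):
        hits = 0
        for seed in range(300):
            rr = generate_rr_series("AF", 75.0, 0.03, 60.0, seed=seed)
            hits += simulate_device_decision(rr) == "AF"
        assert hits >= 0.95 * 300

    def test_nsr_generator_not_detected(self):
        hits = 0
        for seed in range(300):
            rr = generate_rr_series("NSR", 75.0, 0.03, 60.0, seed=seed)
            hits += simulate_device_decision(rr) == "normal"
        assert hits >= 0.95 * 300

    def test_infinite_threshold_always_normal(self):
        rr = generate_rr_series("AF", 75.0, 0.03, 60.0, seed=1)
        assert simulate_device_decision(rr, threshold=np.inf) == "normal"

    def test_too_few_intervals(self):
        with pytest.raises(UndecidedError):
            simulate_device_decision(np.full(5, 0.8))
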