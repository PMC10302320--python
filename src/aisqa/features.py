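"""The 22-entry multi-domain feature vector of one preprocessed recording.

Four feature families, concatenated in a fixed order:

* statistical (5): mean, median, standard deviation, skewness, kurtosis of
  the valid segment's amplitude distribution;
* time-domain (5): mean heart rate, SDNN, valid-segment coverage, mean eCDF
  window-consistency, DTW distance between the averaged morphologies of the
  segment's two halves;
* frequency-domain (6): mean FFT window-consistency, baseline-wander SQI,
  QRS-power SQI, power-line SQI, in-band/out-of-band SNR, and their mean;
* morphology (6): mean R amplitude, mean template spread, and Euclidean /
  cityblock / DTW / correlation similarity of the amplitude-normalized mean
  morphology to the best-matching ideal prototype.

Statistical features are amplitude-covariant by design; morphology
distances are computed on unit-R-amplitude cycles so they measure shape
only, leaving ``r_amp`` as the single amplitude feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .morphology import (
    BeatMorphology,
    PrototypeSet,
    average_morphology,
    dtw_distance,
    segment_beats,
)
from .preprocessing import (
    ArtifactAnalysis,
    ECGRecording,
    PeakList,
    correct_inversion,
    detect_artifacts,
    detect_r_peaks,
    longest_valid_segment,
    validate_heart_rate,
)

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    # statistical
    "mean", "median", "std", "skewness", "kurtosis",
    # time-domain
    "mean_hr", "sdnn", "coverage", "ecdf_consistency", "signal_consistency",
    # frequency-domain
    "fft_consistency", "bas_sqi", "qrs_sqi", "pli_sqi", "snr", "mean_sqi",
    # morphology
    "r_amp", "template_std", "eucl_dist", "cityblock_dist", "dtw_dist", "proto_cc",
)

SUBGROUPS = {
    "statistical": FEATURE_NAMES[0:5],
    "time_domain": FEATURE_NAMES[5:10],
    "frequency_domain": FEATURE_NAMES[10:16],
    "morphology": FEATURE_NAMES[16:22],
}

#: Welch estimation: 4 s Hann windows, 50% overlap (0.25 Hz resolution)
WELCH_NPERSEG_S = 4.0

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "SUBGROUPS",
    "HeartRateGateError",
    "statistical_features",
    "time_domain_features",
    "frequency_domain_features",
    "morphology_features",
    "extract_features",
]


class HeartRateGateError(RuntimeError):
    """Median heart rate outside the physiologic 40-150 bpm gate."""


@dataclass(frozen=True)
class FeatureVector:
    """The 22 named features of one recording, fixed order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("features must be finite")
        object.__setattr__(self, "values", v)

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, map(float, self.values)))


def statistical_features(segment: np.ndarray) -> np.ndarray:
    """Mean, median, std, skewness, kurtosis of the amplitude distribution.

    Skewness is bias-corrected; kurtosis is the raw 4th standardized moment
    (a normal distribution scores 3).  A constant segment degenerates to
    std = skewness = kurtosis = 0 (logged).
    """
    x = np.asarray(segment, dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        logger.warning("constant segment: skewness/kurtosis set to 0")
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=False, bias=False))
    return np.array([float(np.mean(x)), float(np.median(x)), sd, skew, kurt])


def time_domain_features(
    segment: np.ndarray,
    peaks: PeakList,
    analysis: ArtifactAnalysis,
    t_seg: float,
) -> np.ndarray:
    """mean HR, SDNN, coverage, eCDF consistency, half-vs-half morphology DTW."""
    rr_s = peaks.rr_ms / 1000.0
    if rr_s.size < 2:
        raise ValueError("need at least 2 RR intervals")
    mean_hr = 60.0 / float(np.mean(rr_s))
    sdnn = float(np.std(peaks.rr_ms, ddof=1))
    ecdf_consistency = float(np.mean(analysis.cc_ecdf))
    signal_consistency = _half_consistency(segment, peaks)
    return np.array([mean_hr, sdnn, float(t_seg), ecdf_consistency, signal_consistency])


def _half_consistency(segment: np.ndarray, peaks: PeakList) -> float:
    """DTW distance between the averaged morphologies of the two halves."""
    mid = segment.size // 2
    first = peaks.indices[peaks.indices < mid]
    second = peaks.indices[peaks.indices >= mid] - mid
    m1 = average_morphology(segment_beats(segment[:mid], first))
    m2 = average_morphology(segment_beats(segment[mid:], second))
    return dtw_distance(m1.cycle, m2.cycle)


def _band_power(f: np.ndarray, psd: np.ndarray, f1: float, f2: float) -> float:
    sel = (f >= f1) & (f <= f2)
    return float(np.trapezoid(psd[sel], f[sel]))


def frequency_domain_features(
    segment: np.ndarray, fs: float, analysis: ArtifactAnalysis
) -> np.ndarray:
    """FFT consistency plus Welch band-power quality indices.

    bas_sqi  = 1 - P(0,1)/P(0,40)    (baseline-wander share)
    qrs_sqi  = P(5,15)/P(5,40)       (QRS-band power share)
    pli_sqi  = 1 - P(49,51)/P(1,60)  (50 Hz mains share)
    snr      = 10*log10(P(5,40)/P(40,Nyquist)) in dB
    mean_sqi = (bas_sqi + qrs_sqi + pli_sqi)/3
    """
    x = np.asarray(segment, dtype=float)
    nperseg = min(x.size, int(WELCH_NPERSEG_S * fs))
    f, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    nyq = fs / 2.0
    bas = 1.0 - _band_power(f, psd, 0, 1) / max(_band_power(f, psd, 0, 40), 1e-300)
    qrs = _band_power(f, psd, 5, 15) / max(_band_power(f, psd, 5, 40), 1e-300)
    pli = 1.0 - _band_power(f, psd, 49, 51) / max(_band_power(f, psd, 1, 60), 1e-300)
    snr = 10.0 * np.log10(
        max(_band_power(f, psd, 5, 40), 1e-300)
        / max(_band_power(f, psd, 40, nyq), 1e-300)
    )
    fft_consistency = float(np.mean(analysis.cc_fft))
    mean_sqi = (bas + qrs + pli) / 3.0
    return np.array([fft_consistency, bas, qrs, pli, snr, mean_sqi])


def _normalize_cycle(cycle: np.ndarray) -> np.ndarray:
    peak = float(np.max(np.abs(cycle)))
    return cycle / peak if peak > 0 else cycle


def morphology_features(
    mean_morph: BeatMorphology,
    r_amplitudes: np.ndarray,
    prototypes: PrototypeSet,
) -> np.ndarray:
    """Amplitude feature plus shape similarity to the best ideal prototype.

    Distances are evaluated against every selected prototype after unit-R
    normalization; the best match is kept (minimum per distance, maximum
    correlation).
    """
    r_amp = float(np.mean(r_amplitudes))
    template_std = float(np.mean(mean_morph.std_curve))
    cyc = _normalize_cycle(mean_morph.cycle)
    eucl = city = dtw = np.inf
    cc = -1.0
    for proto in prototypes.selected_prototypes:
        p = _normalize_cycle(np.asarray(proto, dtype=float))
        eucl = min(eucl, float(np.linalg.norm(cyc - p)))
        city = min(city, float(np.abs(cyc - p).sum()))
        dtw = min(dtw, dtw_distance(cyc, p))
        if np.std(cyc) > 0 and np.std(p) > 0:
            cc = max(cc, float(np.corrcoef(cyc, p)[0, 1]))
    return np.array([r_amp, template_std, eucl, city, dtw, cc])


def extract_features(
    recording: ECGRecording, prototypes: PrototypeSet
) -> FeatureVector:
    """Run the full preprocessing chain and assemble the 22-feature vector.

    Raises the underlying typed error (too short, no valid segment, peak
    failure, heart-rate gate) rather than returning NaNs; callers batch
    these into reason-coded failure records.
    """
    analysis = detect_artifacts(recording)
    seg = longest_valid_segment(analysis.mask, recording.fs)
    s, _ = correct_inversion(recording.samples[seg.start : seg.end])
    peaks = detect_r_peaks(s, recording.fs)
    if not validate_heart_rate(peaks):
        raise HeartRateGateError(
            f"median HR {peaks.median_hr:.0f} bpm outside the physiologic gate"
        )
    beats = segment_beats(s, peaks.indices)
    morph = average_morphology(beats)
    vec = np.concatenate(
        [
            statistical_features(s),
            time_domain_features(s, peaks, analysis, seg.t_seg),
            frequency_domain_features(s, recording.fs, analysis),
            morphology_features(morph, s[peaks.indices], prototypes),
        ]
    )
    return FeatureVector(values=vec)
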