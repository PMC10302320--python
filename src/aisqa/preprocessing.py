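"""Front-end preprocessing of hand-held single-lead ECG recordings.

Stages, in pipeline order: window the recording into non-overlapping 5 s
blocks; fingerprint each block by its magnitude FFT and by its empirical
amplitude CDF; flag motion-corrupted blocks by the drop of their mean top-N
Pearson correlation (CCmax) to the other blocks; keep the longest clean run
if it lasts at least 30 s; correct device-inversion via the mean/median
asymmetry of the R-dominated amplitude distribution; detect R-peaks with a
Pan-Tompkins detector and gate the recording on a physiologic median heart
rate of 40-150 bpm.

Both fingerprints are deliberately insensitive to heart-rhythm irregularity:
an AF recording has stable spectral content and amplitude distribution
across windows even though its RR intervals are erratic, so irregular rhythm
is not mistaken for a motion artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: empirically determined corruption threshold on CCmax
CC_THRESHOLD = 0.982
#: number of top correlations averaged into CCmax
CC_TOP_N = 5
#: analysis window length, seconds (~5 beats at 60 bpm)
WINDOW_LEN_S = 5.0
#: minimum surviving segment duration, seconds (guideline rule)
MIN_SEGMENT_S = 30.0
#: physiologic median heart-rate gate, bpm
HR_BOUNDS_BPM = (40.0, 150.0)
#: amplitude-grid resolution of the eCDF fingerprint
ECDF_GRID_POINTS = 100

__all__ = [
    "ECGRecording",
    "ArtifactAnalysis",
    "ValidSegment",
    "PeakList",
    "TooShortError",
    "SegmentTooShortError",
    "PeakDetectionError",
    "window_signal",
    "window_ecdf",
    "max_correlation",
    "detect_artifacts",
    "longest_valid_segment",
    "correct_inversion",
    "detect_r_peaks",
    "validate_heart_rate",
]


class TooShortError(ValueError):
    """Recording too short for windowed analysis."""


class SegmentTooShortError(ValueError):
    """No artifact-free segment of at least 30 s remains; recording excluded."""


class PeakDetectionError(RuntimeError):
    """R-peak detection found no usable peaks."""


@dataclass
class ECGRecording:
    """One single-lead (Einthoven I) recording.

    samples are in mV at sampling rate ``fs`` (device: 200 Hz, ~60 s).
    ``device_decision`` is the on-chip rhythm call, ``expert_label`` the
    ordinal quality grade 0 (excellent) .. 3 (uninterpretable), when known.
    """

    samples: np.ndarray
    fs: float = 200.0
    id: str = ""
    device_decision: str | None = None
    expert_label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.samples.size < self.fs:
            raise ValueError("recording must be at least 1 s long")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class ArtifactAnalysis:
    """Per-window CCmax values and the resulting corruption mask."""

    window_len_s: float
    cc_fft: np.ndarray
    cc_ecdf: np.ndarray
    threshold: float
    n_top: int
    mask: np.ndarray  # True = corrupted

    def __post_init__(self) -> None:
        if not (len(self.cc_fft) == len(self.cc_ecdf) == len(self.mask)):
            raise ValueError("per-window arrays must have equal length")


@dataclass(frozen=True)
class ValidSegment:
    """Longest artifact-free stretch, as a half-open sample range."""

    start: int
    end: int
    fs: float

    @property
    def t_seg(self) -> float:
        return (self.end - self.start) / self.fs


@dataclass
class PeakList:
    """Detected R-peaks with derived RR intervals."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def rr_ms(self) -> np.ndarray:
        return np.diff(self.indices) / self.fs * 1000.0

    @property
    def median_hr(self) -> float:
        rr = self.rr_ms
        if rr.size == 0:
            return float("nan")
        return float(np.median(60000.0 / rr))


def window_signal(
    samples: np.ndarray, fs: float, window_len_s: float = WINDOW_LEN_S
) -> list[np.ndarray]:
    """Split into non-overlapping windows; a trailing remainder is dropped."""
    x = np.asarray(samples, dtype=float)
    wlen = int(round(window_len_s * fs))
    n_win = x.size // wlen
    if n_win < 2:
        raise TooShortError(
            f"need at least 2 windows of {window_len_s} s, got {x.size / fs:.1f} s"
        )
    return [x[i * wlen : (i + 1) * wlen] for i in range(n_win)]


def window_ecdf(window: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Empirical CDF of window amplitudes evaluated on a shared grid.

    The grid spans the min-max amplitude range of the whole recording so
    that windows are compared in a common amplitude frame.
    """
    w = np.sort(np.asarray(window, dtype=float))
    if w.size == 0:
        raise ValueError("empty window")
    return np.searchsorted(w, grid, side="right") / w.size


#: Welch sub-segment length (s) and envelope smoothing (bins) of the
#: spectral fingerprint; the smoothed envelope is stable across clean
#: windows under natural heart-rate drift (raw harmonic combs are not),
#: which the high corruption threshold presupposes
FFT_FINGERPRINT_NPERSEG_S = 0.5
FFT_FINGERPRINT_SMOOTH_BINS = 9


def _fft_fingerprint(window: np.ndarray, fs: float) -> np.ndarray:
    # smoothed one-sided power-spectral envelope of the zero-mean window
    w = np.asarray(window, dtype=float)
    nperseg = max(8, int(FFT_FINGERPRINT_NPERSEG_S * fs))
    _, psd = sps.welch(w - w.mean(), fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    k = FFT_FINGERPRINT_SMOOTH_BINS
    return np.convolve(psd, np.ones(k) / k, mode="same")


def max_correlation(vectors: list[np.ndarray], n_top: int = CC_TOP_N) -> np.ndarray:
    """Mean of the N largest inter-window Pearson correlations, per window.

    For window i all correlations against windows j != i are computed,
    sorted descending, and the top ``n_top`` are averaged.  Zero-variance
    fingerprints correlate as 0 by convention (logged).
    """
    m = len(vectors)
    if m < n_top + 1:
        raise TooShortError(f"need at least {n_top + 1} windows, got {m}")
    mat = np.asarray(vectors, dtype=float)
    sd = mat.std(axis=1)
    degenerate = sd == 0
    if np.any(degenerate):
        logger.warning("zero-variance fingerprint in %d window(s)", degenerate.sum())
    centered = mat - mat.mean(axis=1, keepdims=True)
    norm = np.where(degenerate, 1.0, sd * np.sqrt(mat.shape[1]))
    unit = centered / norm[:, None]
    corr = unit @ unit.T
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, -np.inf)  # exclude self before sorting
    top = np.sort(corr, axis=1)[:, -n_top:]
    return top.mean(axis=1)


def detect_artifacts(
    recording: ECGRecording,
    window_len_s: float = WINDOW_LEN_S,
    threshold: float = CC_THRESHOLD,
    n_top: int = CC_TOP_N,
) -> ArtifactAnalysis:
    """Flag motion-corrupted windows via FFT- and eCDF-fingerprint CCmax.

    A window is corrupted iff either representation's CCmax falls below the
    threshold (conservative fusion: maximizes artifact recall).
    """
    if recording.duration_s < MIN_SEGMENT_S:
        raise TooShortError("recording shorter than the 30 s minimum")
    windows = window_signal(recording.samples, recording.fs, window_len_s)
    grid = np.linspace(
        recording.samples.min(), recording.samples.max(), ECDF_GRID_POINTS
    )
    cc_fft = max_correlation(
        [_fft_fingerprint(w, recording.fs) for w in windows], n_top
    )
    cc_ecdf = max_correlation([window_ecdf(w, grid) for w in windows], n_top)
    mask = np.minimum(cc_fft, cc_ecdf) < threshold
    return ArtifactAnalysis(
        window_len_s=window_len_s,
        cc_fft=cc_fft,
        cc_ecdf=cc_ecdf,
        threshold=threshold,
        n_top=n_top,
        mask=mask,
    )


def longest_valid_segment(
    mask: np.ndarray, fs: float, window_len_s: float = WINDOW_LEN_S
) -> ValidSegment:
    """Longest run of clean windows as a sample range; >= 30 s required.

    Ties between equal-length runs resolve to the earliest.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    wlen = int(round(window_len_s * fs))
    best_start, best_len = 0, 0
    run_start, run_len = 0, 0
    for i, corrupted in enumerate(mask):
        if corrupted:
            run_len = 0
        else:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
    seg = ValidSegment(start=best_start * wlen, end=(best_start + best_len) * wlen, fs=fs)
    if seg.t_seg < MIN_SEGMENT_S:
        raise SegmentTooShortError(
            f"longest clean segment is {seg.t_seg:.0f} s < {MIN_SEGMENT_S:.0f} s"
        )
    return seg


def correct_inversion(samples: np.ndarray) -> tuple[np.ndarray, bool]:
    """Undo an upside-down device grip.

    An upright R-dominated ECG has a heavy positive amplitude tail, hence
    mean(s) < median(s) after high-pass distortion.  If that fails (ties
    included) the signal is inverted.  Idempotent after one application on
    R-dominated signals.
    """
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("empty signal")
    if np.mean(s) >= np.median(s):
        return -s, True
    return s, False


def detect_r_peaks(samples: np.ndarray, fs: float) -> PeakList:
    """Pan-Tompkins R-peak detection.

    Band-pass 5-15 Hz -> derivative -> squaring -> 150 ms moving-window
    integration -> adaptive dual threshold with a 200 ms refractory period;
    each detection is refined to the local extremum of the band-passed
    signal.  Amplitude-scale invariant by construction.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10 * fs:
        raise TooShortError("need at least 10 s of signal for peak detection")
    ptp = np.ptp(x)
    if ptp == 0 or not np.isfinite(ptp):
        raise PeakDetectionError("flat or non-finite signal")

    sos = sps.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    mwi_len = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(mwi_len) / mwi_len, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        raise PeakDetectionError("no candidate peaks in integrated signal")

    # adaptive dual-threshold running estimates of signal / noise peak level
    lead_in = mwi[: int(2 * fs)]
    spki = float(lead_in.max())
    npki = float(lead_in.mean())
    accepted = []
    for c in cand:
        level = mwi[c]
        thr = npki + 0.25 * (spki - npki)
        if level > thr:
            accepted.append(c)
            spki = 0.125 * level + 0.875 * spki
        else:
            npki = 0.125 * level + 0.875 * npki
    if not accepted:
        raise PeakDetectionError("no peaks above adaptive threshold")

    # refine to the local extremum of the band-passed signal near each
    # detection; |bp| keeps the landing point on the R deflection whatever
    # the trace polarity
    half = int(round(0.100 * fs))
    refined = []
    for c in accepted:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    idx = np.unique(refined)
    # enforce refractory after refinement
    keep = [int(idx[0])]
    for i in idx[1:]:
        if i - keep[-1] >= refractory:
            keep.append(int(i))
        elif np.abs(bp[i]) > np.abs(bp[keep[-1]]):
            keep[-1] = int(i)
    return PeakList(indices=np.asarray(keep), fs=fs)


def validate_heart_rate(
    peaks: PeakList, bounds_bpm: tuple[float, float] = HR_BOUNDS_BPM
) -> bool:
    """True iff the median instantaneous heart rate is physiologic."""
    if peaks.indices.size < 2:
        return False
    hr = peaks.median_hr
    return bounds_bpm[0] <= hr <= bounds_bpm[1]
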