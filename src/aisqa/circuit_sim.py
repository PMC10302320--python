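"""Electrical model of the hand-held metal-electrode ECG measurement chain.

A dry metal handle electrode couples to the body through the stratum corneum
(SC), whose impedance is modelled as a parallel RC pair per hand.  The
amplifier front end adds a series coupling capacitor ``C_cpl`` into a very
large input resistance ``R_in``; together they form a first-order high-pass
whose cut-off frequency ``f_c = 1/(2*pi*R_in*C_cpl)`` can reach well into the
ECG band for small coupling capacitances, visibly distorting P-, S- and
T-wave morphology while leaving the QRS complex detectable.

The SC capacitance is approximated by a cylindrical capacitor wrapped around
the handle electrode:

    C_sc = 2*pi*eps_0*eps_r*l_elec / ln((d_elec + d_sc) / d_elec)

with electrode length ``l_elec``, electrode radius ``d_elec`` and SC
thickness ``d_sc``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

__all__ = [
    "ElectrodeGeometry",
    "CircuitParams",
    "SimulatedMeasurement",
    "stratum_corneum_capacitance",
    "highpass_cutoff",
    "transfer_function",
    "simulate_measurement",
    "morphology_sweep",
]


class InvalidParameterError(ValueError):
    """A physical parameter is non-positive, non-finite or inconsistent."""


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Cylindrical-capacitor geometry of one handle electrode.

    Parameters
    ----------
    l_elec : float
        Effective electrode length in metres (device manual: 4.5 cm).
    d_elec : float
        Electrode radius in metres (device manual: 1.1 cm).
    d_sc : float
        Stratum corneum thickness in metres (tens of um up to 800 um).
    eps_r : float
        Relative permittivity of the SC, 1e3..1e5 depending on skin humidity.
    eps_0 : float
        Vacuum permittivity, fixed physical constant.
    """

    l_elec: float = 0.045
    d_elec: float = 0.011
    d_sc: float = 100e-6
    eps_r: float = 1e4
    eps_0: float = field(default=VACUUM_PERMITTIVITY)

    def __post_init__(self) -> None:
        vals = (self.l_elec, self.d_elec, self.d_sc, self.eps_r, self.eps_0)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise InvalidParameterError("geometry values must be positive and finite")
        if not self.d_sc < self.d_elec:
            raise InvalidParameterError("d_sc must be smaller than the electrode radius")
        if self.eps_r < 1:
            raise InvalidParameterError("relative permittivity must be >= 1")


@dataclass(frozen=True)
class CircuitParams:
    """Lumped elements of the measurement chain.

    ``R_sc``/``C_sc`` model one skin-electrode interface (two identical ones
    appear in series, one per hand); ``C_cpl`` and ``R_in`` form the input
    high-pass of the amplifier.
    """

    R_sc: float = 1e6      # ohm
    C_sc: float = 10e-6    # farad
    C_cpl: float = 100e-12  # farad
    R_in: float = 50e9     # ohm

    def __post_init__(self) -> None:
        vals = (self.R_sc, self.C_sc, self.C_cpl, self.R_in)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise InvalidParameterError("circuit elements must be positive and finite")


@dataclass
class SimulatedMeasurement:
    """Clean input and distorted output of one simulation run."""

    input_signal: np.ndarray   # mV, the internal source voltage
    output_signal: np.ndarray  # mV, voltage across R_in
    fs: float                  # Hz
    cutoff_hz: float           # first-order cut-off of the coupling stage

    def __post_init__(self) -> None:
        if len(self.input_signal) != len(self.output_signal):
            raise ValueError("input and output must have equal length")


def stratum_corneum_capacitance(geom: ElectrodeGeometry) -> float:
    """Stratum corneum capacitance (F) of one handle electrode.

    Cylindrical-capacitor approximation; strictly decreasing in ``d_sc`` and
    linear in ``eps_r`` and ``l_elec``.
    """
    return (
        2.0 * np.pi * geom.eps_0 * geom.eps_r * geom.l_elec
        / np.log((geom.d_elec + geom.d_sc) / geom.d_elec)
    )


def highpass_cutoff(params: CircuitParams) -> float:
    """First-order cut-off frequency (Hz) of the C_cpl/R_in input stage."""
    return 1.0 / (2.0 * np.pi * params.R_in * params.C_cpl)


def transfer_function(params: CircuitParams, freqs) -> np.ndarray:
    """Complex gain of the measurement chain at the given frequencies (Hz).

    Voltage divider of two identical skin-electrode interfaces (parallel
    R_sc||C_sc each) in series with the coupling capacitor into R_in; the
    output is taken across R_in.  DC gain is exactly 0 (series capacitor).
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f < 0):
        raise InvalidParameterError("frequencies must be >= 0")
    w = 2.0 * np.pi * f
    gain = np.zeros(f.shape, dtype=complex)
    nz = w > 0
    jw = 1j * w[nz]
    z_skin = params.R_sc / (1.0 + jw * params.R_sc * params.C_sc)
    z_cpl = 1.0 / (jw * params.C_cpl)
    gain[nz] = params.R_in / (params.R_in + 2.0 * z_skin + z_cpl)
    return gain


def _analog_coeffs(params: CircuitParams) -> tuple[list[float], list[float]]:
    # H(s) = R_in / (R_in + 2*R_sc/(1+s*R_sc*C_sc) + 1/(s*C_cpl)); clearing
    # denominators gives a 2nd-order rational in s.
    a = params.R_in * params.C_cpl * params.R_sc * params.C_sc
    num = [a, params.R_in * params.C_cpl, 0.0]
    den = [
        a,
        params.R_in * params.C_cpl
        + 2.0 * params.R_sc * params.C_cpl
        + params.R_sc * params.C_sc,
        1.0,
    ]
    return num, den


def simulate_measurement(
    clean_ecg: np.ndarray, fs: float, params: CircuitParams | None = None
) -> SimulatedMeasurement:
    """Filter a clean ECG through the discretized measurement chain.

    The analog divider is discretized with the bilinear transform at the
    signal's sampling rate, preserving the low-frequency pole placement.
    """
    if params is None:
        params = CircuitParams()
    x = np.asarray(clean_ecg, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("clean ECG must be finite")
    if fs <= 0:
        raise InvalidParameterError("fs must be positive")
    num, den = _analog_coeffs(params)
    b, a = sps.bilinear(num, den, fs=fs)
    y = sps.lfilter(b, a, x)
    return SimulatedMeasurement(
        input_signal=x, output_signal=y, fs=fs, cutoff_hz=highpass_cutoff(params)
    )


def morphology_sweep(
    clean_ecg: np.ndarray,
    fs: float,
    c_cpl_grid,
    params: CircuitParams | None = None,
    n_points: int = 200,
) -> list[np.ndarray | None]:
    """Mean heart-cycle morphology of the distorted signal per C_cpl value.

    Each grid entry runs :func:`simulate_measurement`, detects R-peaks on the
    output and averages beats on a fixed cycle-percentage grid.  Entries
    where peak detection fails are returned as ``None`` and the sweep
    continues.
    """
    from .morphology import average_morphology, segment_beats
    from .preprocessing import PeakDetectionError, detect_r_peaks

    grid = list(c_cpl_grid)
    if not grid:
        raise InvalidParameterError("C_cpl grid must be non-empty")
    base = params if params is not None else CircuitParams()
    out: list[np.ndarray | None] = []
    for c_cpl in grid:
        p = CircuitParams(R_sc=base.R_sc, C_sc=base.C_sc, C_cpl=c_cpl, R_in=base.R_in)
        sim = simulate_measurement(clean_ecg, fs, p)
        try:
            peaks = detect_r_peaks(sim.output_signal, fs)
            beats = segment_beats(sim.output_signal, peaks.indices)
            morph = average_morphology(beats, n_points=n_points)
        except (PeakDetectionError, ValueError):
            out.append(None)
            continue
        out.append(morph.cycle)
    return out
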