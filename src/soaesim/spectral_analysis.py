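"""Averaged power spectra of simulated and recorded emission signals.

The pipeline follows the conventions used for otoacoustic-emission records:
the signal (summed hair-bundle displacement, or microphone pressure) is cut
into overlapping segments, each segment is mean-subtracted, tapered with a
Hann window, Fourier transformed, and the one-sided power spectral densities
are averaged across segments.  Simulated chain spectra use 128-ms windows;
recorded emissions use 80-ms windows.  Hop is window/4 (75% overlap)
throughout — the overlap that makes a 1.6-s record yield exactly 47 segments.

Simulated spectra are expressed in dB relative to the peak spectral density
of a single free-running oscillator (alpha = 1) at its natural frequency,
run and windowed identically, so 0 dB means "as much power density as one
isolated unit concentrates at its own frequency".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal as sps

from .model_core import ChainConfig, AlphaProfileSpec

DEFAULT_WINDOW_MS = 128.0
RECORDED_WINDOW_MS = 80.0
#: hop as a fraction of the window (75% overlap)
HOP_FRACTION = 0.25

#: natural frequency (kHz) of the free-running reference oscillator
REFERENCE_FREQ_KHZ = 1.0

_DB_FLOOR = 1e-30


@dataclass
class Spectrum:
    """Averaged one-sided power spectral density on a uniform frequency grid.

    ``power_db`` is in dB re: the free-running-oscillator reference (simulated
    data) or re: unit power density (recorded data).  ``power`` keeps the raw
    (linear) density when available.
    """

    freqs_khz: np.ndarray
    power_db: np.ndarray
    n_segments: int
    window_ms: float
    hop_ms: float
    power: Optional[np.ndarray] = None

    @property
    def bin_khz(self) -> float:
        return float(self.freqs_khz[1] - self.freqs_khz[0])

    @property
    def bin_hz(self) -> float:
        return self.bin_khz * 1000.0

    def band(self, lo_khz: float, hi_khz: float) -> "Spectrum":
        """Restrict to the closed frequency band [lo, hi] kHz."""
        m = (self.freqs_khz >= lo_khz) & (self.freqs_khz <= hi_khz)
        return replace(self, freqs_khz=self.freqs_khz[m],
                       power_db=self.power_db[m],
                       power=None if self.power is None else self.power[m])

    def export_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.freqs_khz, self.power_db]),
                   delimiter="\t", header="frequency_khz\tpower_db", comments="")


@dataclass
class LayeredSpectra:
    """Per-oscillator spectra stacked along the chain (shared frequency grid)."""

    freqs_khz: np.ndarray
    power_db: np.ndarray  # (N, n_freqs)
    n_segments: int
    window_ms: float
    hop_ms: float

    @property
    def N(self) -> int:
        return self.power_db.shape[0]

    def oscillator(self, n: int) -> Spectrum:
        """Spectrum of oscillator ``n`` (1-based chain index)."""
        return Spectrum(self.freqs_khz, self.power_db[n - 1],
                        self.n_segments, self.window_ms, self.hop_ms)

    def export_text(self, path) -> None:
        header = "frequency_khz\t" + "\t".join(
            f"osc{n+1}_db" for n in range(self.N))
        np.savetxt(path, np.column_stack([self.freqs_khz, self.power_db.T]),
                   delimiter="\t", header=header, comments="")


def segment_plan(record_ms: float, window_ms: float, hop_ms: float) -> int:
    """Number of fully contained overlapping segments."""
    if hop_ms <= 0:
        raise ValueError("hop must be > 0")
    if window_ms > record_ms:
        raise ValueError(
            f"window ({window_ms} ms) longer than record ({record_ms} ms)")
    return int(np.floor((record_ms - window_ms) / hop_ms)) + 1


def averaged_power_spectrum(signal: np.ndarray, sample_interval_ms: float,
                            window_ms: float = DEFAULT_WINDOW_MS,
                            hop_ms: Optional[float] = None):
    """Hann-windowed, mean-detrended, segment-averaged one-sided PSD.

    Returns (freqs_khz, psd).  Works on 1-D signals or stacks (last axis =
    time).  Density units are (signal unit)^2 per kHz.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] == 0:
        raise ValueError("empty signal")
    if hop_ms is None:
        hop_ms = window_ms * HOP_FRACTION
    nperseg = int(round(window_ms / sample_interval_ms))
    nhop = int(round(hop_ms / sample_interval_ms))
    if nperseg > signal.shape[-1]:
        raise ValueError("window longer than signal")
    fs_khz = 1.0 / sample_interval_ms  # kHz, since time is in ms
    freqs, psd = sps.welch(signal, fs=fs_khz, window="hann", nperseg=nperseg,
                           noverlap=nperseg - nhop, detrend="constant",
                           scaling="density", average="mean")
    return freqs, psd


# --- reference normalization ------------------------------------------------

_reference_cache: dict = {}


def reference_peak_density(record_ms: float, sample_interval_ms: float,
                           window_ms: float, hop_ms: float) -> float:
    """Peak PSD of a single free-running oscillator (alpha = 1) at its natural
    frequency (1 kHz, the chain's first rung), simulated and windowed
    identically to the chain run."""
    key = (round(record_ms, 6), round(sample_interval_ms, 9),
           round(window_ms, 6), round(hop_ms, 6))
    if key in _reference_cache:
        return _reference_cache[key]
    from .sim_engine import simulate  # deferred: avoid import cycle

    # two uncoupled units (the chain type needs N >= 2); unit 1 sits at 1 kHz
    cfg = ChainConfig(
        N=2, alpha_profile=AlphaProfileSpec(kind="uniform"),
        seed=0, t_total=record_ms + 160.0, t_equilibrate=160.0,
        sample_interval=sample_interval_ms)
    trace = simulate(cfg)
    freqs, psd = averaged_power_spectrum(trace.x[0], sample_interval_ms,
                                         window_ms, hop_ms)
    ref = float(psd.max())
    if ref <= 0:
        raise RuntimeError("reference oscillator produced zero peak density")
    _reference_cache[key] = ref
    return ref


def normalize_to_reference(freqs_khz: np.ndarray, raw_psd: np.ndarray,
                           config: ChainConfig, window_ms: float,
                           hop_ms: float, n_segments: int) -> Spectrum:
    """Convert a raw averaged PSD to dB re: the free-running reference."""
    ref = reference_peak_density(config.record_ms, config.sample_interval,
                                 window_ms, hop_ms)
    power_db = 10.0 * np.log10(np.maximum(raw_psd, ref * _DB_FLOOR) / ref)
    return Spectrum(freqs_khz=np.asarray(freqs_khz), power_db=power_db,
                    n_segments=n_segments, window_ms=window_ms, hop_ms=hop_ms,
                    power=np.asarray(raw_psd))


def summed_spectrum(trace, window_ms: float = DEFAULT_WINDOW_MS,
                    hop_ms: Optional[float] = None) -> Spectrum:
    """Normalized averaged spectrum of the ensemble-summed displacement —
    the model's emission spectrum."""
    if hop_ms is None:
        hop_ms = window_ms * HOP_FRACTION
    freqs, psd = averaged_power_spectrum(trace.summed(), trace.sample_interval,
                                         window_ms, hop_ms)
    n_seg = segment_plan(trace.times.size * trace.sample_interval,
                         window_ms, hop_ms)
    return normalize_to_reference(freqs, psd, trace.config, window_ms,
                                  hop_ms, n_seg)


def layered_spectra(trace, window_ms: float = DEFAULT_WINDOW_MS,
                    hop_ms: Optional[float] = None) -> LayeredSpectra:
    """Per-oscillator normalized spectra, sharing one frequency grid."""
    if hop_ms is None:
        hop_ms = window_ms * HOP_FRACTION
    freqs, psd = averaged_power_spectrum(trace.x, trace.sample_interval,
                                         window_ms, hop_ms)
    n_seg = segment_plan(trace.times.size * trace.sample_interval,
                         window_ms, hop_ms)
    ref = reference_peak_density(trace.config.record_ms,
                                 trace.config.sample_interval,
                                 window_ms, hop_ms)
    power_db = 10.0 * np.log10(np.maximum(psd, ref * _DB_FLOOR) / ref)
    return LayeredSpectra(freqs_khz=freqs, power_db=power_db,
                          n_segments=n_seg, window_ms=window_ms, hop_ms=hop_ms)


def spatiotemporal_map(trace, normalize_amplitude: bool = False) -> np.ndarray:
    """Chain-index × time displacement matrix (low frequencies in row 0).

    With ``normalize_amplitude`` each oscillator's row is scaled by its own
    maximum absolute displacement, which evens out tapered ends for display.
    """
    m = trace.x.copy()
    if normalize_amplitude:
        peak = np.abs(m).max(axis=1, keepdims=True)
        peak[peak == 0] = 1.0
        m = m / peak
    return m


def adjacent_phase_differences(trace, window_ms: float = 100.0) -> np.ndarray:
    """Circular-mean instantaneous phase step between adjacent oscillators.

    Uses the analytic-signal (Hilbert) phase over the trailing ``window_ms``
    of the trace and returns, for each adjacent pair, the circular mean of
    phi_{n+1} - phi_n in (-pi, pi].  A positive value means the higher-
    frequency neighbor leads, i.e. synchronization waves travel from the
    high-frequency end toward the low-frequency end; values near +/-pi mark
    antiphase-locked pairs.
    """
    from scipy.signal import hilbert
    T = int(window_ms / trace.sample_interval)
    seg = trace.x[:, -T:]
    ph = np.angle(hilbert(seg, axis=1))
    d = np.angle(np.exp(1j * (ph[1:] - ph[:-1])))
    return np.angle(np.mean(np.exp(1j * d), axis=1))


# --- recorded-emission path -------------------------------------------------

def load_recording(path):
    """Read a sound-pressure record from WAV (single channel) or two-column
    text (time_s, pressure).  Returns (data, sample_interval_s)."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        from scipy.io import wavfile
        fs, data = wavfile.read(path)
        data = np.asarray(data, dtype=float)
        if data.ndim != 1:
            raise ValueError("expected a single-channel WAV file")
        return data, 1.0 / fs
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected two-column text (time_s, pressure)")
    t, p = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("recording must be uniformly sampled")
    return p, float(dt[0])


def recorded_emission_spectrum(record: np.ndarray, sample_interval_s: float,
                               control: Optional[np.ndarray] = None,
                               control_sample_interval_s: Optional[float] = None,
                               window_ms: float = RECORDED_WINDOW_MS,
                               hop_ms: Optional[float] = None) -> Spectrum:
    """Averaged emission spectrum of a recorded pressure series, optionally
    background-corrected by subtracting a control (postmortem) spectrum in
    power before conversion to dB.

    dB scale is relative (re: unit power density); no absolute calibration.
    """
    si_ms = sample_interval_s * 1000.0
    if hop_ms is None:
        hop_ms = window_ms * HOP_FRACTION
    record = np.asarray(record, dtype=float)
    n_seg = segment_plan(record.size * si_ms, window_ms, hop_ms)
    freqs, psd = averaged_power_spectrum(record, si_ms, window_ms, hop_ms)
    if control is not None:
        ctrl_si = control_sample_interval_s
        if ctrl_si is None:
            ctrl_si = sample_interval_s
        if not np.isclose(ctrl_si, sample_interval_s, rtol=1e-9):
            raise ValueError("control sampling interval differs from record")
        control = np.asarray(control, dtype=float)
        _, psd_ctrl = averaged_power_spectrum(control, si_ms, window_ms, hop_ms)
        if psd_ctrl.shape != psd.shape:
            raise ValueError("control and record segment lengths differ")
        diff = psd - psd_ctrl
        # the difference is only meaningful where emission power rises above
        # the background's own fluctuation; floor it at 10% of the per-bin
        # control density so near-zero/negative bins read as a -10 dB floor
        # relative to background instead of spurious deep notches
        power_db = 10.0 * np.log10(
            np.maximum(diff, np.maximum(0.1 * psd_ctrl, _DB_FLOOR)))
        return Spectrum(freqs_khz=freqs, power_db=power_db, n_segments=n_seg,
                        window_ms=window_ms, hop_ms=hop_ms, power=diff)
    power_db = 10.0 * np.log10(np.maximum(psd, _DB_FLOOR))
    return Spectrum(freqs_khz=freqs, power_db=power_db, n_segments=n_seg,
                    window_ms=window_ms, hop_ms=hop_ms, power=psd)
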