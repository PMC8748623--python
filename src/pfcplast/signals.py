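"""Broadband MUA event extraction and LFP spectral analysis.

MUA events are negative threshold crossings at -3.5 x RMS of the
spike-band (500 Hz - 8 kHz) filtered broadband signal, with a 1 ms dead
time. LFP preprocessing applies a zero-phase 0.5-200 Hz bandpass, a
60 Hz notch, and excludes electrodes whose log-variance is a robust
outlier. Time-frequency power is estimated with the multitaper method
(DPSS tapers) on sliding windows; band time courses subtract the mean
fixation-baseline power at each frequency before averaging within the
alpha (8-14 Hz), beta (20-45 Hz) and gamma (46-70 Hz) bands, and phase
effects are assessed by a one-way ANOVA treating one daily session as
one observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import signal as sps
from scipy import stats
from scipy.signal.windows import dpss

__all__ = [
    "AcquisitionConfig",
    "BandDefinition",
    "STANDARD_BANDS",
    "SpectralPower",
    "DegenerateSignalError",
    "QualityControlError",
    "extract_mua_events",
    "preprocess_lfp",
    "flag_variance_outliers",
    "multitaper_power",
    "band_timecourse",
    "band_power_by_session",
    "phase_band_anova",
]


class DegenerateSignalError(ValueError):
    pass


class QualityControlError(RuntimeError):
    pass


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition-stage constants."""

    threshold_multiplier: float = 3.5
    spike_band_hz: Tuple[float, float] = (500.0, 8000.0)
    lfp_band_hz: Tuple[float, float] = (0.5, 200.0)
    line_hz: float = 60.0
    dead_time_s: float = 1e-3

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")
        for lo, hi in (self.spike_band_hz, self.lfp_band_hz):
            if not 0 <= lo < hi:
                raise ValueError("band edges must be increasing")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if self.hi_hz <= self.lo_hz:
            raise ValueError("band edges must be increasing")


STANDARD_BANDS: Tuple[BandDefinition, ...] = (
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 20.0, 45.0),
    BandDefinition("gamma", 46.0, 70.0),
)


@dataclass
class SpectralPower:
    """Sliding-window power estimate: times x freqs (one trial or averaged)."""

    times: np.ndarray  # window centers, s
    freqs: np.ndarray  # Hz
    power: np.ndarray  # (n_times, n_freqs), PSD units (x**2 / Hz)
    normalization: str = "raw"  # "raw" | "baseline-subtracted"

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.times), len(self.freqs)):
            raise ValueError("power shape inconsistent with grids")
        if self.normalization == "raw" and np.any(self.power < 0):
            raise ValueError("raw power must be nonnegative")


# ---------------------------------------------------------------------------
# MUA extraction
# ---------------------------------------------------------------------------


def extract_mua_events(trace: np.ndarray, fs: float,
                       cfg: AcquisitionConfig = AcquisitionConfig()
                       ) -> np.ndarray:
    """Event times (s) of negative threshold crossings in a broadband trace.

    The trace is bandpass filtered to the spike band, the threshold set
    at ``-multiplier x RMS`` of the full filtered trace, and crossings
    closer than the dead time to the previous event are discarded.
    """
    trace = np.asarray(trace, dtype=float)
    lo, hi = cfg.spike_band_hz
    hi = min(hi, 0.95 * fs / 2)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, trace)
    rms = np.sqrt(np.mean(x ** 2))
    if rms == 0:
        raise DegenerateSignalError("flat trace (RMS = 0)")
    thr = -cfg.threshold_multiplier * rms
    below = x < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if crossings.size == 0:
        return np.empty(0)
    dead = int(round(cfg.dead_time_s * fs))
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= dead:
            kept.append(c)
    return np.array(kept) / fs


# ---------------------------------------------------------------------------
# LFP preprocessing
# ---------------------------------------------------------------------------


def _notch(x: np.ndarray, fs: float, line_hz: float, q: float = 30.0
           ) -> np.ndarray:
    b, a = sps.iirnotch(line_hz, Q=q, fs=fs)
    return sps.filtfilt(b, a, x)


def preprocess_lfp(traces: Dict[int, np.ndarray], fs: float,
                   cfg: AcquisitionConfig = AcquisitionConfig(),
                   exclude_outliers: bool = True
                   ) -> Tuple[Dict[int, np.ndarray], Set[int]]:
    """Zero-phase bandpass + line-notch per electrode; returns cleaned
    traces and the kept-electrode set (variance outliers excluded)."""
    if fs < 500:
        raise ValueError("sampling rate must be >= 500 Hz")
    lo, hi = cfg.lfp_band_hz
    if hi >= fs / 2:
        raise ValueError("LFP bandpass edge at or above Nyquist")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    cleaned = {}
    for el, x in traces.items():
        y = sps.sosfiltfilt(sos, np.asarray(x, dtype=float))
        y = _notch(y, fs, cfg.line_hz)
        cleaned[el] = y
    kept = set(cleaned)
    if exclude_outliers and len(cleaned) >= 8:
        flagged = flag_variance_outliers(cleaned)
        kept -= flagged
    return cleaned, kept


def flag_variance_outliers(traces: Dict[int, np.ndarray],
                           z_threshold: float = 3.0) -> Set[int]:
    """Electrodes whose log-variance robust z-score exceeds the threshold.

    Robust z uses the median and the MAD (scaled to the normal); both
    high-variance (noisy) and near-zero-variance (dead) channels are
    flagged. Raises if every electrode would be excluded.
    """
    if len(traces) < 8:
        raise ValueError("need >= 8 electrodes for outlier screening")
    electrodes = sorted(traces)
    var = np.array([np.var(traces[e]) for e in electrodes])
    logv = np.log(np.maximum(var, np.finfo(float).tiny))
    med = np.median(logv)
    mad = stats.median_abs_deviation(logv, scale="normal")
    if mad == 0:
        mad = np.finfo(float).eps
    z = (logv - med) / mad
    flagged = {e for e, zi in zip(electrodes, z) if abs(zi) > z_threshold}
    if len(flagged) == len(electrodes):
        raise QualityControlError("all electrodes flagged as variance outliers")
    return flagged


# ---------------------------------------------------------------------------
# multitaper spectral estimation
# ---------------------------------------------------------------------------


def multitaper_power(trace: np.ndarray, fs: float,
                     window_s: float = 0.5, step_s: float = 0.05,
                     nw: float = 3.0, n_tapers: int = 5,
                     t0: float = 0.0, fmax: Optional[float] = 100.0
                     ) -> SpectralPower:
    """Sliding-window multitaper PSD estimate of one trace.

    DPSS tapers with time-bandwidth product ``nw``; the per-window PSD is
    the taper-averaged periodogram scaled so that the integral of the
    PSD over frequency approximates the signal variance (Parseval).
    ``t0`` is the time of the first sample, so window centers can be
    expressed relative to cue onset.
    """
    x = np.asarray(trace, dtype=float)
    nwin = int(round(window_s * fs))
    if nwin > len(x):
        raise ValueError("window longer than trace")
    if n_tapers > int(2 * nw - 1):
        raise ValueError(f"n_tapers must be <= 2*NW-1 = {int(2 * nw - 1)}")
    step = max(1, int(round(step_s * fs)))
    tapers = dpss(nwin, nw, Kmax=n_tapers)  # (n_tapers, nwin), unit norm
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    fsel = slice(None) if fmax is None else freqs <= fmax
    starts = np.arange(0, len(x) - nwin + 1, step)
    # one-sided PSD scaling: |X|^2 / fs with unit-norm tapers, doubled
    # off-DC/Nyquist
    scale = np.full(len(freqs), 2.0 / fs)
    scale[0] = 1.0 / fs
    if nwin % 2 == 0:
        scale[-1] = 1.0 / fs
    power = np.empty((len(starts), int(np.count_nonzero(fsel))
                      if fmax is not None else len(freqs)))
    for i, s in enumerate(starts):
        seg = x[s:s + nwin]
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        psd = (np.abs(spec) ** 2).mean(axis=0) * scale
        power[i] = psd[fsel]
    times = t0 + (starts + nwin / 2) / fs
    return SpectralPower(times=times, freqs=freqs[fsel], power=power,
                         normalization="raw")


def band_timecourse(power: SpectralPower, band: BandDefinition,
                    baseline: Tuple[float, float],
                    cue_on: float = 0.0) -> np.ndarray:
    """Baseline-subtracted band power time course.

    At each frequency the mean power over baseline time bins is
    subtracted, then the result is averaged over the band's frequencies.
    The baseline window must precede cue onset.
    """
    b0, b1 = baseline
    if b1 > cue_on + 1e-9:
        raise ValueError("baseline window overlaps the cue period")
    in_base = (power.times >= b0) & (power.times < b1)
    if not np.any(in_base):
        raise ValueError("baseline window contains no spectral estimates")
    base = power.power[in_base].mean(axis=0)
    normed = power.power - base[None, :]
    in_band = (power.freqs >= band.lo_hz) & (power.freqs <= band.hi_hz)
    if not np.any(in_band):
        raise ValueError(f"no frequencies inside band {band.name}")
    return normed[:, in_band].mean(axis=1)


def band_power_by_session(
    session_trial_traces: Dict[int, Dict[int, List[np.ndarray]]],
    fs: float,
    band: BandDefinition,
    baseline: Tuple[float, float],
    epoch: Tuple[float, float],
    t0: float,
    window_s: float = 0.5,
    step_s: float = 0.05,
    cfg: AcquisitionConfig = AcquisitionConfig(),
) -> Dict[int, float]:
    """One baseline-normalized epoch band-power value per session.

    ``session_trial_traces`` maps session index -> electrode -> list of
    per-trial traces (equal length, first sample at ``t0`` relative to
    cue onset). Per session, traces are cleaned, variance-outlier
    electrodes dropped, trial/electrode spectra averaged, and the
    band time course averaged within the epoch window.
    """
    out = {}
    for sidx, by_el in session_trial_traces.items():
        flat = {el: np.concatenate(trials) for el, trials in by_el.items()}
        if len(flat) >= 8:
            kept = set(flat) - flag_variance_outliers(flat)
        else:
            kept = set(flat)
        powers = []
        times = freqs = None
        for el in sorted(kept):
            for trace in by_el[el]:
                cleaned, _ = preprocess_lfp({el: trace}, fs, cfg,
                                            exclude_outliers=False)
                sp = multitaper_power(cleaned[el], fs, window_s=window_s,
                                      step_s=step_s, t0=t0)
                powers.append(sp.power)
                if times is None or len(sp.times) < len(times):
                    times, freqs = sp.times, sp.freqs
        if not powers:
            raise QualityControlError(f"session {sidx}: no usable traces")
        # trials may differ in duration (variable delays): average over
        # the window grid common to every trial
        n_common = min(p.shape[0] for p in powers)
        mean = np.mean([p[:n_common] for p in powers], axis=0)
        mean_power = SpectralPower(times=times[:n_common], freqs=freqs,
                                   power=mean, normalization="raw")
        series = band_timecourse(mean_power, band, baseline)
        in_epoch = (times >= epoch[0]) & (times < epoch[1])
        out[sidx] = float(series[in_epoch].mean())
    return out


def phase_band_anova(session_values: Dict[int, float],
                     session_phases: Dict[int, str]) -> Dict[str, float]:
    """One-way ANOVA of session band power grouped by training phase."""
    groups: Dict[str, List[float]] = {}
    for sidx, v in session_values.items():
        groups.setdefault(session_phases[sidx], []).append(v)
    if len(groups) < 2:
        raise ValueError("need >= 2 phases")
    arrays = [np.asarray(v) for v in groups.values()]
    stat, p = stats.f_oneway(*arrays)
    return {"F": float(stat), "p": float(p),
            "n_sessions": sum(len(a) for a in arrays),
            "n_phases": len(arrays)}
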