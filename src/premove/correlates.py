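"""Quantification of the two pre-movement EEG correlates.

* ERD maps — Morlet-wavelet time-frequency power over 1-50 Hz, expressed as
  % change versus the [-3, -1] s baseline, with per-cell bootstrap
  significance; pre-movement ERD% summarises the alpha or beta band over the
  final pre-onset second.
* MRCP waveforms — trial-averaged slow potentials (CAR, 64 Hz, 0.1-1 Hz
  zero-phase 2nd-order Butterworth) with their negative peak amplitude and
  latency, optionally normalized across movements to the largest peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from mne.time_frequency import tfr_array_morlet
from scipy import signal as sps

from .config import BANDS
from .containers import TrialSet
from .signals import bandpass
from .spatial import car

BASELINE_WINDOW = (-3.0, -1.0)


@dataclass
class TimeFreqMap:
    """% power change vs baseline, freqs x times, for one channel."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel: str
    baseline: tuple[float, float] = BASELINE_WINDOW
    mask: np.ndarray | None = None
    trial_power: np.ndarray | None = None     # trials x freqs x times (bootstrap)

    def band_time_mean(self, band: tuple[float, float], times: tuple[float, float],
                       include_band_hi: bool = False) -> float:
        fsel = (self.freqs >= band[0]) & (
            (self.freqs <= band[1]) if include_band_hi else (self.freqs < band[1]))
        tsel = (self.times >= times[0]) & (self.times < times[1])
        if not fsel.any() or not tsel.any():
            raise ValueError("band or time span outside the map")
        return float(self.values[np.ix_(fsel, tsel)].mean())


@dataclass
class MrcpWaveform:
    """Trial-averaged slow potential per channel at 64 Hz, band 0.1-1 Hz."""

    waveforms: np.ndarray           # channels x times
    times: np.ndarray
    channel_labels: list[str]
    fs: float = 64.0
    peaks: np.ndarray = field(default=None)      # negative peak per channel
    latencies: np.ndarray = field(default=None)  # s of the peak, within [-1, 1]
    scale: float = 1.0              # normalization divisor (microvolts)


def _channel_signal(trials: TrialSet, channel) -> np.ndarray:
    """Resolve `channel` to per-trial 1-D signals: a label indexes the trial
    data; an array is taken as an already-projected virtual channel."""
    if isinstance(channel, str):
        return trials.kept_data()[:, trials.channel_index(channel), :], channel
    arr = np.asarray(channel, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != int(trials.kept.sum()):
        raise ValueError("virtual channel must be trials x samples over kept trials")
    return arr, "OSF"


def _morlet_cycles(freqs: np.ndarray, duration: float) -> np.ndarray:
    """7 cycles per frequency, capped so the wavelet fits the epoch at the
    lowest frequencies (cap: 40% of the epoch duration)."""
    return np.minimum(7.0, np.maximum(1.0, freqs * 0.4 * duration))


def erd_map(trials: TrialSet, channel, freqs=None, n_cycles: float | None = None,
            decim: int = 16, baseline: tuple[float, float] = BASELINE_WINDOW,
            crop: tuple[float, float] | None = None,
            keep_trial_power: bool = True) -> TimeFreqMap:
    """Morlet time-frequency % power change versus the pre-movement baseline.

    `channel` is a Laplacian-filtered channel label or an OSF-projected
    trials x samples array.  The reference power P_ref is computed per
    frequency from the trial-averaged power over the baseline window
    (classical ERD definition), so the map averages to 0 over the baseline
    by construction.

    Wavelet (and filter) transients contaminate roughly one wavelet
    half-width at each epoch edge; for quantitative work epoch wider than
    the span of interest and pass ``crop`` (e.g. [-5, 5] s epochs cropped
    to [-3, 3]) so the retained map is transient-free.
    """
    if int(trials.kept.sum()) < 5:
        raise ValueError("ERD maps need at least 5 trials (unstable baseline)")
    sig, name = _channel_signal(trials, channel)
    sig = bandpass(sig, (1.0, 50.0), trials.fs, order=4, axis=-1)
    if freqs is None:
        freqs = np.arange(1.0, 51.0)
    freqs = np.asarray(freqs, dtype=float)
    duration = sig.shape[-1] / trials.fs
    cycles = np.full(freqs.shape, float(n_cycles)) if n_cycles is not None \
        else _morlet_cycles(freqs, duration)
    power = tfr_array_morlet(sig[:, None, :], trials.fs, freqs, n_cycles=cycles,
                             output="power", decim=decim, verbose="error")
    power = power[:, 0]                          # trials x freqs x times
    times = trials.times[::decim]
    if crop is not None:
        sel = (times >= crop[0]) & (times <= crop[1])
        power = power[:, :, sel]
        times = times[sel]
    values = _percent_change(power.mean(axis=0), times, baseline)
    return TimeFreqMap(values=values, freqs=freqs, times=times, channel=name,
                       baseline=baseline,
                       trial_power=power if keep_trial_power else None)


def _percent_change(avg_power: np.ndarray, times: np.ndarray,
                    baseline: tuple[float, float]) -> np.ndarray:
    bsel = (times >= baseline[0]) & (times < baseline[1])
    p_ref = avg_power[:, bsel].mean(axis=1, keepdims=True)
    return 100.0 * (avg_power - p_ref) / p_ref


def bootstrap_mask(tfmap: TimeFreqMap, alpha: float = 0.05, B: int = 1000,
                   seed: int = 0, chunk: int = 200) -> np.ndarray:
    """Per-cell significance: bootstrap the trial average; a cell is
    significant when the (alpha/2, 1-alpha/2) percentile interval of its
    % change excludes 0."""
    if tfmap.trial_power is None:
        raise ValueError("map was built without per-trial power")
    power = tfmap.trial_power
    n = power.shape[0]
    if n < 10:
        raise ValueError("bootstrap needs at least 10 trials")
    if B < 100:
        warnings.warn(f"B={B} bootstrap resamples is low; intervals are coarse")
    if alpha >= 1.0:
        return np.ones_like(tfmap.values, dtype=bool)
    rng = np.random.default_rng(seed)
    reps = np.empty((B,) + tfmap.values.shape)
    done = 0
    while done < B:
        m = min(chunk, B - done)
        idx = rng.integers(0, n, size=(m, n))
        means = power[idx].mean(axis=1)
        for j in range(m):
            reps[done + j] = _percent_change(means[j], tfmap.times, tfmap.baseline)
        done += m
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    mask = (lo > 0) | (hi < 0)
    tfmap.mask = mask
    return mask


def premovement_erd(tfmap: TimeFreqMap, band: str | tuple[float, float]) -> float:
    """Mean % change over the band and the final pre-onset second [-1, 0)."""
    if isinstance(band, str):
        lo, hi = BANDS[band]
        include_hi = band == "beta"      # 7-30 Hz bins split as [7,12) / [12,30]
    else:
        lo, hi = band
        include_hi = False
    return tfmap.band_time_mean((lo, hi), (-1.0, 0.0), include_band_hi=include_hi)


def mrcp(trials: TrialSet, channels=None, band: tuple[float, float] = (0.1, 1.0),
         target_fs: float = 64.0,
         peak_window: tuple[float, float] = (-1.0, 1.0)) -> MrcpWaveform:
    """Trial-averaged movement-related cortical potential waveforms.

    CAR, anti-aliased downsampling to 64 Hz, zero-phase 2nd-order Butterworth
    0.1-1 Hz, average across kept trials; the peak is the minimum within
    [-1, 1] s of the onset.
    """
    if channels is None:
        channels = list(trials.channel_labels)
    carred = car(trials)
    data = carred.kept_data()
    factor = trials.fs / target_fs
    if abs(round(factor) - factor) > 1e-9:
        warnings.warn(f"fs {trials.fs} not an integer multiple of {target_fs}; "
                      "using polyphase resampling")
        from fractions import Fraction
        frac = Fraction(target_fs / trials.fs).limit_denominator(1000)
        low = sps.resample_poly(data, frac.numerator, frac.denominator, axis=2)
        times = trials.window[0] + np.arange(low.shape[2]) / target_fs
    else:
        low = sps.decimate(data, int(round(factor)), ftype="fir",
                           zero_phase=True, axis=2)
        times = trials.times[::int(round(factor))]
    nyq = target_fs / 2.0
    sos = sps.butter(2, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    low = sps.sosfiltfilt(sos, low, axis=2)
    idx = [trials.channel_index(ch) for ch in channels]
    avg = low[:, idx, :].mean(axis=0)
    sel = (times >= peak_window[0]) & (times <= peak_window[1])
    seg = avg[:, sel]
    arg = seg.argmin(axis=1)
    peaks = seg[np.arange(seg.shape[0]), arg]
    latencies = times[sel][arg]
    return MrcpWaveform(waveforms=avg, times=times, channel_labels=list(channels),
                        fs=target_fs, peaks=peaks, latencies=latencies)


def osf_mrcp_waveform(virtual: np.ndarray, fs: float, window_start: float = -3.0,
                      band: tuple[float, float] = (0.1, 1.0),
                      target_fs: float = 64.0) -> MrcpWaveform:
    """MRCP waveform of an OSF-projected virtual channel (trials x samples)."""
    low = sps.decimate(virtual, int(round(fs / target_fs)), ftype="fir",
                       zero_phase=True, axis=1)
    nyq = target_fs / 2.0
    sos = sps.butter(2, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    low = sps.sosfiltfilt(sos, low, axis=1)
    times = window_start + np.arange(low.shape[1]) / target_fs
    avg = low.mean(axis=0, keepdims=True)
    sel = (times >= -1.0) & (times <= 1.0)
    seg = avg[:, sel]
    arg = seg.argmin(axis=1)
    return MrcpWaveform(waveforms=avg, times=times, channel_labels=["OSF"],
                        fs=target_fs, peaks=seg[np.arange(1), arg],
                        latencies=times[sel][arg])


def normalize_peaks(waveforms: dict[str, MrcpWaveform]) -> dict[str, MrcpWaveform]:
    """Normalize MRCP amplitudes across movements: every waveform and peak is
    divided by the largest |peak| over all movements and channels, so that
    movement/channel maps to exactly -1.0."""
    scale = max(float(np.max(np.abs(w.peaks))) for w in waveforms.values())
    if scale == 0:
        raise ValueError("all peaks are zero; nothing to normalize")
    out = {}
    for mv, w in waveforms.items():
        out[mv] = MrcpWaveform(waveforms=w.waveforms / scale, times=w.times,
                               channel_labels=list(w.channel_labels), fs=w.fs,
                               peaks=w.peaks / scale, latencies=w.latencies,
                               scale=scale)
    return out
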