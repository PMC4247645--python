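"""Movement-onset detection, epoching, and z-score artifact rejection."""

from __future__ import annotations

import warnings

import numpy as np

from .config import BANDS
from .containers import Recording, TrialSet
from .signals import band_power


def detect_onsets(aux: np.ndarray, fs: float, fraction: float = 0.05,
                  refractory_s: float = 2.0) -> np.ndarray:
    """Movement onsets from kinematic/EMG channels.

    Three steps: demean each channel, rectify, average the channels; onsets
    are the upward crossings of ``fraction`` x the maximum of the processed
    signal.  Crossings closer than ``refractory_s`` are merged (first kept) —
    the protocol spaces movements far wider than that, so true onsets are
    never merged.
    """
    aux = np.atleast_2d(np.asarray(aux, dtype=float))
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    processed = np.abs(aux - aux.mean(axis=1, keepdims=True)).mean(axis=0)
    peak = processed.max()
    if peak <= 0:
        warnings.warn("all-zero auxiliary signal: no onsets detectable")
        return np.array([])
    thr = fraction * peak
    above = processed >= thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    merged = []
    last = -np.inf
    for c in crossings:
        t = c / fs
        if t - last >= refractory_s:
            merged.append(t)
            last = t
    return np.array(merged)


def epoch(recording: Recording, onsets, window: tuple[float, float] = (-3.0, 3.0),
          min_rest_s: float = 3.0, movement: str = "unspecified") -> TrialSet:
    """Cut one epoch per onset on the fixed time axis (t = 0 at the onset).

    Onsets lacking full window support inside the recording, or preceded by
    another onset within ``min_rest_s`` (movement started before the waiting
    period elapsed), are dropped with the reason recorded.
    """
    fs = recording.fs
    n_pre = int(round(-window[0] * fs))
    n_post = int(round(window[1] * fs))
    epochs, dropped = [], {}
    onsets = list(np.asarray(onsets, dtype=float))
    for i, onset in enumerate(onsets):
        c = int(round(onset * fs))
        if c - n_pre < 0 or c + n_post > recording.n_samples:
            dropped[i] = "insufficient pre-onset data" if c - n_pre < 0 \
                else "insufficient post-onset data"
            continue
        prev = [o for o in onsets[:i] if onset - o > 0]
        if prev and onset - max(prev) < min_rest_s:
            dropped[i] = "rest before onset shorter than waiting period"
            continue
        epochs.append(recording.data[:, c - n_pre:c + n_post])
    if not epochs:
        raise ValueError("no onset had full window support")
    ts = TrialSet(data=np.stack(epochs), fs=fs,
                  channel_labels=list(recording.channel_labels),
                  window=window, movement=movement)
    ts.rejection_reasons.update({-(i + 1): f"onset {i}: {r}"
                                 for i, r in dropped.items()})
    return ts


def trial_measures(trials: TrialSet) -> dict[str, np.ndarray]:
    """Per-trial artifact measures, one scalar per measure per trial.

    Band power in delta/theta/alpha/beta, variance, and maximum absolute
    amplitude — each computed per channel and averaged over channels.
    """
    x = trials.data
    fs = trials.fs
    out: dict[str, np.ndarray] = {}
    for name, band in BANDS.items():
        out[f"power_{name}"] = band_power(x, band, fs, axis=2).mean(axis=1)
    out["variance"] = x.var(axis=2).mean(axis=1)
    out["max_amplitude"] = np.abs(x).max(axis=2).mean(axis=1)
    return out


def reject_artifacts(trials: TrialSet, multiplier: float = 2.5) -> TrialSet:
    """Mask trials whose any measure exceeds ``multiplier`` x its across-trial mean.

    Single pass (the mean is not recomputed after rejections); rejected trials
    stay in the container, masked, with the offending measures recorded.
    """
    if int(trials.kept.sum()) < 3:
        raise ValueError("artifact rejection needs at least 3 trials (mean unstable)")
    measures = trial_measures(trials)
    kept = trials.kept.copy()
    reasons = dict(trials.rejection_reasons)
    idx = np.flatnonzero(trials.kept)
    for name, values in measures.items():
        vals = values[idx]
        mean = vals.mean()
        if mean <= 0:
            continue
        for local, trial in enumerate(idx):
            if vals[local] > multiplier * mean:
                kept[trial] = False
                prev = reasons.get(int(trial), "")
                tag = f"{name} = {vals[local]:.3g} > {multiplier} x mean {mean:.3g}"
                reasons[int(trial)] = f"{prev}; {tag}" if prev else tag
    out = TrialSet(data=trials.data, fs=trials.fs,
                   channel_labels=list(trials.channel_labels),
                   window=trials.window, movement=trials.movement,
                   kept=kept, rejection_reasons=reasons)
    return out
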