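"""Shared filtering primitives: zero-phase Butterworth bands and decimation."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps


def bandpass(x: np.ndarray, band: tuple[float, float], fs: float,
             order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth bandpass (filtfilt doubles the effective order)."""
    lo, hi = band
    nyq = fs / 2.0
    sos = sps.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x, axis=axis)


def band_power(x: np.ndarray, band: tuple[float, float], fs: float,
               order: int = 4, axis: int = -1) -> np.ndarray:
    """Mean squared amplitude of the band-filtered signal."""
    return np.mean(bandpass(x, band, fs, order=order, axis=axis) ** 2, axis=axis)


def decimate_to(x: np.ndarray, fs: float, target_fs: float,
                axis: int = -1) -> np.ndarray:
    """Anti-aliased downsampling to `target_fs` (integer factor, zero-phase FIR)."""
    factor = fs / target_fs
    if abs(round(factor) - factor) > 1e-9:
        raise ValueError(f"fs {fs} is not an integer multiple of {target_fs}")
    return sps.decimate(x, int(round(factor)), ftype="fir", zero_phase=True, axis=axis)
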