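"""Windowed feature extraction combining ERD band spectra and MRCP time samples.

Every feature vector describes one 1-second window [t-1, t) of one trial
(half-open: the sample at exactly t is excluded, so a 64 Hz window holds
exactly 64 samples and no data at times >= t enters the vector):

* ERD block — per selected channel (Laplacian-filtered, 512 Hz), the AR(16)
  Burg power spectrum at 1 Hz resolution, keeping the bins 7..30 Hz that
  cover the alpha and beta bands (24 bins/channel); the OSF-projected virtual
  channel is processed identically and appended.
* MRCP block — per selected channel (CAR-filtered, downsampled to 64 Hz,
  0.1-1 Hz zero-phase 2nd-order Butterworth), the 64 raw time samples of the
  window; the OSF virtual channel appends 64 more.

With the reference configuration (19 ERD + 8 MRCP channels plus one OSF
virtual channel each) the vector has 19*24 + 24 + 8*64 + 64 = 1056 entries.
The ordering is fixed and exposed as an index map for interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import TrialSet
from .signals import decimate_to
from .spatial import SpatialFilter, car, laplacian
from .spectral import ar_psd, burg

REST_WINDOW_TIMES = (-2.0, -1.75, -1.5, -1.25, -1.0)
INTENTION_WINDOW_TIME = 0.0


def test_window_times(step: float = 0.125) -> np.ndarray:
    """Right edges of the sliding test windows over [-3, 0]: t = -2 .. 0."""
    n = int(round(2.0 / step))
    return -2.0 + step * np.arange(n + 1)


def training_window_times(rest_step: float = 0.25
                          ) -> tuple[np.ndarray, float]:
    """(rest window right edges over [-3, -1], intention window right edge)."""
    n = int(round(1.0 / rest_step))
    return -2.0 + rest_step * np.arange(n + 1), INTENTION_WINDOW_TIME


def window_slice(t: float, fs: float, trial_start: float = -3.0,
                 n_total: int | None = None, length_s: float = 1.0) -> slice:
    """Sample slice of the half-open window [t - length, t) on the trial axis."""
    right = int(round((t - trial_start) * fs))
    left = right - int(round(length_s * fs))
    if left < 0 or (n_total is not None and right > n_total):
        raise ValueError(f"window [{t - length_s}, {t}) truncated by trial edge")
    return slice(left, right)


@dataclass
class FeatureWindow:
    t: float
    vector: np.ndarray
    label: str = "unlabeled"        # rest | intention | unlabeled
    trial: int = -1


@dataclass
class NormalizationStats:
    """Per-feature mean/sd from training windows only; zero-variance features
    are flagged and mapped to 0 on application."""

    mean: np.ndarray
    std: np.ndarray
    zero_variance: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "NormalizationStats":
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training windows")
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        zero = std < 1e-12
        return cls(mean=mean, std=np.where(zero, 1.0, std), zero_variance=zero)

    def apply(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.std
        Z[..., self.zero_variance] = 0.0
        return Z


# ---------------------------------------------------------------------------
# spec-level extractors (single window)

def erd_features(trial_lap: np.ndarray, t: float, fs: float,
                 osf_signal: np.ndarray | None = None, ar_order: int = 16,
                 bins: tuple[int, int] = (7, 30)) -> np.ndarray:
    """ERD block for one window: AR spectra of the Laplacian-filtered channels
    (rows of `trial_lap`), with the OSF virtual signal appended if given."""
    sl = window_slice(t, fs, n_total=trial_lap.shape[-1])
    rows = trial_lap[:, sl]
    if osf_signal is not None:
        rows = np.vstack([rows, osf_signal[sl]])
    freqs = np.arange(bins[0], bins[1] + 1, dtype=float)
    a, e = burg(rows, ar_order)
    return ar_psd(a, e, freqs, fs).reshape(-1)


def mrcp_features(trial_mrcp: np.ndarray, t: float, fs: float = 64.0,
                  osf_signal: np.ndarray | None = None) -> np.ndarray:
    """MRCP block for one window: the 64 Hz low-frequency time samples of the
    selected channels (rows), with the OSF virtual signal appended if given."""
    sl = window_slice(t, fs, n_total=trial_mrcp.shape[-1])
    rows = trial_mrcp[:, sl]
    if osf_signal is not None:
        rows = np.vstack([rows, osf_signal[sl]])
    return rows.reshape(-1)


def build_index_map(erd_channels, mrcp_channels,
                    bins: tuple[int, int] = (7, 30),
                    mrcp_fs: float = 64.0) -> list[tuple[str, str, float]]:
    """Ordered (kind, channel, bin-or-sample-time) description of the vector."""
    freqs = list(range(bins[0], bins[1] + 1))
    entries: list[tuple[str, str, float]] = []
    for ch in list(erd_channels) + ["OSF-ERD"]:
        entries.extend(("erd", ch, float(f)) for f in freqs)
    n_samp = int(round(mrcp_fs))
    for ch in list(mrcp_channels) + ["OSF-MRCP"]:
        entries.extend(("mrcp", ch, -1.0 + (k + 1) / mrcp_fs)
                       for k in range(n_samp))
    return entries


def feature_vector_length(n_erd_channels: int, n_mrcp_channels: int,
                          n_bins: int = 24, n_samples: int = 64) -> int:
    """Closed-form vector length including the two OSF virtual channels."""
    return n_bins * (n_erd_channels + 1) + n_samples * (n_mrcp_channels + 1)


# ---------------------------------------------------------------------------
# batched pipeline used by the cross-validated decoder

class TrialFeaturePipeline:
    """Precomputes the fold-independent signal views and feature blocks.

    The Laplacian/CAR filtering, 64 Hz MRCP resampling and the fixed-channel
    feature blocks do not depend on the training/test split, so they are
    computed once; only the OSF-projected blocks are recomputed per fold.
    """

    def __init__(self, trials: TrialSet, config):
        config.validate()
        self.config = config
        self.trials = trials
        self.fs = trials.fs
        self.labels = list(trials.channel_labels)
        self.erd_channels = [ch for ch in config.erd_channels if ch in self.labels]
        self.mrcp_channels = [ch for ch in config.mrcp_channels if ch in self.labels]
        self.bins = config.erd_bins
        self.n_bins = self.bins[1] - self.bins[0] + 1
        self.mrcp_fs = config.mrcp_fs
        self.n_mrcp_samples = int(round(self.mrcp_fs))
        self.times = test_window_times(config.test_step)
        self.rest_times, self.intention_time = training_window_times(
            config.train_rest_step)

        kept = trials.kept_data()
        self.n_trials = kept.shape[0]
        self.raw = kept

        lap = laplacian(_subset(trials, kept))
        erd_idx = [self.labels.index(ch) for ch in self.erd_channels]
        self.lap_erd = lap.data[:, erd_idx, :]

        carred = car(_subset(trials, kept))
        low = decimate_to(carred.data, self.fs, self.mrcp_fs, axis=2)
        nyq = self.mrcp_fs / 2.0
        sos = sps.butter(2, [config.mrcp_band[0] / nyq, config.mrcp_band[1] / nyq],
                         btype="band", output="sos")
        low = sps.sosfiltfilt(sos, low, axis=2)
        mrcp_idx = [self.labels.index(ch) for ch in self.mrcp_channels]
        self.mrcp_low = low[:, mrcp_idx, :]
        self._mrcp_sos = sos

        self._erd_fixed = self._batch_erd(self.lap_erd)      # trials x T x (ch*bins)
        self._mrcp_fixed = self._batch_mrcp(self.mrcp_low)   # trials x T x (ch*64)

        self.index_map = build_index_map(self.erd_channels, self.mrcp_channels,
                                         self.bins, self.mrcp_fs)

    # -- batched blocks ------------------------------------------------------

    def _windows_512(self, x: np.ndarray) -> np.ndarray:
        """x: trials x channels x samples -> trials x T x channels x 512."""
        n = x.shape[-1]
        cuts = [x[..., window_slice(t, self.fs, n_total=n)] for t in self.times]
        return np.stack(cuts, axis=1)

    def _batch_erd(self, lap: np.ndarray) -> np.ndarray:
        wins = self._windows_512(lap)                       # N x T x C x 512
        freqs = np.arange(self.bins[0], self.bins[1] + 1, dtype=float)
        a, e = burg(wins, self.config.ar_order)
        psd = ar_psd(a, e, freqs, self.fs)                  # N x T x C x bins
        return psd.reshape(psd.shape[0], psd.shape[1], -1)

    def _batch_mrcp(self, low: np.ndarray) -> np.ndarray:
        n = low.shape[-1]
        cuts = [low[..., window_slice(t, self.mrcp_fs, n_total=n)]
                for t in self.times]
        wins = np.stack(cuts, axis=1)                       # N x T x C x 64
        return wins.reshape(wins.shape[0], wins.shape[1], -1)

    def _osf_blocks(self, osf_erd: SpatialFilter, osf_mrcp: SpatialFilter,
                    trial_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raw = self.raw[trial_idx]
        virt_erd = np.einsum("c,tcs->ts", osf_erd.w, raw)
        wins = np.stack([virt_erd[:, window_slice(t, self.fs, n_total=raw.shape[-1])]
                         for t in self.times], axis=1)      # n x T x 512
        freqs = np.arange(self.bins[0], self.bins[1] + 1, dtype=float)
        a, e = burg(wins, self.config.ar_order)
        erd_block = ar_psd(a, e, freqs, self.fs)            # n x T x bins

        virt_m = np.einsum("c,tcs->ts", osf_mrcp.w, raw)
        virt_low = decimate_to(virt_m, self.fs, self.mrcp_fs, axis=1)
        virt_low = sps.sosfiltfilt(self._mrcp_sos, virt_low, axis=1)
        m_block = np.stack(
            [virt_low[:, window_slice(t, self.mrcp_fs, n_total=virt_low.shape[-1])]
             for t in self.times], axis=1)                  # n x T x 64
        return erd_block, m_block

    def vectors(self, trial_idx, osf_erd: SpatialFilter,
                osf_mrcp: SpatialFilter) -> np.ndarray:
        """Full 1056-feature vectors for all test-grid windows of the given
        trials: shape (len(trial_idx), n_windows, n_features)."""
        trial_idx = np.asarray(trial_idx, dtype=int)
        erd_osf, mrcp_osf = self._osf_blocks(osf_erd, osf_mrcp, trial_idx)
        return np.concatenate([
            self._erd_fixed[trial_idx], erd_osf,
            self._mrcp_fixed[trial_idx], mrcp_osf,
        ], axis=2)

    def window_index(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise ValueError(f"t={t} is not on the test-window grid")
        return i

    def training_matrix(self, vectors: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Stack the rest and intention training windows out of per-trial
        test-grid vectors; returns (X, y) with y=1 for intention."""
        rest_idx = [self.window_index(t) for t in self.rest_times]
        int_idx = self.window_index(self.intention_time)
        X_rest = vectors[:, rest_idx, :].reshape(-1, vectors.shape[2])
        X_int = vectors[:, int_idx, :]
        X = np.vstack([X_rest, X_int])
        y = np.concatenate([np.zeros(len(X_rest), dtype=int),
                            np.ones(len(X_int), dtype=int)])
        return X, y


def _subset(trials: TrialSet, kept_data: np.ndarray) -> TrialSet:
    return TrialSet(data=kept_data, fs=trials.fs,
                    channel_labels=list(trials.channel_labels),
                    window=trials.window, movement=trials.movement)
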