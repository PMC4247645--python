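"""Synthetic EEG with planted movement-intention correlates.

Generates continuous 32-channel recordings at 512 Hz that carry the two
pre-movement EEG signatures of self-initiated movement with known ground
truth, so every downstream stage is testable without human data:

* ERD — the alpha (7-12 Hz) and beta (13-28 Hz) sensorimotor rhythms lose a
  known fraction of their power from a fixed lead time before each movement
  onset until 1 s after it.  The rhythms are stationary band-limited Gaussian
  processes (filling their bands, as physiological rhythms do, so band-mean
  power estimates see the full effect); the loss is a multiplicative envelope
  on the rhythm components only, so the planted % power change has the closed
  form ``100 * erd_depth``.
* MRCP — a slow negative potential ramps up to a known peak amplitude exactly
  at each onset, spatially peaked over the midline motor cortex.

The background is 1/f-shaped Gaussian noise plus the stationary rhythms with
random per-trial phase, mixed through Gaussian scalp maps on the 10/10 grid.
A kinematic auxiliary channel carries one rectified movement burst per trial,
constructed so that its 5%-of-maximum crossing falls on the true onset.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import montage
from .containers import AuxChannel, Recording, TrialSet

FS = 512.0

#: burst geometry: Gaussian peaking 0.25 s after onset, sigma such that the
#: leading edge crosses 5% of the peak at the onset itself.
_BURST_PEAK_DELAY = 0.25
_BURST_SIGMA = _BURST_PEAK_DELAY / np.sqrt(-2.0 * np.log(0.05))


@dataclass
class EffectSpec:
    """Planted effect sizes and trial structure for one synthetic session.

    ``erd_depth`` is the fractional power change of the planted rhythms in
    (-1, 0] (e.g. -0.5 = 50% desynchronization); ``mrcp_peak`` the negative
    potential reached at onset, in microvolts.  Trials follow the self-paced
    protocol: one onset per ``trial_period`` seconds, at least 3 s of rest
    before each onset and 3 s of data after it.
    """

    erd_depth: float = -0.5
    erd_channel: str = "C3"
    erd_lead: float = 1.0            # s before onset at which ERD begins
                                     # (a longer lead bleeds into the [-3,-1]
                                     # baseline and caps the measurable ERD%)
    mrcp_peak: float = -5.0          # microvolts, <= 0
    mrcp_channel: str = "Cz"
    mrcp_ramp: float = 2.0           # s of ramp-up to the peak
    mrcp_decay: float = 1.5          # s of post-onset rebound (near-symmetric
                                     # bump keeps the filtered peak at t ~ 0)
    noise_exponent: float = 1.0      # 1/f^exponent background power
    noise_std: float = 7.0           # microvolts per channel
    alpha_amp: float = 14.0          # RMS of the 7-12 Hz rhythm at its map peak
    beta_amp: float = 9.0            # RMS of the 13-28 Hz rhythm at its map peak
    alpha_band: tuple[float, float] = (7.0, 12.0)
    beta_band: tuple[float, float] = (13.0, 28.0)
    map_sigma: float = 0.85          # scalp-map width, grid units (focal source)
    # trial-to-trial variability: what limits single-trial decoding in real
    # EEG.  Constructed so the *trial-averaged* planted values are preserved.
    rhythm_trial_sigma: float = 0.4  # lognormal sigma of per-trial rhythm gain
    erd_depth_jitter: float = 0.5    # uniform relative jitter of the ERD depth
    mrcp_amp_jitter: float = 0.5     # uniform relative jitter of the MRCP peak
    mrcp_latency_sd: float = 0.1     # s, Gaussian jitter of the MRCP peak time
    n_trials: int = 50
    trial_period: float = 13.0       # s per trial
    onset_range: tuple[float, float] = (3.5, 8.0)  # onset time within a trial
    outlier_trials: tuple = ()       # trial indices amplitude-scaled (artifact tests)
    outlier_scale: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if not (-1.0 < self.erd_depth <= 0.0):
            raise ValueError("erd_depth must be in (-1, 0]")
        if self.mrcp_peak > 0:
            raise ValueError("mrcp_peak must be <= 0")
        lo, hi = self.onset_range
        if lo < 3.0 + 0.5:
            raise ValueError("onset must leave >= 3 s of rest (plus ramp margin)")
        if hi + 3.0 > self.trial_period:
            raise ValueError("onset must leave >= 3 s of post-movement data")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")

    def to_dict(self) -> dict:
        return asdict(self)


def planted_erd_percent(spec: EffectSpec) -> float:
    """Closed-form planted pre-movement ERD, in % power change of the rhythms."""
    return 100.0 * spec.erd_depth


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float,
                      std: float, n_channels: int, fs: float) -> np.ndarray:
    """Gaussian noise with 1/f^exponent power spectrum, per-channel independent."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1) * shaping
    out = np.fft.irfft(spec, n=n, axis=1)
    out *= std / out.std(axis=1, keepdims=True)
    return out


def _erd_envelope(t: np.ndarray, onset: float, depth: float, lead: float,
                  ramp: float = 0.25) -> np.ndarray:
    """Amplitude envelope: 1 at rest, sqrt(1+depth) in the desynchronized span
    [onset-lead, onset+1], with cosine transitions of `ramp` seconds."""
    gain = np.sqrt(1.0 + depth)
    env = np.ones_like(t)
    t0, t1 = onset - lead, onset + 1.0
    inside = (t >= t0) & (t <= t1)
    env[inside] = gain
    fall = (t >= t0 - ramp) & (t < t0)
    env[fall] = 1.0 + (gain - 1.0) * 0.5 * (1 - np.cos(np.pi * (t[fall] - (t0 - ramp)) / ramp))
    rise = (t > t1) & (t <= t1 + ramp)
    env[rise] = gain + (1.0 - gain) * 0.5 * (1 - np.cos(np.pi * (t[rise] - t1) / ramp))
    return env


def _mrcp_bump(t: np.ndarray, onset: float, peak: float, ramp: float,
               decay: float = 1.5) -> np.ndarray:
    """Slow potential: cosine ramp from 0 to `peak` at the onset, cosine decay."""
    out = np.zeros_like(t)
    up = (t >= onset - ramp) & (t <= onset)
    out[up] = peak * 0.5 * (1 - np.cos(np.pi * (t[up] - (onset - ramp)) / ramp))
    down = (t > onset) & (t <= onset + decay)
    out[down] = peak * np.cos(np.pi * (t[down] - onset) / (2 * decay)) ** 2
    return out


def _mrcp_source_gain(spec: EffectSpec, labels) -> float:
    """Source amplitude such that the *measured* peak equals ``mrcp_peak``.

    The measurement chain (CAR, then 0.1-1 Hz zero-phase bandpass) shrinks
    the planted bump: CAR subtracts the scalp-map mean from the peak channel
    and the bandpass clips the lowest-frequency content.  The source is
    scaled by the inverse of that noise-free attenuation, so the planted
    parameter is exactly what the analysis chain ideally recovers at the
    peak channel.
    """
    if spec.mrcp_peak == 0.0:
        return 0.0
    from .signals import bandpass

    mrcp_map = montage.scalp_map(labels, spec.mrcp_channel, spec.map_sigma)
    car_gain = 1.0 - mrcp_map.mean()
    pad = 4.0
    t = np.arange(int(round((spec.mrcp_ramp + spec.mrcp_decay + 2 * pad) * FS))) / FS
    unit = _mrcp_bump(t, pad + spec.mrcp_ramp, -1.0, spec.mrcp_ramp,
                      spec.mrcp_decay)
    filtered_min = bandpass(unit * car_gain, (0.1, 1.0), FS, order=2).min()
    return spec.mrcp_peak / filtered_min


def _kinematic_burst(t: np.ndarray, onset: float) -> np.ndarray:
    """Rectified Gaussian burst of ~0.5 s starting at the onset (zero before)."""
    bump = np.exp(-((t - onset - _BURST_PEAK_DELAY) ** 2) / (2 * _BURST_SIGMA ** 2))
    bump[t < onset] = 0.0
    return bump


def generate_recording(spec: EffectSpec) -> tuple[Recording, list[float]]:
    """Continuous synthetic recording plus the exact list of movement onsets."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = list(montage.CHANNELS_32)
    n_ch = len(labels)
    n_per_trial = int(round(spec.trial_period * FS))
    n_total = n_per_trial * spec.n_trials

    data = _one_over_f_noise(rng, n_total, spec.noise_exponent, spec.noise_std,
                             n_ch, FS)
    kin = np.zeros(n_total)

    from .signals import bandpass

    rhythm = np.zeros(n_total)
    for band, amp in ((spec.alpha_band, spec.alpha_amp),
                      (spec.beta_band, spec.beta_amp)):
        if amp > 0:
            r = bandpass(rng.standard_normal(n_total), band, FS)
            rhythm += amp * r / r.std()

    erd_map = montage.scalp_map(labels, spec.erd_channel, spec.map_sigma)
    mrcp_map = montage.scalp_map(labels, spec.mrcp_channel, spec.map_sigma)
    source_gain = _mrcp_source_gain(spec, labels)

    onsets: list[float] = []
    for k in range(spec.n_trials):
        t_start = k * spec.trial_period
        onset = t_start + rng.uniform(*spec.onset_range)
        onsets.append(onset)

        sl = slice(k * n_per_trial, (k + 1) * n_per_trial)
        t = t_start + np.arange(n_per_trial) / FS

        # per-trial draws (fixed order for seeded determinism)
        gain = rng.lognormal(mean=-spec.rhythm_trial_sigma ** 2 / 2,
                             sigma=spec.rhythm_trial_sigma)
        depth_i = np.clip(
            spec.erd_depth * (1 + spec.erd_depth_jitter * rng.uniform(-1, 1)),
            -0.999, 0.0)
        amp_i = -source_gain * (1 + spec.mrcp_amp_jitter * rng.uniform(-1, 1))
        lat_i = rng.normal(0.0, spec.mrcp_latency_sd)

        env = _erd_envelope(t, onset, depth_i, spec.erd_lead)
        source = _mrcp_bump(t, onset + lat_i, amp_i, spec.mrcp_ramp,
                            spec.mrcp_decay)

        data[:, sl] += erd_map[:, None] * (gain * rhythm[sl] * env)[None, :]
        data[:, sl] += mrcp_map[:, None] * source[None, :]
        kin[sl] = _kinematic_burst(t, onset)

        if k in set(spec.outlier_trials):
            data[:, sl] *= spec.outlier_scale

    rec = Recording(
        data=data, fs=FS, channel_labels=labels,
        aux={"kin": AuxChannel(kin, FS)},
        annotations=[(float(t), "movement_onset") for t in onsets])
    return rec, onsets


def generate_trialset(spec: EffectSpec,
                      window: tuple[float, float] = (-3.0, 3.0)) -> TrialSet:
    """Epochs aligned to the *true* onsets (bypasses onset detection)."""
    rec, onsets = generate_recording(spec)
    n_pre = int(round(-window[0] * FS))
    n_post = int(round(window[1] * FS))
    epochs = []
    for onset in onsets:
        c = int(round(onset * FS))
        epochs.append(rec.data[:, c - n_pre:c + n_post])
    return TrialSet(data=np.stack(epochs), fs=FS,
                    channel_labels=rec.channel_labels, window=window,
                    movement="synthetic")
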