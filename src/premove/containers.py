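"""In-memory containers for recordings and epoched trials, plus the internal
single-file store.

The internal store is a `.npz` archive holding the numeric arrays plus a JSON
metadata entry (sampling rate, labels, time axis, audit trail).  EDF/GDF are
import-only; epoch-aligned trial arrays do not map onto those formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import montage


@dataclass
class AuxChannel:
    """A non-EEG channel (kinematic / EMG style) with its own sampling rate."""

    data: np.ndarray
    fs: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("aux fs must be positive")
        if self.data.ndim != 1:
            raise ValueError("aux channel must be 1-D")


@dataclass
class Recording:
    """Continuous multichannel EEG (microvolts) plus auxiliary channels.

    data is channels x samples; `aux` maps names to :class:`AuxChannel`;
    `annotations` is a list of (time_s, label) pairs.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    aux: dict[str, AuxChannel] = field(default_factory=dict)
    annotations: list[tuple[float, str]] = field(default_factory=list)
    unknown_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        labels = list(self.channel_labels)
        if len(labels) != self.data.shape[0]:
            raise ValueError("one label per channel row required")
        dupes = {lb for lb in labels if labels.count(lb) > 1}
        if dupes:
            raise ValueError(f"duplicate channel labels: {sorted(dupes)}")
        self.channel_labels = labels

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


@dataclass
class TrialSet:
    """Epoched trials on a fixed time axis relative to movement onset (t = 0).

    data is trials x channels x samples; `kept` masks artifact-rejected trials
    (rejected trials stay in the array — audit trail, never deleted);
    `rejection_reasons` maps trial index -> human-readable reason.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    window: tuple[float, float] = (-3.0, 3.0)
    movement: str = "unspecified"
    kept: np.ndarray | None = None
    rejection_reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("trial data must be trials x channels x samples")
        expected = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window {self.window} at fs={self.fs} implies {expected} samples, "
                f"got {self.data.shape[2]}")
        if self.kept is None:
            self.kept = np.ones(self.data.shape[0], dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)
        self.channel_labels = list(self.channel_labels)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window[0] + np.arange(n) / self.fs

    def kept_data(self) -> np.ndarray:
        return self.data[self.kept]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def drop_channels(self, labels) -> "TrialSet":
        keep = [i for i, lb in enumerate(self.channel_labels) if lb not in set(labels)]
        return TrialSet(
            data=self.data[:, keep, :], fs=self.fs,
            channel_labels=[self.channel_labels[i] for i in keep],
            window=self.window, movement=self.movement,
            kept=self.kept.copy(), rejection_reasons=dict(self.rejection_reasons))


# ---------------------------------------------------------------------------
# internal single-file store

def save_recording(path, rec: Recording) -> None:
    meta = {
        "kind": "recording",
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "annotations": [[float(t), str(lb)] for t, lb in rec.annotations],
        "unknown_labels": rec.unknown_labels,
        "aux": {name: ch.fs for name, ch in rec.aux.items()},
    }
    arrays = {"data": rec.data, "meta": _meta_array(meta)}
    for name, ch in rec.aux.items():
        arrays[f"aux_{name}"] = ch.data
    np.savez(path, **arrays)


def save_trialset(path, ts: TrialSet) -> None:
    meta = {
        "kind": "trialset",
        "fs": ts.fs,
        "channel_labels": ts.channel_labels,
        "window": list(ts.window),
        "movement": ts.movement,
        "rejection_reasons": {str(k): v for k, v in ts.rejection_reasons.items()},
    }
    np.savez(path, data=ts.data, kept=ts.kept, meta=_meta_array(meta))


def load_internal(path):
    """Load a Recording or TrialSet from the internal store (dispatch on kind)."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"].tobytes()).decode())
        if meta["kind"] == "recording":
            aux = {
                name: AuxChannel(npz[f"aux_{name}"], fs)
                for name, fs in meta.get("aux", {}).items()
            }
            return Recording(
                data=npz["data"], fs=meta["fs"],
                channel_labels=meta["channel_labels"], aux=aux,
                annotations=[(t, lb) for t, lb in meta.get("annotations", [])],
                unknown_labels=meta.get("unknown_labels", []))
        if meta["kind"] == "trialset":
            return TrialSet(
                data=npz["data"], fs=meta["fs"],
                channel_labels=meta["channel_labels"],
                window=tuple(meta["window"]), movement=meta["movement"],
                kept=npz["kept"],
                rejection_reasons={int(k): v for k, v in
                                   meta.get("rejection_reasons", {}).items()})
    raise ValueError(f"unrecognized container kind in {path}")


def _meta_array(meta: dict) -> np.ndarray:
    return np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)


def load_recording(path, format: str = "internal") -> Recording:
    """Read a recording from the internal store or from EDF/GDF.

    EDF/GDF channels whose labels are not on the 32-channel 10/10 montage are
    kept but listed in ``Recording.unknown_labels``.
    """
    if format == "internal":
        rec = load_internal(path)
        if not isinstance(rec, Recording):
            raise ValueError(f"{path} holds a {type(rec).__name__}, not a Recording")
        return rec
    if format in ("edf", "gdf"):
        import mne

        reader = mne.io.read_raw_edf if format == "edf" else mne.io.read_raw_gdf
        raw = reader(path, preload=True, verbose="error")
        labels = list(raw.ch_names)
        dupes = {lb for lb in labels if labels.count(lb) > 1}
        if dupes:
            raise ValueError(f"duplicate channel labels: {sorted(dupes)}")
        known = set(montage.CHANNELS_32)
        unknown = [lb for lb in labels if lb not in known]
        data = raw.get_data() * 1e6  # volts -> microvolts
        annotations = [(float(on), str(desc))
                       for on, desc in zip(raw.annotations.onset,
                                           raw.annotations.description)]
        return Recording(data=data, fs=float(raw.info["sfreq"]),
                         channel_labels=labels, annotations=annotations,
                         unknown_labels=unknown)
    raise ValueError(f"unknown format {format!r}")
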