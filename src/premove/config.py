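"""Pipeline configuration: every tunable parameter of the decoding chain."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from . import montage

#: Canonical frequency bands (Hz), half-open on the right except beta.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (7.0, 12.0),
    "beta": (12.0, 30.0),
}


@dataclass
class PipelineConfig:
    """Parameters of the full rest-vs-intention decoding pipeline.

    Times are seconds relative to movement onset (t = 0); windows are
    half-open ``[t-1, t)`` and indexed by their right edge ``t``.
    """

    montage_name: str = "standard-10-10-32"
    epoch_window: tuple[float, float] = (-3.0, 3.0)
    bands: dict = field(default_factory=lambda: dict(BANDS))

    # preprocessing
    onset_fraction: float = 0.05        # of the max rectified kinematic amplitude
    onset_refractory_s: float = 2.0
    artifact_multiplier: float = 2.5    # trial measure > multiplier x mean -> rejected
    drop_channels: tuple = ("FC3", "FC1")

    # window bookkeeping
    train_rest_step: float = 0.25
    test_step: float = 0.125

    # features
    ar_order: int = 16
    erd_bins: tuple[int, int] = (7, 30)       # inclusive, 1 Hz resolution -> 24 bins
    mrcp_fs: float = 64.0
    mrcp_band: tuple[float, float] = (0.1, 1.0)
    mrcp_channels: tuple = montage.MRCP_CHANNELS

    # optimal spatial filter
    osf_erd_band: tuple[float, float] = (7.0, 30.0)
    osf_erd_init: str = "C3"
    osf_mrcp_init: str = "Cz"
    osf_max_iter: int = 500
    osf_tol: float = 1e-6

    # sparse discriminant analysis
    sda_budget: int | None = None       # None -> n_training_trials - 1
    sda_ridge: float = 1e-2
    sda_max_iter: int = 30
    sda_tol: float = 1e-6

    # evaluation
    threshold_mode: str = "pooled"      # pooled equal-sens-spec working point
    n_permutations: int = 10

    seed: int = 0

    @property
    def erd_channels(self) -> list[str]:
        return montage.erd_feature_channels(montage.CHANNELS_32, self.drop_channels)

    def validate(self) -> None:
        lo, hi = self.epoch_window
        if not (lo <= -3.0 and hi >= 0.0):
            raise ValueError("epoch window must span at least [-3, 0]")
        for step in (self.train_rest_step, self.test_step):
            if step <= 0 or abs(round(2.0 / step) - 2.0 / step) > 1e-9:
                raise ValueError(f"step {step} does not divide the 2 s window span")
        if not 0 < self.onset_fraction < 1:
            raise ValueError("onset fraction must be in (0, 1)")
        if self.sda_budget is not None and self.sda_budget < 1:
            raise ValueError("feature budget must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["erd_channels"] = self.erd_channels
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for key in ("epoch_window", "drop_channels", "mrcp_channels", "erd_bins",
                    "mrcp_band", "osf_erd_band"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg
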