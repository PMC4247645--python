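"""Onset detection, epoching, and artifact rejection on the simulated sessions.

Reports how accurately the kinematic onset detector recovers the true onsets
and how many trials survive the 2.5x-mean artifact rule; writes the epoched
trial containers for the later stages.
"""

import json
from pathlib import Path

import numpy as np

from premove import PipelineConfig
from premove.containers import load_internal, save_trialset
from premove.preprocess import detect_onsets, epoch, reject_artifacts

SCRATCH = Path("scratch")
RESULTS = Path("results")
cfg = PipelineConfig()

truth = json.loads((RESULTS / "simulation_ground_truth.json").read_text())
report = {}
for name in ("strong", "null"):
    rec = load_internal(SCRATCH / f"recording_{name}.npz")
    kin = rec.aux["kin"]
    onsets = detect_onsets(kin.data, kin.fs, fraction=cfg.onset_fraction,
                           refractory_s=cfg.onset_refractory_s)
    true = np.array(truth[name]["onsets_s"])
    matched = np.array([onsets[np.argmin(np.abs(onsets - t))] for t in true])
    err_ms = 1000 * (matched - true)

    trials = epoch(rec, onsets, window=cfg.epoch_window, movement=name)
    trials = trials.drop_channels(cfg.drop_channels)
    trials = reject_artifacts(trials, multiplier=cfg.artifact_multiplier)
    save_trialset(SCRATCH / f"trials_{name}.npz", trials)

    report[name] = {
        "n_true_onsets": int(true.size),
        "n_detected": int(onsets.size),
        "onset_error_ms": {"mean": float(err_ms.mean()),
                           "max_abs": float(np.abs(err_ms).max())},
        "n_epochs": int(trials.n_trials),
        "n_kept": int(trials.kept.sum()),
        "rejections": {str(k): v for k, v in trials.rejection_reasons.items()},
    }
    print(f"{name}: detected {onsets.size}/{true.size} onsets "
          f"(|err| <= {np.abs(err_ms).max():.0f} ms), kept "
          f"{trials.kept.sum()}/{trials.n_trials} trials")

(RESULTS / "preprocessing.json").write_text(json.dumps(report, indent=2))
print(f"wrote {RESULTS / 'preprocessing.json'}")
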