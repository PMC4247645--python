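"""Empirical chance level of the percent-correct metric.

Repeats the full leave-one-out decoding of the strong session with training
labels shuffled per fold (10 permutations) — the floor against which the
real decoding accuracies are judged.
"""

import json
from pathlib import Path

import numpy as np

from premove import PipelineConfig
from premove.containers import load_internal
from premove.evaluation import loo_evaluate

SCRATCH = Path("scratch")
RESULTS = Path("results")
cfg = PipelineConfig()

trials = load_internal(SCRATCH / "trials_strong.npz")
summary = loo_evaluate(trials, cfg, n_permutations=10, seed=11)

out = {
    "chance_mean_pct": summary.chance_mean,
    "chance_sd_pct": summary.chance_sd,
    "per_permutation_pct": summary.chance_percents,
    "real_percent_correct": summary.percent_correct,
    "real_auc": summary.auc,
    "n_trials": summary.n_trials,
    "n_permutations": len(summary.chance_percents),
}
(RESULTS / "chance.json").write_text(json.dumps(out, indent=2))
print(f"chance level: {summary.chance_mean:.1f} +/- {summary.chance_sd:.1f}% "
      f"correct trials (real decoder: {summary.percent_correct:.1f}%)")
print(f"wrote {RESULTS / 'chance.json'}")
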