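"""Generate the reference synthetic sessions.

Creates a strong-effect 50-trial session (planted -50% alpha/beta ERD at C3,
-5 uV MRCP at Cz) and a matched null session, and stores the continuous
recordings plus ground truth.  Containers go to scratch/ (binary); the
ground-truth summary to results/.
"""

import dataclasses
import json
from pathlib import Path

from premove import EffectSpec, generate_recording
from premove.containers import save_recording

SCRATCH = Path("scratch")
RESULTS = Path("results")
SCRATCH.mkdir(exist_ok=True)
RESULTS.mkdir(exist_ok=True)

sessions = {
    "strong": EffectSpec(n_trials=50, seed=1),
    "null": EffectSpec(erd_depth=0.0, mrcp_peak=0.0, n_trials=50, seed=101),
}

summary = {}
for name, spec in sessions.items():
    rec, onsets = generate_recording(spec)
    save_recording(SCRATCH / f"recording_{name}.npz", rec)
    summary[name] = {
        "planted": dataclasses.asdict(spec),
        "n_onsets": len(onsets),
        "onsets_s": [round(float(t), 4) for t in onsets],
        "duration_s": rec.duration,
    }
    print(f"{name}: {len(onsets)} trials, {rec.duration:.0f} s, "
          f"ERD depth {spec.erd_depth}, MRCP peak {spec.mrcp_peak} uV")

(RESULTS / "simulation_ground_truth.json").write_text(
    json.dumps(summary, indent=2, default=list))
print(f"wrote {RESULTS / 'simulation_ground_truth.json'}")
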