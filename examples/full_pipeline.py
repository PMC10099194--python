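"""End-to-end run: simulate, train, infer, fit fusion, fuse, evaluate.

Uses the desk-scale defaults (200 clips, 10 subjects, micro backbone);
takes about half a minute on one CPU.
"""

import json
import tempfile

from somnoscope.config import load_config
from somnoscope.pipeline import run_e2e

with tempfile.TemporaryDirectory() as tmp:
    cfg = load_config(None, ["seed=0", f"out_dir={tmp}/run"])
    report = run_e2e(cfg)
    print(json.dumps(report, indent=2, sort_keys=True))

# clip_symptoms: per-class precision/recall/f1/accuracy and ROC area of the
# eye/mouth anomaly classifier on held-out subjects' clips.
# fatigue_state: window-level metrics of the constrained MAP fusion against
# the scripted ground truth (positive class = fatigued).
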