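"""Generate a small synthetic face-clip cohort and inspect its manifest.

Each subject gets a scripted behavior timeline (prolonged eye closures,
yawns) rendered as schematic face frames; clips inherit multilabel
symptom annotations and a fatigue state from the script.
"""

import tempfile

from somnoscope import DatasetConfig, make_dataset

with tempfile.TemporaryDirectory() as tmp:
    cfg = DatasetConfig(n_subjects=6, clips_per_subject=10, seed=7)
    manifest = make_dataset(cfg, tmp)

    print(f"clips: {len(manifest)} from {cfg.n_subjects} subjects")
    print(manifest.head(6).to_string(index=False))
    print("\nlabel prevalence:")
    print(manifest[["label_eye", "label_mouth", "state"]].mean().round(3).to_string())
    print("\nsplit sizes (subject-disjoint):")
    print(manifest.groupby("split")["subject_id"].agg(["count", "nunique"]).to_string())

# label_eye / label_mouth are 1 when >= 50% of the clip's frames lie inside
# an eye-closure / yawn episode; state marks clips carrying either symptom.
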