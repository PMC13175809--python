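"""Deterministic preprocessing: validation, standardization, sampling.

Runs the cleaning pipeline on a small generated dataset plus one
deliberately broken study (missing a view) and prints the manifest:
which studies were accepted, and the per-study normalization record
(the mean/sd used for z-scoring).
"""

from kneemil import PreprocessConfig, RawStudy, SynthConfig, \
    generate_dataset, preprocess_dataset

dataset = generate_dataset(SynthConfig(n_exams=4, seed=3,
                                       base_resolution=48))
studies = [RawStudy(e.exam_id, e.views, e.labels) for e in dataset.exams]
broken = RawStudy("broken", {k: v for k, v in dataset.exams[0].views.items()
                             if k != "axial"}, None)
studies.append(broken)

config = PreprocessConfig(S=8, R=32)
exams, manifest = preprocess_dataset(studies, config)

for entry in manifest:
    if entry["accepted"]:
        print(f"{entry['exam_id']}: accepted, study mean "
              f"{entry['mean']:.4f}, sd {entry['sd']:.4f}")
    else:
        print(f"{entry['exam_id']}: rejected -> {entry['reasons']}")
print(f"\nevery accepted exam now has shape {exams[0].views.shape} "
      "(views, slices, height, width); pixel values are z-scored per study.")
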