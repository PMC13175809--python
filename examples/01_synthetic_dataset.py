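"""Generate a synthetic three-view knee-MRI dataset in benchmark layout.

Builds 50 exams with planted label-dependent lesions, writes them as
NPY view stacks plus headerless label CSVs, and prints the label
prevalences — the fraction of exams positive for abnormality, ACL tear
and meniscus tear.
"""

import tempfile
from pathlib import Path

from kneemil import SynthConfig, generate_dataset, write_mrnet_layout

config = SynthConfig(n_exams=50, seed=0, base_resolution=48)
dataset = generate_dataset(config)

root = Path(tempfile.mkdtemp(prefix="kneemil_"))
write_mrnet_layout(dataset, root, split="train")

print(f"wrote {len(dataset.exams)} exams under {root}")
print("label prevalences (fraction of positive exams):")
print(dataset.labels[["abnormal", "acl", "meniscus"]].mean().round(3))
first = dataset.exams[0]
shapes = {v: a.shape for v, a in first.views.items()}
print(f"exam {first.exam_id}: per-view stack shapes {shapes}")
print("slice counts vary per view; preprocessing later fixes them to S.")
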