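"""Generate a small synthetic head-CT corpus and inspect its ground truth.

Each study is a stack of phantom slices (skull ring + brain + one of four
lesion classes) with a templated report whose text is consistent with the
lesion class — positive findings are asserted, and normal studies *negate*
the finding their anamnesis asks about.
"""

from collections import Counter
from pathlib import Path

from ctsearch import generate_corpus, write_study_files, write_truth_table

OUT = Path("scratch/example_corpus")

studies, truth = generate_corpus(n=12, base_seed=42, image_size=64, n_slices=2)
OUT.mkdir(parents=True, exist_ok=True)
for study in studies:
    write_study_files(study, OUT)
write_truth_table(studies, OUT / "truth.csv")

print(f"wrote {len(studies)} studies to {OUT}/ (DICOM slices + report.json each)")
print("class counts:", dict(Counter(truth.values())))
example = studies[0]
print(f"\nexample study {example.study_id} (truth: {example.truth_class})")
print("  anamnesis:  ", example.report.anamnesis)
print("  report_text:", example.report.report_text)
print("  slice shape:", example.slices[0].shape, "| HU range:",
      int(example.slices[0].min()), "to", int(example.slices[0].max()))
# The class counts follow the requested mix exactly (largest-remainder
# rounding); rerunning with the same base_seed reproduces every pixel.
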