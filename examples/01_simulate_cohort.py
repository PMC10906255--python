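"""Simulate a plasma fingerprint cohort with planted differential markers.

Builds a template library of 60 background metabolites plus the 8
reference markers (4 up-, 4 down-regulated at standardized effect 1.5),
renders 20 + 20 profile-mode spectra, and writes spectra/metadata/
ground-truth CSVs.
"""

from pathlib import Path

import fingermet as fm
from fingermet.io import write_ground_truth, write_spectra

out = Path("scratch_example_cohort")
out.mkdir(exist_ok=True)

templates, truth = fm.build_template_library(
    n_background=60, n_differential=8, effect_size=1.5, seed=42)
spec = fm.CohortSpec(groups=(("HC", 20), ("AECOPD", 20)), seed=42)
spectra, metadata, truth = fm.simulate_cohort(spec, templates, fm.NoiseSpec(), truth)

write_spectra(spectra, out / "spectra.csv")
metadata.to_csv(out / "metadata.csv", index=False)
write_ground_truth(truth, out / "ground_truth.csv")

print(f"{len(spectra)} spectra on a {spectra[0].mz.size}-point m/z grid")
print(f"planted markers (name, m/z, direction):")
for name, mz, direction, effect in truth.differential_features:
    print(f"  {name:24s} {mz:9.4f}  {direction}")
# Each marker's m/z is its neutral monoisotopic mass plus one cation
# (H+/Na+/K+) minus an electron; 'up' means higher in AECOPD than HC.
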