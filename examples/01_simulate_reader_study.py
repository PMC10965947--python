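"""Simulate one ROI and a noisy reader, then inspect what the reader saw.

Generates a 150x150 um ROI as a hard-core point pattern (tumor and other
cells, 30% PD-L1 positivity), simulates an annotator with misses, class
confusion and localization jitter, and prints the resulting counts.
"""

from pdl1bench import CellClass, ReaderModel, generate_tissue_roi, simulate_reader

roi = generate_tissue_roi(
    tumor_density_per_mm2=4000,
    other_density_per_mm2=2000,
    positivity_fraction=0.3,
    seed=1,
)
reader = ReaderModel(
    miss_rate=0.05,
    confusion=[[0.85, 0.01, 0.14], [0.02, 0.9, 0.08], [0.1, 0.01, 0.89]],
    jitter_sigma_um=1.5,
    extra_rate_per_mm2=60,
)
annotated = simulate_reader(roi, reader, seed=2, source_id="P1")

truth_counts = {c: sum(p.label is c for p in roi.cells) for c in CellClass if c.value != "background"}
read_counts = {c: sum(p.label is c for p in annotated.points) for c in truth_counts}
print(f"ground truth: {len(roi.cells)} cells  {[(c.value, n) for c, n in truth_counts.items()]}")
print(f"reader P1:    {len(annotated.points)} points {[(c.value, n) for c, n in read_counts.items()]}")
print("The reader misses ~5% of cells, relabels a few (mostly neg-tumor <-> other),")
print("jitters each point by ~1.5 um, and hallucinates a handful of extras.")
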