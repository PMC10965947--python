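"""End-to-end synthetic benchmarking study with written reports.

Runs the whole pipeline under one seed: simulates the cell-level reader
study (reader panel + detector on shared ROIs) and the slide-level TPS
study, computes all agreement statistics, and writes JSON/CSV reports plus
provenance into a run directory.
"""

from pdl1bench import RunConfig, run_pipeline

config = RunConfig(seed=11, n_cases_cell=6, rois_per_case=3, n_cases_tps=60)
results = run_pipeline(config, "scratch/example_run")

cell = results["cell_level"]
slide = results["slide_level"]
print(f"mean reader-reader macro F1: {cell['reader_reader_f1']['mean']:.3f} "
      f"(CI {cell['reader_reader_f1']['ci_low']:.3f}-{cell['reader_reader_f1']['ci_high']:.3f})")
print(f"mean reader-AI macro F1:     {cell['reader_ai_f1']['mean']:.3f}")
print(f"background share of disagreements: "
      f"reader-reader {cell['background_disagreement']['reader_reader_mean']:.1%}, "
      f"reader-AI {cell['background_disagreement']['reader_ai_mean']:.1%}")
print(f"ICC(2,1) readers: {slide['icc_readers']['value']:.3f}")
print(f"mean linear kappa: reader-reader {slide['linear_kappa']['reader_reader']['mean']:.3f}, "
      f"reader-AI {slide['linear_kappa']['reader_ai']['mean']:.3f}")
ba = slide["bland_altman_ai_minus_median_reader"]
print(f"Bland-Altman AI minus median reader: {ba['mean_diff']:+.2f} "
      f"[{ba['loa_low']:.2f}, {ba['loa_high']:.2f}]")
print("\nreports written to scratch/example_run/: f1_report.json, pairwise_f1.csv,")
print("agreement.json, tps_table.csv, semiauto_annotation.json, provenance.json")
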