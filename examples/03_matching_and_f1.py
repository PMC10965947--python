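"""Hit-criterion matching and F1 between two annotators of the same ROI.

Two simulated readers annotate one ROI; their point sets are matched under
the 8 um hit criterion (closest prediction wins, one-to-one), tallied into
a 4-class confusion matrix including the background (presence/absence)
class, and scored with per-class and macro F1.
"""

from pdl1bench import (
    ReaderModel,
    background_disagreement_fraction,
    confusion_from_match,
    f1_from_confusions,
    generate_tissue_roi,
    match_points,
    simulate_reader,
)

roi = generate_tissue_roi(seed=5, positivity_fraction=0.4)
model = ReaderModel(miss_rate=0.06, jitter_sigma_um=2.0, extra_rate_per_mm2=80,
                    confusion=[[0.85, 0.01, 0.14], [0.02, 0.9, 0.08], [0.1, 0.01, 0.89]])
a = simulate_reader(roi, model, seed=6, source_id="P1")
b = simulate_reader(roi, model, seed=7, source_id="P2")

match = match_points(a, b, radius_um=8.0)
print(f"P1: {len(a.points)} points, P2: {len(b.points)} points")
print(f"matched pairs: {len(match.pairs)}, unmatched P1: {len(match.unmatched_refs)}, "
      f"unmatched P2: {len(match.unmatched_preds)}")

conf = confusion_from_match(match)
print("\nconfusion matrix (rows = P1, cols = P2):")
print(conf.to_dataframe())

report = f1_from_confusions([conf])
print(f"\nmacro F1: {report.macro_f1:.3f}")
for cls, score in report.per_class.items():
    print(f"  {cls.value:10s} precision {score.precision:.3f} recall {score.recall:.3f} F1 {score.f1:.3f}")
print(f"background share of disagreements: {background_disagreement_fraction(conf):.1%}")
print("(the background row/column counts cells one reader saw and the other did not)")
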