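"""Two-step semi-automatic annotation on a rendered synthetic IHC image.

Renders an ROI with three homogeneous regions (PD-L1 positive tumor,
negative tumor, other cells), detects nucleus centers by color
deconvolution + Laplacian-of-Gaussian blob detection, and transfers class
labels from the free-hand region polygons to the detected points.
"""

from pdl1bench import semiauto_annotation_demo

demo = semiauto_annotation_demo(seed=42)
print(f"true cells:        {demo['n_truth']}")
print(f"detected + labeled: {demo['n_detected']}")
print(f"recovered (correct label, <=3 um): {demo['recovered_fraction']:.1%}")
print(f"mean localization error: {demo['mean_localization_error_um']:.2f} um")
print(f"macro F1 vs ground truth (8 um hit criterion): {demo['macro_f1']:.3f}")
print()
print("A recovered fraction near 100% means the classical detector finds each")
print("hematoxylin-stained nucleus and the polygon intersection assigns the")
print("intended class; the residual error is the raster discretization.")
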