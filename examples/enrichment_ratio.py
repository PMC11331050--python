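"""Enrichment of immune-complex spots on dorsal F-actin ruffles.

Builds a two-channel z-stack phantom in which 60% of total spot intensity
sits on the filament mask, then runs the full per-cell pipeline: sharpest-
slice selection, maximum projection, band-pass / LoG filtering,
thresholding, spot detection, on/off classification, and the enrichment
ratio R = sum(I_on) / sum(I_all) in six sectors.
"""

from ssmic import enrichment, synth

stack, truth = synth.make_spot_filament_stack(n_spots=48, on_fraction=0.6, seed=1)
result = enrichment.per_cell_enrichment(stack)

print(f"ground-truth on-filament intensity fraction: {truth.intensity_on_fraction:.3f}")
for i, (r, n) in enumerate(zip(result.roi_ratios, result.n_spots)):
    shown = "no spots" if r is None else f"R = {r:.3f}"
    print(f"  ROI {i}: {n:2d} spots, {shown}")
print(f"cell mean R: {result.cell_mean:.3f}")
print("R near the built-in fraction means the pipeline recovers how much of")
print("the complexes' intensity is presented on the actin network (1 = all on).")
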