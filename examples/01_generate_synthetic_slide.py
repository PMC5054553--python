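"""Render a synthetic Ki-67 stained slide with full ground truth.

Builds a small slide at eight-fold-reduction resolution containing a dense
immunopositive cluster, a hemorrhage patch and a vessel wall, writes the
PNG + masks + ground-truth JSON, and prints what was placed.
"""

from ki67hotspot.synthetic import SyntheticSpec, generate_slide, save_outputs

spec = SyntheticSpec(
    width_px=800,
    height_px=600,
    n_pos_cells=250,
    n_neg_cells=1800,
    pos_clusters=[((220, 220), 50, 70)],
    hemorrhage_blobs=[((560, 400), 70)],
    vessel_walls=[([(100, 480), (300, 520), (500, 470)], 5)],
    seed=42,
)
slide, truth = generate_slide(spec)
save_outputs("scratch/example_slide", slide, truth)

print(f"slide: {slide.shape[1]} x {slide.shape[0]} px at {slide.um_per_px:.4f} um/px")
print(f"immunopositive nuclei placed: {truth.achieved_pos}")
print(f"immunonegative nuclei placed: {truth.achieved_neg}")
print(f"tissue area: {truth.masks['tissue'].sum()} px")
# The achieved counts can fall short of the request when rejection sampling
# runs out of room; they are the ground truth all downstream stages use.
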