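"""Choose a window size from emission-distribution overlap.

Uses the polar/brown-bear diversity values. For each candidate window size
the three emission distributions (expected window-score distributions under
AA/AB/BB ancestry) are computed analytically and their maximum pairwise
overlap is measured by integrating min(f_i, f_j). The smallest window with
overlap <= 0.5 is recommended: smaller windows detect shorter ancestry
tracts but separate the states less cleanly.
"""

from ibsancestry import model
from ibsancestry.popstats import DiversityEstimates

div = DiversityEstimates(pi_A=0.000615, pi_B=0.00233, pi_AB=0.003564)
params = model.ModelParams(g=1000, p=0.2, N=3000, a=5, b=5, diversity=div)

print(f"minimum admissible window: {model.minimum_window(div, 5, 5)} bp "
      "(>= 10 expected IBS tracts per panel comparison)")

rec = model.recommend_window_size(params, grid=range(4000, 30_001, 2000))
print("\nwindow_bp  max_pairwise_overlap")
for w, ov in rec.overlaps:
    marker = "  <- recommended" if w == rec.w else ""
    print(f"{w:9d}  {ov:.4f}{marker}")
print(f"\nrecommended window: {rec.w} bp")
print("overlap <= 0.5 means the decoder can distinguish the ancestry states")
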