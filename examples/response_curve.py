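"""Pixel-binned stain-vs-reporter dose–response curves.

Simulates the endpoint antibody-stain channel in two generator modes — one
where the stained protein is driven by the induced construct
(stain = β·mCherry + noise) and a control where it is flat — and fits the
binned response curve (bin width 50 a.u.) in each.
"""

import numpy as np

import optolight as ol
from optolight import ops
from optolight.quantify import binned_response, response_slope
from optolight.simulate import GeneratorConfig, render_field, sample_cells, single_region_field

conditions = {"0": ol.get_condition("0"), "7": ol.get_condition("7")}
for mode, label in (("P2B", "reporter-coupled"), ("P2A", "flat control")):
    gen = GeneratorConfig(seed=3, stain_mode=mode, region_width_um=400.0,
                          region_height_um=300.0, cell_density_per_mm2=6000.0)
    fs = single_region_field(gen, "7", irradiated=True)
    rng = np.random.default_rng(gen.seed)
    cells = sample_cells(gen, fs, rng)
    stack, _ = render_field(cells, fs, gen, np.arange(12) * 120.0, conditions,
                            rng, ("mCherry", "stain"))
    mch = ops.max_project(stack, "mCherry", 11)
    stain = ops.max_project(stack, "stain", 11)
    fit = response_slope(binned_response(mch, stain, bin_size=50.0, min_cluster_area=6))
    print(f"{label:17s}: slope = {fit['slope']:+.3f} "
          f"(95% CI {fit['ci_low']:+.3f} .. {fit['ci_high']:+.3f}), "
          f"r = {fit['pearson_r']:+.3f} over {fit['n_bins']} bins")

print("\nA slope near the configured β (here 2) with r ≈ 1 shows linear "
      "induction of the stained protein by the light-driven construct; the "
      "control's slope CI covering 0 shows stain independent of reporter level.")
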