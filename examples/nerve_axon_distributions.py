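"""Axon calibre distributions and group comparison.

Generates nerve cross-section phantoms for a control group and a group
with a 40% calibre shrink (modelling axonopathy), measures per-axon CSA
from the images, and compares binned size distributions by two-way ANOVA
(group x size bin) with per-bin Šidák-corrected marks.
"""

import numpy as np

from nmquant import axonometry as ax
from nmquant import synthetic_data as sd

edges = np.linspace(0, 40, 11)
dists = []
for group, scale, base_seed in (("control", 1.0, 0), ("treated", 0.6, 50)):
    for section in range(4):
        spec = sd.NervePhantomSpec(n_axons=200, seed=base_seed + section)
        vol, _truth = sd.generate_nerve_phantom(spec)
        table = ax.measure_axons(vol)
        if scale != 1.0:  # calibre shrink applied to the measured table
            table = table.assign(csa_um2=table.csa_um2 * scale)
        dists.append(ax.build_size_distribution(table, edges, group=group))
        if section == 0:
            motor = table.is_motor.sum()
            print(f"{group} section 0: {len(table)} axons ({motor} motor), "
                  f"mean CSA {table.csa_um2.mean():.1f} um^2")

anova, per_bin = ax.compare_distributions(dists)
print("\ntwo-way ANOVA on per-section bin counts:")
print(anova.table[["effect", "F", "p", "stars"]].to_string(index=False))
n_sig = int(per_bin.significant.sum())
print(f"\nbins flagged after Sidak correction: {n_sig}/{len(per_bin)}")
print("A group or group:bin effect indicates the calibre distribution differs "
      "between groups — the signature of axon loss or shrinkage.")
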