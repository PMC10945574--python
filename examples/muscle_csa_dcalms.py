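"""Digital-reslicing fibre CSA analysis on a synthetic muscle section.

Builds a ground-truthed phantom of a 30-µm longitudinal muscle section,
runs the full analysis (fibre-axis estimation, transverse reslicing,
watershed segmentation, CSA measurement, endplate classification) and
compares recovered class means against the analytic truth.
"""

import numpy as np

from nmquant import pipeline
from nmquant import synthetic_data as sd

spec = sd.MusclePhantomSpec(n_fibers=16, seed=4)
vol, truth = sd.generate_muscle_phantom(spec)
print(f"phantom: {spec.n_fibers} fibres, volume shape (c,z,y,x) = {vol.data.shape}, "
      f"voxel {vol.voxel_size_um} um")

result = pipeline.analyze_muscle_volume(vol)
tilt = np.degrees(np.arccos(abs(result.axis[0])))
print(f"estimated fibre axis tilt from section long axis: {tilt:.1f} deg")

print("\nper-class CSA summary (unclipped fibres):")
print(result.summary.to_string(index=False))

matched = pipeline.match_measured_to_truth(result, truth, vol.voxel_size_um)
ok = matched[~matched.measured_clipped & ~matched.true_clipped]
err = 100 * (ok.csa_um2 - ok.true_csa_um2).abs() / ok.true_csa_um2
agree = (ok.measured_class == ok.true_class).mean()
print(f"\n{len(ok)} unclipped fibres matched to truth: "
      f"median CSA error {err.median():.1f}%, class agreement {100*agree:.0f}%")
print("Mean CSA per innervation class tracks the atrophy gradient: denervated "
      "fibres are smallest, graft- and endogenously innervated fibres largest.")
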