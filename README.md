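# nmquant — neuromuscular quantification toolkit

`nmquant` quantifies how well engrafted motor neurons re-innervate and
rescue skeletal muscle, the measurement problem at the heart of optogenetic
cell-replacement therapies for motor neuron disease. It is written for
neuromuscular and regenerative-medicine labs that image thick muscle
sections and nerve cross-sections on a confocal microscope and record
isometric muscle tension, and who need the downstream numbers — fibre
cross-sectional areas by innervation status, endplate innervation
fractions, axon calibre distributions, and contractile metrics — computed
reproducibly rather than by hand in a mix of imaging and chart software.

Four analysis families are covered, each exercised against ground-truthed
synthetic phantoms generated by the package itself:

1. **Digital-reslicing fibre CSA (dCALMS-style).** High-resolution imaging
   of whole muscles is infeasible, so fibre size is measured from 30-µm
   *longitudinal* sections: the confocal stack is treated as a calibrated
   3-D volume, the local fibre axis **v** is estimated by structure-tensor
   eigenanalysis (the eigenvector of the smallest eigenvalue of
   ⟨∇I ∇Iᵀ⟩), a virtual plane transverse to **v** is extracted by
   trilinear interpolation in physical µm coordinates, fibres are
   delineated by marker-controlled watershed, and CSA = pixel count ×
   pixel area. Cutting a fibre at tilt θ from perpendicular inflates area
   by 1/cos θ; measuring on the axis-perpendicular plane removes that bias.
2. **Endplate innervation.** α-bungarotoxin endplates are detected as 3-D
   blobs; each is classified from its overlap with the graft marker
   (GFP/YFP) and the pan-motor marker (ChAT) into graft-full /
   graft-partial / endogenous / denervated, fibres inherit endplate
   classes with precedence graft > endogenous > denervated, and the
   innervated fraction is 100·n_innervated/n_total.
3. **Axon calibre distributions.** Nerve cross-sections (βIII-tubulin =
   all axons, ChAT = motor subset) are segmented per axon; binned CSA
   histograms are compared across groups with a Type-II two-way ANOVA
   (group × size bin) plus per-bin Šidák-corrected marks.
4. **Force-trace physiology.** From stimulus-annotated force recordings:
   maximal tetanic force (baseline-subtracted peak in ≥20 Hz windows),
   fold change, optically- vs electrically-evoked force ratio (%-of-ENS),
   motor unit number estimation by counting twitch-amplitude increments
   along an intensity ramp, and a fatigue index
   1 − (mean peak of last 10 bursts)/(mean peak of first 10 bursts) over a
   250 ms / 20 Hz / 1 s⁻¹ / 180 s burst protocol.

Group statistics mirror the reporting conventions of the field: mean ±
SEM, one-way ANOVA with Tukey's HSD, and two-way ANOVA with the figure
legends' significance bands.

## Worked example

```python
from nmquant import synthetic_data as sd, pipeline

spec = sd.MusclePhantomSpec(n_fibers=16, seed=4)
vol, truth = sd.generate_muscle_phantom(spec)
result = pipeline.analyze_muscle_volume(vol)
print(result.summary.to_string(index=False))
```

prints (see `examples/muscle_csa_dcalms.py` for the full script):

```
innervation_class  mean_csa_um2  sem_csa_um2  n
            graft    729.500000          NaN  1
       endogenous    675.250000          NaN  1
      unconfirmed    645.057692    44.519885 13
```

Each row is one innervation class of muscle fibre: the mean cross-sectional
area in µm² on the axis-perpendicular plane, its standard error (undefined
for a single fibre), and the number of unclipped fibres measured. Matching
the measured fibres back to the phantom's analytic ground truth in the same
run gives a median CSA error of 0.6% and 100% class agreement. The other
examples print endplate counts and the 10.5% worked innervation fraction
(`endplate_innervation.py`), axon-distribution ANOVA tables
(`nerve_axon_distributions.py`), and force metrics — a 6-unit MUNE
recovered exactly and fatigue indices of 0.001 (stable) vs 0.750
(decay-to-25% protocol) (`force_trace_metrics.py`).

A thin CLI mirrors the common shell workflows:

```bash
nmquant phantom muscle --out out/ --seed 1
nmquant dcalms out/muscle_phantom.ome.tif --out results/
nmquant physio trace.csv events.csv
```

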