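# Methods

This note documents the models, conventions and design choices behind
`nmquant`, in the spirit of a methods supplement: what each component
assumes, which parameters matter, and what the synthetic phantoms do and
do not establish about real data.

## Coordinate and calibration conventions

Volumes are `(channel, z, y, x)` arrays with voxel sizes given as
`(x, y, z)` in µm; voxel `(k, j, i)` sits at world position
`(i·vx, j·vy, k·vz)` (voxel-centre convention, 0-based). All geometry —
axis estimation, plane construction, interpolation — is done in physical
µm coordinates, so anisotropic voxels (z steps coarser than xy pixels, the
normal confocal situation) are handled without ever resampling the stack
to isotropic, which would add a second interpolation pass. Calibration is
read from OME metadata or supplied explicitly; it is never silently
assumed to be 1 µm. Intensity dtype is preserved on read; analyses work in
float internally.

## Digital transverse reslicing

**Axis estimation.** The local fibre orientation is the eigenvector of the
smallest eigenvalue of the structure tensor ⟨∇I ∇Iᵀ⟩, with gradients taken
at physical spacing after light (σ = 1 px) smoothing. For a fibre-fill
channel, intensity varies across fibres and hardly along them, so the
direction of least variation is the fibre axis. The sign is fixed to a
positive x component (ties toward +y, then +z). A near-isotropic tensor
(relative eigengap < 10⁻³) raises an error rather than returning a
meaningless direction; the fix is a larger ROI containing fibre
boundaries.

**Reslicing.** A sampling plane is defined by origin, unit normal and an
orthonormal in-plane basis (deterministically derived from the normal:
u = unit projection of +y, v = n × u). Samples are trilinear
(`scipy.ndimage.map_coordinates`, order 1), which is exact on affine
intensity fields — one of the test invariants. Points outside the
voxel-centre hull are marked missing (NaN), never zero-filled, and
missing pixels are excluded from every downstream area measurement;
regions touching them are flagged clipped.

**Oblique-angle policy.** The canonical CSA is measured on the plane
perpendicular to the *local fibre axis*, because a cut at tilt θ inflates
area by 1/cos θ (the package's oblique-geometry test verifies exactly this
scaling on an analytic cylinder at 0°, 15°, 30°). A `cos_correction` mode
instead measures on the fixed section-transverse plane and multiplies by
cos θ of the global axis — provided for comparison with workflows that
reslice along a fixed anatomical axis, and because which of the two the
original semi-automated workflow used is not recorded; axis-perpendicular
is the faithful reading of "transverse".

## Fibre segmentation and CSA

Segmentation is marker-controlled watershed on the inverted smoothed
(σ = 1 px, configurable) fibre channel. In seeded mode the markers are
user-supplied points — the semi-automated workflow. In automated mode,
markers come from the distance transform of the Otsu foreground: within
each foreground component, the region above half the component's maximum
distance is taken as marker blobs and one peak is kept per blob. A plain
distance-peak rule oversegments elongated fibre profiles (their distance
ridge carries several peaks ≥ the separation distance apart); the
blob-per-component rule keeps one marker for a convex elongated profile
while still splitting touching profiles at their waist. Regions below
20 px (default) are discarded as specks. Watershed ids follow image-scan
order, so runs are reproducible.

CSA is pixel count × pixel area — the same definition used for axon
calibres, chosen over fitted-ellipse area for consistency and because it
makes the zero-noise oracle exact up to a boundary-pixel band. Clipped
fibres (touching the image border or missing pixels) are retained in
tables but excluded from group statistics by default: their area is only a
lower bound.

## Endplate detection and innervation classes

Endplates are detected on the Gaussian-smoothed (σ = 0.5 µm) α-BTx channel
by Otsu threshold and 3-D connected components (26-connectivity), kept
within [5, 5000] µm³ by default (the bounds are configurable; whether the
original automated count used size filters is not recorded). Marker
overlap is the fraction of endplate voxels positive in the GFP or ChAT
channel, thresholded by a per-endplate local Otsu over the padded bounding
box (robust to shading). Local Otsu alone will happily "split" pure noise,
so a volume-wide robust background ceiling (P50 + 3·(P84 − P50); the
upper-percentile spread survives the clipping of negatives that defeats a
MAD estimate) gates the local foreground: if the above-threshold mean does
not rise above it, the overlap is zero.

Classification thresholds are T_full = 0.5 and T_min = 0.05 of endplate
voxels: GFP ≥ T_full → graft_full; T_min ≤ GFP < T_full → graft_partial;
otherwise ChAT ≥ T_min → endogenous; else denervated. The source imagery
shows these categories but prints no cut-offs, so both are exposed in the
API and config. "Innervated" fractions count graft_full + graft_partial,
matching the definition used for the published 364/3482 = 10.5% count.
Fibres inherit endplate classes with precedence graft > endogenous >
denervated (a fibre carrying both a de-novo graft junction and a
denervated endplate is graft-innervated); fibres with no endplate in the
imaged volume are *unconfirmed*.

## Axon morphometry and distribution comparison

Axon profiles are segmented like fibres (smoothed Otsu, distance-transform
watershed, area filter 0.5–200 µm² by default). Motor identity is assigned
by centroid containment of a ChAT profile in a βIII profile, which makes
the motor subset a subset of the total by construction. Histograms use
right-open bins with explicit under-/overflow counts; default edges are 20
equal-width bins over the pooled 1st–99th percentile range, recorded in
the output. Group comparison is a Type-II two-way ANOVA (group × size bin)
on per-section bin counts — counts, not proportions, were chosen since the
per-section statistic used originally is unstated — with per-bin
comparisons Šidák-corrected across bins.

## Force-trace metrics

All metrics subtract a baseline (median of the 200 ms before the relevant
stimulus), making them invariant to constant offsets. Trains at ≥ 20 Hz
count as tetanic — the stimulation frequency used for fused contractions
in this preparation. Peak search windows extend 50 ms past the stimulus to
catch the twitch tail.

**MUNE.** Twitch amplitudes along the intensity ramp are extracted after
5 ms boxcar smoothing (so the max statistic is not dominated by
single-sample noise) and scanned in intensity order; an increment is
counted when the amplitude exceeds the running plateau by k·σ_noise
(k = 3, σ from the pre-stimulus baseline). The estimator is intentionally
conservative: as noise approaches the single-unit step it misses units
(monotone non-increasing in noise, verified by simulation), which is the
physiologically safe failure mode. At least 5 stimuli are required.

**Fatigue index.** 1 − mean(last-10 burst peaks)/mean(first-10 burst
peaks), clipped to [0, 1], on the 250 ms / 20 Hz / every 1 s / 180 s burst
protocol (≥ 20 bursts spanning ≥ 170 s required). The first/last-10
definition is this package's choice; the source shows traces but prints no
formula. The decay-to-25% validation phantom sets the fatigue time
constant to τ = 170/ln 4 s so that the *last-10 over first-10* amplitude
ratio is exactly 25%, making the analytic index exactly 0.75.

## Group statistics

Mean ± SEM uses the sample SD (n − 1); SEM is reported as undefined at
n = 1 rather than 0. One-way ANOVA pairs with Tukey's HSD over all C(k,2)
pairs (statsmodels); with two groups it reproduces the two-sample t-test
(F = t², a test invariant). Two-way ANOVA uses Type-II sums of squares,
appropriate for the unbalanced group sizes typical of animal cohorts.
Significance stars follow the figure legends verbatim — *: p ≤ 0.05,
**: p ≤ 0.0002, ***: p ≤ 0.002, ****: p ≤ 0.00002 — which are non-monotone
as printed (the two-star band is stricter than the three-star band); bands
are checked from strictest to loosest. Multiple unpaired t-tests are
uncorrected by default with an optional Šidák flag, since no correction
method was specified for them.

## Synthetic phantoms: what they emulate and what they don't

**Muscle sections.** Straight elliptical cylinders spanning a
30-µm-thick section, quasi-parallel (per-fibre tilt ≤ 5° by default —
fibres in a longitudinal section are locally straight at ROI scale;
curvature is out of scope). Class proportions default to the reference
muscle's observed 62:13:28:117 (graft : endogenous : denervated :
unconfirmed) of 220 fibres, and class CSA means to the reported group
means (922.3, 1018.3, 525.4, 668.8 µm²) with a lognormal spread of
CV = 0.25 — a typical within-class fibre-size dispersion chosen once as
realistic. True CSA is recorded analytically (π·a·b). Eccentricity
defaults to 0.6–0.85 with the minor axis along z so typical fibres fit the
section thickness; fibres whose ellipse crosses the section faces are
flagged clipped, not rejected. Graft-class fibres carry an endplate blob
overlapped by a GFP⁺ (and ChAT⁺) terminal with an axon tube, endogenous
fibres a ChAT-only terminal, denervated fibres a bare endplate, and
unconfirmed fibres none — their endplate lies outside the scanned region.
Default voxel size is (1.0, 0.5, 0.5) µm (x, y, z): acquisition parameters
were not recorded, so defaults are chosen, not copied. The PSF is an
isotropic-in-µm Gaussian (σ given in µm, converted per axis to voxels);
noise is Poisson(scale·signal)/scale + N(0, σ_g), the standard confocal
approximation. One integer seed drives population, geometry and noise
streams independently.

**Nerve sections.** Non-overlapping discs packed by random sequential
adsorption (largest first), calibres drawn from a bimodal lognormal
mixture (means 3 and 20 µm², weights 0.65/0.35) with a 35% motor subset
appearing in both channels. Real axon profiles are not perfectly circular
and fascicles have density gradients; the phantom tests segmentation,
subset logic and distribution statistics, not packing realism.

**Force traces.** A pool of 6 motor units with individual twitch forces
and strictly increasing recruitment thresholds; each pulse adds a
peak-normalised alpha-function twitch (τ = 25 ms), pulses in ≥ 20 Hz
trains are scaled by a fusion gain (3.0, giving a tetanus:twitch ratio
≈ 5 and a maximal fused force ≈ 7.5 g, the reported trained-group
maximum), the drive decays as exp(−t/τ_fatigue), and Gaussian noise is
added. Linear summation ignores the saturating force–frequency
nonlinearity of real muscle; that affects none of the metrics tested,
which compare peaks and increments.

Passing the phantom suites therefore establishes the *computational*
correctness of the pipeline — geometry, segmentation on well-contrasted
images, classification logic, estimator behaviour under controlled noise —
not robustness to real-tissue confounds (uneven staining, fibre branching,
debris, drift), which require real validation data.

## Problem sizes and numerical choices

The test and acceptance suites use: 100 zero-noise fibres (5 volumes × 20)
for the CSA oracle; n ≈ 500/class population draws for parameter recovery
(rasterising 2000 fibres at study voxel sizes is unnecessary for a
population-level check — imaging fidelity is covered by the CSA oracle);
20 seeded draws at the observed group sizes (62 graft vs 28 denervated)
for the atrophy-detection power check; 100 seeded staircases for MUNE; and
full 180-burst traces for fatigue. Watershed ties are broken by
deterministic marker order; Otsu thresholds operate on finite pixels only;
degenerate inputs (blank slices, empty ROIs, saturated designs, n = 1
groups) raise explicit errors or warn-and-return-empty as documented per
function. All randomness flows from integer seeds through
`numpy.random.SeedSequence` spawning, so every result in the README and
the acceptance output is bit-reproducible.

## Known limitations

* Fibre typing (fast/slow), central nucleation, g-ratio and EM-scale axon
  analysis are out of scope.
* The endplate detector merges endplates closer than the blur scale
  (documented resolution limit, covered by a test).
* The automated segmentation modes assume well-contrasted fill/marker
  channels; heavily shaded real sections will need the seeded
  (semi-automated) mode.
* `cos_correction` mode corrects only for the global tilt, not per-fibre
  tilt dispersion; the axis-perpendicular mode is preferred.
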