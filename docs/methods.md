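# Methods

This package re-implements, as a tested library, the quantification chain
used to map the postsynaptic connectivity of *Drosophila* mushroom body
output neurons (MBONs) with the anterograde transsynaptic reporter
trans-Tango: seed-constrained segmentation of the postsynaptic channel,
regional quantification over a 34-region central-brain atlas with per-brain
Z-score normalization, laminar/LAL prevalence mapping, two-channel
co-localized soma counting, open-field trajectory kinematics with group
activity, and stimulus-aligned ΔF/F analysis.  Because the real imaging and
video data live in an external repository, every stage is exercised against
a synthetic-data generator that plants machine-readable ground truth.

## Seed-constrained segmentation

The scientific core is a denoising rule: postsynaptic reporter signal is
trusted only where it is spatially continuous with the presynaptic terminal
field of the driver line, which removes off-target ("extraneous") label
from leaky drivers.  Both channels are binarized, the postsynaptic mask is
decomposed into connected components, and a component is retained iff it
intersects the presynaptic seed mask dilated by a small radius.

Parameters and defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| connectivity | 26 | – | the most permissive 3D adjacency; the original criterion was visual continuity, which 26-connectivity approximates best |
| dilation radius | 1 | voxels | absorbs ≤1 voxel of channel mis-registration without bridging genuine gaps; must be reported with results |
| postsynaptic threshold | Otsu per volume | a.u. | the postsynaptic channel is bimodal (background vs reporter) |
| presynaptic seed threshold | 99th-percentile quantile | a.u. | terminal fields are sparse and bright |

Components touching the volume border are kept (no border suppression).
A constant (e.g. all-zero) postsynaptic channel yields an empty result
rather than a degenerate-histogram error; a genuinely constant volume fed
directly to Otsu binarization is an error.  Otsu ties follow the
binned-histogram argmax of `skimage.filters.threshold_otsu`; the test suite
pins the induced class split, not the reported threshold value, against an
exhaustive between-class-variance scan.

Guarantees verified by tests: exact agreement with an independent
breadth-first flood-fill oracle on random instances for all three
connectivities; monotonicity in the postsynaptic threshold; idempotence;
nesting of retained sets across 6 ⊆ 18 ⊆ 26 connectivity.

## Regional quantification and Z-profiles

Retained voxels are tallied per atlas label (equivalent to multiplying the
binary mask by each of the 34 binary region masks); voxels outside the
atlas are reported separately, never dropped.  The per-brain profile is

    z_r = (s_r − mean_r' s_r') / sd_r' s_r'      (sample sd, n−1)

computed **within one brain across its 34 regions**.  The normalization
axis was genuinely ambiguous in the source description; the within-brain
reading is implemented as the default because the heatmap caption describes
normalization "within each brain" to capture expression level, and the
across-brain alternative is available as `zscore_across_brains`.  A profile
therefore always has mean 0 and sample sd 1 (to 1e-9) and is invariant
under per-brain gain and offset.  Uniform profiles are rejected as
degenerate rather than mapped to zeros.

Per-line heatmap rows are arithmetic means of Z over that line's brains
(the aggregation was unstated; n is reported alongside), and missing
line × region combinations are explicit gaps.  `mode="count"` is the
default signal measure — a binary mask carries no meaningful intensity —
with `mode="intensity"` available for sensitivity analysis.

Laminar (9-layer FSB) and LAL prevalence maps report, per stratum, the
percentage of brains whose retained count reaches a positivity threshold
(default 10 voxels, a free parameter that is a mandatory field of every
output).  Percent-of-brains was chosen over percent-of-signal because the
source figure legends describe percentages "across brains"; the
signal-fraction alternative is a trivial variation on `RegionSignal` sums
and no claim is made about which reproduces the published maps.

## Co-localized soma counting

The published counts were manual and blinded; the automated stand-in is:
Gaussian smoothing (σ = radius/2), local-maximum detection with a minimum
separation (closer maxima merge to the brighter peak), an optional
counting window (one hemibrain, anterior of a stop plane standing in for
the PAL-cluster landmark, which was identified morphologically and is out
of scope to automate), and a **maximum one-to-one matching** between the
TH⁺ and trans-Tango centroid sets under a distance cap (default: the
expected soma radius, i.e. co-localization = overlapping somata).
One-to-one matching, rather than any-overlap, prevents one bright soma
from absorbing several partners; tests verify equality with an exhaustive
matching oracle.  Summaries are mean ± SEM (sample sd/√n); SEM for n = 1
is reported as undefined (NaN), never 0.  Reproducing the published
empirical counts (e.g. 25 ± 0.7 for one line) requires the real volumes
and is out of scope.

## Trajectory kinematics and group activity

Trajectories are planar position series in mm at a fixed frame rate
(33 frames/s in the source assay, 37 mm circular arena).  Features are
computed on a centered moving average of the positions (default window
5 frames ≈ 0.15 s; valid-mode, so the series is trimmed rather than
edge-padded): pathlength as the summed step lengths, velocity as step
length × fps, angular velocity as the absolute wrapped heading change
× fps in deg/s, averaged over frames whose adjacent steps are both
nonzero (headings are undefined on zero-length steps).  Group activity is
the per-frame count of flies whose step exceeds a movement threshold
(default 0.05 mm/frame ≈ 1.7 mm/s), averaged within 10 s bins and then
across replicate arenas; the threshold is a mandatory field of the output.
The per-frame moving-fly definition of "activity counts" is one of two
possible readings and is flagged as such.

Genotype comparisons use one-way fixed-effects ANOVA (sum-of-squares
decomposition computed in-package so that zero within-group variance with
unequal means reports F = +∞, p = 0 instead of a numerical failure) with
Tukey HSD post hoc via `scipy.stats.tukey_hsd`.  Calibration is tested:
the null rejection rate at α = 0.05 over 2000 simulated datasets
(3 groups × 10 standard-normal values) is 0.05 ± 0.01, and a planted 2-sd
between-genotype speed difference is detected reliably.

## Calcium traces

ΔF/F uses F0 = mean fluorescence over a baseline window (default: the 2 s
immediately preceding stimulus onset — the baseline definition was
unstated and is fully parameterized).  Frames flagged shutter-closed
(the imaging shutter protects the PMTs during the 400–500 ms LED pulse)
are missing values throughout: they never enter F0, means, or SEMs, and
masked timepoints are NaN, never 0.  Replicates are aligned so onset maps
to t = 0, trimmed to the common window, and averaged with per-timepoint
SEM over the contributing replicates.  No detrending or bleaching
correction is applied by default (none was described).

## The synthetic-data generator

The generator produces every input with planted truth; all generators are
pure functions of their arguments including the seed.

* **Atlas** — compact blobs packed by rejection-sampled centers
  (minimum pairwise distance scaled to the per-region volume share) with
  Voronoi assignment capped at a radius; 34 regions carry the standard
  central-brain abbreviations (AL … WED).  Grids are (z, y, x), 0-based,
  isotropic 1 µm/voxel by default (no acquisition spacing was stated for
  the registered standard brain; spacing is a free parameter).
* **Tracing brains** — a compact terminal field in the terminal region
  (presynaptic channel, noise-free); postsynaptic neurites grown by biased
  unit-step random walks from terminal voxels toward each target region,
  dilated to a 1-voxel tube radius.  Unit steps make the tube 26-connected
  to the terminal field by construction.  Two deliberate realism choices:
  walks keep a 1-voxel standoff from *foreign* neuropils (real neurite
  bundles travel through inter-neuropil tracts), and the per-region voxel
  budget (weight × `n_neurite_voxels`, default 400, capped at 60 % of the
  region volume) is enforced on the **dilated** tube, since dilation
  inflates small neurite sets proportionally more and would otherwise bias
  allocations toward equality.  Clutter blobs are rejected within a
  Chebyshev distance of 2 from the connected set, which guarantees
  disconnection under 26-connectivity.  Gaussian noise (sd `noise_sigma`)
  is added to the postsynaptic channel and clipped at 0.
* **Soma channels** — spherical top-hats of the soma radius convolved
  with a 1-voxel Gaussian (no PSF model is claimed); co-localized pairs
  share a centroid up to sub-voxel jitter; same-channel packing respects a
  minimum separation with a capacity error on infeasible requests.
* **Trajectories** — stationary, straight, circular, and correlated-walk
  models with specular reflection at the arena wall (wall interaction was
  undescribed).  Series carry round(fps·duration)+1 samples at exact 1/fps
  spacing so the sampled span equals the nominal duration and the closed
  forms (pathlength v·T, angular speed 360°/period) hold exactly; the
  circular truth stores the chord-polygon pathlength, which is what a
  sampled series measures.
* **Calcium** — baseline F0 before onset, shutter-closed flags over the
  stimulus interval, and F0·(1 + a·exp(−(t − t_end)/τ)) afterwards, so the
  first open frame carries ΔF/F exactly a.

What the generator does **not** emulate: optics (PSF, bleaching,
scattering), anatomical neuropil shapes, registration error, tracker
noise, and biological variability in soma brightness.  Passing tests
therefore demonstrate the correctness of the bookkeeping and the
topological rules on data that satisfy the stated model — not performance
on real volumes, where thresholding and continuity judgments are the
dominant error source.

## Problem sizes and numerical choices

Tests and the acceptance script run the volumetric stages on 48³ grids
(34 regions, ~400 tube voxels per brain, 5 clutter blobs, noise sd 10–15
against signal 100), soma counting on 40×72×72 grids (12 vs 10 somata,
7 co-localized, SNR ≈ 10), and oracle sweeps on 16³ masks — sizes chosen
so the whole suite completes in minutes while every planted structure
remains resolvable.  Ranking recovery for planted target regions is
evaluated among non-terminal regions: the retained mask legitimately
overlaps the terminal region itself (postsynaptic neurites are continuous
with the terminals by definition, and MBON feedback onto the mushroom
body is a real feature of the circuit), so the terminal region's own rank
is uninformative about clutter rejection.

Known limitations: the packaged driver-line registry marks rows inferred
from the running text (rather than transcribed from the resource table)
with `provenance=inferred`; the NRRD codec is deliberately minimal
(attached header, raw/gzip, little-endian); and no statistical testing of
region enrichment across lines is provided.
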