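# Methods

This note documents the models implemented in `closecontact`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that were genuinely open.

## Image formation and the synthetic generator

A scene is a physical description of the bilayer-proximal zone: a uniform
glycocalyx layer of intensity 100 (expected photons per camera pixel) into
which circular close contacts are punched, each reducing the local
intensity to `background · (1 − exclusion_depth)`. Rendering follows the
imaging chain of a TIRF microscope with an EMCCD:

1. **Rasterization** on a fine grid that subdivides each 107 nm camera
   pixel into `supersample × supersample` subpixels (default 20, i.e.
   5.35 nm). An integer subdivision makes the later binning exact; at the
   default the central-pixel value of a 400 nm test disc matches a 1 nm
   grid to better than 0.5% (tested).
2. **PSF blur** with a Gaussian of σ = 131 nm, the width fitted to a
   bead-measured PSF of a NA 1.49 TIRF objective. The kernel is normalized
   and boundaries are reflective, so constants are preserved and total
   intensity is conserved; reflective boundaries avoid dark rims on the
   small simulated fields.
3. **Binning** to the camera grid by block averaging.
4. **EMCCD noise**: photon counts are Poisson; the electron-multiplying
   register is modeled as a Gamma distribution with shape = photon count
   and scale = gain (250 ADU/photon), which yields the characteristic
   excess-noise factor of 2; Gaussian read noise and a constant digitizer
   offset are added. Per-pixel mean is `gain·μ + offset` and variance
   `2·gain²·μ + read²` — the photon-transfer test in the suite verifies the
   slope within 10%.

The membrane and calcium channels are rendered directly at camera
resolution (footprint discs and painted per-cell traces, blurred with the
PSF); the sub-pixel accuracy of the fine grid matters only for the
glycocalyx channel, whose sub-diffraction dips carry the science. Emitter
channels paint integrated-Gaussian spots; diffusing emitters take Brownian
substeps within each frame (default 10) so that long exposures motion-blur
them, mimicking the strategy of imaging single bound ligands at 200 ms
exposure.

**What the generator does not emulate:** TIRF evanescent-field depth,
optical aberrations, photobleaching, bilayer inhomogeneities, cell-shape
irregularity (footprints are discs), and calcium-trace kinetics beyond
step-like rises. Passing tests therefore demonstrate correctness of the
measurement machinery under controlled conditions, not robustness to every
artifact of real data.

## Close-contact segmentation

The glycocalyx channel is flat-field corrected (division by the
mean-normalized time-sum of a cell-free stack), smoothed with a temporal
running mean (5 frames) and a spatial Gaussian (σ = 1 px), and its
Laplacian taken — overall a LoG band-pass that responds at the edges of
dark holes and is positive at their centres. Thresholds are expressed in
units of the statistics of pixels *outside* segmented cell areas ("notCZ"),
recomputed per frame so drifting illumination cannot bias them:

- **hysteresis threshold** on the LoG at `h_low = 3` / `h_high = 5` notCZ
  standard deviations — the primary detector, edge-based so that weakly
  excluded contacts are not under-segmented;
- **late-contact threshold**: the edge-enhanced image (Gaussian − LoG,
  which deepens holes) below `mean − h2·std` (`h2 = 2`) of the notCZ
  Gaussian image, morphologically eroded (disk of radius 1, the smallest
  symmetric element) — recovers large, fully formed contacts whose flat
  interior the LoG misses.

Detections smaller than 2 px are discarded, detections are connected over
time by temporal overlap (3-D labeling), and labels spanning fewer than
`min_persistence_frames = 5` frames are dropped. The persistence filter is
the temporal arm of the noise filtering: a noise excursion entering the
5-frame rolling mean can masquerade as a contact for up to one window, so
requiring persistence of at least one full window removes it, while
genuine contacts persist for tens of frames. With these defaults the
pipeline produces zero false contacts on 40 simulated null videos while
detecting 250 nm contacts at 40% exclusion in ~90% of noise realizations;
the measured detectability threshold for 250 nm contacts is 30–40%
exclusion depending on the noise seed. All thresholds are user-settable in
`SegmentationConfig` because contact size and contrast vary between bilayer
compositions; the defaults were calibrated on simulated fixtures.

Segmentation is pixel-based, so the smallest reportable contact area is one
camera pixel — 0.011 μm² at 107 nm pixels. Reported areas of
sub-diffraction contacts are blurred upward by the PSF and shallow contacts
are thresholded smaller; the edge-based LoG minimizes (but does not remove)
the coupling between measured area and exclusion depth, and the simulation
module exists precisely to quantify this bias.

## Cell footprints and labeling

The membrane channel accumulates dye in the bilayer over time; a linear
background (fitted against time on the 20% dimmest pixels per frame, which
approximate cell-free bilayer) is subtracted, keeping the first-frame
level. Each frame is DoG-filtered (σ = 1 px vs half the cell radius) and
thresholded with the union of a global threshold (default: median + 4
MAD-based SDs, robust to the cells' own bright pixels) and a per-frame Otsu
threshold, which helps with dim, spread cells. The Otsu contribution is
rejected when it would select more than 40% of the frame: pure-noise frames
lack the bimodality Otsu assumes and would otherwise segment half the
field. Holes are filled (the DoG responds at edges) and components below
20 μm² removed.

Labels are assigned by a watershed over *(t, y, x)*: adhered cells barely
move, so their masks overlap in consecutive frames and flood from a single
seed placed on the last frame (local maxima of the DoG or of the mask's
distance transform, separated by at least one cell radius, default 5 μm).
Seeds can be overridden from a file — the file-based replacement for
interactive seed editing. Disconnected mask components are attached to the
nearest label within twice the cell radius (Euclidean in pixels and frames,
preferring earlier frames), otherwise dropped. Watershed ties are resolved
deterministically; segmenting the same video twice gives identical labels.

## Calcium analysis

Per-cell traces (bulk assay: tracked local maxima; contact assay: mean in a
5 μm-radius circle at the cell centroid, missing centroids linearly
interpolated) are normalized to a baseline defined as the mean of the
lowest decile of intensities within the first 60 s of the track — a
deterministic reading of "lowest 10%, typically from the first 30–60 s";
the window is configurable. Triggering requires a rising crossing of 3×
baseline sustained for ≥ 10 s, on the smoothed trace by default (a flag
switches to the raw normalized trace). Cells appearing to trigger within
40 s of track start are excluded from population denominators: these are
settling, pre-activated cells whose bright signal fades. Adhesion is the
first time from which the frame-to-frame speed stays below 0.2 μm/s to the
track end.

Population cumulative curves are fitted with a logistic in time whose lower
asymptote is 0 and whose upper asymptote is fixed — 100% for adhesion, 80%
for signaling, the empirical ceiling of cells that respond to direct TCR
cross-linking. The exact sigmoid family is not prescribed anywhere; the
logistic is the simplest symmetric choice. `time_to_50` is the fitted
midpoint (where the curve reaches half its plateau) and is reported as
undefined when the raw fraction never reaches half the plateau.

## Events, stages, and contact features

Five per-cell events delimit the interaction: first membrane signal
(searching), first close contact (scanning), calcium release (spreading),
and maximum footprint area (synapsing), with adhesion recorded alongside.
The footprint-area trace is smoothed with a 5-frame mean filter before
taking its maximum. Stage intervals are half-open `[event, next_event)` so
every frame has exactly one stage; stages III/IV require triggering;
out-of-order events (e.g. a trigger before the first contact) are clipped
to the previous boundary with a warning.

`exclusion_10 = 1 − p10(I_inside)/mean(I_outline)` uses the 10th percentile
of flat-field-corrected intensities inside the contact (linear
interpolation between order statistics — the most common percentile
convention, pinned for reproducibility) over the mean on the one-pixel-wide
outline of the owning cell's membrane mask. The alternative outside
definition (10 px dilated rings, refined against neighbouring contacts) is
available in `regions` and is the one used for enrichment and CD45
exclusion, where rings are additionally clipped to the cell mask when the
protein sits on the cell — otherwise the membrane edge fakes a signal drop.

Quality control excludes cells touching the field edge before triggering
or, for non-triggering cells, within 300 s (configurable) of their first
contact.

## Single-molecule counting

Frames are averaged over a 5-frame running window and blurred (σ = 1 px);
local maxima (8-connected) above a calibrated threshold are counted, and
credited to a contact when they fall inside its segmented area. The
threshold is calibrated on a pre-cell stack as the smallest value admitting
fewer than 2 detections — with strictly-above detection this is exactly the
second-largest local maximum of the processed stack, making the
calibration deterministic. The signaling timepoint is the maximum of the
calcium-trace gradient (central differences on the smoothed trace).

## Statistics

- **Kaplan–Meier / log-rank** — delegated to `lifelines` (with
  exponential-Greenwood log(−log) confidence intervals); tests verify
  against a from-scratch product-limit computation and a 10,000-draw
  permutation oracle.
- **Dose-response** — 4PL `bottom + (top − bottom)/(1 + (EC50/dose)^hill)`
  fitted by unweighted least squares on log10-dose (no weighting scheme is
  prescribed); constrained parameters (typically the bottom, pinned to the
  non-cognate-ligand response) are honoured exactly, and zero-dose points
  are carried by the constrained bottom.
- **FCS density** — `G(τ) = G0·GD(τ)·GT(τ) + Off` with the 2-D diffusion
  form `GD = 1/(1 + τ/τD)` (appropriate for a supported bilayer; a 3-D
  form is available for solution calibration) and an optional triplet term.
  `N = 1/G0`, spot diameter `d = √(8 ln2 · D·τD)` with D the literature
  diffusion coefficient of the calibration dye (a config input, not a
  constant), density `N/(π(d/2)²)`. Standard curves for sub-resolution
  densities are least-squares lines through the origin.
- **Surface area** — per z-slice, the Otsu-thresholded outer membrane
  contour's perimeter (Crofton estimator, which corrects pixel-counting
  staircase bias) × 0.2 μm slice depth, summed. **Known limitation:** the
  slab model ignores surface slope, so strongly curved caps are
  underestimated — for a sphere the method converges to π²r², 21.5% below
  the true 4πr² (a cylinder is exact). Real measurements on wrinkled cells
  are dominated by in-plane perimeter, where the bias is smaller, but
  absolute areas of smooth round cells should be treated as lower bounds.

## Problem sizes and determinism

Simulated test fixtures use fields of 3–16 μm, 10–60 frames, and 8–40 noise
realizations per condition — small enough for the suite to run in well
under a minute per module while leaving every statistical check
comfortable margins. All randomness flows through seeded
`numpy.random.Generator` instances; seeded runs are bit-reproducible, and
the segmentation itself is fully deterministic.
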