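# Methods

This note documents the models, conventions and numerical choices behind
`toroquant`: what the synthetic generator simulates, how each measurement is
defined, which parameters matter, and what the validation on synthetic data
does and does not establish about real microscopy.

## Imaging model and calibration

All calculations assume widefield fluorescence imaging of laterally widened
*E. coli* at 0.065 µm/pixel with a lateral PSF of 350 nm FWHM (Gaussian
approximation, σ ≈ 149 nm ≈ 2.29 px) and an axial FWHM of 800 nm; z-stacks
are reduced by maximum projection before 2-D analysis. These constants live
in `ImagingConfig` and are overridable per run. The arm-asymmetry ROI is a
disk of 20 px diameter, i.e. exactly 1.3 µm at the default pixel size.

Because the pipeline's shape and density readouts (tube width, compaction)
presuppose restored images — such stacks are routinely deconvolved before
quantification — fluorescence channels pass through Richardson–Lucy
deconvolution (maximum-likelihood under Poisson noise) with the known
Gaussian PSF, 10 iterations by default, before any thresholding or
measurement. Ten iterations recover tube widths and compaction ratios to
within a few percent on calibration renders while leaving noise
amplification negligible at the simulated photon budgets; the step can be
disabled (`deconvolve=False`), in which case apparent, PSF-convolved widths
are measured (the generator reports both `true_fwhm_um` and
`true_apparent_fwhm_um = 2√(2 ln 2)·√(σ_tube² + σ_PSF²)` for that purpose).

## Synthetic cells

The generator renders a chromosome as a Gaussian-profile tube (cross-section
σ_tube) along a parametric curve: a circle for toroids, two tangent circles
for figure-eight dimers (catenated sisters), a straight bar for open
nucleoids. Channel totals are exact before noise: each noiseless field is
normalized to its specified photon budget. The MukB channel occupies an
angular arc of the ring; DNA density inside that arc is multiplied by the
compaction factor and the whole field renormalized, so compaction is
testable without breaking conservation. ori/ter foci are point sources
rendered directly at the PSF width. Phase contrast is a dark cell footprint
on a bright background with an edge halo — sufficient for threshold-based
cell masking, not an optical model.

Arm imbalance is generative: the two halves of the MukB arc (split by the
axis from the ring centre through ori) are weighted (1 ± b), which makes the
asymmetricity statistic of the noiseless field equal b exactly — machine
precision when the axis is grid-aligned, which the self-consistency tests
exploit. DNA receives its own imbalance the same way but only within a
0.65 µm radius of ori: a global half-ring weighting would displace the
chromosome centre of mass sideways and tilt the measured ori–CoM axis by
~10°, contaminating both recoveries; the local form models what the
statistic actually sees (local density fluctuation near ori) while keeping
the CoM central.

Noise is Poisson on (blurred signal + 10 photons/px background), optionally
plus Gaussian read noise. Reproducibility: every cell draws from a stream
keyed by (population seed, cell index) and the background from a dedicated
stream — Poisson additivity makes the composite field an exact Poisson
sample — so populations are bit-identical across reruns and robust to
re-ordering.

### Strain presets (study conditions)

| preset | contour (µm) | σ_tube (µm) | compaction | MukB bias b | DNA bias | P(arc over ter) |
|---|---|---|---|---|---|---|
| wildtype | 4.5 | 0.187 | 1.8 | 0.33 | 0.27 | 0.04 |
| delta_matp | 3.5 | 0.191 | 1.75 | 0.49 | 0.32 | 0.11 |
| mukb_eq | 3.8 | 0.174 | 1.2 | 0.26 | 0.25 | 0.20 |

The MukB arc half-width defaults to 35°, chosen so the condensin domain
(arc ≈ 0.87 µm) is well resolved at the 350 nm PSF while remaining
sub-micron, consistent with reported sub-micron cluster Feret diameters.
Photon budgets (DNA 2×10⁵, MukB 8×10⁴, 8×10³ per focus) give peak-pixel
SNR ≈ 15–20, a realistic regime for live-cell widefield imaging; they are
stated in the fixture manifest. "Arc over ter" relocates the MukB arc to
the terminus focus with the per-cell probabilities above, emulating the
MatP-dependent displacement phenotypes.

## Measurements

**Segmentation.** Cells: Otsu on the inverted phase image, hole filling,
small-object removal, labels in raster order. QC: masks dilated by 2 px that
touch another cell are flagged `touching_neighbor` (automated stand-in for
manual curation of too-close neighbours); border-touching masks
`border_clipped`. Channels: Gaussian smoothing (σ = 1 px), background = the
median of in-cell pixels below their 25th percentile (robust to large
bright structures), Otsu threshold on the in-cell residual; the numeric
threshold is recorded per cell. On calibration renders the resulting masks
track the half-maximum contour of the underlying tube (IoU ≥ 0.8).

**Backbone and topology.** The DNA mask (holes < 25 px filled, so shot
noise cannot mint loops while the toroid bore survives) is thinned to a
skeleton; the pixel graph drops diagonal edges bridged by a shared
4-neighbour so no spurious 3-cycles arise; terminal branches shorter than
5 px are pruned. Cycles shorter than 10 px of polyline length are ignored.
One cycle, no branch points → toroid; two cycles sharing a node →
figure-eight; no cycle → open; anything else → complex. Paths are ordered
from the topmost-then-leftmost pixel, clockwise in image coordinates, so
left/right side assignments reproduce across runs.

**Contour length** sums graph edges (1 px straight, √2 px diagonal) over
all loops/paths — for non-toroidal nucleoids this sums the pieces, and the
topology class is reported alongside so such cells can be filtered. Chain
codes overestimate smooth curves by a few percent at these radii
(discretization), which the ±5 % recovery band absorbs.

**Width** is the mean FWHM of intensity profiles sampled every 3 px of arc,
perpendicular to the local tangent, 15 px long with linear interpolation;
the half-maximum is taken above the cell's background level and crossings
are located by linear interpolation. Stations whose profile leaves the
image are skipped and counted; fewer than 10 valid stations flags the cell
instead of returning a value.

**Colocalization** follows the intensity-overlap definition: the percentage
of total in-cell (background-subtracted) DNA intensity inside the MukB
mask. Both directions are computed and stored — DNA-in-MukB as the primary
readout and MukB-in-DNA as the converse — since either convention appears
in practice. Focus–mask colocalization is binary: a focus counts as
overlapping when a disk of one PSF FWHM diameter around its sub-pixel
centre intersects the mask by ≥ 1 px.

**Compaction** uses the pixel-wise partition of the DNA mask by the MukB
mask and compares per-area mean densities. Equal densities give exactly 1;
an empty partition is flagged undefined rather than guessed. The generator
truth for the overlap fraction is defined on the half-maximum footprint of
the noiseless, unblurred MukB tube.

**Asymmetricity** centres the ROI on the brightest ori focus (cells with
several ori foci are additionally flagged `multi_ori`), draws the oriented
axis from the DNA centre of mass through that focus, and sums intensity on
the clockwise and anticlockwise sides. Pixels exactly on the axis split
50/50 by default (an exclude-axis mode exists). Side labels are geometric:
imaging alone cannot assign them to the genomic left/right arms.

**Ploidy.** The reference statistic for content normalization is the
median over 1-ori/1-ter cells — median rather than mean so a single
mis-segmented reference cell cannot shift the scale; uniform gain changes
cancel through it. Multiplicity thresholds (1.5, 3.0) are midpoints between
integer chromosome equivalents and are configurable.

**Statistics.** Single-factor ANOVA by explicit between/within
sum-of-squares with p from the F distribution (cross-checked in tests
against an independent library implementation and the two-group F = t²
identity). Star convention: ns > 0.05 ≥ * > 0.01 ≥ ** > 0.001 ≥ *** >
0.0001 ≥ ****; boundary p-values go to the more significant bin (strict
inequalities would leave them unassigned). Summaries report mean ± sd,
mean ± sem or median per metric following each metric's customary
convention, recorded in the summary table.

**Genome window.** Peak membership is by interval midpoint (with circular
wrap); upstream = increasing coordinate from ori, downstream = decreasing;
a midpoint exactly at ori counts for neither. The relative excess is
100·(n_up − n_down)/n_down. Genome length and ori coordinate must be given
explicitly — there is no default genome build.

## Validation scope

Recovery tests run the full pipeline on fixed-seed synthetic populations
(50 cells per condition, ~150×150–800×800 px fields) and require: MukB arm
bias 0.33 recovered within ±0.05 (population median), DNA-in-MukB fraction
within ±2 points, compaction 1.8 within ±0.15 and 1.2 within ±0.1, contour
length within ±5 %, width within ±10 %, exact focus counts beyond 3 PSF σ
separation, and topology classification ≥ 95 % correct at fixture SNR
(100 % noiseless). Population sizes were chosen so these checks complete in
seconds while sampling error stays well inside the tolerance bands.

The generator emulates the statistical structure the analysis assumes —
tube-like chromosomes with angular condensin domains, multiplicative
compaction, diffraction-limited foci, Poisson optics. It does not emulate
out-of-focus haze from the ~1 µm cell height, spectral bleed-through,
uneven illumination, photobleaching, or genuinely irregular nucleoid
shapes. Passing recovery tests therefore demonstrates the correctness and
calibration of the measurement code under controlled conditions, not the
biological accuracy of any particular threshold on real data; on real
images the QC flags and recorded thresholds are the audit trail.

Known limitations: chain-code contour lengths carry a small positive bias;
Otsu thresholds depend on the in-cell background fraction and can shift
masks when cells are segmented much larger than the nucleoid;
deconvolution entangles the DNA arm bias with mask asymmetry at very high
generative biases (≥ 0.5), which slightly deflates compaction recovery when
the condensin arc sits away from the biased region; and the ploidy
classifier assumes focus detection saturates below ~4 foci per channel.
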