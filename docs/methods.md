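# Methods

This note documents the models, the synthetic-data design and the numerical
choices behind `lungtarget`, in the spirit of a package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## The measurement model

An MSI dataset is a set of pixels on an integer grid, each with a spectrum
(m/z, intensity ≥ 0) acquired in positive mode over 300–1000 Da. Continuous
mode shares one m/z axis across pixels; processed mode stores per-pixel axes.
I/O is imzML 1.1 + ibd via pyimzml, with m/z and intensities written as
float64 so write→read is bit-exact; the ibd UUID and SHA-1 declared in the
XML are verified on read. Coordinates follow the imzML convention (1-based,
x rightward, y downward); the single place this maps to 0-based row/col grids
is `MSIDataset.pixel_rows_cols`.

**TIC normalization.** Each retained pixel is scaled so its total ion count
equals a common target — by default the mean raw TIC, which preserves the
global intensity scale for display (a target of 1 gives compositional
spectra). Pixels with zero TIC carry no information and are dropped with a
logged count rather than imputed. Normalization is idempotent, conserves
within-pixel peak ratios to machine precision and removes a multiplicative
per-pixel drift exactly — the test suite checks all three algebraically.

**Ion images.** The intensity in a *closed* window [m₀ − t, m₀ + t] is
reduced (sum by default) per pixel. An acquired pixel with no peaks in the
window is 0 (a measurement of absence); a never-acquired grid cell is NaN
(missing), and all downstream statistics consume only finite, masked pixels.
Default window half-width is 0.1 Da (TOF-like); ppm mode is available for
Orbitrap-like data. The default analyte table uses monoisotopic [M+H]⁺
values — salmeterol 416.2795, d3-salmeterol +3.0188 (3 × (²H − ¹H)), Heme b
616.1773, PC(32:0) 734.5694, PC(36:4) 782.5694. These are assumptions, not
calibrations: adduct species for the phospholipid markers are not uniquely
implied by nominal masses, so the table is fully overridable from CSV/YAML.

**Tissue mask.** `tic_threshold` marks pixels whose raw TIC exceeds the
q-quantile of the TIC distribution (default q = 0.40, suited to framed
sections where tissue occupies roughly 60 % of the field — as in the default
phantom; the parameter must be adapted to other framings). Because the
off-tissue and on-tissue TIC distributions are separated by a wide gap, any
quantile landing in the gap yields the same mask; the choice of q only
matters near the off-tissue fraction. `marker_union` offers a
marker-threshold alternative.

## Segmentation

Histological compartments differ in molecular composition, so unsupervised
clustering of pixel spectra reproduces histology. The chain is:

1. **Features**: spectra binned at 0.5 Da over the acquired range; bins empty
   everywhere are dropped (they would only dilute correlation distances).
2. **Weak denoising**: per-channel Gaussian smoothing with σ = 1 px, masked
   and renormalized so off-mask pixels neither contribute nor receive signal.
   σ = 1 is the mildest standard choice; σ = 0 disables it.
3. **Bisecting k-means under correlation distance** d(u, v) = 1 − ρ(u, v),
   which clusters by spectral *shape* and is insensitive to residual
   brightness differences. Greedy top-down: the segment with the largest
   within-segment sum of distances to its centroid (ties: larger pixel count,
   then lower label id) is split by a 2-means (centroid = arithmetic mean of
   member spectra, distance = correlation distance to it) until k segments
   exist. Each 2-means runs `n_restarts` (default 4) random initializations
   and keeps the best objective; the second seed of each restart is sampled
   with probability proportional to squared distance from the first
   (k-means++-style), which reliably discovers small but spectrally extreme
   populations such as blood vessels. Empty clusters are re-seeded at the
   farthest point; convergence is assignment stability (cap 100 iterations).
   Zero-variance (flat) spectra get distance 1 to everything and are logged.
   Everything is deterministic given the seed.

   "Correlation distance" here is 1 − Pearson between pixel spectra.
   Székely's distance-correlation statistic is a different quantity; 1 −
   Pearson is the reading consistent with standard MSI software parameter
   naming, and the one implemented.
4. **ROI naming by marker enrichment**: highest mean PC(32:0) → alveolar;
   among enriched PC(36:4) candidates the first ring-shaped segment
   (perimeter²/area ≥ 25) → epithelium; the adjacent segment with the
   next-highest PC(36:4) → sub-epithelium; highest Heme b → vessel; lowest
   TIC → lumen/background; leftovers unassigned. Two robustness guards:
   segments below 0.5 % of the labelled area are excluded from the rankings
   (a noise scrap can otherwise narrowly win a mean contest), and the ring
   test is restricted to segments with ≥ 50 % of the top candidate's
   bronchiolar marker (a background frame also has huge perimeter²/area and
   must never be named epithelium). All thresholds are arguments.

k defaults to 6 for the lung phantom — three quantified compartments plus
lumen, vessel and off-tissue background. k is a user choice, not a derived
quantity.

## Targeting factors

With plasma concentration P_r per route r, the normalized exposure of
compartment c is E_r(c) = mean pixel intensity of the route-r drug channel in
c divided by P_r, and the targeting factor TF(c) = E_inhaled(c)/E_iv(c). The
dual-isotope design makes this ratio internal to one section: tissue,
preparation and detection cancel. TF is invariant to common rescaling of
both channels (e.g. the TIC target); scaling one route's plasma by a factor
scales its TFs inversely — both are asserted as exact algebraic tests.

Replicate aggregation computes TF per section and averages (default),
preserving biological-replicate variance; pooling intensities first is
available. A section-level factor uses the whole tissue mask with no
regional breakdown. No isotope-effect correction is applied between the two
isotopologues by default; a configurable response factor on the IV channel
exists (default 1.0). The kinetic profile is the whole-section mean of one
channel across post-dose times, optionally overlaid (least-squares rescaled)
on a companion concentration series with the Pearson r between the series
reported.

Statistical conventions: RSD uses the sample (n−1) standard deviation on
TIC-normalized intensities within the tissue mask (off-tissue zeros would
inflate it arbitrarily); correlations are computed on the intersection of
both images' finite masks and reported in percent, rounded only for display;
the group test is the pooled-variance two-sided Student t (Welch behind a
flag).

## The synthetic lung

The generator emulates the *statistical* structure of a dual-dosed rat lung
section, not its anatomy: a 200 × 200 px elliptical section at 10 µm
(≈ 2 × 2 mm), an alveolar field with 1.5 % porosity holes, five circular
airways (lumen radius 6–8 px + 3 px epithelium + 4 px sub-epithelium rings),
six vessels, framed by off-tissue background. Fourteen m/z channels: the two
drug channels, the three histology markers, six structural lipids and three
matrix ions. Each compartment has a distinct mean spectrum; real
compartments differ across hundreds of lipids, and the phantom's stronger
per-channel contrasts stand in for that spectral richness — the property
that makes correlation-distance segmentation work on real tissue.

**Ground truth by construction.** The inhaled-drug means in the three
quantified compartments are *derived* from the requested targeting factors
(5 / 31 / 45) via inhaled = TF × iv × P_inh/P_iv, never set independently, so
every scenario's true TF is exact. Plasma concentrations (inhaled 2,
IV 8 nmol/L) are invented, physiologically ordered values (inhalation gives
lower systemic exposure); they are scenario design, not data. IV drug means
follow perfusion (alveolar 120 > sub-epithelium 60 > epithelium 35, vessel
100 — below alveolar tissue at 30 min, when tissue accumulation exceeds
blood); inhaled means are bronchiolar-enriched by construction.

**Noise model**, in an order chosen so TIC normalization removes exactly and
only the drift term: (1) mean-one log-normal per-pixel biological
variability, per channel class (inhaled drug σ = 0.7 — patchy deposition; IV
drug 0.25; markers/lipids 0.2; matrix 0.15); (2) mean-one log-normal
per-airway deposition multipliers (σ = 0.15) on the inhaled channel;
(3) Poisson counting noise; (4) mean-one log-normal per-pixel TIC drift
(σ = 0.3) multiplying the whole spectrum. All factors are mean-one so raw
channel expectations equal the scenario table. Off-tissue pixels carry only
sparse matrix signal; lumens a distinct mucus/surfactant-like low profile.

What the phantom does **not** model: branching airway trees, isotope
envelopes and adduct chemistry, spatially correlated deposition patches
(inhaled patchiness is white per-pixel noise, which spatial denoising
attenuates; real deposition blobs would survive smoothing), matrix
suppression gradients, mass-calibration drift and 3-D structure. Passing
tests therefore demonstrate correctness of the *analysis* under a plausible
noise model, not performance on any particular instrument's data.

## Problem sizes and numerical choices

Default analyses run on 200 × 200 px sections (40 000 spectra); the suite's
multi-seed checks use 10–40 seeds and 1–3 replicate sections per seed, sizes
at which one full section simulates in ~0.2 s and segments in ~1 s on one
CPU. Recovery accuracy at these sizes: across 10 seeds × 3 replicates the
median relative error of pipeline-recovered TFs is below 15 % per
compartment (the acceptance suite computes it each run). Two known,
understood biases at the default noise level: the epithelium TF reads a few
percent high because lumen boundary pixels with zero IV signal dilute the
epithelium ROI's IV mean, and the sub-epithelium TF reads a few percent low
through the ratio bias of TIC normalization when one channel (inhaled,
σ = 0.7) is a large noisy share of its own pixel TIC. Both shrink with
noise and vanish with ground-truth ROIs, where noiseless recovery is exact
to 1e-12.

Degenerate inputs are first-class: empty datasets, all-zero pixels, windows
outside the acquired range, constant images in a correlation, single-pixel
segments selected for splitting, unplaceable geometry and missing/corrupt
ibd companions all raise descriptive errors (tested). Determinism: every
stochastic step takes a seed; pipeline runs with equal config + seed produce
byte-identical CSV/JSON artifacts, and the manifest records seed, config
hash and package versions.
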