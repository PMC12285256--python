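# Methods

This note documents the models behind `dropscreen`, the parameter choices
that matter, what the synthetic-data generators do and do not emulate, and
the numerical conventions.

## Occupancy measurement

A droplet micrograph is modelled as a bright oil background, a dark
oil–water interface ring at the droplet boundary, and an aqueous lumen at
background brightness containing dark cells. Occupancy is

    A_occup(%) = (A_droplet − A_ex) / A_droplet × 100

with `A_droplet` the lumen area in pixels and `A_ex` the non-cell area
within it.

Pipeline:

1. **Detection.** Canny edges (σ = 1.5) followed by a circular Hough
   transform over a radius window of the expected droplet radius ± 20 %
   (expected radius from the 120 µm diameter prior and the pixel scale).
   The largest radius among near-best accumulator peaks is taken, so the
   outer interface edge wins over the inner one. Frames with no edges, no
   circle above an accumulator floor of 0.25, or a circle extending past
   the frame edge raise a detection error — a partial droplet has no valid
   occupancy. A user-supplied geometry (manual delineation) bypasses this
   step.
2. **Lumen extraction.** Background level and noise are estimated from
   pixels outside 1.1× the detected radius. Dark pixels (below
   `bg − 0.3·(bg − p0.5)`, with `p0.5` the 0.5th percentile inside the
   circle) are labelled; the component with the largest filled area is the
   interface ring, and the lumen is its filled interior minus the ring
   itself. `A_droplet` is the lumen pixel count. If cells merge with the
   ring (near-full droplets leave no open lumen), the filled disk eroded by
   the nominal ring width (2 px) is used instead. Whether the interface
   ring belongs to the droplet area is an imaging convention; we measure
   the lumen only and exclude the ring.
3. **Segmentation.** Otsu's threshold on the lumen pixels separates cells
   from medium (cells darker by default; a polarity flag inverts). A
   morphological opening (radius 1 px, switchable) suppresses salt noise in
   the cell mask. A near-uniform lumen — Otsu class separation below
   `max(6σ_bg, 0.1·(bg − p0.5))` — is degenerate: it is reported as
   cell-free when its level is statistically indistinguishable from the
   background (within 3σ_bg), and as fully occupied when uniformly dark.

All intensity decisions are quantile/Otsu-based, so occupancy is invariant
under global affine rescaling of the image (outside the degenerate branch,
which compares levels to the background estimated from the same image and
is therefore also affine-equivariant).

Replicate droplets are summarized as mean ± SD (ddof = 1), matching the
convention of reporting growth-curve points as the SD over five droplets.

## Occupancy → OD600 calibration

OD600 is regressed on occupancy by ordinary least squares (R² = 1 −
RSS/TSS). Regression direction: OD600 as response, because the screen's
use case converts a *measured* occupancy into an OD estimate. One curve
should be fitted per species: cell size and contrast differ between
organisms, so occupancy-per-OD is species-specific. Queries outside the
fitted occupancy range are flagged as extrapolation rather than refused.

## Growth model

Growth is described by the Baranyi–Roberts model on the log-density scale
y(t) = ln OD(t):

    y(t) = y0 + µ·A(t) − ln(1 + (e^{µ·A(t)} − 1) / e^{ymax − y0})
    A(t) = t + (1/µ)·ln(e^{−µt} + e^{−h0} − e^{−µt−h0})

Parameters: `µ` (maximum specific growth rate, h⁻¹), `y0`/`ymax` (log
initial and carrying densities), and `h0` (dimensionless physiological
state of the inoculum). Lag time is the standard identity `lag = h0/µ`.
The implementation evaluates the braking term in log space
(`ln(1 − e^{−d} + e^{m−d})` via `logaddexp`) so large `µ·A` cannot
overflow; it matches direct numerical integration of the Baranyi ODE
system to better than 10⁻⁶.

Fitting is nonlinear least squares on ln OD (equal weights, which
corresponds to constant-CV measurement noise), with multi-start initial
values from a log-linear segment scan: `µ` from the steepest three-point
slope, lag candidates at {0, 0.5, 1, 1.5}× the tangent-intercept estimate.
Bounds keep `µ ≥ 0`, `h0 ≥ 0`. The lowest-RSS solution is kept
(convergence tolerance 10⁻⁸ on the cost). A flat series (ln OD range
< 10⁻⁸) short-circuits to `µ = 0` with the lag reported as 0 and flagged
undefined.

## Encapsulation statistics

Cell loading is Poisson: `P(k) = λᵏe^{−λ}/k!`, occupied fraction
`1 − e^{−λ}`, and `λ = density × (π/6)d³` (a 120 µm droplet is ≈ 0.905 nL,
so ~1.1×10⁶ cells/mL gives λ ≈ 1). Two-strain mixtures assume independent
loading (cultures are premixed; no interaction is modelled). Headline
screen expectations (`n_droplets × (1 − e^{−λ})`) are reported both exactly
and rounded to 2 significant figures, reproducing "approximately N"
reporting conventions.

## Sorting gates

The top-fraction gate takes the empirical (1−q) quantile (linear
interpolation between order statistics) as the threshold and selects
droplets *strictly* above it; ties at the threshold are excluded, so the
gate never sorts more than requested. An instrument realizes such a gate
only approximately (a real run sorting 10,356 of 1,002,443 droplets at a
nominal 1 % gate realized 1.03 %); that calibration slack is documented,
not reproduced. Gate selection is invariant under strictly monotone
transforms of intensity. Histograms default to log-spaced bins, mirroring
the sorter display.

## Enrichment

The enrichment ratio of an OTU is its post-sorting relative abundance
divided by its post-cultivation (pre-sort) relative abundance. Relative
abundance (not raw reads) is used because the two libraries are sequenced
to different depths; ratios of raw counts would be depth-confounded. OTUs
absent from the pre-sort library have an undefined ratio and are flagged,
not pseudocounted, by default (an optional 0.5-count pseudofraction is
available). Ratio exactly 1 is kept as its own class rather than folded
into either side. A useful identity for validation:
Σ pre_fraction·ratio = Σ post_fraction = 1.

## Activity normalization

Specific activity is the kinetic fluorescence slope (OLS over the full
read window, 20 min by default) divided by the protein mass in the assayed
supernatant (from a Bradford curve, bovine gamma globulin standards
0–0.25 mg/mL). Relative activity scales specific activities so a chosen
reference strain is exactly 100 %. IU conversion uses the Nma standard
curve (16 pmol–1 nmol released-fluorophore standards, fitted intercept
retained rather than forced through the origin): 1 IU = 1 µmol product/min,
referred to the supernatant volume in the reaction (50 µL default).
Specificity profiles normalize a 19-residue P1 panel (all standard amino
acids except Cys) to its maximum = 100 %.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions for all tests:

- **Images** (default 160×160 px, 1 µm/px, 120 µm droplet, background
  0.92, cells 0.30, Gaussian noise SD 0.02): cells are seeded as
  non-overlapping dark disks (rejection-sampled, attempt-capped) and grown
  by constrained dilation to the *exact* pixel count matching the target
  occupancy, so ground truth is exact by construction. Blobs stay 2 px
  clear of the interface ring where the target permits. The contrast model
  (which the imaging modality leaves open) was chosen so that an empty
  lumen matches the background level — this is what makes the degenerate
  "no cells" case decidable. Not modelled: point-spread, shading,
  polydispersity, droplet coalescence, and the cell-aggregation artifact
  that can depress occupancy in late E. coli droplet cultures (the
  generator is monotone in time).
- **Screen populations**: per-strain counts i.i.d. Poisson(λ); end-point
  fluorescence = lognormal baseline (median 14, log-SD 0.35, putting the
  empty-droplet histogram mode in the 10–20 band) plus, per strain,
  `fluor_rate × ∫OD dt` along the Baranyi trajectory started at k× the
  single-cell inoculum. The two bundled model strains are a high-protease
  producer (lag 8.9 h in droplet culture, fluor_rate 60) and a weak one
  (fluor_rate 6), giving the bimodal intensity structure a two-strain sort
  exploits.
- **OTU tables**: multinomial sampling at exact depths; expected post
  fractions ∝ pre × factor. Because relative abundances renormalize, the
  realized ratio is factor/Σ(pre·factor); the 45-enriched/35-depleted
  scenario rebalances group masses so Σ(pre·factor) = 1, making configured
  factors the realized expected ratios. Read-level sequence simulation,
  chimeras and OTU picking are out of scope.
- **Growth series**: Baranyi OD with multiplicative Gaussian noise
  (SD = noise_sd × OD, i.e. constant CV — plate-reader noise at the ODs of
  interest scales with signal, and additive noise of fixed size would
  swamp the low-OD lag phase entirely).

Every generator maps one seed to bit-identical output; a global seed fans
out to per-component substreams (`numpy SeedSequence`), so stages can be
regenerated independently.

Passing tests on these synthetics demonstrate the *arithmetic and
estimator* fidelity of the pipeline — formula correctness, round-trip
accuracy, sampling-law behaviour — not robustness to real-world optics,
instrument gating electronics, or sequencing artifacts.

## Problem sizes

Default experiment sizes were chosen to hold Monte-Carlo error well below
the tolerances being checked: 10⁵ droplets for Poisson-law checks
(SE of the occupied fraction ≈ 0.0015), depth 10⁶ reads for enrichment
classification (per-OTU count CVs < 2 %), 50 image fixtures for estimator
round-trips, 10 seeds for the calibration-fidelity experiment, and 20
seeds for noisy growth-parameter recovery.

## Known limitations

- Droplet detection assumes exactly one dominant droplet per frame; no
  multi-droplet tracking.
- The uniform-lumen (degenerate) branch decides "no cells" by similarity
  to the background level; a medium much darker than the carrier oil
  would need the polarity/contrast convention revisited.
- The Baranyi fitter reports the best of a small multi-start; pathological
  series (e.g. a single outlier creating a false shoulder) can still find
  a local optimum.
- Enrichment scoring has no replication model; it scores a single pre/post
  pair and makes no significance claims.
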