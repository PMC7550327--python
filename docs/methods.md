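# Methods

This note documents the analysis model, the synthetic-data generator, the
numerical conventions, and the design decisions where more than one
reasonable choice existed.

## Analysis model

The pipeline assumes a screen laid out on 384-well plates (16 rows × 24
columns) with library reagents in 21 columns (336 wells/plate), controls in
columns 2 and 23 (16 non-targeting, 8 PLK1, 8 PDK1) and media-only wells in
column 24, measured in three arms (pre-treatment T0; vehicle; drug at IC25)
with duplicate plates per arm.

Stages, in order:

1. **Standard curve.** Quadruplicate standards at each ladder level are
   averaged, then a least-squares line `A = intercept + slope·C` is fitted
   (scipy `linregress`). At least two distinct levels are required; a
   non-positive slope raises an assay failure. The endpoint LDH assay is
   treated as linear over the 0–3.2 mM ladder.
2. **Background and inversion.** The mean absorbance of a plate's media-only
   wells is its background. Assay-well concentration is
   `dilution · (A − background) / slope` — the *net*-absorbance inversion.
   The curve intercept is deliberately not subtracted again: the media-only
   wells already contain the assay's intrinsic color, so background
   subtraction removes intercept and media lactate in one step. Negative net
   absorbances clamp to zero concentration and are flagged. The dilution
   factor defaults to 3 (media diluted 1:3 before the assay); because the
   background is measured per plate on identically diluted wells, applying
   the dilution correction before or after subtraction differs only in the
   constant, and the net-inversion form makes the choice irrelevant.
3. **Lactate per cell** divides the concentration by the same well's T48
   count. Exclusion is decided on the well's T48 fold change (< 0.2 by
   default), never on the raw count; a zero count excludes the well rather
   than raising.
4. **Normalization.** Every parameter is expressed as fold change to the
   mean of the same plate's NT wells, so multiplicative plate effects cancel
   exactly. deltaT = T48 − T0 is computed per replicate (pairing each T48
   plate with the T0 plate of the same replicate and well), normalized per
   plate, then averaged across replicates ("average of normalized"; the
   alternative order is equivalent when NT means agree across replicates,
   which the test suite checks).
5. **QC gate.** Per plate instance, the CV of the NT controls is computed
   for counts, deltaT and lactate/cell; any CV above 30% fails the plate,
   and failed instances are excluded from hit calling (their partner
   replicate still contributes, with the replicate count recorded). Z'
   (PLK1 vs NT for counts/deltaT, PDK1 vs NT for lactate) and SSMD (log2 FC
   scale) are computed per plate and averaged screen-wide. SSMD's
   denominator assumes independent control populations (paired differences
   are not available); wells with non-positive FC cannot be
   log-transformed, are excluded and counted — which leaves the SSMD of a
   kill control's deltaT undefined, with the reason recorded. Sample (n−1)
   standard deviations are used throughout.
6. **Robust Z.** `(x − median)/(1.4826·MAD)` over all library genes
   screen-wide, per parameter and arm (per-plate scoping is available). The
   1.4826 normal-consistency constant is configurable (set 1.0 to interpret
   thresholds on the raw-MAD scale). A zero MAD leaves all scores undefined
   and flags the population as degenerate rather than raising, so an
   idealized zero-noise all-neutral screen flows through.
7. **Bins and hits.** Severity bins partition the FC axis with half-open
   intervals; a value exactly on an edge takes the lower-severity side.
   Only three edges are externally pinned — the viability-hit
   correspondence (FC < 0.08), the glycolysis-hit region (FC < 0.5 =
   LAC4∪LAC5) and the low-cell threshold (0.2) — the remaining defaults
   (viability 0.8/0.4/0.08/0.0; lactate 1.0/0.75/0.5/0.25; counts
   0.8/0.4/0.2) are this package's convention and fully configurable. The
   viability LC bin is defined on the deltaT sign by default (net cell
   death); defining it on T48 FC < 0.2 is a config option. Hits use strict
   inequalities (Z < −1.5 viability, Z < −1.66 glycolysis); glycolysis hits
   are filtered for the low-cell bin first. Drug enhancers require the
   drug-arm bin ≥ 2 severity levels beyond the control-arm bin; the
   enumerated pair table is the primary implementation and the index rule a
   cross-check (they agree on all 25 pairs per parameter, by test).
   Glycolysis enhancers additionally must not be low-cell in either arm.
8. **Expression triage.** Hits with an expression value strictly below the
   empirical 12th percentile of the profile (numpy linear-interpolation
   percentile) are recorded as `removed_not_expressed`. Candidate (pre-
   triage) and final counts are both reported. Hits missing from the
   profile are kept and flagged by default (configurable to remove).
9. **Deconvolution validation.** A duplex passes a binned criterion when
   its FC lands in a bin at least as severe as the gene's primary-screen
   bin; it passes the ratio criterion when its replicate-averaged
   drug/control lactate-per-cell ratio falls more than 2 SD below the mean
   of the NT ratios (threshold recomputed from the screen at hand; a config
   override exists for replicating a fixed operating point such as 0.55).
   A gene validates with ≥ 2 of 4 duplexes. An unassessable duplex counts
   as non-passing but keeps the gene in the denominator; a gene with no
   assessable duplex leaves the histogram but stays among submitted genes,
   so percentages are always over the submitted count.

### Calibration scope in the deconvolution lactate criterion

Bin thresholds are primary-screen constructs. The binned lactate criterion
therefore converts duplex absorbances with the **primary** screen's standard
curve and normalizes to the **primary** screen's NT lactate-per-cell
reference. This models the analysis an unsuspecting pipeline performs across
batches — and is exactly where assay-gain drift bites: a gain change `g`
scales all cross-calibrated FCs by `g` and shifts bins, whereas any
within-screen normalization would cancel it. The within-gene drug/control
ratio cancels the gain algebraically, and its threshold derives from the
same screen's NT controls, so ratio-based confirmations are unaffected by
attenuation; `dynamic_range_check` measures the net-signal attenuation
between two curves (1 − slope ratio, for linear curves) and advises the
ratio criterion above a 20% trigger. Count and deltaT criteria involve no
cross-batch calibration and use within-screen FCs. The direction of the
binned-criterion bias depends on the drift structure; the package makes no
claim about matching any particular screen's bias direction, only that
FC-based validation is not gain-invariant and the ratio is.

## Synthetic-data generator

The generator emulates the screen's design (plates, arms, duplicates,
controls, standards) and its statistical structure:

- `T0 = 450 · pre_growth`, `T48 = T0 · arm_growth · m_v · plate_effect`
  with the drug arm's net growth at 75% of control (IC25 semantics);
  counts get multiplicative log-normal noise and round to whole nuclei.
- Media lactate = `yield_per_cell · m_l · T48` plus a media background
  (0.45 mM); absorbance = `intercept + slope · gain · C/3` with additive
  Gaussian read noise. `gain` < 1 models an attenuated enzyme batch
  (default 0.64 for deconvolution, i.e. 36% less net signal at the top
  standard, backgrounds unchanged).
- Every library gene draws continuous log-normal effect multipliers
  (viability log-sd 0.25, lactate log-sd 0.25) plus a mild gene-by-drug
  interaction (log-sd 0.05 viability, 0.08 lactate) — the between-gene
  dispersion that makes replicate plates correlate strongly on raw values
  and gives the robust-Z population its spread. Planted classes override
  one parameter with a well-separated effect: strong kills (multiplier
  0.02–0.3), lactate suppressors (0.15–0.45), and drug enhancers whose
  extra factor applies only in the drug arm. PLK1 wells get multiplier
  0.02, PDK1 wells lactate 0.6, NT wells are neutral.
- Dying wells (true T48 FC < 0.2) release cellular contents: an additive
  media-lactate bonus proportional to cells lost (the death artifact). The
  threshold coincides with the analysis's low-cell exclusion, so artifact
  wells are excluded from lactate analysis downstream — which is the point
  of that exclusion.
- Duplex screens interpolate each duplex between neutral and the pool
  phenotype, `m_duplex = 1 − e·(1 − m_pool)`, with efficacy `e` drawn from
  an effective (0.75–1, probability 0.55) or inert (0–0.35) component, or
  forced by an explicit profile.

**Truth labels** are defined as the analysis outcome on the zero-noise
realization of the same gene effects (rounding included). This makes
"ground truth" a measurement-limit concept: with noise disabled the
pipeline reproduces the labels exactly, and under noise its sensitivity and
false-discovery rate measure noise robustness alone. Robust-Z thresholds
are population-relative, so labels defined on raw multipliers would differ
from any finite-sample analysis at the decision boundary and make exactness
claims seed-dependent.

Noise defaults (count CV 4%, absorbance SD 0.008 AU, plate-effect log-sd
0.05) are a calibration: together with the effect spreads they place the
raw-count replicate Pearson correlation of a simulated screen in the
0.85–0.99 band that screens of this design report, while keeping the
decision boundary sparse enough for reliable hit recovery. The generator
does **not** emulate: spatial/edge effects within plates, transfection-
efficiency variation between wells, image-segmentation artifacts,
saturating or otherwise nonlinear assay response, batch drift within a
screen, or correlated off-target structure between siRNAs. Passing tests
therefore demonstrate correctness of the analysis under the stated
statistical model, not robustness to those real-data pathologies.

Default problem sizes in tests and the acceptance script — 2,000 genes for
the primary screen, 400 genes × 4 duplexes for deconvolution — were chosen
to exercise multi-plate structure while keeping a full run in seconds.

## Numerical conventions and degenerate inputs

- Bin edges: strictly decreasing, half-open `[edge, previous_edge)`;
  exact-edge values take the lower-severity bin.
- Hit thresholds: strict `<`.
- Robust Z with MAD = 0: all scores NaN, degenerate flag (no exception).
- Z' with equal control means: −infinity. Pearson with a constant
  replicate: NaN. SSMD with all positive-control FCs non-positive: NaN with
  reason.
- NT mean ≤ 0 on a plate: that parameter is unusable for the plate (NaN
  fold changes) rather than an exception.
- Lactate: negative net absorbance clamps to 0 mM with a flag; zero cell
  count excludes the well.
- Ratio threshold with zero NT spread: threshold = NT mean, flagged
  degenerate.
- Missing values are empty fields on disk; counts are whole numbers;
  identical config + seed reproduces byte-identical simulator output.

## Limitations

- The bin edges not pinned by the published thresholds are conventions;
  analyses of real screens should set them from their own data.
- The Z ↔ FC correspondences (e.g. −1.5 ↔ 0.08) are properties of a
  particular screen's distribution and are not enforced or assumed.
- SSMD uses the independence approximation for the denominator.
- The deconvolution ratio criterion is computed screen-wide; per-plate
  scoping of the NT threshold is a config option whose effect on real data
  has not been characterized here.
- Selection of deconvolution candidates (ranking, pathway input) is out of
  scope; candidate lists are inputs.
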