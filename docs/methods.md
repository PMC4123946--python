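# Methods

## Data model and conventions

A land-cover map is a 2-D grid of five codes — MF (mature/primary forest),
NF (non-forest: crops, pasture, bare ground), SF (secondary/regenerating
forest), WATER and NODATA — with a per-pixel area in hectares. A stack is an
ordered, co-registered series of such maps with strictly increasing
day-resolved dates. Time differences are decimal years (day count / 365.25)
because acquisition gaps are irregular (one to four years is typical of dry-
season optical series) and all rates are per-year.

WATER is a *permanent* common mask: the union of water cells over all dates
is imposed on every date, so open water never participates in change
analysis. NODATA is *per-date* (cloud): a NODATA cell is excluded from that
date's areas and transitions, but pixel run logic continues across the gap
(see below). The one asymmetry between the two is deliberate — water is a
stable landscape feature, cloud is an observation failure.

Cloud over persistent mature forest is recoverable: given a mask of cells
known (from the most recent cloud-free imagery) to be MF throughout the
series, `fill_cloud_gaps` turns NODATA inside the mask into MF and touches
nothing else. Cloud over NF/SF is not recoverable and stays NODATA.

## Temporal-consistency correction

Regrowth or cleared land cannot return to *mature* forest over observation
gaps of a few years, so a label SF or NF followed by MF is a classification
error. The correction relabels that MF as SF — never NF, because spectral
confusion between NF and MF is implausible whereas older regrowth mimics
mature forest. The scan is a single chronological pass whose corrected
labels feed the next comparison, so corrections propagate forward
([MF, NF, MF, MF] → [MF, NF, SF, SF]). A NODATA date is skipped: each date
is compared against the pixel's most recent non-NODATA label.

Whether such a correction should be single-pass or iterated is a genuine
design choice; we adopted the single forward pass and *prove* (exhaustively,
for every {MF, NF, SF, NODATA} sequence up to length 7) that it equals the
rescan-until-fixpoint alternative, so the choice is immaterial.

## Trajectory metrics

All three metrics are defined on observed dates, with events dated at the
first observation of the new state (events occur inside gaps, so observed
onsets are conservative and first-date states are censored):

* **ASF** — at any date where the pixel is SF, the decimal years since the
  first date of the current uninterrupted SF run. If the run starts at the
  first stack date the value is only a minimum age and carries a censored
  flag.
* **PALU** — the duration of the NF run immediately preceding the current
  SF run. SF standing at the first date has no observed prior use:
  PALU = 0 with a `palu_zero` flag. An MF→SF transition across a long gap
  (clearance and abandonment both unobserved) also yields PALU = 0, without
  the flag.
* **FC** — the cumulative count of observed MF→NF or SF→NF transitions.
  Pixels NF at the first date whose clearance therefore predates the series
  carry `fc_nf_start`; when binning FC classes these (and first-date-SF
  pixels with no observed clearance) are promoted to the low class (1×),
  since at least one clearance must have occurred.

Runs continue across NODATA dates when the same label resumes; a label
change across a gap is dated at the first post-gap observation. When the
*first* date itself is NODATA for a pixel, its first observation starts the
run logic but censored/`palu_zero` flags are reserved for runs starting at
stack date 0 — the flags mean "standing since the series began", which an
unobserved first date cannot assert.

Durations accumulate in decimal years and are floored to whole years before
class binning, because the class definitions are stated in whole years:
ASF initial ≤5 / intermediate 6–15 / advanced ≥16; PALU short ≤2 /
medium 3–4 / long ≥5; FC low 1 / medium 2 / high ≥3. The PALU×FC cross-tab
is the percentage of current SF area per class pair and sums to 100. The
class-proportion curves index each date by years since the site-level onset
of SF, defined as the first date with any non-censored SF (first-date SF has
unknown onset and is included in shares but does not define the origin).

## Change rates

Transition areas are exact 3×3 cross-tabulations over cells thematic at both
dates, times pixel area. Two relative-rate conventions are exposed because
they answer different questions and neither covers all processes well:

* `ln_area`: r = (100/Δt)·ln(A₂/A₁), the standard annualized compound rate
  of change of a class area; exact and signed. Used by default for MF and
  total deforestation (A₂ = A₁ − cleared area).
* `transition_fraction`: r = 100·T/(A_source·Δt), the transition area as an
  annualized fraction of the source class. Used by default for SF
  reclearance and for regrowth, whose reference areas (standing SF, standing
  NF) are small relative to the fluxes; values can legitimately exceed
  100 % yr⁻¹ for multi-year gaps or high turnover, which matches how such
  rates are reported in the change-detection literature. The regrowth
  denominator is configurable (NF at t₁ by default, SF at t₁ optionally)
  because conventions differ between studies.

The absolute rate is always R = T/Δt (ha yr⁻¹), so R·Δt recovers the
transition area exactly. Summaries report min, max, mean, median, IQR
(Q3−Q1 with linear-interpolation quantiles — the common "type 7" rule,
declared for reproducibility) and sample standard deviation (ddof = 1;
reported as 0 for a single period). Rates with a zero denominator are
excluded from summaries and counted in a QC attribute.

### Period typology

Each period gets two orthogonal labels. Clearance composition: **a** MF
clearance only, **b** MF > SF clearance, **c** MF < SF clearance, **e** SF
reclearance only. Net balance: **d** clearance exceeds regrowth, **f**
regrowth exceeds clearance. "Only" means the other term does not exceed 1 %
of the larger clearance term (the source descriptions give no threshold;
1 % is our default and is configurable). Deterministic tie-breaks: equal
clearances → b with a tie flag; clearance equal to regrowth → d with a tie
flag; a period with no clearance at all → a with a degenerate flag (no
typology row describes it).

## Accuracy assessment and inverse area calibration

The error matrix is oriented rows = reference, columns = classified; overall
accuracy is trace/n, omission errors are row-wise, commission errors
column-wise, and classes with empty rows/columns yield flagged NaNs.

Pixel counting estimates class areas with a bias driven by asymmetric
confusion. The inverse estimator corrects it using the conditional
distribution of the reference class given the classified class:

    p_j  = (n_.j + f_j) / N
    pi_i = sum_j (n_ij / n_.j) * p_j

with n_ij the validation counts, f_j the map pixels classified as j outside
the validation sample, and N = n + Σf_j. We define f_j as *excluding* the
validation pixels; with N ≫ n the alternative (including them) differs by
under 0.1 %. Calibrated proportions are nonnegative and sum to 1 by
construction; with a diagonal matrix the calibration is the identity. The
validation design (fixed points per class from distinct large patches) is
treated as a simple random sample in the estimator — a documented
approximation. Only the inverse (not the classical/forward) calibration is
implemented, and no variance estimate is attached.

Validation points are sampled by `make_reference_sample`: connected
components (4-connectivity) of each class with area above a floor (default
6 ha) are enumerated, a fixed number per class is drawn without replacement,
and each patch contributes the patch cell nearest its centroid (exact
centroids of concave patches can fall outside them).

Overlay analyses are plain cross-tabulations: crop/protected-area masks
against a map give overlap areas, shares of the mask, relative incidence
(RI = 100·overlap/class area), and the deforestation-incidence ratio
outside/inside a protected mask (NF∪SF fraction of thematic area outside,
divided by the same inside; infinite when the inside is undisturbed).

## Synthetic landscape

The simulator exists so that every stage has a known-truth test bed. Each
pixel is an independent continuous-time semi-Markov chain: MF survives a
per-year clearance hazard, cleared land is used for a whole-year duration
drawn from the PALU distribution, regrowth survives a per-year reclearance
hazard and is cleared back to NF, indefinitely. Per-year hazards p convert
to exponential rates λ = −ln(1−p), so survival scales correctly across
irregular gaps; the degenerate hazard p = 1 draws the event uniformly within
the year. The chain is then sampled at the configured observation dates, and
the truth tables are produced from the *observed* label sequence by an
independent naive per-pixel scan — so truth and implementation agree only if
the vectorized metric code implements the definitions correctly, which is
the point of the comparison.

Defaults (the simulated study conditions, chosen once): observation dates
are a real 21-date 1984–2011 Landsat acquisition calendar with 1–3 year
gaps; pixels are 0.09 ha (30 m); the MF clearance hazard is 0.02 yr⁻¹ and
the SF reclearance hazard 0.10 yr⁻¹, inside the ranges of mean annual MF
(0.7–3.9 % yr⁻¹) and SF (6–20 % yr⁻¹) clearance reported for Amazon sites;
PALU is geometric with mean 2 years (short use periods dominate observed
landscapes); 5 % of pixels start as SF and 3 % as NF (matching first-date
proportions of long Amazon series); a one-pixel water border exercises the
common-mask path.

What the simulator does **not** emulate: spatial autocorrelation of
clearance (pixels are independent, so simulated landscapes are
salt-and-pepper rather than patchy — validation-point sampling tests
therefore build patchy maps explicitly), fire scars, spectral confusion
structure beyond a per-class multinomial (confusion is i.i.d. across cells,
with no spatial or temporal correlation of errors), and sub-year seasonal
effects. Passing tests demonstrate algorithmic correctness under the
declared definitions, not classifier performance on real imagery.

Classification noise is injected by `corrupt_with_confusion`, relabelling
each thematic cell independently according to its true-class row of a
row-stochastic confusion matrix (WATER/NODATA are never corrupted);
`ConfusionSpec.from_error_matrix_counts` converts published validation
counts into such a matrix.

## Numerical and degenerate-input choices

* Codes are fixed small integers (0 water, 1 MF, 2 NF, 3 SF, 255 NODATA)
  for bit-exact text round-trips.
* Confusion rows must sum to 1 within 1e-12; calibrated proportions sum to
  1 within 1e-9 (float accumulation over three classes).
* The logarithmic rate raises on non-positive areas rather than returning
  ±inf; per-period rates with zero source areas become NaN and are excluded
  from summaries with a QC count.
* Empty SF at a requested cross-tab date raises; curves return an empty
  frame when no SF ever appears.
* Problem sizes used in the shipped checks — 200×200 pixels × 25 dates for
  full-scale truth recovery, 21,840 exhaustive label sequences for the
  correction fixpoint proof, 30 replicates × 40,000 pixels × 600 validation
  points for the calibration experiment — were chosen as the smallest sizes
  at which Monte-Carlo standard errors are far below the tested effects.

## Known limitations

* ASF/PALU are minimum estimates by construction (events dated at first
  observation); with 2–4 year gaps the bias can reach the gap length.
* Fire-driven clearance is indistinguishable from anthropogenic clearance.
* The calibration treats the patch-centroid validation design as simple
  random sampling and attaches no confidence intervals.
* No reprojection or resampling: inputs must already be co-registered.
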