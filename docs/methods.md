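# Methods

## Measurement model

Structures are measured on a sagittal MRI series of parallel slices with
thickness `t` and interslice gap `g`; every per-slice measurement is treated
as representative of a slab of one centre-to-centre spacing `s = t + g`
(defaults `t = 4` mm, `g = 0.8` mm, `s = 4.8` mm).  Cross-sectional areas are
therefore slab sums of per-slice lengths, `CSA = Σ lᵢ·s` (mm²), and volumes
slab sums of per-slice traced polygon areas, `V = Σ aᵢ·s` (mm³).  Two
deliberate simplifications:

- **No inter-slice interpolation.** The slab sum weights every slice,
  including the first and last, by the full spacing `s`.  Interpolating
  between slices or weighting edge slices by `t` alone are defensible
  alternatives; the pure slab sum was chosen because it is exactly linear in
  the per-slice values, which makes the agreement statistics of derived
  parameters transparent functions of the per-slice agreement.
- **Absence is zero, not missing.** A structure that is not present on a
  slice (e.g. no posterior disc material) is recorded as a 0 mm measurement.
  The only missingness channel is the dural sac: slices where it cannot be
  measured are declared in the session filename bracket group, carry no ADSL
  record, and drop out of the CDS sum.  This keeps "measured as absent"
  distinct from "not measurable", which matters for the pairing rules.

Lengths are Euclidean distances between the stored ROI endpoint coordinates
(millimetres in the image plane; pixel spacing is deliberately not carried).
Traced areas use the shoelace formula; self-intersecting outlines are
rejected (checked with shapely) rather than silently signed-area-cancelled.

## Validation of stored values

ROI exports carry a declared value next to the coordinates.  `validate_records`
recomputes every value from the coordinates and flags discrepancies beyond a
tolerance (default 0.05 mm — declared values are rounded exports, so exact
equality would be wrong).  When all flags within one slice can be resolved by
permuting structure labels, the permutation is reported as a suggestion; it is
never applied automatically, because relabelling is a data-correction decision
for a human.

## Pairing and exclusion rules

- Length parameters are paired per (participant, level, slice) on slices both
  sessions measured.  Each slice counts as one observation; clustering of
  slices within participants is ignored, matching how multi-slice agreement
  tables pool slices.
- CSA and volume parameters are paired per participant, and only for
  participants whose start and end slice agree between sessions — otherwise
  the sums run over different windows and would disagree for geometric rather
  than rater reasons.  Excluded participants are logged with the two windows.
- CDS uses its own criterion — identity of the two sessions' ADSL slice
  sets — since a window mismatch consisting entirely of missing-dural slices
  does not affect the CDS sum (this is why the CDS row can have a different
  n from the other CSA rows).

## Agreement statistics

`bland_altman` uses the multiplier 1.96 (not 2.0) for the limits of
agreement, and the normal quantile (not t) for the CI of the bias; the pooled
ns here are large and this choice reproduces printed reference tables within
rounding.  With differences `d`: bias `d̄`, `s_d` with the n−1 denominator,
LOA `d̄ ± 1.96·s_d`, CI of bias `d̄ ± 1.96·s_d/√n`, bias "present" iff the CI
excludes 0.  `s_d = 0` is not an error: the LOA collapse onto the bias and
the result is flagged degenerate (this is the expected noiseless-pipeline
output).  The LOA-proportion `(upper − lower)/mean·100` is reported
half-away-from-zero rounded to one decimal, the convention of the reference
tables; `flag_outliers` operationalizes "far outside the LOA" as "outside the
LOA", the threshold being configurable through the LOA multiplier.

`printed_loa_attainable` audits a reported table row by exact interval
arithmetic: it decides whether any unrounded (bias, SD) within half an ulp of
the printed values yields LOA that round to the printed interval.

## Reliability statistics

- **Weighted kappa:** disagreement weights `1 − |i−j|/(m−1)` (linear,
  default) or `1 − ((i−j)/(m−1))²` (quadratic) on the m×m cross-tabulation.
  The weight scheme is a genuine free choice for ordinal slice numbers;
  linear is the common default of the standard packages and is used unless
  asked otherwise.  The CI uses the asymptotic (Fleiss–Cohen–Everitt)
  standard error — deterministic and comparable across packages (it matches
  statsmodels' `cohens_kappa` to machine precision) — with a seeded
  percentile bootstrap as an option.  A table with all mass in one cell has
  chance agreement 1 and kappa is reported as undefined, not 1.
- **ICC(2,1):** Shrout–Fleiss two-way random-effects absolute-agreement
  single-measurement form from the ANOVA mean squares, CI via the F interval
  with Satterthwaite degrees of freedom (matches pingouin's ICC(A,1)).  A
  residual sum of squares below 1e-12 of the total is treated as exactly
  zero, so noiseless tables return ICC = 1 with a collapsed CI instead of
  float residue; a table with no subject and no error variance is an error.
- **Sample sizes:** `n = 2k²` for kappa; Bonett's
  `n = 8·z²·(1−ρ)²·(1+(k−1)ρ)²/(k(k−1)w²) + 1` rounded up ("k" here is the
  number of raters — with k = 2, ρ = 0.9, α = 0.05, w = 0.2 this gives 15);
  LOA precision factor `1.96·√(3/n)` (the half-width of the 95% CI of each
  LOA limit in units of `s_d`).

## The synthetic study generator

`SimConfig` defaults encode the study conditions the analysis battery is
designed for: 32 participants, one disc level each (10/12/10 across
L3-L4/L4-L5/L5-S1), a true slice window with start drawn from {1,2,3,4}
(mode 2) and end from {6,7,8,9} (mode 8), and true structure means of
14.7/9.5/31.1/3.5/3.6/8.5 mm for AIVH/PIVH/IVDL/ADML/PDML/ADSL.  The printed
reference tables give no between-participant SDs (their SD column describes
paired differences), so the truth spreads are the package's own choice of a
realistic anatomical spread: 2.0/1.5/3.0/1.2/1.2/1.5 mm between participants
plus 0.8 mm of slice-to-slice variation within a participant.  Per-slice
traced areas default to means 63/39 mm² (consistent with disc-material
volumes on the order of 1–2·10³ mm³ over a seven-slice window) with
between-participant SDs 15/10 mm² and 5 mm² slice variation.  Rater sessions
add a fixed bias (defaults 0 vs 0.2 mm, 0 vs 2 mm²) and Gaussian error
(0.5 mm, 4 mm²), floored at zero (areas at 0.01 mm², the smallest traceable
outline); each rater independently mis-selects each window end by ±1 with
probability ε (default 0.1), clamped to the ordinal category sets; dural-sac
missingness is a per-slice property of the scan (probability 0.05), shared by
both raters.

Truth and errors are truncated Gaussians — the simplest family consistent
with the targeted means; the truncation is negligible at the default sizes.
What the generator does **not** emulate: real landmark ambiguity (osteophytes,
low-contrast boundaries), heavy-tailed blunders behind real outliers,
correlated errors between neighbouring slices, and any imaging physics.
Passing recovery tests therefore show that the statistical pipeline is
correct, not that real raters behave like the generator.

Determinism: a single mandatory seed drives one `numpy` generator through a
fixed draw order, so identical configurations give bit-identical studies,
including the emitted ROI CSV files.

Closed-form recovery targets used by the tests: the difference of two
sessions has bias `b_A − b_B` and SD `√(σ_A² + σ_B²)`; slice-level ICC(2,1)
targets `σ_s²/(σ_s² + σ_r² + σ_e²)` with `σ_s²` the between-unit truth
variance (participant + slice components), `σ_r² = (b_A − b_B)²/2` the
two-rater bias component and `σ_e²` the mean error variance.

## Problem sizes in the test suite

The stochastic checks use 300–400 simulated participants for bias/LOA/ICC
recovery (Monte-Carlo SE comfortably inside the asserted tolerances), a
2000-subject rating table for the variance-component ICC check, 200 study
replicates for LOA coverage, and 1000 random tables for each brute-force
oracle comparison.  These sizes were chosen so that the asserted tolerances
are several Monte-Carlo standard errors wide.

## Known limitations

- The volume estimator is a slab sum; against a hypothetical interpolating
  read-out it will differ most for structures that change rapidly between
  slices.
- ICC on pooled slices inherits the pooling assumption of the pairing rules;
  with few participants and many slices the CI understates the clustering
  uncertainty.
- The CI methods (asymptotic kappa SE, F-interval ICC) are large-sample
  approximations; small-n CIs from other software may differ slightly.
- `loa_proportion` requires a positive mean and is reported already rounded;
  it is a descriptive ratio, not an inferential quantity.
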