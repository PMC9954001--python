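# Methods

## Scope

`combiscreen` implements the computational core of a Cmax-anchored
pharmacological screen on patient-derived tumor cells: vehicle
normalization, trapezoidal AUC scoring, treatment ranking across a sample
panel, median-effect/combination-index synergy analysis, and the
expression-side computations that accompany such screens (two-rule DEG
filtering, range-based heatmap gene selection, UPGMA clustering, 2^−ΔΔCt).
Wet-lab quantifications (blots, apoptosis, ELISA, migration), survival
analysis of animal studies, microarray preprocessing, and ontology
enrichment are out of scope.

## Dose–response scoring

Viability is raw signal divided by the per-sample vehicle mean; replicates
are averaged per dose with the sd retained for reporting (no weighting — a
weighting scheme would demand a calibrated error model we do not have).
Values above 1 are preserved: growth stimulation is information, not an
artifact.

The AUC is the trapezoid sum over the *measured* points, not over a fitted
curve; the four-parameter logistic fit exists for EC50 reporting and
generator round-trip checks only. The dose axis is log10(µM) by default: a
log-serial dilution ladder then has uniform ΔX per step, which is what
makes the plain trapezoid formula natural; a linear axis is available as
an option. Negative viabilities are floored at 0 before integration —
"everything dead" is the maximal scoreable effect — while values above 1
are integrated as-is so stimulation drives the score negative.

Score anchors default to theoretical references: AUC_min = 0 (full kill)
and AUC_max = log-range × 1 (no effect). Theoretical anchors make scores
comparable across plates, screens and laboratories, unlike per-screen
observed extremes, and give the boundary semantics exactly: a full-kill
curve scores 100, a vehicle-level curve 0, a uniformly stimulated curve
(e.g., viability 1.2 everywhere) scores −20. Empirical anchors can be
passed explicitly where within-screen normalization is wanted.

The Hill fit is a least-squares 4PL on the log10-dose axis with tight
convergence tolerances; with fewer than four distinct doses the top and
bottom are pinned to the observed extremes and only (EC50, slope) are
fitted. Curves with viability range < 0.05 are flagged flat and
unconverged rather than fitted: a flat curve has no identifiable EC50.

## Synergy

Fraction affected is fa = 1 − viability, clamped to [0.01, 0.99]. The
logit linearization diverges at 0 and 1, so clamped points are excluded
from median-effect regression but retained (flagged) for CI evaluation.
The median-effect fit is OLS of log10(fa/(1−fa)) on log10(dose); with
exactly two points the 2×2 system is solved directly. CI is the classical
exclusive two-term form, evaluated per measured dose pair at its own
observed fa (non-constant-ratio design), because the screen combines drugs
at fixed dose pairs (Cmax, 10% Cmax) rather than diluting a fixed-ratio
mixture. |CI − 1| ≤ 0.05 is reported as "additive" so that noise does not
flip the synergism/antagonism label across the exact boundary; the raw CI
is always reported alongside. A combination is called synergistic overall
when a strict majority of its points have CI < 1.

Assay-design note: median-effect parameters are only estimated reliably
from doses that bracket Dm. A ladder anchored far above or below Dm puts
most points at extreme fa, where the logit transform amplifies and skews
noise and the clamp truncates it; in validation studies we therefore fit
single agents on 2-fold ladders from 8×Dm downward (six points spanning
fa ≈ 0.1–0.9). This mirrors standard practice for the method and is a
property of the assay design, not of the estimator.

## Panel ranking

Scores are assembled per dose tier into a treatments × samples matrix with
explicit masking; untested cells are absent from every aggregate. The
aggregate is the unweighted mean over tested samples (median by flag), the
headline ranking uses the 10% Cmax tier — the tier that favours
combinations acting at the lowest concentration — and treatments tested on
fewer than 3 samples are listed but unranked, so a single lucky sample
cannot produce a winner. Ties share the minimal rank and order
lexicographically, making output deterministic.

## Expression

The array platform's proprietary per-gene error model is not reproducible,
so the p-value in rule 1 comes from a per-gene Welch (unequal-variance)
two-sample t-test on log2 intensities. This is a substitution and is the
main caveat when comparing DEG lists against platform-native output.
Benjamini–Hochberg adjustment is off by default (matching the stated
filter) and available by flag (matching the adjusted-p convention some
reports use). Rule 2 — undefined log2 ratio with group-mean intensity
difference ≥ 1000 — is applied to group means; a group with no usable
signal contributes 0 to the difference.

"Data transformation" before clustering is read as log2; rows are then
mean-centered. Clustering is UPGMA (average linkage) on euclidean distance
by default, 1−Pearson optionally; constant rows, whose correlation is
undefined, are dropped with a flag under the correlation metric. The
implementation is the standard agglomerative linkage routine; its output
is verified in the test suite against a brute-force O(n³) re-implementation
on random matrices.

ΔΔCt uses group means of Ct: ΔCt = Ct_target − Ct_reference per group,
ΔΔCt = ΔCt_treated − ΔCt_calibrator, fold = 2^−ΔΔCt. The ΔΔCt sd is the
quadrature sum of the four standard errors (target/reference ×
treated/calibrator), reported as the fold-change interval
[2^−(ΔΔCt+sd), 2^−(ΔΔCt−sd)]; this matches a Monte-Carlo resampling of the
replicate means because ΔΔCt is linear in the four means. With a single
replicate anywhere only the point estimate is returned.

## Synthetic screen generator

The generator is the package's ground-truth instrument, not a data
faithfulness claim. Defaults encode the screen design: 6-point dose
ladders, half-log (√10) dilutions topping at Cmax (the dilution factor of
the original screen is not stated; half-log over six points is the common
convention spanning 2.5 decades), 3 replicates, multiplicative lognormal
noise with sd 0.05 on the log scale (plate readouts are positive and
heteroscedastic; 3–5% CV is typical of luminescent viability assays), and
per-sample lognormal multipliers (sd 0.2) on EC50 only, keeping slope
recovery clean while emulating between-patient sensitivity differences.

Combinations are built by solving the Loewe equation
ψ·d_a/Dx_a(fa) + ψ·d_b/Dx_b(fa) = 1 for fa by bisection in (10⁻⁶, 1−10⁻⁶),
using each component's exact median-effect parameters; the scalar ψ on
both doses gives ground-truth CI = 1/ψ in closed form. Dose pairs whose
root falls outside the open interval are clamped and flagged. Expression
fixtures plant exact group-mean log2 shifts under gaussian log2 noise; Ct
fixtures plant exact ΔΔCt shifts.

Not emulated: plate spatial effects (edge wells, gradients), seeding-
density artifacts, tumorsphere growth kinetics, assay drift between
plates, heavy-tailed outlier wells, and correlated gene–gene expression
structure. Passing tests therefore demonstrate correctness of the
computations under the stated noise model, not robustness to every plate
pathology of real screens.

## Numerical choices

- Loewe bisection: Brent's method, xtol 10⁻¹⁵; endpoints clamp with flag.
- Hill fit: bounded trust-region least squares, xtol/ftol/gtol 10⁻¹⁴, so
  noise-free round trips recover parameters to ≤ 10⁻⁶ relative error.
- All logarithms in the median-effect linearization are base 10 (any base
  is equivalent; fixed for reproducibility).
- Ties: heatmap gene selection and treatment ranking break ties
  lexicographically; sorts are stable.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; no global RNG state. Identical seeds give
  bit-identical tables, and a pipeline rerun with the same config and seed
  is byte-identical.

## Validation problem sizes

The test and reference runs use desk-scale designs chosen to exercise each
property: 6-point ladders; 10 samples × 12 treatments for ranking recovery
over 100 seeds; 50 seeds at noise sd 0.03 for noisy CI calibration; 200
seeded runs for noisy EC50 recovery; 6×4 matrices against the brute-force
UPGMA oracle; 10⁵ Monte-Carlo draws for the ΔΔCt error check.

## Known limitations

- The Welch-test substitution above means DEG lists are comparable to
  platform-native ones only in their filtering logic, not their exact
  p-values.
- CI estimates at very low fraction affected are noise-dominated (fa is a
  small difference of two numbers near 1); the per-point table flags
  clamped values, and the overall call uses the majority of points.
- The score's theoretical anchors presume the ladder spans the informative
  range; a ladder entirely below a drug's active range scores near 0
  regardless of the drug's potential at higher exposures — by design,
  since exposures above Cmax are not clinically achievable.
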