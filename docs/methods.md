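# Methods

## Pipeline

Stages, in order: (1) cohort screens — closed age window [6, 30] years,
removal of centers with fewer than 10 subjects in either group, a one-pass
per-center z-score screen (|z| > 3 in any ROI, SD with n−1, zero-SD ROIs
contribute z = 0); (2) inter-center variance removal; (3) per-group
polynomial trajectory fits with a deviance-test FDR mask; (4) entropy-guided
subsampling; (5) mean-centered / behavioral PLS; (6) turning point;
(7) linear-SVM classification. All stages are deterministic given their
seeds; the pipeline spawns per-stage child seeds from one master seed via
`numpy.random.SeedSequence`.

## Center harmonization

Scanner/site effects are modeled as additive per-center offsets. For each ROI
an OLS model regresses CT on an intercept, dummy-coded centers (first center
in sorted order is the reference), age powers up to the working degree d,
group coded ±1, and age^k × group interactions (k ≤ d). Only the fitted
center effects are subtracted, after re-centering them to a size-weighted
zero mean — this keeps each ROI's grand mean and millimeter scale intact and
makes the adjustment independent of the reference-center choice. The
adjustment is a projection: applying it twice equals once. Each polynomial
degree of the downstream analysis consumes CT adjusted with the same-degree
model, keeping every analysis internally consistent. Non-positive adjusted
values are logged, never clipped. Empirical-Bayes shrinkage (ComBat-style)
is deliberately out of scope; the model is plain regression.

## Trajectory models and masking

Fits are ordinary least squares on the Vandermonde basis (1, a, …, a^d),
per ROI × group, no group or center terms (inputs are group-pure and
harmonized). Goodness of fit uses the Gaussian-ML likelihood ratio against
the intercept-only model, n·ln(RSS₀/RSS₁), referred to χ² with d degrees of
freedom. A perfect fit (RSS₁ ≤ 1e−12·RSS₀) returns p = 0 with a degeneracy
flag; data identical to their mean return p = 1. Benjamini–Hochberg runs
within each group × degree family (via `statsmodels.multipletests`); an ROI
is kept if it passes in **both** groups (`both_groups`, default) or in at
least one (`any_group`) — both rules exist because the two plausible
readings of the masking rule conflict, and the stricter one is the default.
Downstream stages that need one rectangular ROIs × 3 coefficient layout use
the ROIs kept at **every** degree (intersection), the conservative choice
that keeps the documented ROI-major column order well-defined.

## Turning point

For a fitted quadratic f with curvature c < 0 on [lo, hi], the vertical
distance to the chord through (lo, f(lo)) and (hi, f(hi)) is
f(a) − chord(a) = c(a − lo)(a − hi), a parabola maximized exactly at
(lo + hi)/2 — 18 years on [6, 30] — independent of slope and intercept.
Vertical (not perpendicular) distance is the natural "distance at an age"
reading and gives the closed form. The function refuses convex fits and
non-quadratic degrees.

## Subsampling

Candidates are subsets of n subjects drawn without replacement
(defaults n = 70; 100,000 candidates at full scale, 2,000 as the fast
default; the single-center configuration uses n = 40, K = 50). The age
histogram uses one-year bins on [6, 30] (24 bins) — the finest resolution
consistent with 70-subject samples; entropy is Shannon entropy in nats
(selection is rank-invariant to the log base, so only binning matters).
The top K by entropy are retained, ties broken by draw order; duplicate
candidate subject-sets are allowed. Selected subsamples are ~0.07 nats below
the ln 24 ≈ 3.18 ceiling at n = 70.

## PLS

Mean-centered PLS decomposes the groups × features matrix of group means
minus their unweighted grand mean (groups are balanced by construction,
K subsamples each). Two groups give a rank-one contrast (asserted); the LV
is oriented so the design salience of the first group (ASD) is positive.
Behavioral PLS decomposes the behaviors × features Pearson correlation
matrix; constant features get zero correlation, constant behaviors are an
error. Permutation p-values use the +1-smoothed estimator
(1 + #{σ_perm ≥ σ})/(1 + n_perm), shuffling group labels (mean-centered) or
the X/Y row correspondence (behavioral). The bootstrap resamples
observations within group (mean-centered) or paired rows (behavioral),
re-decomposes, aligns each LV's sign by the dot product with the original
saliences, and reports z = salience / bootstrap SE. Behavioral overall
correlations (per subscale) are computed with the LV oriented so the mean
brain salience is positive, making the sign of r reflect the raw
feature-behavior direction — e.g. negative when higher ADOS goes with more
negative curvature — independent of the design-side sign convention used
for saliences and bootstrap ratios.

## Classification

Each repeat: half/half split within group × 2-year age bins (odd bins
coin-flip the extra subject), independent entropy subsampling per half and
group, shape fits, then a linear-kernel SVM (unit box penalty, C = 1,
`sklearn.svm.SVC`) on the training half's subsample rows, evaluated on the
test half's rows; accuracy/sensitivity/specificity in percent, 5th/95th
empirical percentiles as the interval. **Features are standardized with the
training half's statistics by default.** Shape coefficients live at
1e−2…1e−4 mm/yr^d; at that scale a unit box penalty leaves every row inside
the hinge margin, the weight vector stays near zero and the decision is
dominated by the intercept (measured: strong-contrast curvature accuracy
~52%, sensitivity 35% / specificity 100%, versus 100% after scaling). The
raw-scale behavior of common SVM toolbox defaults remains available as
`standardize=False`. Entropy selection is re-run within every repeat; model
comparisons are pairwise independent t-tests with BH-FDR per parcellation.

## Synthetic generator

The generator emulates a multi-center developmental cohort: ages continuous
uniform on [6, 30] (the subsampling stage itself rewards uniformity, and no
cohort age density is prescribed); unbalanced groups; additive per-center CT
offsets (evenly spaced in ±0.15 mm by default); i.i.d. Gaussian measurement
noise (0.1 mm); ADOS-Generic subscores as rounded non-negative integers
(0–8 communication/social, 0–4 stereotyped) for ASD subjects only. The TD
base trajectory is convex thinning: intercept ≈ 3.55 mm, raw slope
−0.085 mm/yr, curvature +0.001 mm/yr², giving a fitted linear slope of
≈ −0.05 mm/yr and CT within 2–3.5 mm across the window.

Three presets: `null` (identical groups), `paper-like`, `strong`. The
contrast presets plant, in the first 20% of ROIs (a contiguous block),
slope +0.012 / curvature −0.002 (doubled for `strong`), expressed around
age 18 so the groups agree mid-window and CT stays physiological; with
symmetric ages the fitted linear slope shifts by exactly the slope delta and
the quadratic coefficient by exactly the curvature delta, while the cubic
coefficient carries no contrast. The base slope is steep enough that the ASD
fitted slope stays clearly negative even under the doubled contrast, so
planted ROIs retain detectable trends at every degree (earlier bases with
fitted slopes near zero made planted ROIs fail their own goodness-of-fit
screen). Magnitudes were set once from these structural requirements; only
contrast directions are externally prescribed.

Symptom coupling: every subject carries a latent standard-normal severity
factor. ASD subjects' CT in the planted ROIs gains
−severity_scale · severity · (age − 18)² (a pure curvature perturbation of
exactly −severity_scale·severity, bounded over the window), and ADOS
subscores increase with the same factor — so subgroup mean ADOS correlates
negatively with subgroup-fitted curvature, the planted direction the
behavioral PLS must recover. What the generator does **not** emulate:
spatial covariance between ROIs, non-uniform age densities, scanner
differences beyond additive offsets, heteroscedastic or non-Gaussian noise,
or subject-level trajectory heterogeneity beyond the severity factor.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted structure, not performance on real MRI data.

## Exchangeability of subsample rows (important caveat)

The permutation tests treat subsample/subgroup rows as exchangeable
observations. They are not, in general: rows within a group share (a) the
group's full-cohort sampling deviation (per-feature variance ∝ σ²(n)·n/N)
and (b) overlapping membership whenever the drawn mass n·K approaches the
group size N. Row-label permutation cannot see these shared components, and
because the test statistic aggregates ~120 features, even mild per-feature
inflation drives the observed singular value past essentially all permuted
ones. Measured on the null generator: at N ≈ 680 per group (a realistic
cohort size) with n = 35, K = 20, the group-PLS permutation test rejected a
true null in ~78% of replicates; the analogous behavioral test with
200 subgroups of 20 from 200 ADOS-complete subjects rejected in ~50%.
Calibration is restored in the near-disjoint regime n·K ≪ N (group PLS:
6% rejection at N = 20,000 per group over 200 replicates; behavioral:
~3% at N_asd = 4,000, K = 200). The calibration experiments in the
end-to-end suite (tests/test_acceptance.py) therefore run at those sizes, while effect-recovery
experiments run at realistic cohort sizes (where the shared components only
add to the planted signal). Users applying the subsample-permutation design
to real cohorts should treat its p-values as anti-conservative and the
bootstrap ratios as the more interpretable output.

## Numerical choices

OLS via `numpy.linalg.lstsq`; design-matrix rank is checked by QR with a
relative tolerance and rank deficiency reported with the offending column
names. Entropy tie-breaks follow candidate draw order. Bootstrap SE uses
n−1; zero-SE features get z = 0. Permutation p can never be exactly 0
(+1 smoothing). CSV round-trips write 17 significant digits and read with
`float_precision="round_trip"`, so serialization is lossless. Negative ADOS
sentinels (−9999) become missing on read; ABIDE-style DX/sex integer codes
are remapped via a configurable mapping (1 = ASD, 2 = TD by default).

## Known limitations

Beyond the exchangeability caveat: no spline or mixed-effects trajectory
models; no empirical-Bayes harmonization; subsample-level (not subject-
level) classification; the deviance test assumes Gaussian residuals; the
turning point is defined only for concave quadratics on a fixed window.
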