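# Methods

## Sequence model and validation

All encoders operate on sequences over the 20 standard amino acids
(ACDEFGHIKLMNPQRSTVWY). FASTA input is uppercased and
whitespace-stripped before validation; B, J, O, U, X, Z, `*` and gap
characters are non-standard. Selenocysteine (U) is treated as
non-standard rather than as a 21st residue — the descriptor spaces are
defined over the 20-letter alphabet and a 21-letter extension would
change every dimensionality. The default validation policy is `reject`
(an explicit error naming the offending characters), so silent data loss
cannot happen in a pipeline; `drop` is opt-in and logs the count of
excluded sequences, mirroring the usual dataset-cleaning step.

## Descriptors

**GPC.** The gap G counts *skipped* residues: a pair occupies positions
p and p + G + 1, so a length-N sequence has exactly N − G − 1 pairs and
the printed denominator N − G − 1 makes each 400-descriptor block a
probability distribution. This is the only reading under which the
denominator equals the pair count; G = 0 reduces to the ordinary
dipeptide composition. Descriptor order is row-major alphabetical
(AA, AC, …, YY) with gaps ascending, giving deterministic column
identity across runs. Sequences shorter than G + 2 are rejected with
both N and G in the message.

**PAAC.** The correlation function is Φ(ψᵢ, ψᵢ₊ⱼ) = [Θ(ψᵢ) − Θ(ψᵢ₊ⱼ)]²
with Θ the residue property centered to zero mean and divided by the
root-mean-square deviation over the 20 amino acids (population
convention, denominator 20). f_x is the raw occurrence count, not the
frequency: with the shared denominator Σf + wΣρ this makes the 20 + d
entries sum to exactly one, the convention of the original formulation.
Defaults are d = 1 and w = 0.05; the weight is not dictated by the
method itself, so the conventional value is used and both are
configurable. The default property is the classical hydrophobicity
scale from the bundled table.

**CTD.** The standard three-group encoding over 7 physicochemical
attributes (hydrophobicity, van der Waals volume, polarity,
polarizability, charge, secondary-structure propensity, solvent
accessibility), 21 descriptors each: 3 composition fractions, 3
transition frequencies over adjacent pairs in either order divided by
N − 1, and per group the 1-based positions of the first, 25%, 50%, 75%
and last occurrence divided by N. The quantile position is that of the
ceil(q·count)-th occurrence; a group absent from the sequence encodes
all five distribution values as 0. The attribute scheme is a data file
(`data/ctd_groups.tsv`) so users may substitute their own partitions.

**ACF.** For each property table u (standardized exactly as in PAAC) and
lag j ≤ n, the descriptor is the mean lagged product
(1/(N−j)) Σ u(ψᵢ)u(ψᵢ₊ⱼ). Autocorrelation of this form is symmetric
under sequence reversal, which the property tests assert. Standardized
rather than raw property values are used so that tables on wildly
different scales (mass vs hydropathy) contribute comparably; this choice
is a convention and is recorded here because the functional form of
"autocorrelation over AAindex properties" admits both readings. Five
classical tables ship with the package (hydrophobicity, hydrophilicity,
side-chain mass, Kyte–Doolittle hydropathy, Grantham polarity); a full
AAindex-style TSV can be supplied for the 531-index configuration, in
which order-2 ACF yields 1,062 descriptors.

## Feature selection

Each technique is pinned to its standard formulation: the two-class
F-score (between-class separation of class means over pooled
within-class variance, 0/0 scored 0); mutual information between the
label and an equal-frequency 10-bin discretization; absolute
coefficients of an L1-penalized logistic fit with the penalty chosen by
3-fold internal cross-validation over 10 candidate strengths;
impurity-decrease importance of a 500-tree random forest; and squared
weights of a linear SVM at C = 1. All parameters are overridable and
recorded in the result metadata; stochastic techniques take a seed and
ties are broken by feature name, so rankings are reproducible. The
subset size k defaults to 484 but is a free parameter — in the original
protocol this number arose as the count of non-zero LASSO coefficients,
which is data-dependent.

## Classifiers and the hierarchical flow

SVMs use the libsvm defaults: cost 1, γ = 1/p, degree 3, coef0 0. Inputs
are standardized per feature with training-set mean and standard
deviation before the kernel, and the statistics travel with the
classifier. This matches the default behaviour of the standard SVM
front ends built on libsvm and is not optional decoration: raw
compositional descriptors live at scale ~10⁻³, where an RBF kernel at
γ = 1/p is numerically constant and a cost-1 linear SVM cannot express
the required weights — both verified to collapse to chance on the
synthetic benchmark, while the standardized fit recovers the signal.
Probabilities come from the libsvm-native Platt calibration; fits are
deterministic given the seed.

Kernel screening evaluates each requested kernel by stratified k-fold
accuracy and picks the best, breaking ties in the fixed order radial,
linear, polynomial, sigmoid.

The hierarchical predictor gates strictly: stage 1 calls HSP when the
calibrated HSP probability is ≥ 0.5 (threshold exposed as a flag, ties
resolved toward the positive class); non-HSP sequences never reach
stage 2; only sequences whose stage-2 argmax is HSP40 reach stage 3.
Stage 2 is a single multi-class (one-vs-rest, maximum probability)
classifier rather than six independent binary models, so every HSP
receives exactly one family; the per-family binary view lives in the
evaluation module. All stages share one pipeline (encoder spec plus
selected-feature list), selected on the stage-1 problem. The reported
probability of a prediction is that of the deepest stage that produced
the call. Model bundles serialize each stage with its kernel, classes,
scaling statistics, seed and a training-data digest, and round-trip to
identical predictions.

## Evaluation protocol

Undefined ratios (zero denominators in precision, sensitivity, MCC, …)
return NaN, never 0, and fold averaging is NaN-aware — a silent zero
would bias averages over folds. AUC-ROC is the trapezoidal area over
all score thresholds, which equals the fraction of correctly ordered
positive/negative pairs with ties counted one half (asserted against a
brute-force oracle). AUC-PR uses the step-wise average-precision rule,
not trapezoids, because PR interpolation is known to be biased; any
comparison with trapezoidal PR figures should note the convention.

Five-fold stratified splitting (shuffled, seeded) is the default.
K-fold metrics are per-fold values averaged, matching the convention of
reporting fold means; LOOCV metrics are computed from the pooled
leave-one-out predictions because fold-size-one metrics are degenerate.
The balanced-resampling protocol draws equal-size positive/negative
samples without replacement (default 100 samples), cross-validates each,
and reports per-metric means with standard errors over samples; the
whole procedure is reproducible from a single seed. One-vs-rest family
evaluation treats each family as positive against the union of the rest
and also reports class-size-weighted averages.

## Synthetic benchmarks

The generator draws residues i.i.d. from a base distribution (uniform
0.05 by default) and plants `round((m−1)(N−G−1)·p_a·p_b)` occurrences of
each biased pair (a, b, G) at random positions — the expected excess
over the i.i.d. pair count at enrichment multiplier m. Planting rewrites
positions rather than rejection-sampling whole sequences, so the
intended enrichment is achieved at any length in bounded time; later
plants may overwrite members of earlier ones, a dilution that is
negligible at the default densities. Lengths are uniform on 80–600,
straddling the length variability seen across real HSP families.

The study conditions are fixed in the profile presets: the strong-bias
benchmark gives each of the six families four distinct biased pairs
(gaps 0–3, multiplier 10) and uses class counts proportional to the
curated corpus imbalance — 354/1,257/159/278/52/81 positives plus
signal-free negatives; the DnaJ preset mirrors 63/53/1,107/22; the null
benchmark has two identical signal-free classes and calibrates the
protocol at chance. What passing tests show is that the pipeline
recovers planted compositional signal through encoding, selection,
training and staged prediction, and reports chance when there is none.
What they do not show is performance on real chaperones: real families
share homologous domains, have non-uniform residue usage, and their
signal is not confined to a handful of gapped pairs, so accuracies on
these benchmarks are not estimates of accuracy on biological data.

## Problem sizes

The test suite exercises the full pipeline at 0.15× the corpus-shaped
class counts (≈650 training sequences for stage 1) and the end-to-end
recovery check at 0.2×; the acceptance script runs at 0.5×
(2,180 sequences, 1,600 → 484 features), a 300-per-class null benchmark,
a 0.5× DnaJ set and 100 balanced resamples of 60 + 60 from a 120 + 120
pool. These sizes were chosen so the whole pipeline — including
500-tree forests on 1,600 descriptors and Platt-calibrated SVM folds —
remains a minutes-scale desk computation while keeping every class
large enough for stratified five-fold splitting.

## Known limitations

- Stage-3 training requires a separate DnaJ-labeled set; when absent,
  predictions stop at the family level.
- The LASSO ranking uses a logistic L1 path, not the exact least-squares
  LASSO; coefficients ranked by magnitude are insensitive to this choice
  at the sizes used, but the zero-coefficient count differs.
- The bundled property collection is 5 tables, not the full 531-index
  AAindex; ACF dimensionality scales with whatever collection is
  supplied.
- Per-fold AUCs require both classes and probability outputs; folds
  missing either contribute NaN and are excluded from the mean.
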