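# Methods

## The model

A first-order hidden Markov model is laid along each gene's missense-variant
positions (one observation per position; positions are ordered by genomic
coordinate and sequences never cross gene boundaries). Observations are
ternary vectors over M score features: 1 = the score places the variant in
its top Q% ("present"), 0 = scored but below the cutoff, 2 = missing.
Emissions are independent Bernoulli per feature given the state; a missing
feature contributes likelihood 1 (no evidence) and is excluded from both the
numerator and denominator of the emission update during training, so
missingness is ignorable by construction — the model assumes scores are
missing at random given the state, which real predictors (whose coverage
correlates with gene properties) can violate.

Key assumptions: score features are conditionally independent given the
state (the usual segmentation-model simplification; correlated predictors
are captured only through state multiplicity), one state per position shared
by all alternate alleles at that position during training (training samples
one allele per position), and first-order spatial dependence.

## Numerical scheme

Forward–backward uses per-position scaling constants, plus an additional
per-position rescaling of the emission likelihood vector by its maximum in
log space, so sequences of 10^5 positions with near-0/1 emission parameters
neither underflow nor return NaN (tested). The scaling constants give the
log-likelihood directly. Probabilities inside logs are floored at 1e-300;
an observation with zero likelihood in every state raises rather than
propagating NaN.

## Training

Baum–Welch with:

- **Pseudo-counts** (default 1) added to every expected count — initial,
  transition, and both Bernoulli outcomes — before normalization. This is
  where counts exist, so it is the only consistent placement.
- **Gene subsampling**: optionally each EM iteration draws `n_subsample`
  sequences uniformly without replacement from the seeded RNG. The
  per-iteration likelihood is then a noisy estimate, so subsampled runs
  execute exactly `max_iterations` (default 200) and tolerate decreases;
  full-batch runs stop when the improvement falls below `convergence_delta`
  (default 1e-3). With no subsampling and zero pseudo-counts the trace is
  exactly monotone (tested to 1e-8).
- **Restarts**: initialization is not prescribed anywhere authoritative, so
  we use seeded random draws — emissions ~ Uniform(0.2, 0.8), transition
  rows and the initial distribution from normalized Gamma(5) draws — with
  `n_restarts` (default 3) runs keeping the best full-data log-likelihood.
  Draw order per restart: initialization first, then one subsample per
  iteration, all from one RNG seeded by `TrainingConfig.seed`, making runs
  bit-reproducible.
- A dead state (never visited under zero pseudo-counts) keeps its previous
  transition row and emissions rather than dividing by zero.

## Binarization

The top-Q% cutoff is an order statistic: the ceil(Q%·n)-th largest
non-missing value per column, with ≥-inclusion. Distinct values give exactly
ceil(Q%·n) present calls; a mass tied at the maximum exceeding Q% is coded
present in full (the tie rule), and ties at an interior cutoff are likewise
included — the simplest extension of the maximal-tie rule that is monotone
in Q. Score columns are dropped by QC when their missing fraction exceeds
0.5 or when more than half of their non-missing values are tied at the
maximum (such columns carry no usable top-Q% signal).

`binarize` also accepts an explicit value threshold. This exists because a
count-based cutoff can only reproduce a generator's present/absent bits
exactly when the column's marginal present rate is exactly Q%, which a
Bernoulli-emission HMM does not guarantee; the synthetic generator therefore
draws present scores uniformly in [1−Q/100, 1] and absent scores in
[0, 1−Q/100) and reports that boundary, and the exact round-trip
(binarize ∘ simulate = codes) holds at the reported threshold. Quantile-mode
binarization of simulated scores agrees except at the marginal-rate
boundary.

## Assignment

Enumerating all per-position allele choices is exponential, so each target
variant is assigned from N = 9 (default) local combinations over a window of
k = 3 (default) positions per side, truncated at gene ends: the target's row
is fixed, flanking rows are drawn uniformly per combination, each
combination is decoded as a standalone chain starting from the model's
initial distribution, and the call is the posterior argmax at the target's
position. Argmax ties go to the lowest state index (deterministic); only
ties in the mode over combinations are broken uniformly at random. The
seeded RNG is split into separate flank-sampling and tie-breaking streams,
and variants are processed in (gene, pos, ref, alt) order, so annotation is
byte-reproducible. Segments are maximal same-state runs over all annotated
rows in that order; a one-call-per-position variant is available via
`segment_assignments(per_position=True)` since it is genuinely ambiguous
which convention published segment statistics use.

With uniform transitions the chain factorizes: the posterior at any interior
position is proportional to its own emission likelihood, so assignments
become a deterministic function of the variant's own codes — this closed
form is used as a correctness oracle in the tests.

## Characterization and evaluation defaults

- State summary groups cut the top-5 counts at lower bounds
  (ceil(0.8·M), ceil(0.15·M), 1, 0), generalizing the empirical cuts
  (35, 7, 1, 0) observed at M = 43.
- Cross-model state matching uses Pearson correlation of emission vectors
  (max per state, and Hungarian assignment when a one-to-one matching is
  needed); zero-variance profiles yield NaN.
- Enrichment counts variant rows by default; a unique-position mode exists
  because counting alleles vs positions is a genuine convention choice.
  Coordinates: a 1-based variant position p overlaps a 0-based half-open
  interval [start, end) iff start ≤ p−1 < end; conversion is centralized.
- Paired evaluations: one-hot states enter as K−1 indicators plus intercept
  (identical fits, stable solvers). Logistic models use a weak ridge
  (C = 1e3), identical for both feature sets so the comparison is fair.
  The overall AUROC pools out-of-fold predictions rather than averaging
  per-fold AUROCs. Rows missing the evaluated score are dropped per score
  and counted. Rank orientation is 1 = most damaging everywhere; DMS values
  are rank-scaled within protein, predictor scores across proteins, with
  the fitness-assay convention (lower raw value = more damaging) as the
  default orientation.
- In `compare_assignments`, identical segment-length samples give a
  one-sided Mann–Whitney p of ~0.5 (slightly above with tie corrections);
  the identity case is asserted as p > 0.45.

## The synthetic world

The generator's defaults are the scales the test suite states: K = 4 states,
M = 8 scores, 300 genes × 80 positions, transition stickiness 0.7 (diagonal
mass, remainder uniform — a doubly stochastic chain, so the stationary
distribution is uniform), 10% missing, Q = 10. Emission profiles assign each
state ~0.8 on the features it owns (features modulo K), ~0.4 on a few random
extras, ~0.05 elsewhere — separable (pairwise Pearson < 0.8 across seeds)
yet overlapping. Labels follow logistic(a·score + b_state + b0) and DMS
values c·score + d_state + Gaussian noise, with the per-state offsets
returned as ground truth.

What a green test does **not** establish: the generator makes no attempt at
realistic gene structure, codon-consistent amino-acid substitutions,
realistic inter-score correlation beyond the shared state, informative
missingness, or class imbalance like real pathogenic/benign sets. Tests on
this world certify the algorithms, not biological performance.

## Known limitations

- Binarization discards within-top-Q score magnitude; the annotation is a
  hard state call (the posterior itself is computed but only the argmax and
  vote counts are exported).
- Initialization and the subsampled-likelihood estimator of the original
  segmentation software are not public; our seeded scheme is a substitute,
  so learned models agree with that software in distribution, not bitwise.
- Mode assignment with small N can be unstable for variants whose posterior
  is nearly flat; `n_mode_votes` and `tie_broken` are exported so such calls
  can be filtered.
- Training fixes one variant-per-position sample per run; resampling across
  EM iterations would require re-invocation with a new seed.
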