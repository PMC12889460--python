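# missense-states

Discrete **prioritization states** for missense variants, learned from the
combinatorial patterns of many pathogenicity predictors.

Dozens of computational predictors score every possible missense variant, and
they frequently disagree: a variant can sit in the top decile of one score
and the bottom half of another. Ensemble methods collapse this disagreement
into yet another single number. This package instead models it: a
multivariate hidden Markov model is laid along each gene's missense
positions, each score is binarized to "prioritized / not prioritized /
missing", and the learned hidden states correspond to interpretable
*combinations* of which predictors flag a variant — "flagged by everything",
"flagged only by conservation scores", "flagged by nothing" — while the
transition parameters exploit the tendency of neighboring variants in a
protein to share a state.

## Model

For a gene with positions $t = 1..T$ carrying one variant each, the
observation is a vector $S_t \in \{0,1,2\}^M$ over $M$ rank-scaled scores:
$S_{t,n}=1$ if the variant is in the top $Q\%$ for score $n$, $0$ if scored
but not prioritized, $2$ if missing. The HMM has $K$ states with initial
distribution $\pi$, transition matrix $A$, and independent Bernoulli
emissions $p_{k,n}$:

$$P(S_t \mid z_t = k) = \prod_{n=1}^{M} p_{k,n}^{[S_{t,n}=1]} (1-p_{k,n})^{[S_{t,n}=0]}$$

with missing features contributing a factor of 1. Parameters are learned by
Baum–Welch (optionally with per-iteration gene subsampling and pseudo-counts;
multiple seeded restarts). Each variant is then assigned a state by posterior
decoding over $N$ randomly sampled "local combinations" of a $k$-position
window around it, taking the mode of the per-combination calls. States are
characterized by fold enrichments against interval annotations,
$(B_{s,a}/B_s)/(B_a/B_{total})$, amino-acid substitution preferences, and by
how much predictive information they add to any individual score in paired
cross-validated evaluations.

## Worked example

```bash
python examples/01_simulate_and_train.py
```

```
simulated 24000 variants in 300 genes with 8 scores (10% missing)
built 300 per-gene training sequences (one random variant per position, 24000 positions total)
EM converged after 16 iterations, log-likelihood -70417.2
after state matching: mean |emission error| = 0.0034, mean |transition error| = 0.0039
errors near zero mean the learned states are the generating states, up to relabeling
```

A known 4-state model generates scores for 24,000 variants; training a fresh
model from the binarized scores recovers the generating emission and
transition parameters to within 0.004 mean absolute error (states are
matched by Hungarian assignment on emission-profile correlation, since HMM
state labels are arbitrary).

```bash
python examples/02_annotate_variants.py
```

```
annotated 3200 variants into 4 states; 95.9% match the generating state
971 segments, mean length 3.30 variants
uniform transitions reassign 6.2% of variants; mean segment length drops from 3.30 to 2.51 (one-sided Mann-Whitney U p = 2.98e-15)
```

The second block quantifies the value of spatial context: replacing the
learned transitions with uniform ones changes 6% of assignments and breaks
long same-state segments, confirming the chain structure carries information
beyond each variant's own scores.

The remaining examples show state characterization (`03_characterize_states.py`:
emission ranking into groups, fold enrichment for a BED annotation,
substitution preferences) and predictive evaluation
(`04_predictive_evaluation.py`: paired AUROC / Spearman with and without
one-hot state features, and the per-state probability that a high-scoring
variant is pathogenic).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch under the given seed — simulates
the default world, binarizes, trains with 3 restarts, annotates every
variant under the learned and uniform-transition models, computes fold
enrichments against a designed annotation, and runs the paired
classification/regression evaluations — printing each stage's key numbers
and writing the results manifest to `--out`.

## Layout

- `src/missense_states/hmm.py` — Bernoulli-emission HMM: scaled
  forward–backward, Baum–Welch with subsampling/pseudo-counts/restarts
- `src/missense_states/encode.py` — score QC, rank scaling, top-Q%
  binarization, per-gene training sequences
- `src/missense_states/annotate.py` — local-combination mode assignment,
  uniform-transition comparison, segmentation
- `src/missense_states/characterize.py` — emission summaries, fold
  enrichment, substitution preferences, cross-model matching
- `src/missense_states/evaluate.py` — paired classification/regression
  evaluations, conditional positive probabilities, rank-by-state profiles
- `src/missense_states/synthetic.py` — ground-truth simulators for all of
  the above
- `src/missense_states/io.py` — plain-text readers/writers (variant TSV,
  BED, model files, codes, assignments) and the run configuration

See `docs/methods.md` for modeling assumptions, parameter defaults and known
limitations.
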