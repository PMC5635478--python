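# Methods

## Data model and distant supervision

The unit of analysis is a relation tuple `(drug CUI, key phrasal
pattern, event CUI)` extracted upstream from one sentence; the pattern
is the hyphen-joined predicate phrase linking the two entities and
exists in a surface and a lemmatized form. A seed knowledge base of
`(drug, event, label)` facts provides entity-level supervision: any
pair attested with *both* labels across the merged sources is removed
before lookup (no source-priority resolution is attempted), every
tuple whose pair survives the lookup joins a labeled bag carrying the
seed label, and all remaining tuples form unlabeled bags. Bags are
keyed corpus-wide by the exact CUI pair, so labeling partitions the
tuple set and a pair can never appear in two bags. Bag ids derive
deterministically from the pair.

This silver standard is noisy by construction: a sentence can mention
a (drug, event) pair without expressing the entity-level relation.
That noise is the reason for the MIL layer rather than something the
labeling step tries to repair.

## Features

Five representations: lexical form S/L × granularity P/W, plus BOW.
Phrase granularity always yields exactly three tokens — the structural
precondition of the dependency model. BOW tokenization lowercases,
strips punctuation and stop words (configurable list) and expects
entity spans already CUI-substituted in `sentence_text`; the TF
normalizer `|x|` counts retained tokens (after stop-word and
out-of-vocabulary removal). IDF uses the natural log; the base only
rescales TFIDF weights but is fixed for reproducibility. Vocabulary
and IDF statistics come from the training partition: labeled bags in
supervised mode, labeled ∪ unlabeled in transductive modes (which
legitimately see the unlabeled set at training time). Unknown tokens
at predict time are dropped; Laplace smoothing in the models covers
the unseen-term mass.

## iEM

Standard multinomial naive Bayes trained by EM. The exponent `N(w,x)`
is the active weighting model's weight, which generalizes raw counts
so that B/TF/TFIDF genuinely change the model. The M-step adds λ
(default 1.0, λ > 0 required) to every posterior-weighted count.
Posteriors are computed in log space (underflow is the obvious failure
mode past a few dozen tokens). Distant-supervision labels are clamped
one-hot throughout EM; only unlabeled posteriors move. Convergence:
the maximum absolute change of any free posterior < 1e-7, or 50
iterations — the convergence constant is stated by the method, the
monitored quantity (posterior delta) is this package's choice, and the
trace also records the log likelihood.

A note on monotonicity: with Laplace smoothing the M-step is the
Dirichlet(λ+1) MAP update, so the EM ascent guarantee applies to the
*smoothed* objective `log-likelihood + λ·Σ log θ`, which the trace
records as `penalized_objective` alongside the raw observed-data log
likelihood. The raw trace is non-decreasing in practice but can dip by
~1e-4 on some inputs; the penalized trace cannot, and that is the
quantity the test suite asserts.

## dEM

The dependency representation replaces the independence product with a
γ-weighted mixture of all six chain-rule factorizations of
`p(q, r, s | c)` over the fixed roles q = drug, r = pattern,
s = event (the model refuses W/BOW inputs). Pairwise and triple
conditionals are interpolated toward lower-order estimates with β (2
weights) and α (4 weights). All three weight vectors are fixed
hyperparameters, not learned by EM.

Raw tables are posterior-weighted co-occurrence counts: the raw
pairwise numerator for `p(w|g,c)` is `λ + Σᵢ N(w,xᵢ)·1[g ∈ xᵢ]·pᵢ(c)`
and the denominator sums the same restricted counts over the whole
vocabulary (`λ|W| + …`), so every conditioning context is a proper
distribution and the estimator reduces to the textbook conditional MLE
when posteriors are one-hot. Conditioning is a membership test, so an
instance whose roles repeat a token feeds each distinct context
exactly once. A context never seen in a class backs off to the
λ-uniform table. Triple contexts are unordered pairs; the six
factorizations share one β and one α.

Defaults follow the best reported setting:
γ = [0.45, 0.02, 0.45, 0.02, 0.04, 0.02], β printed as a 4-vector
[0.97, 0.02, 0.01, 0.00] (the first two entries are kept and
renormalized, since the pairwise interpolation defines two weights),
and α printed as a 2-vector [0.10, 0.90] (mapped to (α₁, 0, 0, α₄)).
Both printed-length and equation-length vectors are accepted.

Implementation: the E-step is vectorized (dense pairwise count arrays,
flat-indexed sparse triple-context arrays); the public scalar
likelihood reads the same parameter object, and the tests pin the two
paths to each other and to an independently coded brute-force
enumeration at 1e-12.

## MIL aggregation and training modes

Bag scores are per-class maxima of member-instance posteriors; the
label is the class with the larger maximum and exact ties go to ADR,
the positive class. The per-class maxima need not sum to one — the
aggregation reflects the relaxed assumption that the most confident
instance of the bag's polarity should dominate.

Supervised mode fits on labeled bags only (with all posteriors
clamped, one M-step is the fixed point) and then scores unlabeled
bags. Transductive modes initialize unlabeled posteriors (supervised
predictions for `t_pml`; 0.5 for `t_p05`; Uniform(0,1) draws from the
run's single seeded generator for `t_prandom`) and run EM over the
union. Hard decision making re-thresholds free posteriors to one-hot
every iteration — the reading under which it changes training rather
than only the final call; soft posteriors flow through unchanged. In
evaluation the held-out test fold plays the role of the unlabeled set.

## Pattern scoring

`S = sign(0.5 − p(IND|pattern)) · (1 − H)` with H the binary entropy
in bits of the pattern's empirical class distribution over labeled
instances, `0·log 0 ≡ 0` and `sign(0) = 0`. Scoring is analytical and
selection (|S| > threshold, default 0.2 since no canonical threshold
exists) does not by default remove instances from training; an
explicit pruning helper is provided because the interplay between
selection and training is ambiguous in the source method — neither
behavior is asserted as canonical.

## Synthetic data

The generator is the package's test bed; its defaults are the study
conditions of the experiments. Defaults: 60 drugs, 60 events, 40
patterns, bag sizes 1 + Poisson(mean_bag_size − 1) with mean 2,
balanced classes, pattern purity 0.9, noise 0.05, KB coverage 0.5.

*Non-interaction regime.* Conditional on the bag label, the drug is
uniform (class-neutral), the event comes from a class-conditional
distribution in which each event is predominantly one relation type
and crosses over to the opposite label at the corpus's contradiction
level (`noise_rate`) — reflecting that real clinical events lean
strongly ADR or IND without fully determining the label — and each
instance's pattern comes from the label's distribution, or the
opposite one with probability `noise_rate` (within-bag noise). A
`pattern_purity` fraction of patterns is class-exclusive; the rest are
ambiguous and used by both classes at half an exclusive pattern's
per-class rate (their usage splits). Tokens are independent given the
class, so the naive-Bayes assumption holds exactly and iEM estimates
converge to the generating distributions as the sample grows.

Because event statistics are estimated per event, the event vocabulary
is kept dense enough (60 events) that wrong-class event counts are not
spuriously zero; an early bimodal-Beta affinity design produced rare
but fatal label-contradicting events through exactly that sparsity and
was replaced by the two-sided crossover design. Tying the crossover to
`noise_rate` also makes the noise-free purity-1 corpus exactly
separable, which the separable-limit tests rely on.

*Interaction regime.* Drugs split into two groups and the pattern
block each class uses swaps between groups, so the class marginals of
drugs, patterns and events are all uninformative and only the
drug–pattern joint carries the label — a structure the dependency
representation can model and the independence model cannot. Events
carry no signal here by design, to isolate the joint effect.

What the generator does *not* emulate: clinical language (sentences
are templated), entity-recognition errors, pattern extraction noise,
per-document structure, and heavy-tailed vocabulary frequencies.
Passing tests therefore demonstrate correctness of the machinery and
the models' relative behavior under the assumed structure, not
clinical-grade accuracy.

## Experiment fixtures and tuned weights

Problem sizes were chosen to keep the full test suite and the
reproduction script fast at one CPU while keeping count tables dense
enough to be estimable:

* recovery experiment — 2,000 bags, purity 0.95, noise 0.05, coverage
  0.5; supervised iEM, stratified 5-fold bag-level CV;
* dependency experiment — interaction regime, 1,500 bags of mean size
  3, 40 drugs / 40 events / 24 patterns, full coverage, no noise; five
  evaluation seeds;
* transduction experiment — defaults with 800 bags and coverage 0.2,
  warm-started transductive iEM vs supervised, five seeds.

For the dependency experiment the interpolation weights were tuned by
grid search on a dedicated tuning seed never reused for evaluation —
mirroring the original protocol, which also re-tuned β/α per setting —
and frozen at β = (0.1, 0.9) with γ and α at their defaults. At
desk-scale counts the default β₂ = 0.02 leaves the likelihood
unigram-dominated, and sparse triple contexts contribute a mild
anti-signal for held-out instances (a present context with an unseen
target scores below the absent-context uniform back-off); a pairwise-
dominant β exposes the drug–pattern joint directly. This is a known
small-sample property of the back-off estimator, not of the mixture
representation itself.

## Numerical choices and degenerate inputs

λ defaults to 1.0 everywhere and is configurable per model. Empty
instances fall back to the class priors. Precision with zero predicted
positives is reported as 0 with a warning, not NaN. Stratified folds
are deterministic given the seed; all randomness flows from explicit
seeds through owned generators (no global state). Mixture weights are
validated (non-negative, renormalized, Σ = 1 within 1e-9) at load.
Cross-validation splits at the bag level only — instance-level splits
would leak (drug, event) pairs across folds.

## Known limitations

Two classes only (the tables are sized generically but everything is
tested for ADR/IND). γ/β/α are not learned. No negation or hedge
handling, no cross-sentence relations, no semantic-group checking of
CUIs (assumed done upstream). The dEM advantage demonstrated on the
interaction fixture depends on pairwise-dominant interpolation
weights; with the published defaults the advantage requires far larger
corpora than the fixtures used here.
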