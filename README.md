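# adrmil

Distant supervision and multiple-instance EM classifiers for labeling
drug–event relations in clinical text as **adverse drug reaction
(ADR)** or **indication (IND)**.

## The problem

Clinical notes mention drugs next to clinical events constantly, but a
sentence rarely says outright whether the event was *caused* by the
drug (an ADR) or was the *reason* it was prescribed (an indication).
Hand-labeling sentences at scale is impractical, so this package
labels data automatically: a seed knowledge base of known
(drug, event, label) facts — the kind exported from SIDER or
DrugBank — is joined against pre-extracted sentence tuples of the form
*(drug CUI, key phrasal pattern, event CUI)*, e.g.
`(C0033487, be-hold-due-to, C0020649)` for *"propofol was held due to
hypotension"*. All sentences sharing one (drug, event) pair form a
**bag**; the knowledge-base label applies to the bag (the entity
level), while individual sentences inside it may contradict it — the
classic multiple-instance learning (MIL) setting with noisy labels.

The package is aimed at pharmacovigilance / clinical-NLP researchers
who already have tuple extraction (NER, sentence splitting, open IE)
upstream and want the labeling, modeling and evaluation machinery.

## The models

Instance classification is generative, trained by EM with labeled
instances clamped to their distant-supervision labels:

* **iEM** — naive-Bayes independence:
  `p(c|x) ∝ p(c) · Π_w p(w|c)^N(w,x)`, where `N(w,x)` is the term
  weight under the active weighting model (Bernoulli `B`, `TF`, or
  `TFIDF`), and the M-step is Laplace-smoothed
  (`p(w|c) = (λ + Σᵢ N(w,xᵢ) pᵢ(c)) / (λ|W| + Σ_z Σᵢ N(w_z,xᵢ) pᵢ(c))`).
* **dEM** — an interpolated dependency representation over the role
  triple (drug *q*, pattern *r*, event *s*): the class-conditional
  likelihood is the γ-weighted mixture of all six chain-rule
  factorizations of `p(q,r,s|c)`, with pairwise conditionals backed
  off as `p(w|g,c) = β₁p(w|c) + β₂p_raw(w|g,c)` and triple
  conditionals as
  `p(w|g₁,g₂,c) = α₁p(w|c) + α₂p_raw(w|g₁,c) + α₃p_raw(w|g₂,c) + α₄p_raw(w|g₁,g₂,c)`,
  each raw table Laplace-smoothed (Σγ = Σβ = Σα = 1).

Bag labels come from the relaxed MIL aggregation
`p(y|B) = max_j p(y|x_j)` per class, argmax over classes, ties to ADR.
Besides purely supervised training (`sl`), three transductive modes
fold the unlabeled bags into EM, differing in how their posteriors are
initialized: from a supervised model's predictions (`t_pml`), at a
neutral 0.5 (`t_p05`), or uniformly at random (`t_prandom`). Decisions
can stay *soft* (full posteriors through EM) or be *hard*-thresholded
to one-hot labels each iteration.

A pattern-analysis utility scores each key phrasal pattern by
entropy-inverted polarity,
`S = sign(0.5 − p(IND|pattern)) · (1 − H(p(ADR|pattern)))` ∈ [−1, +1].

Because the clinical corpora this method targets are access-restricted,
the package ships a first-class synthetic generator that emulates their
statistical structure (bags, class-skewed patterns and events, partial
KB coverage, within-bag noise, and an optional drug–pattern interaction
regime that only the dependency model can exploit).

## Worked example

```python
from adrmil import (SynthConfig, generate, filter_ambiguous_seeds, label_corpus,
                    corpus_summary, FeatureConfig, TrainConfig, cross_validate)

tuples, seeds, truth = generate(SynthConfig(n_bags=400, kb_coverage=0.5, seed=42))
corpus = label_corpus(tuples, filter_ambiguous_seeds(seeds))
print(corpus_summary(corpus))

features = FeatureConfig(lex_form="L", granularity="P", weighting="B")
report = cross_validate(corpus, features, TrainConfig(model="iem", mode="t_pml"),
                        k=5, seed=42)
print(f"mean precision {report.mean_precision:.3f}  recall {report.mean_recall:.3f}  "
      f"F1 {report.mean_f1:.3f}  accuracy {report.mean_accuracy:.3f}")
```

prints

```
{'labeled_bags': 209, 'unlabeled_bags': 191, 'labeled_instances': 423,
 'unlabeled_instances': 390, 'adr_bags': 100, 'ind_bags': 109}
mean precision 0.953  recall 0.960  F1 0.955  accuracy 0.957
```

400 generated (drug, event) bags; half their pairs appear in the seed
KB, so distant supervision labels 209 bags (423 sentences) and leaves
191 bags unlabeled. A lemmatized phrase-granularity Bernoulli
representation with warm-started transductive iEM then classifies
held-out bags at 0.955 mean F1 over stratified 5-fold bag-level
cross-validation — each fold's test bags, labels hidden, serve as the
unlabeled set during that fold's EM.

The same pipeline is scriptable:

```bash
adrmil simulate --n-bags 400 --seed 42 --out-dir data/
adrmil label --tuples data/tuples.jsonl --seeds data/seeds.tsv --out data/bags.jsonl
adrmil score-patterns --tuples data/tuples.jsonl --seeds data/seeds.tsv --out patterns.tsv
adrmil cv --tuples data/tuples.jsonl --seeds data/seeds.tsv \
          --model dem --mode pml --features lp --weighting b --seed 42
```

File formats (tuple JSONL / seed TSV / bag JSONL / report TSV+JSON) and
the YAML experiment-config schema are documented in the module
docstrings (`adrmil.corpus`, `adrmil.evaluate`).

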