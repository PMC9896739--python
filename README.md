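# ddxrank

Listwise learning-to-rank for differential-diagnosis decision support.

## The problem

When a physician works up a difficult or rare-disease case, the productive
question is not "what single disease is this?" but "what is the ranked list
of diseases I should be considering?". That framing maps exactly onto
information retrieval: the patient's symptom set is the query, the candidate
diseases are the documents, and the system's job is to put the right
diseases near the top of the list. `ddxrank` implements that mapping as a
small, fully reproducible learning-to-rank engine for researchers studying
diagnostic decision support.

The training data are *graded* cases: each case records the observed
symptoms (in acquisition order) together with a relevance score for every
disease worth mentioning — the confirmed diagnosis scores highest, the
differential diagnoses (related diseases, or diseases important to rule out)
score lower, and everything else is implicitly zero. Real corpora of this
kind are private clinical assets, so the package ships a seeded synthetic
generator that reproduces their statistical shape.

## The model

A one-hidden-layer network scores every disease from a multi-hot symptom
vector x:

    s = W2 · relu(W1 x + b1) + b2        s ∈ R^{n_diseases}

Two loss functions train the *identical* network, so comparing them isolates
the effect of the loss:

- **ApproxNDCG (listwise).** Ranking quality is measured by NDCG with gain
  g(rel) and discount log2(1 + rank). NDCG is not differentiable — an item's
  rank is a step function of the scores — so each rank is replaced by the
  smooth estimate

      π̂_i = 1 + Σ_{j≠i} σ(α (s_j − s_i)),   σ = logistic,

  which is plugged into the DCG discount, normalized by the exact ideal DCG,
  and minimized as `loss = −ApproxNDCG`. As α → ∞, −loss converges to the
  exact ndcg. During training the surrogate is evaluated on per-list
  standardized scores, which keeps the sigmoid comparisons from saturating
  (see `docs/methods.md`).
- **MSE (pointwise baseline).** Mean squared error between the score vector
  and the label vector, disease by disease.

Evaluation follows k-fold cross-validation (default k = 5) on the evaluation
functions `ndcg`, `ndcg@5`, `ndcg@10`, `ndcg@20` and `mse`, plus a clinical
criterion: the fraction of cases whose confirmed disease lands in the top 10
suggestions, and progressive-input *rank trajectories* that replay a case's
symptoms one at a time and track a target disease's rank.

## Worked example

```python
from ddxrank import (DiseaseRanker, GeneratorConfig, LossConfig,
                     TrainConfig, generate_corpus, predict)

corpus = generate_corpus(GeneratorConfig(seed=7))   # 2000 cases, 200 diseases
res = DiseaseRanker(corpus, LossConfig(loss="approx_ndcg"),
                    TrainConfig(epochs=30, seed=0)).fit()
print(res.summary())

case = corpus.cases[0]
pred = predict(res.model, corpus.symptom_vocab, corpus.disease_vocab,
               case.symptoms, top_n=5)
print(pred.to_text())
```

prints

```
DiseaseRanker fit summary
=======================================================
loss function:        approx_ndcg (alpha=10)
network:              400 -> 64 (relu) -> 200
cases (train / val):  1600 / 400
optimizer:            adam, lr=0.01, batch=32, epochs trained=30
seed:                 0
-------------------------------------------------------
training-split evaluation functions:
  ndcg       0.9899
  ndcg@5     0.9853
  ndcg@10    0.9819
  ndcg@20    0.9868
  mse        11.0904
final validation:     ndcg=0.9114, mse=11.0566

Inputted symptoms: s328, s104, s176, s082, s004, s212, s213, s079, s025, s028, s218, s114, s130

rank    score  disease      code
   1     4.66  Disease 146  d146
   2     2.67  Disease 131  d131
   3     1.51  Disease 100  d100
   4     1.48  Disease 151  d151
   5     0.36  Disease 182  d182
```

The case's confirmed disease (`d146`) is ranked first; the diseases below it
are the model's differential list. The ndcg values are in [0, 1] (1 = the
model's ordering is label-optimal); `mse` is on the squared scale of the
relevance labels (confirmed = 17.0 by default), which is why the
listwise-trained model's mse is large — it optimizes ordering, not
calibration.

The same workflow is available from the shell:

```sh
ddxrank generate --out corpus.jsonl --vocab-dir vocab/
ddxrank train --corpus corpus.jsonl --vocab-dir vocab/ --out model.json
ddxrank predict --model model.json --vocab-dir vocab/ --symptoms s328,s104 --top 10
ddxrank trajectory --model model.json --vocab-dir vocab/ \
    --symptoms s328,s104,s176 --targets d146 --cutoff 10
ddxrank evaluate --corpus corpus.jsonl --vocab-dir vocab/ --out report.csv
```

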