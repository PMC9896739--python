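# Methods

This note documents the models, the synthetic data, and the numerical
choices behind `ddxrank`, in the spirit of a statistical package's model
documentation. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Ranking model

The scorer is deliberately minimal: a single hidden layer

    s(x) = W2 · relu(W1 x + b1) + b2

mapping a multi-hot symptom indicator x (dimension = symptom vocabulary
size) to one real score per disease (dimension = disease vocabulary size).
One hidden layer is enough because the learning problem is a smoothed
table lookup — symptom patterns to graded disease lists — and a deeper
network would only add variance on corpora of a few thousand cases.
Weights are He-initialized from the training seed; biases start at zero.
Hidden width defaults to 64 (`TrainConfig.hidden_dim`).

All randomness — initialization, the train/validation split, batch
shuffling — flows from `TrainConfig.seed` through `numpy.random.default_rng`,
so a fit is bit-reproducible on a fixed platform.

## Losses

### ApproxNDCG (listwise)

NDCG for one case with labels `rel` and scores `s` is

    DCG  = Σ_i g(rel_i) / log2(1 + rank_i),    NDCG = DCG / IDCG,

with gain g(r) = r by default (see "Gain choice" below) and 1-based ranks.
`rank_i` is a step function of the scores, so NDCG has zero gradient almost
everywhere. The surrogate replaces each rank by a sum of pairwise logistic
comparisons,

    π̂_i = 1 + Σ_{j≠i} σ(α (s_j − s_i)),

which is exact in the limit α → ∞ and satisfies Σ_i π̂_i = n(n+1)/2 for
every α (because σ(x) + σ(−x) = 1). The training loss is

    loss = − (1/IDCG) Σ_i g(rel_i) / log2(1 + π̂_i)  ∈ [−1, 0],

where IDCG is the *exact* ideal DCG (labels are constants; no smoothing is
needed there). Lists whose labels are all zero contribute loss 0 and zero
gradient (the same policy the `ndcg` metric uses). The steepness α defaults
to 10, the conventional temperature 0.1 of published implementations;
it is configurable because the right value depends on the score scale.

Gradients are analytic. Writing f(π) = 1/log2(1+π), the chain rule gives

    ∂loss/∂s_k = Σ_{i: g_i>0} c_i A_ik − c_k Σ_j A_kj,
    c_i = − g_i f'(π̂_i) / IDCG ≥ 0,
    A_ik = α σ'(α (s_k − s_i))  (symmetric, zero diagonal).

Only items with positive gain enter the DCG sum, so the implementation
builds the pairwise sigmoid tensor between those items and the full list —
shape (batch, positives, n) rather than (batch, n, n) — which is what makes
training on 200-disease lists cheap. Gradient correctness is verified
against central finite differences in the test suite (worst-case
norm-relative error well below 1e-4).

### Score standardization (a deliberate numerical choice)

Applied to raw scores, the surrogate has a failure mode: it can increase
−ApproxNDCG not only by fixing the ordering but also by inflating the score
gaps it already has, driving every σ(α Δ) to 0 or 1. Once saturated, the
gradient vanishes and training freezes with whatever misorderings remain.
We observed exactly this on separable corpora: training plateaued at ndcg
0.94–0.99 for every steepness (0.03–10), learning rate, capacity and weight
decay tried, while per-case score optimization from the same starting order
converged — the saturation, not the surrogate's minima, was the obstacle.

The fix used here: during training (and in the default loss configuration)
the surrogate is evaluated on per-list standardized scores,
z = (s − mean(s)) / std(s), with the chain rule carried through the
transform. Standardization is strictly monotone per list, so it changes no
ranking, none of the surrogate's limit/range/policy properties, and no
evaluation metric; it only removes the scale degree of freedom so ordering
pressure never dies. With it, the separable benchmark trains to ndcg 1.0.
The raw-formula surrogate remains available via
`LossConfig(standardize=False)` and is tested for the same gradient and
limit properties.

### MSE (pointwise baseline)

`mean_i (s_i − rel_i)²` per case, gradient `2(s − rel)/n`. The baseline
shares the network, the optimizer, the data splits and every
hyperparameter with the listwise system; only the loss differs. That
fairness contract is structural in `compare_systems` (one fold list, one
`TrainConfig`, two `LossConfig`s differing only in the `loss` field).

## Training loop

Mini-batch gradient descent with per-list losses averaged over the batch
(a listwise loss is a per-query quantity; batching averages queries).
Optimizer: Adam (β1 = 0.9, β2 = 0.999, ε = 1e-8) by default, plain SGD
optionally; learning rate 0.01, batch 32, 30 epochs by default. Optional
L2 weight decay on the weight matrices (off by default) and optional early
stopping on validation ndcg with a patience counter (off by default).
Non-finite batch losses abort training with an error naming the epoch.
Learning curves (ndcg and mse on the training and validation splits, per
epoch) are recorded on every fit and exportable to CSV.

## Metrics

`dcg`, `ndcg`, `ndcg@k`, `rank_of` and `topk_hit` use 1-based ranks,
discount log2(rank + 1) and descending-score order with ties broken by
vocabulary index (file order), making every ranking deterministic across
platforms. `ndcg` of an all-zero-label list is 0 by convention
(`MetricConfig.zero_ideal_policy`). Full-list `ndcg` runs over the entire
disease vocabulary; cutoffs 5/10/20 are the reported truncations.

Gain choice: identity gain g(r) = r is the default because relevance labels
here are real scores reaching 17+, for which the exponential gain 2^r − 1
overflows any reasonable dynamic range; the exponential gain remains
available for integer-graded data.

## Synthetic corpus generator

The generator emulates the structure of graded clinical case corpora, which
are not publicly distributable. Latent state: each disease has a
characteristic symptom profile (uniform size in `symptoms_per_disease`,
default 6–12, overlapping across diseases) and a prevalence weight drawn
from Gamma(shape 3, scale 1) — a few common diseases, a long rarer tail.
A case then:

1. draws its confirmed disease with probability proportional to prevalence;
2. observes each profile symptom independently with probability
   `sensitivity` (default 0.75), plus Poisson(`noise_rate`, default 1.5)
   off-profile symptoms drawn uniformly (at least one symptom is forced);
3. grades as differentials the `n_differentials` (default 5–9) other
   diseases whose profiles best overlap the observed symptoms (Jaccard
   similarity); ties break by circular code distance from the confirmed
   disease, then by index — deterministic, and avoiding the degenerate
   situation where zero-overlap ties hand every case the same low-index
   differentials;
4. scores the confirmed disease `confirmed_score` (default 17.0) and the
   r-th differential `confirmed_score · decay^(r+1)` (decay 0.7), giving
   score profiles of the magnitude and smooth decrease typical of graded
   relevance lists. The scheme is an invented, documented stand-in — real
   corpora do not publish their scoring formula — and is isolated in
   `GeneratorConfig`.

The default configuration (200 diseases, 400 symptoms, 2000 cases, seed 7)
is the standard study corpus used throughout the tests and the acceptance
script; 2000 cases keeps a full two-system 5-fold comparison around half a
minute while leaving ~10 cases per disease. `separable_config()` produces
the diagnostic limit: disjoint profiles, sensitivity 1, no noise — a corpus
a correct implementation must learn to rank perfectly.

`generate_trajectory_fixture` emits one case per target disease with
symptoms ordered least-specific-first (descending document frequency across
profiles), emulating a workup in which common findings arrive before
pathognomonic ones; it drives the progressive-input rank-trajectory
evaluation.

What the generator does *not* emulate: symptom co-occurrence beyond profile
overlap, temporal progression, age/sex structure, coding noise, and any
real epidemiology. Tests passing on synthetic corpora therefore demonstrate
correctness and internal consistency of the ranking machinery — not
clinical performance.

## Evaluation protocol

Case-level k-fold cross-validation (default k = 5, shuffled with a fixed
split seed via scikit-learn's `KFold`); per fold, train on the remaining
cases and average the evaluation functions over the held-out cases; report
per-fold values, means and standard deviations (the sd is reported because
scaled-down experiments need a noise estimate). The two-system report
(`compare_systems`) is the package's central deliverable: with everything
shared except the loss, the listwise system's ndcg family consistently
dominates the pointwise baseline's on the default corpus, while the
baseline wins on mse — each system wins its own objective, which is the
expected and tested direction.

The clinical-criterion report (`topk_report`) measures the fraction of
cases whose confirmed disease ranks within the top k (default 10) — the
threshold at which a suggestion list is plausibly useful in a differential
diagnosis workflow.

## Degenerate inputs and edge policies

- Empty corpora: readable and writable (header-only file); model
  construction rejects them.
- All-zero-label lists: ndcg 0 and loss 0 by policy.
- Single-item lists: π̂ = 1 exactly; surrogate gradient 0.
- Unknown symptom codes at prediction: hard error by default (silently
  dropping symptoms changes the ranking invisibly); opt-in warn-and-skip.
- Model archives embed vocabulary checksums and refuse to load against
  mismatched vocabularies.
- Score ties everywhere rank by vocabulary index.

## Known limitations

- Raw model scores are printed in prediction output; they are ordinal, not
  calibrated probabilities.
- The listwise model's mse on the label scale is large by construction;
  comparing systems on mse favors the pointwise baseline, on ndcg the
  listwise system. Both are reported.
- Bit-level reproducibility is per-platform (BLAS reduction order may vary
  across builds).
- Disease relatedness (which targets count as "related" in trajectory
  studies) must be supplied by the user; the package does not infer it.
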