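# Methods

## The model

The toolkit addresses a common pattern in clinical-NLP screening: texts
are embedded into high-dimensional numeric features, most dimensions are
redundant or noisy, and many moderately accurate classifiers are cheaper
to obtain than one excellent one. Two mechanisms carry the load.

### NCA feature weighting

The feature-selection variant of Neighborhood Component Analysis learns
a diagonal metric: each feature r gets a weight w_r, entering the
pairwise distance as w_r²·|x_ir − x_jr| (cityblock base distance). A
softmax over negative distances defines the probability p_ij that sample
i picks j as its reference neighbor; the objective is the average
probability of picking a same-class neighbor, minus an L2 penalty
λ·Σ w_r². Maximizing it pushes weight onto features along which classes
separate and shrinks the rest toward a common noise floor.

Assumptions: the signal is axis-aligned (a diagonal metric cannot
exploit correlated feature pairs), and classes form neighborhoods at the
scale set by the weights. Full metric-learning NCA (a dense
transformation matrix) is out of scope.

The gradient is closed-form; with D_ijr = |x_ir − x_jr|,

    dF/dw_r = (2 w_r / n) Σ_i [ p_i Σ_k p_ik D_ikr − Σ_{j∈class(i)} p_ij D_ijr ] − 2 λ w_r.

Fitting is per-sample stochastic gradient ascent: weights start at
all-ones, the step is 0.01/√epoch, up to 50 epochs, with early stop when
the relative epoch-end objective change stays below 1e-6 for three
epochs. The visit order is reshuffled each epoch from the seed, so a
(data, config) pair determines the weights bit-for-bit. Because weights
appear only squared, the fitted vector is stored as its nonnegative
representative. The softmax is computed with max-subtraction for
overflow safety.

λ defaults to 1/n, the documented default of the routine family this
implements; it keeps weights bounded without flattening the planted
signal at the sample sizes used here (weights ≈ 2.0 for informative vs
≈ 0.8 for noise columns on the default fixture).

### CWINCA subset search

Selection wraps the weights in a deterministic search:

1. min-max normalize every column to (x − min)/(max − min + ε),
   ε = 1e-8 — constant columns map to zeros instead of 0/0;
2. fit NCA weights on the normalized matrix;
3. rank features by descending weight (ties broken by ascending
   original position, making runs reproducible);
4. form the normalized cumulative weight and take the first size
   reaching 0.5 as the window start and the first reaching 0.999 as the
   stop. When the thresholds are unreachable (total weight zero) the
   start falls back to 10 — clamped to d for narrow matrices — and the
   stop to d;
5. score each prefix size in the window with the misclassification rate
   of a 1-NN cityblock classifier under seeded stratified 10-fold CV,
   with per-fold standardization fit on the training fold only (fitting
   scalers on held-out folds would leak);
6. keep the smallest size attaining the minimal loss (first-minimum
   tie-break prefers parsimony).

The candidate subsets are nested prefixes, so the search is linear in
the window width, and the whole trace (ranking, cumulative weights,
window, per-size losses, chosen subset) is recorded.

The 1-NN predictor is implemented directly (scipy distance matrix +
argmin) rather than through a library classifier so that equal-distance
ties resolve to a defined rule — lowest training index — which the
brute-force test oracles share. Fold assignment is stratified by class;
when a class has fewer members than folds it degrades to plain k-fold
with a logged warning rather than failing.

Two leakage postures are offered. The default replicates the
conventional order — select on the full matrix, then cross-validate
classifiers — which optimistically biases downstream accuracy because
selection saw every label. `nested_selection_loss` (CLI `--nested`)
re-runs the entire selection inside each outer training fold and scores
the held-out fold on that fold's subset, giving the statistically sound
estimate. Selected columns of the normalized matrix are passed forward
unchanged; no re-normalization after selection.

### Classifier bank and prediction vectors

Each feature set is scored by a bank of seeded classifiers under
stratified k-fold CV: polynomial-kernel SVM (degree 3, C = 1 — the
conventional cubic default), the shared 1-NN, a CART tree, a
one-hidden-layer MLP (100 units), L2 logistic regression, and bagging
over 30 trees. Only out-of-fold predictions are recorded: each sample's
label comes from a model that never trained on it, so the attached
accuracies are honest and usable for ensemble ranking.

### IHMV voting

Prediction vectors are sorted by accuracy (ties by original order) and
mode-voted at every depth k = 3..m; the labeling with the highest
accuracy wins, smallest k on ties. k starts at 3 because smaller
ensembles degenerate to single-model or tie-dominated voting; when
m < 3 only k = m is evaluated. Votes within an ensemble are unweighted —
the "hybrid" character lives in the accuracy-based ranking and depth
selection, not in fractional vote weights; a weighted variant can be
layered on `mode_vote` without changing the sweep. A tied mode resolves
to the vote of the best-ranked model among the tied labels' voters, then
to the smallest label in canonical order. Since k = m is always
evaluated, the result dominates the plain all-model vote by
construction. At deployment, where truth is unavailable, `vote_with_k`
applies a depth frozen during calibration.

### Metrics

Confusion matrices use rows = true class, columns = predicted, over the
sorted union of observed labels. Precision, recall and F1 are reported
per class and macro-averaged (unweighted class means), as percentages.
A class never predicted gets precision 0 with a logged warning rather
than NaN.

## Text frontend

Cleaning lowercases, strips punctuation and symbols, collapses runs of
three or more identical characters to two ("soooo" → "soo"), removes
stopwords from a pinned built-in English list (an explicit input, so
runs are reproducible), and rejoins tokens with single spaces; the
operation is idempotent. Spelling correction is a deliberate no-op hook:
no dictionary is pinned, and a silent aggressive corrector would be
untestable. Texts that clean to empty are dropped with a logged count.

Two embedding backends: transformer adapters (lazy imports; mean
pooling of the final hidden layer by default, CLS optional) and a
dependency-free hashing backend that maps unsalted token hashes into a
fixed-width signed-count vector. The hashing backend is the tested
path — deterministic, fast, and sufficient to exercise every downstream
stage; transformer adapters raise a clear error pointing at it when
their dependencies are absent. Per-backend matrices concatenate
column-wise into a combined feature vector (label vectors must match
exactly; no silent alignment).

## Synthetic generators — what they emulate and what they do not

`make_planted_features` draws class-conditional Gaussians: informative
columns have class means separated by `class_sep` (default 2.0)
within-class standard deviations, noise columns are label-independent
standard normals, classes balanced to ±1. This is the simplest regime in
which weight-based recovery is expected, and it mirrors the moderate,
axis-aligned separability that sentence embeddings of distinct content
classes exhibit. Defaults (n = 200, 3 informative + 17 noise) keep
recovery nontrivial — noise columns outnumber signal 5.7:1.

`make_prediction_ensemble` plants per-model accuracies with errors
independent across models and uniform over wrong labels — the Condorcet
regime in which majority voting provably helps. Real classifier banks
have correlated errors, so voting gains on real data will be smaller
than on these fixtures.

`make_text_corpus` gives each class a token pool with a controllable
shared fraction; texts are 5–20 tokens long. It contains no syntax,
polysemy, code-switching or platform idiom. Passing tests on these
generators therefore demonstrates the algorithmic contracts — recovery,
dominance, determinism — not clinical-grade performance on real
social-media text, which depends on embedding quality and label noise
the generators deliberately exclude.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds carried in
the config objects; reports serialize with sorted keys so identical runs
are byte-identical. Oracle-equivalence tests use exact equality: the
implementation and its brute-force counterparts share the tie rule and
the train-only standardization formula, so their error counts coincide
integer-for-integer. Test and acceptance workloads use n ≤ 200, d ≤ 128,
5–10 folds, and 10–100 replicate seeds — sizes chosen so the full
recovery and voting distributions are exercised in seconds while leaving
the algorithms' asymptotics untouched.

## Known limitations

- The NCA solver is plain SGD; no mini-batching or second-order
  acceleration, so fits scale as O(epochs · n² · d).
- The diagonal metric cannot credit features that are informative only
  jointly.
- The default pipeline reproduces the conventional select-then-CV order
  and inherits its selection bias; use the nested mode for unbiased
  estimates.
- IHMV needs labeled data to choose k; deployment requires a calibration
  run.
- The hashing embedder ignores word order and semantics entirely; it is
  a testing and baseline device, not a substitute for contextual
  embeddings on real corpora.
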