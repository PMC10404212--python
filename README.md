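# incfrnn

Incremental fuzzy-rough nearest neighbour (IncFRNN) brainprint
authentication: EEG distraction-descriptor extraction, correlation-based
feature selection, fuzzy-rough classification, and incremental
training-pool update strategies evaluated under an imbalanced streaming
protocol.

## The problem

EEG-based person authentication ("brainprint") must operate on a signal
that is nonstationary: a person's EEG response drifts within and across
sessions, so a static training pool goes stale. Incremental instance-based
learners refresh the pool as authentication attempts stream in — but the
standard update strategies are either impractical (inserting misclassified
objects requires the *true* label, which an authentication system never
has) or harmful (FIFO insertion/eviction is label-blind and, on the heavily
imbalanced client-vs-impostor streams of a many-user system, can wash every
client exemplar out of the pool).

This package implements a label-free, probability-based update strategy for
the fuzzy-rough nearest neighbour classifier, alongside the two reference
strategies (actual-class and FIFO/KNN), plus the full signal path that
feeds them: a "distraction descriptor" of spectral features computed on
alpha (8–13 Hz) and beta (13–30 Hz) band EEG from occipito-temporal
channels (T5, T6, O1, OZ, O2).

## The method

**Classification.** Similarity between objects is the fuzzy tolerance
relation

    R(x, y) = min_a ( 1 − |a(x) − a(y)| / (a_max − a_min) ),

the minimum over attributes of range-normalised closeness. A test object
*y* is scored against each class *C* through its fuzzy lower and upper
approximations over the k = 5 most similar training objects,

    (R↓C)(y) = min_x I(R(x, y), C(x)),   (R↑C)(y) = max_x T(R(x, y), C(x)),

with the Kleene–Dienes implicator I(a, b) = max(1 − a, b) and minimum
t-norm T(a, b) = min(a, b); the predicted class maximises
(lower + upper) / 2.

**Probability-based update.** After each prediction the pool may absorb the
test object. The decision combines the relative difference D between the
top two neighbour similarities, a threshold

    Threshold = 0.5 · Σᵢ (Simᵢ − Simᵢ₊₁) / ((Simᵢ + Simᵢ₊₁) / 2)

over the retrieved neighbour list, and usage-weighted class probabilities
P(Cᵢ) built from per-object frequency counters. The object is inserted
(under its *predicted* label — no ground truth is read) iff D > Threshold
and the prediction disagrees with the most probable class, or D < Threshold
and they agree. When a window size W > 0 caps the pool, the least-used
object (FIFO among ties) is evicted.

**Evaluation.** Inverse 10-fold cross-validation: each fold uses one
stratified tenth as the initial pool and streams the other nine tenths
prequentially (classify, then update). Client is the positive class;
reported metrics are AUC, accuracy, recall, precision and F-measure, with
Anderson–Darling normality checks and paired t-tests for strategy
comparisons. Because the original 45-subject EEG corpus is not public, the
`synthetic` module generates both raw EEG-like sessions (subject-specific
alpha peaks, stimulus phase-locking, channel coupling, artefact trials) and
feature-space streams with the 1:44 client:impostor imbalance and drift.

## Worked example

Stream one fold of a synthetic 45-subject session (6 750 objects, 150 of
them the client's) through the probability-based learner with the 60%
window (4 050 objects):

```python
from incfrnn import (
    simulate_feature_stream, inverse_tenfold_split, stream_run,
    UpdateConfig, Strategy,
)

table = simulate_feature_stream(seed=1)          # 6750 x 12 features + class
train, stream = inverse_tenfold_split(table, seed=1)[0]
report = stream_run(
    table, train, stream, "frnn",
    UpdateConfig(k=5, window_size=4050, strategy=Strategy.PROBABILITY),
)
for name, value in report.metrics.items():
    print(f"{name:10s} {value:.4f}")
print("final pool size:", report.final_pool_size,
      " objects inserted:", report.n_inserted)
```

prints

```
auc        0.8189
accuracy   0.9462
recall     0.3630
precision  0.1690
f_measure  0.2306
final pool size: 4050  objects inserted: 4144
```

The accuracy (0.946) is close to the 0.978 a constant all-impostor
predictor would score on this 1:44 stream — the imbalance makes accuracy
nearly meaningless, which is why recall and F-measure carry the
comparisons. Recall 0.363 means the learner recovers over a third of the
client's authentication attempts while never seeing a true label; a
FIFO-windowed KNN on the same stream falls below 0.01 (client exemplars
are evicted blindly). Per-seed results vary widely with how separable the
sampled client happens to be from its 44 impostors.

A command-line interface wraps the same stages:

```sh
incfrnn --seed 1 simulate                 # synthetic feature stream
incfrnn --seed 1 stream --table <stream.csv>
incfrnn --seed 1 compare --table <stream.csv> --n-seeds 3
```

## Layout

- `incfrnn.pool` — training pool, frequency counters, attribute ranges
- `incfrnn.frnn` — fuzzy tolerance relation, lower/upper approximations
- `incfrnn.strategies` — probability-based and actual-class updates
- `incfrnn.knn` — Euclidean KNN with FIFO window (benchmark)
- `incfrnn.descriptor` — FIR filtering, epoching, PSD/WPS/coherence
- `incfrnn.cfs` — correlation-based feature selection
- `incfrnn.evaluate` — splits, prequential runs, metrics, significance
- `incfrnn.synthetic` — EEG session and feature-stream generators
- `incfrnn.io`, `incfrnn.config`, `incfrnn.cli` — formats, manifests, CLI

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
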