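# Methods

This note records the model, the defaults, and the places where the design
was genuinely open — what the package computes and why, in enough detail to
audit or change it.

## Classifier

The fuzzy tolerance relation divides each per-attribute absolute
difference by that attribute's observed range (`a_max − a_min`) and takes
the minimum over attributes, so one discordant attribute dominates. Test
objects arriving from a stream can fall outside the recorded range; they
are clamped into it before the division, keeping every similarity in
[0, 1]. A zero-width range (constant attribute) contributes similarity 1:
a constant attribute cannot discriminate.

The lower/upper approximation operators are the Kleene–Dienes implicator
`max(1 − a, b)` and the minimum t-norm, the pair used by the original
fuzzy-rough nearest neighbour formulation; class memberships are crisp.
The decision rule is the argmax of `(lower + upper)/2`, with ties resolved
by the larger upper approximation and then lexicographic label order. With
these operators `lower ≤ upper` is *not* guaranteed for a class absent
from the neighbour list (lower can be `1 − max sim` while upper is 0);
only the [0, 1] bounds are asserted.

Neighbour ranking breaks similarity ties by smaller insertion index, so
predictions are deterministic and independent of physical storage order.

## Probability-based update

Order of operations per test object (`strategies.apply_probability_update`):

1. retrieve `min(k + 1, pool size)` neighbours — the threshold sum over
   `i = 1..k` references `Sim_{k+1}`, so k + 1 similarities are needed for
   the k consecutive pairs; on smaller pools the sum simply truncates;
2. `D` = relative difference of the top two similarities (the same
   functional form as the threshold's summand);
3. class probabilities from the counters *before* this step's usage
   increment (the ordering is a package decision; nothing downstream
   depends on the alternative beyond shifted probability values);
4. increment the usage counters of the top k neighbours;
5. insert iff (`D > Threshold` and predicted ≠ most-probable class) or
   (`D < Threshold` and predicted = most-probable class); equality never
   inserts (both conditions are strict). Inserted objects carry the
   **predicted** label — at authentication time no true label exists;
6. while a positive window is exceeded, evict the least-used object,
   first-in-first-out among counter ties.

Counters start at 1 on insertion so the per-class counter mass in the
probability denominator cannot be zero for any class present in the pool.
The probability expression is not a normalised distribution; only its
argmax is consumed. If the predicted class ties for that argmax it is
taken as the most-probable class (this favours the "agreement" insertion
condition); other ties resolve lexicographically.

Cold start: a pool with fewer than two objects cannot furnish the two
similarities `D` needs, so the object is inserted unconditionally.

Attribute ranges only widen; deletion does not shrink them. An exact
recompute after each deletion would cost O(n·d) per step, and a widened
range changes similarities only by a bounded monotone rescaling (all stay
in [0, 1]). `pool_delete_least_used(..., exact_stats=True)` recomputes
exactly when wanted.

The actual-class strategy inserts the object under its true label whenever
the prediction was wrong, and shares the counter and eviction machinery.
The KNN benchmark votes over Euclidean neighbours (vote ties to the single
nearest; no distance weighting) and always inserts, evicting the oldest
object past the window; its insert-label mode defaults to the predicted
label to mirror the no-ground-truth setting, with an actual-label mode
available since instance-based reference implementations historically
consume labelled instances.

## Distraction descriptor

Preprocessing: odd-length windowed-sinc FIR bandpass (default 513 taps at
512 Hz ≈ 1 s impulse response, adequate for the 8 Hz lower edge), applied
by reflection-padded convolution so the output is time-aligned and
length-preserving; 1 s epochs cut from each trial onset; trials whose
absolute amplitude exceeds 100 µV on any channel are discarded (a peak of
exactly 100 µV is kept — the screen is strictly "larger than").

Three feature families per alpha/beta band:

- **PSD shape features** — computed on the raw-FFT power spectrum
  `P(k) = |X(k)|²/N` (rectangular window, no zero padding; Parseval holds
  to rounding). The literature names "concavity of the spectral
  distribution", "variance of spectral power" and "nondominant region of
  the power spectrum" without formulas; the operationalisations here are
  explicit surrogates and should be read as such: concavity is the
  quadratic coefficient of a least-squares parabola on
  `log10(P + 1e−12)` over in-band bins; power variance is the variance of
  in-band `P`; the nondominant ratio is 1 minus the fraction of in-band
  power within ±1 Hz of the in-band peak.
- **Wavelet phase stability (WPS)** — complex Morlet (ω₀ = 6, the standard
  time–frequency trade-off) at the band-centre frequency; per time point,
  the modulus of the trial-averaged unit phasor of the wavelet phase;
  the scalar is the time average over the epoch interior (half a wavelet
  support, 2σ of the Gaussian envelope, excluded at each edge). 1 means
  perfect inter-trial phase locking; M random-phase trials give
  ≈ 1/√M.
- **Coherence** — per-trial Hann-tapered auto- and cross-spectra averaged
  across trials before forming `|Pxy|²/(Pxx·Pyy)` (single-segment
  coherence is identically 1, hence the two-trial minimum and the taper to
  control leakage); the feature is the in-band mean, clipped to [0, 1].

Granularity: one descriptor object per trial, so a 45-subject × 150-trial
study yields the ≈ 6 750 objects the streaming protocol assumes. WPS and
coherence are inherently multi-trial; they are computed over a sliding
block of the B = 10 most recent trials and assigned to the block's last
trial (the first trials fall back to the earliest two-trial block). The
default grid — 5 channels × 2 bands × 3 PSD features, 5 × 2 WPS, and
2 coherence pairs (O1–OZ, OZ–O2) × 2 bands — yields 44 named features; the
12-feature descriptor used for authentication is a named column selection
over this table. How the original 210-candidate set decomposed is not
recoverable, so the grid is a documented reconstruction, not a
replication.

## Feature selection

CFS merit `k·r̄_cf / √(k + k(k−1)·r̄_ff)` with absolute Pearson
(point-biserial) correlations — appropriate for continuous spectral
features; the discretising symmetrical-uncertainty variant found in older
toolkits is heavier and unneeded here. Search is greedy forward best-first
with patience 5; ties break lexicographically, so the output is invariant
to column order. A duplicate of an in-subset feature raises redundancy
without raising relevance and can never improve the merit (property-
tested). Selection is intended to run once on the training split of each
fold.

## Evaluation protocol

"10-fold cross-validation" combined with a 10%/90% train/test split is
reconciled as *inverse* 10-fold CV: each stratified tenth serves once as
the initial pool while the other nine tenths stream in a seeded arrival
order that is shared across compared strategies — paired tests over runs
are therefore valid. Client is always the positive class. AUC is the
trapezoidal area under the ROC swept over score thresholds with half
credit for ties (equal to the Mann–Whitney pair-counting estimator;
cross-checked against an independent implementation in the tests).
Precision is reported as 0 when no client predictions were made.

Normality of per-run metric differences is checked with the
Anderson–Darling test (statsmodels' `normal_ad`: estimated mean/variance,
small-sample correction). The paired t statistic uses the standard
`mean/(sd/√N)` form; all-zero differences report t = 0, p = 1, and
identical nonzero differences report the limit t = ±∞, p = 0. Significance
is declared at p ≤ 0.05.

## Synthetic data

The generator replaces an unavailable 45-subject visual-oddball corpus and
encodes exactly the structure the method relies on:

- raw sessions: 150 trials (60 target / 90 non-target, shuffled) of 2.5 s
  at 512 Hz on five channels; per channel, pink noise plus a
  subject-specific alpha oscillation (peak uniform in [8, 13] Hz,
  log-normal power) whose phase on target trials is von Mises-concentrated
  around the stimulus (κ gamma-distributed across subjects), plus a beta
  oscillation whose amplitude and the noise floor grow with the ambient
  condition (quiet < low < high distraction); channels are linearly mixed
  by a symmetric coupling matrix (rows renormalised so coupling changes
  correlation, not power); artefact trials receive a 150 µV transient;
  alpha power drifts multiplicatively per trial. Epoch content is a
  stylised oscillatory model without evoked potentials — the descriptor
  consumes band features only, so simulating full ERPs would add nothing
  the pipeline reads.
- feature streams (the fast path used for strategy comparisons): 45
  subjects × 150 objects in 12 dimensions (the selected-descriptor size);
  subject means from N(0, I), random full covariances of unit average
  scale, and a linear mean drift of one within-subject standard deviation
  over the stream along a random per-subject direction. One subject is the
  client (150 of 6 750 objects, the 1:44 imbalance of a 45-subject pool).
  The between/within scales were chosen once as moderate-overlap
  conditions — consistent with the mid-0.6 recall/precision regime the
  method is reported to operate in — and are not calibrated to any target.

What passing tests on this data do and do not show: they verify the
*mechanisms* (counter-driven retention beats label-blind FIFO under
imbalance and drift; phase-locking and coupling are recoverable by WPS and
coherence), not absolute performance on human EEG. Real EEG adds
intersession variability, non-Gaussian feature distributions, and
condition effects of unknown size; none of these are claimed.

## Problem sizes and numerics

The strategy-comparison checks run ten replicate full-scale streams (6 750
objects, one inverse-tenfold split each) — enough for stable means at
roughly a minute of runtime; the acceptance script uses three replicates.
Tolerances: Parseval to 1e−9 relative; WPS/coherence limits to 1e−9/1e−6;
formula hand-checks to 1e−12. Degenerate inputs are errors, not silent
values: empty pools, single-trial coherence/WPS, constant vectors in the
normality test, single-class AUC.

## Known limitations

- Coherence and WPS block assignment gives the first trials of a session
  look-ahead values (the earliest computable block); irrelevant for the
  shuffled streaming protocol but visible in trial-resolved audits.
- The widened attribute ranges after deletions make similarities depend
  (boundedly) on pool history; use `exact_stats` where exactness matters.
- The ARFF dialect covers numeric attributes plus one nominal class only.
- Counters reset per fold; there is no cross-fold persistence.
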