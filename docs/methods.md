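# Methods

This note records the models and procedures `eegens` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions made where the design was
genuinely open.

## Data model and synthetic generator

An *epoch* — a fixed-length window of multichannel EEG, default 10 s of
24 channels at 250 Hz — is the unit of classification. Labels are binary
(0 normal, 1 abnormal), assigned per recording and inherited by its
epochs; all evaluation is per-epoch. EDF files are read and written in
the classic 16-bit layout, so a write→read round trip is exact up to one
quantization step of the per-channel physical range (the test suite
cross-checks our writer against an independent EDF reader).

The generator emulates the coarse spectral signature of normal versus
epileptiform EEG:

* **normal**: 1/f ("pink") background (default exponent 1, 15 µV RMS), a
  10 Hz alpha rhythm (10 µV, random phase per channel), and white sensor
  noise (2 µV);
* **abnormal**: the same background plus (a) periodic 3 Hz spike-and-wave
  bursts with peak amplitude `(burst_amplitude − 1) × 15 µV` (default
  multiplier 3) visible on all channels with random per-channel gains,
  and (b) 2–8 Hz band power elevated to `low_band_ratio` (default 2)
  times the normal expectation. The band effect is calibrated exactly:
  the burst waveform's in-band power is measured per epoch and the
  background's 2–8 Hz component rescaled so the *total* hits the target
  ratio, which the Welch-spectrum tests verify within a few percent.

Setting both effect parameters to 1 produces two identical distributions
— a built-in null used by the tests. The defaults constitute the "easy"
benchmark: a strong, broadly distributed effect on which any competent
pipeline should approach perfect accuracy. The generator does **not**
emulate inter-subject variability, electrode artifacts (blinks, EMG),
montage geometry, non-stationary background drift, or the rarity and
focality of real ictal events. Passing on it therefore demonstrates that
each pipeline's machinery is wired correctly and can exploit a planted
class difference — not clinical-grade performance.

Splits are stratified: train/test by random per-class permutation,
k-fold CV by round-robin dealing with a rotating offset so remainders
spread over folds (every fold's class ratio is within one sample of the
global ratio, and validation folds partition the training set exactly).

## Feature battery

Per channel per epoch: mean, variance, skewness, kurtosis, energy, peak
amplitude, absolute sum, zero crossings (a zero sample followed by a
nonzero one counts as a crossing), line length, Hjorth mobility and
complexity (first differences as the derivative; constant signals return
0), Shannon entropy of the normalized Welch spectrum (nats), five-band
powers (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz)
and total Welch power, db4 wavelet sub-band energies at depth 4, FFT
dominant-frequency magnitude, Higuchi fractal dimension (k_max = 10),
rescaled-range Hurst exponent (8 log-spaced window sizes), first-order
DFA exponent (windows 4…n/4, log-spaced), and the mean absolute Pearson
correlation of the channel with all others. These parameter choices are
the common quantitative-EEG defaults; all are arguments. Non-finite
extractor output is imputed by the column median (an all-non-finite
column is dropped with a warning), and a degeneracy guard zeroes the
variance-normalized shape features for (near-)constant signals instead
of letting floating-point residue through.

## Hilbert–Huang front end

The Hilbert transform uses the FFT method — zero the negative-frequency
bins, double the positive ones, keep DC and Nyquist — which realizes the
principal-value convolution integral exactly for finite discrete
signals; no quadrature path is provided. EMD sifting uses cubic-spline
envelopes through the local extrema, mirror-extending the two outermost
extrema at each boundary. Sifting of a mode stops when the Cauchy
criterion `Σ(h_prev − h)² / Σh_prev² < 0.2` **and** the IMF count
property (|#extrema − #zero-crossings| ≤ 1) hold, or after 50 sifts;
decomposition stops at `max_imfs` (default 5 for features) or when the
residual has fewer than two maxima or minima. The stopping threshold 0.2
is the classical recommendation; requiring the count property as well
keeps every emitted IMF a genuine mode without materially changing the
decomposition of well-behaved signals.

The HHT feature vector (a fixed width regardless of how many IMFs a
signal yields; missing modes are zero-filled) contains, per IMF: energy
fraction, mean and SD of instantaneous frequency over the interior 90%
of samples (phase differencing is unreliable at the edges), and mean
envelope amplitude; plus the residual energy fraction and the marginal
Hilbert-spectrum energy fractions in the five clinical bands, on a
64-bin log-spaced frequency grid. Whether these features replace or
augment the time-domain battery was open; they are used alone by
default, with augmentation available by concatenating tables.

## ESCD feature selection

Connection `C_i = |PCC(F_i, y)| ∈ [0, 1]`; distance `D_i` = mean
Euclidean distance of the z-scored column to all other z-scored columns.
The two terms are made commensurate by dividing `D` by its maximum,
keeping it in (0, 1] while preserving relative spread. The alternative —
min–max rescaling `D` onto [0, 1] — was measured and rejected: all
z-scored features have nearly equal mean inter-feature distances, so
min–max stretches pure sampling noise across the full unit interval and
can swamp the bounded correlation term (planted-signal recovery drops
from 100/100 to as low as 92/100 seed blocks). Ties in the final
`C_i + D_i` ranking break toward the lower column index.

## Genetic algorithms

One engine serves both the binary mask selector and the box-bounded
hyperparameter tuner: fitness-proportional roulette selection (with a
shift when fitnesses are non-positive; an optional reciprocal mode
inverts fitness), single-point crossover (probability 0.6), elitism
(10 of 300 at full scale), and mutation applied per individual with
probability 0.2 as a single uniformly chosen gene flip (binary) or
redraw within bounds (real). The one-gene reading of "the value of every
individual is randomly changed" makes mutation a local move at every
chromosome length, which converges reliably where a per-bit rate of 0.2
degenerates into random search (measured on the known-optimum test
problem: 30/30 versus 3/20 seeds reaching the optimum). Mask fitness is
`accuracy − λ·(selected/Q)` with λ = 0.01, so accuracy dominates and
smaller masks break ties; all-zero masks are repaired by setting one
random bit. Evaluations are cached by mask, and the best-ever individual
is returned with a per-generation best-fitness history (non-decreasing
whenever elitism ≥ 1). Note the λ pressure (0.01/Q per feature) is far
below cross-validated-accuracy noise, so the selector prunes markedly
but does not drive masks to the minimum achievable size.

## Rank ensemble (equidistant assessment and ranking determination)

Parameter grids are equidistant: `steps` equally spaced values inclusive
of endpoints, rounded half-up and deduplicated for integer parameters
(so the canonical "k, 2, 16, 4" grid is {2, 7, 11, 16}). Each grid value
is trained and scored on the internal validation split independently —
the selection is a pure argmax with ties to the smaller value, and is
therefore invariant to evaluation order (the contract that replaces any
particular parallelization scheme). The default roster holds eight
classical learners (KNN, RBF and linear SVM, logistic regression, random
forest, extra trees, Gaussian naive Bayes, decision tree), each with a
four-point grid on its main knob; the roster is fully configurable.

Diversity is reported as the interrater kappa
`κ = 1 − Disav / (2 q̄ (1 − q̄))` with `q̄` the mean per-model
per-instance correctness and `Disav` the mean pairwise disagreement over
ordered pairs; identical members give 1, complementary errors at
q̄ = 0.5 give −1, independent chance members give ≈ 0. It is a reported
diagnostic only — nothing downstream consumes it.

Pruning clusters the models' 0/1 validation prediction vectors with
k-means (k = 20, 10 seeded restarts; squared Euclidean distance between
vote vectors is exactly the disagreement count) and keeps the most
accurate member per cluster, ties to the lower model index — so the
globally best member always survives. Ranking determination then runs
simulated annealing over inclusion vectors: initial bits Bernoulli(0.4),
objective = majority-vote validation accuracy (fewer members break
ties), neighbor = flip one model drawn proportionally to per-model
selection probabilities (initialized at 0.4, multiplied by 1.1 capped at
0.95 for members of accepted improving solutions), acceptance
`exp(Δ/T)` with T₀ = 1 and geometric cooling 0.95, 500 iterations at
full scale, empty selections repaired to the best single model,
best-ever vector returned.

Voting: class 1 wins when at least half the members vote 1 (the tie goes
to the abnormal class, the clinically conservative choice); with weights
(non-negative, summing to 1) the threshold is 1/2 — a printed threshold
of half the member count is unsatisfiable for normalized weights. The
divide-and-conquer voter recursively halves the instance set until
blocks fall under a threshold (default 10⁴) and concatenates block
votes; since the vote is column-wise this is bit-identical to the direct
computation for every threshold, which the suite checks exhaustively on
small matrices — the split is a correctness contract, not a performance
claim.

## Infinite-ICA subspace ensemble

The latent model is `Z = H (W ⊙ B) + E` on the z-scored feature matrix
(features × samples; D = samples), with Gaussian mixing H, Gaussian
weights W (σ_w² = 1), Bernoulli mask B with per-row activation
probability π_q ~ Beta(α/Q_trunc, 1) (α = 2, Q_trunc = 16 by default; a
finite truncation of the unbounded-rows construction), and Gaussian
noise. Inference is Gibbs sampling with these numerical choices, each
made because the naive alternative measurably breaks source-count
recovery:

* mask entries are sampled with their weight integrated out
  (conjugate), using the collapsed Beta-Bernoulli predictive
  `(α/Q + m_{q,−i}) / (1 + (D−1) − m_{q,−i})` for the prior odds — a
  *sampled* π_q occasionally comes out large by chance and
  mass-activates a row, which then self-sustains;
* H is initialized on the unit left-singular directions of Z at the
  prior's natural scale (‖h‖² ≈ n_obs σ_h²); columns scaled toward zero
  would make spurious activations on them likelihood-free;
* H columns of dead rows (m_q = 0) are not re-randomized — their
  conditional is the prior, and redrawing them lets a random direction
  drift onto structure the active rows already explain, splitting real
  sources redundantly (a valid Gibbs-update skip);
* σ_e² is initialized from the SVD tail — the spectrum no truncated
  model could explain — because a hot start lets junk activations latch
  during burn-in and they decay only over many hundreds of sweeps;
* π_q and σ_e² get their conjugate Beta / inverse-gamma updates; the
  model state is the final sweep, but the *encoder* uses the posterior
  mean of H and σ_e² over the second half of the sweeps (default 200
  sweeps at analysis scale, 100 inside the pipeline), since a single
  draw carries substantial sampling noise.

With these choices, three planted dense sources under Q_trunc = 8 are
recovered (active-row count within one of truth) in ≈ 99/100 seeded
runs; the naive sampler recovers ≈ 29/100.

The number of rows with any active entry is the inferred source count.
Unseen samples are encoded by the Bayes posterior mean of the masked
sources given the posterior-mean H (a ridge projection restricted to
active rows). Because the Gaussian-weight half of the model leaves
rotations of the latent basis unidentified, the scores are then rotated
to maximal statistical independence (FastICA) — consistent with the
model being an ICA — before the ensemble split; without the rotation,
some runs spread class structure so evenly that dropping any two latents
destroys it, and every feature-subset member sits at chance.

The ensemble itself draws overlapping random subsets in the classical
random-subspace manner (default 9 members, each seeing 80% of the
latents), so any informative direction reaches most members; a disjoint
partition of a compact latent representation leaves most members without
class signal and the majority vote fails even on separable data
(measured: 0.60–0.92 versus 1.00 on the benchmark). A partition planner
is also provided for the conventional disjoint-blocks use on wide raw
feature tables. Per subspace, "svm" mode trains one RBF-kernel SVM
(C selected by internal 3-fold CV over {0.5, 1, 4, 8}); "hybrid" mode
adds a one-hidden-layer MLP (32 logistic units, 500 epochs) and an
extended nearest neighbor. All members vote by unweighted majority.

The extended nearest neighbor assigns a query tentatively to each class
and picks the class maximizing the generalized coherence statistic — the
average over classes of the fraction of same-class points among each
training point's k nearest neighbors in the augmented set (k = 5
default, ties to class 0). This is the two-class form of the
class-consistency reading of "the unknown sample is assigned to every
class"; on well-separated data it agrees with plain KNN, which the tests
check.

## Bagging and GA-tuned tree ensembles

Bagging draws R = 25 bootstrap resamples of training size (resampling a
single-class bag up to 10 times before failing), fits one RBF SVM per
bag on z-scored features, records each member's *in-bag*
misclassification fraction (an out-of-bag variant exists but is off by
default, matching the stated in-bag definition), and predicts by
majority vote. The GA wrapper scores masks by 3-fold CV accuracy of one
SVM on the masked features; the final committee trains on the selected
mask.

The tree trio is tuned over a 10-gene mixed integer/real chromosome
whose bounds center on the stated defaults (forest: 100 estimators,
depth 50, leaf size 15, with split/leaf-node settings 25/10 fixed;
XGBoost: η 0.4, depth 4, min child weight 2, γ 0.2, max delta step 1.5,
L1/L2 = 1; LightGBM: 31 leaves, rate 0.4, depth 4). Fitness is 1 − the
mean stratified-CV error rate of the three learners' majority vote —
the classification form of tuning to average prediction error; a
regression variant would swap in relative error but is out of scope for
the binary task. The three tuned learners vote; three is odd, so ties
cannot occur (asserted). Learner internals are delegated to
scikit-learn, xgboost, and lightgbm.

## Factor analysis and the layered KNN

Factor analysis is maximum-likelihood EM on centered data
(scikit-learn's implementation; tol 1e-4, max 500 iterations),
zero-variance columns dropped with a warning and a warning when samples
< features. On pure-noise data the fitted loadings necessarily absorb
the Marchenko–Pastur excess of the top sample eigenvalues — about
`sqrt(2 ψ sqrt(q/n))` per column — which is the correctly derived null
bound the tests assert.

LKNN training, per class: center = member mean; member distances to the
center; Tukey-hinge quartiles (medians of the lower/upper halves, the
median included in both when the count is odd — matching the
quarters-of-the-data narrative); fences `V_low = Q1 − 1.5·IQR`,
`V_high = Q3 + 1.5·IQR`. The upper fence uses Q3: a lower-quartile upper
fence would contradict both the IQR definition and the standard Tukey
rule (a literal flag is available). Members above `V_high` are rejected;
points below `V_low` are merely "expressive" — no rejection rule is
attached to them. The largest retained distance over all classes,
`F_max`, splits into L = 4 layers of width `F_max/L`; a member's layer
is `ceil(distance/width)` clamped to [1, L], and its weight is
`L − layer + 1` — inner layers (closer to their class center, the most
typical exemplars) weigh more, which is the reading consistent with
distant members being *less* representative. Prediction: the k = 5
nearest retained members (distance ties at the boundary break to the
lower member index), association rate 1/distance (an exact-match
distance of zero short-circuits to that member's class), per-class
affiliation = Σ rate × layer weight, scores normalized to sum to one,
argmax with ties to the lower class label. With L = 1 every weight is 1
and the rule collapses to inverse-distance-weighted KNN — verified
against that oracle, and the general rule against a literal brute-force
reimplementation.

## Evaluation harness

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/n,
positive class = abnormal. Empty denominators yield NaN with a warning
rather than an error. The k-fold harness re-runs *every* data-dependent
fitting step — ESCD, GA, annealing, Gibbs sampling, factor fitting —
inside each training fold; feature extraction is label-free and computed
once outside the loop. Fold metrics are reported alongside the
pooled-counts aggregate (the primary number: pooled accuracy is exactly
(ΣTP+ΣTN)/Σn) and the mean of fold metrics. A regression test
demonstrates the leakage this guards against: selecting features on the
full table before CV inflates permuted-label accuracy above chance,
while the honest per-fold path stays in the null band.

## Problem sizes and seeds

The test suite and the acceptance script run the five pipelines on the
full-scale easy benchmark (200 epochs × 24 channels × 10 s at 250 Hz)
with reduced search budgets — annealing 200 iterations, GA populations
6–15 with 3–8 generations, 100 Gibbs sweeps, 15 bags — which keep the
complete run in minutes on one CPU while leaving each method's behavior
qualitatively unchanged on this problem size; unit tests use a 6-channel
4 s variant. Every stochastic component takes an explicit seed, and
refitting with the same seed reproduces byte-identical manifests.

## Known limitations

* The synthetic benchmark is deliberately easy; none of the reported
  accuracies transfer to clinical data.
* Binary labels only; multiclass voting and multiclass LKNN are out of
  scope.
* The EMD implementation is the classic single-channel sifting; no
  ensemble (EEMD/CEEMDAN) or multivariate variants.
* The truncated sparse-source sampler is a finite approximation; true
  nonparametric inference over unbounded sources (reversible jump) is
  out of scope.
* EDF support covers the standard 16-bit, uniform-rate, continuous
  layout only.
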