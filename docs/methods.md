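# Methods and design notes

## The analysis in one paragraph

Six neck-muscle EMG channels (SCM, SC, UT, both sides; 1000 Hz) recorded
during rectilinear and curvilinear walking are conditioned (zero-lag
4th-order Butterworth band-pass, zero-lag 50-Hz notch, per-channel
amplitude normalisation), cut into nonoverlapping 500-ms windows, and
summarised by ten spectrotemporal features per window per channel plus
band-wise intermuscular magnitude-squared coherence (MSC) per muscle pair.
Per-subject feature vectors feed NCA feature weighting and K-NN / LDA /
RBF-SVM classifiers under stratified, seeded 5-fold cross-validation with
all data-dependent steps (standardisation, NCA ranking) fit inside
training folds.  Band-averaged MSC over all 15 channel pairs defines a
weighted 6-node functional muscle network per subject; after proportional
thresholding, node strength and normalized betweenness centrality are
averaged over nodes and compared between groups with a pooled-variance
t-test.

## The synthetic cohort model

No EMG from the underlying study is publicly available, so the package
ships a generator whose ground truth is known analytically.  Channel c is

    x_c(t) = a_c · e_c(t) · Σ_b [ √γ_cb · u_b(t) + √(1−γ_cb) · ν_cb(t) ]
             + ε · w_c(t)

with u_b a unit-variance Gaussian process band-limited to band b (zero-phase
4th-order Butterworth filtering of white noise, so the in-band spectrum is
flat to within filter rolloff) shared by the drive's channel set, ν and w
independent noises, e_c a nonnegative periodic gait envelope, a_c a
per-channel amplitude.  For two channels sharing a drive, the population
MSC inside the band is exactly γ_c·γ_d (the classic common-source result),
which `expected_msc` returns and the estimation stack is tested against.

Defaults (the study-design conditions):

| parameter | default | rationale |
|---|---|---|
| n_per_group | 20 | the study's group sizes (20 CNP, 20 control) |
| tasks, trials | 2 tasks × 3 trials | the study's protocol |
| duration_s | 6 s/trial | a ~6-m walk at comfortable speed |
| fs | 1000 Hz | the study's sampling rate |
| stride_hz | 1 Hz | typical stride rate in adults |
| band γ (baseline) | delta 0.5, theta 0.4, alpha 0.35, beta 0.3, high-beta 0.25 | intermuscular coherence between postural muscles is strongest at low frequencies; magnitudes are free parameters chosen once for testability, not population claims |
| drive sets | one per band per side over (SCM, SC, UT) | the within-side coupling the feature set probes |
| group effect | CNP-curvilinear: delta γ −0.25 on all covered channels; SCM amplitude ×1.3 | mirrors the reported weaker delta-band connectivity during curvilinear gait and the SCM's discriminative role; the rectilinear task carries no effect |
| noise_floor | 0.05 (relative broadband power) | small measurement-noise floor |

**Gait envelope.** e_c(t) = 0.2 + 0.8·(0.5(1+sin(2π·stride_hz·t+φ_c)))²:
nonnegative, periodic, one activation burst per stride.  The per-channel
phases φ_c are small distinct offsets (π/30 increments across the six
channels).  This is deliberate: amplitude modulation convolves the spectrum
with the envelope's harmonics, and if two channels' envelopes are far out
of phase the shared drive decorrelates — with antiphase envelopes the
estimated MSC of a γ=1 pair drops to ~0.27.  Neck muscles activate with
each step on both sides (they are not antiphase like leg muscles), so
near-common phase is also the physiologically sensible choice; with the
default offsets the residual attenuation of estimated MSC is ≲7 % of the
γ_c·γ_d value, inside the ±0.05 recovery tolerance the tests enforce.

**Amplitude effects and normalisation.** The per-channel amplitude scale is
almost entirely removed by the pipeline's own amplitude normalisation (a
constant channel scale divides out exactly; only its interaction with the
unscaled noise floor survives).  Class separation on the default cohort is
therefore carried by the coherence features, which is also the study's
central claim.  What the generator does *not* emulate: motor-unit
physiology, realistic broadband EMG spectra (power concentrates in the
driven 1–30 Hz bands), kinematic gait variability, nonstationary artifacts.
Passing tests demonstrate that the estimation and inference machinery
recovers known structure; they do not validate the biological effect sizes.

## Signal conditioning

* Band-pass: zero-lag (forward–backward) Butterworth, order 4, 10–500 Hz.
  A band edge at Nyquist (500 Hz at fs = 1000) is unrealizable; the upper
  cutoff is clipped to 0.99·fs/2 = 495 Hz with a warning.
* Notch: zero-phase 2nd-order IIR at 50 Hz, −3 dB bandwidth 2 Hz (Q = 25);
  the bandwidth is a package default, none being specified upstream.
* Normalisation: each channel divided by its maximal 0.5-s-epoch amplitude
  over the task (all trials pooled), *after* filtering.  "Maximal
  amplitude over an epoch" is read as the maximum epoch RMS — robust to
  single-sample artifacts; the single-sample-peak variant is available via
  `norm_mode="epoch_peak"`.  Normalisation precedes windowing.
* Windows: ⌊N/500⌋ contiguous nonoverlapping 500-sample windows per trial;
  the trailing remainder is discarded; windows never span trial joins.

**Separate conditioning for the coherence path.** The 10-Hz high-pass
attenuates the delta band (1–4 Hz) by roughly 70 dB, after which 0.5-s
Welch bins at 2–4 Hz are dominated by spectral leakage from the ≥10 Hz
passband: "delta coherence" of the high-passed signal measures leakage,
not coupling (numerically: a planted delta-band group effect becomes
invisible).  MSC and the band networks are therefore computed on signals
conditioned with the band-pass low edge moved down to the lowest analysed
band (1 Hz), notch and normalisation unchanged; the amplitude features
keep the 10–500 Hz chain exactly.  This is the one point where the package
deviates from a literal reading of the upstream conditioning chain, and it
does so because the literal chain cannot produce the low-band connectivity
it is meant to analyse.

## Features

Time-domain (per 500-ms window): MAV, RMS, VAR, WL, SSI with VAR computed
exactly as the conventional EMG definition prints it — Σx²/(N−1), *no*
mean subtraction (band-passed EMG is zero-mean to good approximation).
Hence SSI = (N−1)·VAR = N·RMS² identically, which the tests exploit.
Frequency-domain, from a one-sided rectangular-window periodogram
(Parseval-checked): MNF, MDF (smallest grid frequency where cumulative
power reaches half the total), PKF, MNP, TTP.  PKF is implemented as the
*frequency* of the maximal PSD bin (ties to the lowest frequency); the
printed formula "max(P_j)" — a power, not a frequency — is available via
`pkf_literal=True`.  Window-level features are averaged (arithmetic mean)
over all windows of all trials of a subject × task; the aggregation rule
is a package choice, none being stated upstream.  Samples are
subject-level (40 per task; the confusion-matrix arithmetic of the
published curvilinear rows is consistent with 40 pooled samples), with the
"combine" view pooling both tasks' rows (80 samples, task kept as a
metadata column, not a feature).

## Coherence and networks

Welch MSC: 0.5-s segments (2-Hz resolution), nonoverlapping by default
(50 % overlap configurable), Hann taper, auto-/cross-spectra pooled across
trials weighted by segment count, never across a trial join.  At least two
segments are required — a single-segment MSC is identically 1.  With L
independent segments and incoherent inputs the estimator's mean is ≈ 1/L;
this bias is used as a test oracle.  Band values are bin means with
half-open assignment (lo < f ≤ hi), so the 2-Hz grid gives the delta band
bins {2, 4} Hz and shared edges are never double-counted.  The 2-bin delta
resolution is a faithful consequence of the 0.5-s segment choice; a longer
coherence segment is a documented configuration alternative
(`CoherenceConfig.seg_s`), not a silent change.

Classification uses the three within-side pairs per side (×5 bands, plus a
broadband 1–30 Hz mean per pair → 36 MSC features).  Networks use all 15
unordered pairs including cross-side ones: a within-side-only 6-node graph
is two disconnected triangles with degenerate betweenness (the
within-side-only variant exists as a config switch).  Proportional
threshold: keep the ⌈p·15⌉ strongest upper-triangle edges (weights
retained, not binarised; ties broken by lexicographic node-pair order so
every subject keeps the same count); default p = 0.5, prominently exposed
since the upstream density is unstated.  Strength is the incident weight
sum; `strength_mean` (mean retained incident weight, the scale of a single
edge weight) is also reported since per-node connectivity near 0.9 in the
upstream tables suggests an edge-weight scale.  Betweenness uses edge
length 1/w, exact Dijkstra/Brandes shortest paths with fractional counting
of ties, normalized by (n−1)(n−2)/2; it is validated against exhaustive
simple-path enumeration on 6-node graphs.

## NCA feature weighting

The feature-weighting NCA variant (per-feature weights, not a learned
subspace): d_w(x_i,x_j) = Σ_r w_r²|x_ir−x_jr|, softmax neighbour
probabilities with kernel width σ, objective Σ_i p_i − λΣ_r w_r²,
maximised by monotone gradient ascent from w = 1 with backtracking line
search (step halved until the objective does not decrease, grown 1.2× on
success; softmax computed with row-max subtraction for stability).
Convergence: improvement < 1e−6 for 5 consecutive iterations or 300
iterations.  Defaults σ = 1 on standardized features and λ = 1/n; both are
exposed and logged, as the upstream hyperparameters are unstated.  Because
the distance uses squared weights, duplicated features share *squared*
weight (w_a² + w_b² ≈ w_single²).  Features below 2 % of the maximum
weight are reported as irrelevant (`relevant_features`); the operative
selection mechanism is the top-k sweep against cross-validated accuracy.
By default the ranking is refit inside each training fold (no selection
leakage); `--paper-mode` fits once on all data, reproducing the simpler
single-ranking procedure, and is labelled in every report.

## Classification and statistics

K-NN: Euclidean, k = 5.  LDA: shared-covariance discriminant (SVD solver;
a shrinkage-regularised variant is available for near-singular
covariances).  SVM: RBF kernel, C = 1, gamma = 1/n_features on
standardized inputs.  Stratified 5-fold CV with seeded shuffling; fold
membership is a pure function of (seed, sorted subject ids).  Metrics come
from the single pooled confusion matrix over all held-out predictions
(per-fold accuracies are also emitted); the positive class for
sensitivity/specificity is CNP, a choice logged in every report since it
is not derivable from the published rates alone.  Default NCA subset size
k = 16 (the published best-SVM subset size), configurable.

t-test: two-sided, pooled variance, df = n_a+n_b−2; degenerate
zero-variance inputs resolve by continuity (equal means → p = 1, unequal
→ p = 0).  Normality screening uses the Lilliefors-corrected KS test
(parameters estimated from the sample; the naive KS null would be
anti-conservative).  No multiple-testing correction is applied across
bands × metrics by default, mirroring the upstream analysis; a Bonferroni
option exists.

## Validation problem sizes

The test suite exercises: 600-s single-pair recordings for coherence
recovery (±0.05 of γ_c·γ_d; 1200 Welch segments); γ grids
{0, 0.3, 0.6, 0.9} for monotonicity; 200 random 6-node graphs against
brute-force strength/betweenness (1e−9); 20 seeded replicates of
1-informative/9-noise NCA recovery at n = 40; the full default cohort
(20+20 subjects × 2 tasks × 3 × 6-s trials) for the directional findings
(curvilinear > rectilinear accuracy for all three classifiers, NCA
selection not hurting, reduced CNP delta-band strength); and 1000 null
simulations for t-test type-I calibration (5 % ± 1.5 %).

## Known limitations

* The synthetic effect magnitudes (γ reduction 0.25, SCM amplitude ×1.3)
  are configurable defaults chosen for testability, not estimates of the
  clinical population; no effect sizes are published to calibrate against.
* Delta-band values rest on two 2-Hz bins; conclusions about that band are
  resolution-limited by design.
* The published K-NN curvilinear per-class rates are not jointly
  consistent with any 40-sample pooled confusion matrix; that row's
  pooling scheme is unknown and is not reverse-engineered here.
* Subjects appear in both tasks of the "combine" view, so its CV folds are
  not independent across tasks.
* No artifact/ECG removal, no gait-cycle time normalisation, no directed
  or time-resolved coherence, no network metrics beyond strength/BC.
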