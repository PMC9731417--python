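# Methods

This note records the models, conventions and open design choices behind
`pcgfusion`, in the order the pipeline runs.

## Ingestion

Recordings are averaged to mono, resampled to 2205 Hz by polyphase rational
resampling with an anti-aliasing low-pass, and amplitude-normalised to
max |x| = 1. Normalisation is a deliberate choice (disable with
`load_record(..., normalize=False)`): several features (max, RMS, energy)
would otherwise reflect recording gain rather than physiology.

## Empirical mode decomposition

Sifting subtracts the mean of natural-cubic-spline envelopes fitted through
the local maxima and minima; boundaries are handled by mirror-extending two
extrema across each end. Extrema are strict sign changes of the first
difference; plateaus count once, at their midpoint. A candidate mode is
accepted when the Cauchy criterion SD = Σ(h_{k−1} − h_k)²/Σh_{k−1}² < 0.2
holds *and* the mode satisfies the two IMF restrictions
(|#extrema − #zero-crossings| ≤ 1, near-zero envelope mean), with at most 50
sifting passes (a warning is logged on non-convergence). Decomposition stops
at a monotone residue (≤ 2 extrema) or 15 modes. Because each mode is
subtracted from the running residue, completeness (signal = Σ modes +
residue) holds to floating-point accuracy by construction; the test suite
verifies < 1e-8 relative error on random signals.

## IMF screening

* **Corr & RMSE rule.** Thresholds are the means of the per-layer scores
  over the first L−1 layers, which are also the selection candidates; the
  comparison is boundary-inclusive (≥ λ, ≤ δ). With identical scores on all
  layers, every candidate is selected.
* **Adaptive Hausdorff rule.** Only the first seven layers are screened.
  ε sums the HD of the first min(7, L) layers and always divides by 7, so a
  short decomposition (L < 7) gets a proportionally *stricter* threshold —
  this follows the printed formula rather than a per-layer mean.
* **Fixed HD baseline** (`method="hd"`): mean HD over layers 1..L−1 as the
  threshold, candidates 1..L−1, mirroring the Corr & RMSE construction.
* An empty selection falls back to the single best layer (argmax Corr /
  argmin HD) with a logged warning: a pipeline must not emit a zero signal.

### Point-set embedding for the Hausdorff distance

A time series must be turned into a point set before HD applies; nothing in
the method's statement fixes how. The default embedding is
`time_amplitude_2d`: sample j maps to (j/fs seconds, xⱼ/max|s|), amplitudes
shared-scaled by the *source* signal so quiet noise layers stay near the
time axis; signals are stride-decimated to ≤ `hd_max_points` (default 2000)
points before the O(nm) distance. Two alternatives are exposed:

* `amplitude_1d` — bare amplitudes on the line;
* `spectrum` — the magnitude-spectrum curve (4096-point FFT, frequency
  normalised by Nyquist, magnitudes by the source spectrum's peak).

The choice matters. On dense raw point clouds the HD reduces to an
amplitude-coverage comparison, which keeps the loudest layers: appropriate
for recordings whose noise is small relative to the heart sounds, but at
very low SNR (0 dB) it ranks broadband-noise layers as "similar" and the
screening stops denoising. The `spectrum` embedding inverts this trade-off:
concentrated oscillatory energy stands far above the thin per-bin floor of
white noise, so on a tone buried at 0 dB the rule selects exactly the
tone-carrying layers (≈ 9 dB SNR gain, verified in the suite) — but it also
discards murmur-band layers, whose energy is noise-like, and murmurs are
precisely what separates several valve conditions. The default therefore
remains `time_amplitude_2d`; switch to `spectrum` when the goal is
denoising a narrowband signal rather than preserving murmur content.

## Segmentation and cardiac reserve times

S1/S2 localisation is a Liang-style Shannon-energy envelope detector:
band-pass 25–150 Hz (4th-order Butterworth, zero-phase), per-sample Shannon
energy −y²ln y² smoothed over 20 ms, threshold at mean + 0.5·SD of the
normalised envelope, burst merging across gaps < 50 ms, and boundary
refinement at 10 % of each burst's peak smoothed energy with sub-sample
interpolation. S1 vs S2 uses the physiological rule that systole is shorter
than diastole. Plausibility guards reject noise-like inputs: supra-threshold
duty cycle > 0.6, bursts longer than 0.3 s, more than 5 bursts/s, cycle-
period coefficient of variation > 0.35, or systole/diastole ratio > 0.85.

T1 and T2 are the mean S1/S2 widths, T12 the mean S1-onset→S2-onset
interval, T11 the mean S1→S1 period; all averaged over detected cycles
(one value per recording, since the feature vector holds one entry each).
T11 requires at least two cycles. When segmentation fails, the reserve
features are NaN and are median-imputed at the dataset level, so one bad
record cannot abort a batch. Absolute reserve-time values are
segmentation-method-dependent; the classification experiments only need
within-run consistency.

## Feature conventions

Where the feature table leaves a formula open, the package fixes it as
follows (each isolated behind one function):

* moments use population (1/N) normalisation; kurtosis is non-excess
  (Gaussian → 3);
* X_peak = max|x| in the crest (X_peak/X_RMS), impulse (X_peak/mean|x|) and
  margin (X_peak/X_RM) factors; peak-to-peak = max − min is its own feature;
  X_RM is the square-root amplitude (mean √|x|)²;
* the form factor is E[X²]/E[|X|], the printed formula;
* quartiles interpolate linearly between order statistics (type 7);
* energy entropy = Shannon entropy (nats) of 20 ms frame-energy fractions;
  spectral Shannon entropy uses the normalised power spectrum;
* instantaneous energy/frequency come from the analytic signal; the
  instantaneous frequency is the central-difference derivative of the
  unwrapped phase over 2π, negative values clipped to 0, five edge samples
  trimmed;
* sample and approximate entropy use m = 2, r = 0.2·SD under the Chebyshev
  metric (k-d-tree pair counting; exact, verified against an O(N²) oracle);
* multiscale permutation entropy: order 3, delay 1, scales 1–5, each scale
  normalised by log 3! and averaged — parameters sized for short records;
* exponential entropy follows the Pal–Pal form Σ p·e^(1−p) − 1 over the
  20 ms frame-energy distribution (the table names the feature without
  defining it; this is an explicit stand-in);
* constant inputs define all entropies as 0, with a warning.

The 36-feature variant simply drops T1/T2/T11/T12.

## Feature ranking

Mutual information is the plug-in estimator on 10-bin equal-frequency
discretised features, in nats. mRMR is greedy MID:
score(f) = MI(f; y) − mean_{g∈S} MI(f; g). Ties in every method break by
original feature order (stable sorts), so rankings are deterministic.

**KCCA-gated mRMR.** The cited refinement counts only label-relevant
redundancy. Operationalisation here: for a candidate/selected pair (f, g),
compute the first canonical correlation of a low-rank regularised kernel
CCA (Gaussian kernel, median-distance width, ridge `reg` = 0.1, ≤ 200
subsampled points) between the label-explained components E[f|y] and
E[g|y], scale it by √(R²_f·R²_g) (the label-explained variance fractions),
and zero the MI(f; g) penalty when this gate falls below 0.3. Exact copies
of an informative feature remain fully penalised (gate ≈ R² ≈ 1); features
correlated only through label-independent noise are not (gate ≈ 0). As
reg → ∞ the gates collapse and the ranking degenerates to relevance-only.

**QPFS** solves min_w ½(1−α)wᵀQw − αFᵀw on the probability simplex with
α = mean(Q)/(mean(Q) + mean(F)) (SLSQP; verified against a
projected-gradient oracle). **MIC** is an in-package equipartition-grid
approximation of MINE: equal-frequency bins on the feature axis, contiguous
class-code groupings on the label axis, all grids with a·b ≤ n^0.6 (and
a ≤ 15·b), score max I/log min(a, b) ∈ [0, 1]. **Tree** importance is mean
impurity decrease over a 200-tree random forest; **RFECV** eliminates one
feature per step (100-tree forest) and picks the CV-optimal count with
stratified 10-fold CV.

## Evaluation protocol

Stratified 10-fold CV with pooled out-of-fold predictions, so correct +
error = n and accuracy = correct/n, matching result tables that report both
CV accuracy and whole-corpus counts. κ = (p_o − p_e)/(1 − p_e). Classifier
defaults: RF 100 trees; k-NN k = 5 on per-fold standardised features
(scaler fit on training folds only); decision tree unlimited depth, Gini.
The incremental curve evaluates k = 1..p and reports the smallest k
attaining the maximum. An 80/20 stratified holdout is available for
protocols that separate training and testing before CV.

## Synthetic generator

Each record is a train of Gabor bursts: S1 (default 35 Hz, 90 ms) and S2
(60 Hz, 80 ms, amplitude 0.8 relative) at a fixed heart rate with systole
fraction 0.37, plus a class-specific murmur — band-passed noise with a
Tukey window in systole (AS 180–420 Hz, MR 90–250 Hz) or diastole
(MS 100–220 Hz), or a 250 Hz mid-systolic click (MVP) — and white noise at
an exact SNR. Burst "width" means the 10 %-of-peak energy-envelope support,
the same convention the segmenter refines to, so generated and detected
boundaries are directly comparable. Corpus generation jitters heart rate
±10 %, S2 amplitude ±20 % and murmur level ±10 % per record,
deterministically per seed.

What the generator does *not* emulate: murmurs are unstructured filtered
noise without the amplitude contour or harmonic texture of real murmurs;
heart rate is constant within a record; there are no recording artefacts,
friction sounds or sensor variation. Consequences: (i) passing tests show
the pipeline's mechanics are correct and that the archetypes are separable,
not that clinical accuracy transfers; (ii) at 0 dB SNR the murmur signature
is spectrally inside the noise floor, so *any* screening that removes noise
also removes murmur information — on this generator the no-reconstruction
baseline can match or exceed the reconstruction arm at 0 dB, unlike on
clinical recordings with structured murmurs at moderate noise. This is a
known limitation of the synthetic conditions, not a property of the method
claimed here.

## Problem sizes and numerical choices

The desk-scale study uses 1.5 s records for the classification corpora
(n = 500, 100 per class, SNR 15 dB) and 3 s records for segmentation
recovery; the 0-dB robustness comparison uses 100-record corpora over
5 seeds. HD is computed on ≤ 2000 points per signal (decimation changes the
distance smoothly). Tolerances: EMD completeness 1e-8 relative; feature
oracles 1e-9 relative; QPFS simplex constraints and oracle objective 1e-6;
reserve-time recovery ±10 ms. Degenerate inputs (constant signals, empty
selections, single-cycle recordings) raise typed errors or take documented
conventions rather than propagating NaNs.
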