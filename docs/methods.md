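# Methods

## Problem and model

`ecgident` performs closed-set identification: given beats from N enrolled
subjects, assign each new beat to one of them. The unit of identification
is a single QRS complex — 94 samples centered on the R-peak (45 before, 49
after, half-open on the right), cut at the record's native sampling rate.
Because the window is defined in samples, its physical duration varies with
the sampling rate (188 ms at 500 Hz, 261 ms at 360 Hz); records are never
resampled.

Each beat is described twice and the descriptions are fused at the feature
level (never at the decision level):

* **Wavelet block (256).** A level-4 discrete wavelet decomposition splits
  the beat into subbands [cA4, cD4, cD3, cD2, cD1]. With symmetric
  boundary extension the subband lengths follow l ← ⌊(l + L − 1)/2⌋ for
  filter length L; for coif5 (L = 30) on a 94-sample beat they are
  61/45/37/33/33, totalling 209 coefficients. The concatenation is
  right-zero-padded (or right-truncated, for k > 1 multi-beat rows) to a
  fixed 256-length vector so every wavelet family and window size meets the
  same classifier interface. Truncation discards the tail of cD1 first,
  the band dominated by high-frequency detail. Supported families: haar,
  db2, bior6.8, sym5, coif5 (default coif5); orthogonal families are
  validated at load against the double-shift orthogonality relation of
  their filters.

* **Deep block (128).** A convolutional-recurrent network treats the beat
  as a length-94k sequence of scalars: LSTM(128, sequences) →
  LSTM(64, sequences) → Conv1D(32, k3) → Conv1D(64, k5) → Conv1D(32, k8)
  (all same-padded, ReLU) → dropout 0.5 → max-pool(5, stride 2, same) →
  dropout 0.2 → flatten (32·⌈94k/2⌉) → dense 256 (ReLU) → dense 128
  (ReLU) → dense softmax over subjects. After supervised training, the
  128 post-ReLU activations of the penultimate dense layer are the feature
  vector (dropout inactive at inference). Parameter arithmetic: an LSTM
  with h units on d-dim input has 4(h(d+h)+h) weights; a convolution with
  f filters of width w on c channels has cwf+f; a dense layer from m to u
  has (m+1)u. The total is affine in the number of classes with slope 129.

The fused 384-vector is classified by a 100-tree random forest with a fixed
`random_state`. RBF-SVM (C = 1, γ = 'scale') and 5-NN baselines, both
behind a train-fit standardizer, are provided for comparison; they are
comparative baselines, so their unstated hyperparameters are standard
defaults recorded in the run manifest.

## Preprocessing and detection choices

* All filters are zero-phase (forward–backward), so R-peak indices are not
  shifted — segmentation is index-based, so phase distortion would corrupt
  the windows. Reflect padding sized to the filter's settling time
  (≈ 3/cutoff seconds for the high-pass) controls edge transients.
* The mains notch is a Butterworth band-stop, order 5, 48–52 Hz. A
  second-order pole-radius IIR notch (zeros on the unit circle, poles at
  radius r = 0.95) is exposed as an optional variant but is not in the
  default chain, being causal and therefore phase-shifting.
* The drift filter is a high-pass Butterworth, order 5, default cutoff
  0.5 Hz (the conventional lower edge of the diagnostic ECG band),
  configurable to 1.5 Hz. A low-pass at 1.5 Hz would destroy the QRS.
* Min–max normalization maps to [−1, 1] with exact endpoint attainment; a
  constant record raises an error rather than returning zeros, since such a
  record carries no biometric information.
* Pan–Tompkins internals (band-pass 5–15 Hz order 2, 150 ms integration,
  0.125/0.25 threshold updates, 200 ms refractory, 1.66·RR search-back,
  360 ms T-wave slope discrimination) are the classic constants, all
  overridable via `PanTompkinsConfig`. Detections are refined to the local
  maximum of the clean signal within ±50 ms. An empty result is returned
  (not an error) when nothing crosses threshold.
* Boundary beats whose window would cross the signal edge are dropped, not
  padded. Multi-beat rows are built from non-overlapping groups of k
  consecutive beats of the same subject within one record — overlapping
  groups would leak shared beats between training and test splits.

## Training protocol

The network is trained with mini-batch Adam (learning rate 1e−3, batch 32,
categorical cross-entropy), default 100 epochs; weights are
Glorot-uniform with forget-gate biases at 1. Everything — initialization,
shuffling, dropout masks — derives from explicit seeds, so runs are
reproducible on a single thread. Weights are float32 by default; the
gradient implementation is verified against central finite differences at
float64. No gradient clipping, no class weighting, no augmentation, no
hyperparameter search: class imbalance in real corpora is documented, not
corrected.

## Synthetic data: what it emulates and what it does not

The generator draws one template per subject — five Gaussian bumps
(P, Q, R, S, T) with amplitude/center/width sampled uniformly from
physiological ranges (R amplitude 0.8–1.6 mV, centers ordered
P < Q < R < S < T, mean RR 600–1100 ms, RR jitter σ 10–40 ms) — and renders
beat trains plus three noises: a 0.2 Hz baseline-wander sinusoid
(default 0.15 mV), a 50 Hz mains sinusoid (0.05 mV) and white Gaussian
noise (σ 0.02 mV). Planted R-peak indices are returned exactly, which is
what makes detector recall/precision and localization measurable.

It does **not** emulate: beat-to-beat morphology variability within a
subject (the template is fixed up to additive noise), arrhythmic rhythms,
motion/electrode artifacts, multi-session recordings, or realistic
inter-subject similarity structure. Passing the end-to-end test therefore
shows the pipeline is implemented coherently — detection, windowing,
features, fusion and evaluation compose correctly and recover planted
identities — not that real-population accuracy would match. Identification
accuracy on real corpora depends on population size, class balance and
recording conditions, and requires the corresponding recordings.

## Benchmark and test sizing

The default benchmark is 10 subjects × 60 beats at 500 Hz under the
moderate-noise defaults above, split 80/20 per subject (test count
⌊n·0.2⌋, minimum 1, seeded). At this scale the whole suite — including one
100-epoch training of the network and the fused/ single-route comparisons —
runs in minutes on one CPU core; the acceptance script trains 60 epochs,
which the loss/accuracy history shows is already past convergence on this
fixture. These sizes are the package's chosen study conditions for the
self-contained tests, not limits of the implementation.

## Numerical notes and edge cases

* Subband arithmetic, perfect reconstruction (≤ 1e−8) and Parseval energy
  conservation under periodization (orthogonal families only; bior6.8 is
  biorthogonal and excluded) are property-tested against brute-force
  oracles.
* Metric conventions: zero-denominator ratios (e.g. recall of an
  unsupported class) are reported as 0 and flagged; macro means are
  unweighted and include flagged zeros. Accuracy equals micro-recall
  equals trace/total by construction.
* The WFDB reader covers the dialect the package writes: plain-text header
  plus 16-bit little-endian samples with gain/baseline in the header
  (format 16, sample-interleaved for multi-channel files); channel 0 is
  the default selection.
* Known limitations: the detector is tuned for adult morphologies at
  fs ≥ 100 Hz; min–max normalization is per record, so inter-record
  amplitude information is deliberately discarded; k > 1 rows truncate
  wavelet coefficients beyond 256; the softmax head is retrained from
  scratch for each enrollment population (no transfer or incremental
  enrollment).
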