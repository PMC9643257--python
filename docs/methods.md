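# Methods

## Problem and model

The task is binary screening of pre-segmented paediatric swallow sounds
recorded by cervical auscultation: *normal* (label 0) versus *aspirating*
(label 1). The discriminating physical signature is spectral: both classes
are short (≈0.2–1.5 s) low-frequency-dominated noise bursts, but
aspirating swallows additionally carry a narrowband spectral peak near
20 kHz. The front end therefore measures *where* spectral power sits, not
how much of it there is: spectral subband centroids (SSCs) over a Mel
filterbank, pooled per clip, feed a class-weighted kernel SVM.

## Front end

- **Pre-emphasis** `y[n] = x[n] − 0.97 x[n−1]`, with `x[−1] = 0` so output
  length equals input length. Gain at angular frequency ω is
  `√(1 + 0.97² − 2·0.97·cos ω)`; the test suite verifies measured tone
  gains against this closed form within 1 %.
- **Framing**: frame length `L = round(0.020 fs)`, hop `round(0.010 fs)`,
  0-based start indices, trailing partial frames dropped, Hamming window.
  A clip shorter than one frame is rejected at feature extraction (not at
  read time, keeping I/O orthogonal to DSP).
- **Spectrum**: magnitude-squared FFT of the zero-padded frame, `nfft` the
  smallest power of two ≥ L (1024 at 44.1 kHz). No density scaling: each
  centroid is a ratio of weighted sums over one subband, so any global
  scale cancels exactly.
- **Filterbank**: M = 26 triangles, edges equally spaced in
  `mel(f) = 2595 log10(1 + f/700)` between 0 Hz and Nyquist, snapped to
  FFT bins. The bank extends to Nyquist because the informative aspiration
  signature sits near 20 kHz; truncating at a conventional speech band
  would discard it. Amplitude- versus area-normalisation of the triangles
  is irrelevant here — per-subband scaling cancels in the centroid.
- **Centroids**: `C[t,m] = Σ f_k w_m[k] P_t[k] / Σ w_m[k] P_t[k]`. A
  subband with zero weighted power falls back to its centre frequency,
  which preserves the ascending cross-band order on silent frames.
  Ascending order is guaranteed on flat and unimodal spectra and holds on
  all synthetic material; with overlapping triangles and adversarial
  spectra adjacent centroids can in principle invert, so the library
  monitors (optional warning) rather than enforces it on arbitrary input.
- **Pooling**: per-subband mean and standard deviation over frames,
  concatenated → 2M = 52 dimensions. The standard deviation uses the
  population convention (divisor T; configurable `std_ddof`): a
  single-frame clip has a well-defined all-zero std block. Features are
  pooled per swallow clip, not per patient — the dataset arithmetic
  (106+18 swallows split 62/62) works at the swallow level.

## Classifier

50/50 stratified random split (per-class shuffled under an explicit seed;
an odd class count leaves the extra item in training). Grid search over
kernels {sigmoid, RBF, polynomial}, C ∈ {0.1, 1, 10, 100},
γ ∈ {scale, 0.001, 0.01, 0.1}, degree ∈ {2, 3}, evaluated by stratified
five-fold cross-validation (stratification is necessary: with only 9
aspirating training examples, unstratified folds could be single-class).
Selection maximises plain validation accuracy, ties broken by grid order;
the chosen point, per-fold scores and the full score table are recorded in
the model metadata. Per-class regularisation uses inverse-frequency
("balanced") weighting, `w_c = n / (2 n_c)` — for a 53:9 training set the
aspirating:normal weight ratio is 53/9. Feature standardisation is
deliberately off (escape hatch available): SSCs are ordered frequency
locations and z-scoring would destroy that structure. Split and CV seeds
are required configuration with default 0.

The scikit-learn `SVC`/`GridSearchCV`/`StratifiedKFold` machinery stands
behind this module; the package's contribution is the front end, the
protocol, and the evaluation surface, all of which are tested against
independent oracles (closed forms, brute-force summations, expanded-label
recomputation).

## Evaluation

Positive class fixed to aspirating. From the 2×2 counts: sensitivity
`tp/(tp+fn)`, specificity `tn/(tn+fp)`, PPV `tp/(tp+fp)`, NPV `tn/(tn+fn)`,
F1 the harmonic mean of PPV and sensitivity; normal-class metrics by class
swap, giving the duality sensitivity(normal) = specificity(aspirating).
Any metric with a zero denominator is reported as undefined (NaN), never
as 0 — on a single-class test set a fabricated value would misstate the
evidence. Reports round half-up at 2 decimals (0.885 → 0.89); raw values
are always retained.

## Synthetic data generator

The generator emulates the *spectral geometry* of the two classes, not
swallow physiology:

- base burst: white noise shaped in the frequency domain, flat to 300 Hz
  then −12 dB/octave, through a linear 40 ms attack / 150 ms decay
  envelope — a stand-in for the low-frequency "flushing" sound;
- aspiration signature: Gaussian-band noise (not a tone, avoiding
  FFT-bin-alignment artefacts) centred at 19.5 kHz, 600 Hz wide, at RMS
  ratio 0.3 to the base. The top Mel band spans ≈16.9–22.05 kHz with its
  triangle peak at ≈19.3 kHz; the signature pulls that band's centroid to
  ≈19.5 kHz while normal clips sit ≈19.3 kHz or below, a designed-in
  separation of >100 Hz across a full 124-clip dataset;
- broadband floor at 60 dB below the base RMS (a clean close-contact
  recording); durations uniform in 0.3–1.0 s; peak amplitude normalised
  to 0.9; default composition 106 normal + 18 aspirating to exercise the
  class-imbalance machinery.

Every clip is a pure function of (seed, label, index), so datasets
regenerate byte-identically.

What passing tests on this generator show — and what they do not: the
pipeline recovers a class contrast that lives exactly where the front end
looks (the top subband), under realistic imbalance, framing and
quantisation. They do not show clinical performance: real swallow sounds
have unknown spectral tilt, duration and amplitude statistics,
breath/cough contaminants, and inter-subject variability that the
generator deliberately omits. The signature strength is a dial
(`peak_rms_ratio`); as it falls beneath the broadband floor the class
distributions converge and accuracy collapses — note that a
balanced-weighted SVM on indistinguishable classes does not settle at the
majority rate but oscillates between near-chance solutions, so the
degradation check asserts collapse, not a specific asymptote.

## Numerical and design choices

- Sampling rate default 44.1 kHz: the informative band reaches ~20 kHz, so
  Nyquist must exceed it; all frame/FFT sizes derive from the clip's
  actual rate. No resampling anywhere.
- 16-bit PCM WAV I/O with scaling `int / 2^{bits−1}`; write-then-read
  round-trips within one quantisation step (2⁻¹⁵). Multi-channel input is
  averaged to mono.
- Filterbank edge snapping to bins fails loudly (with a suggested fix)
  when adjacent edges collide, rather than producing degenerate filters.
- Grid-search problem sizes: the acceptance surface uses the full default
  dataset (124 clips) with 20 split seeds, and a 3-ratio sweep with 3
  seeds each for the degradation property — about half a minute in total.

## Limitations

- Clips must arrive pre-segmented; no automatic swallow detection.
- Strictly binary; no penetration grading, no probability calibration,
  no ROC thresholding (hard labels only).
- The generator is a controlled test harness, not a clinical simulator;
  reported synthetic accuracies characterise the pipeline, not the task.
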