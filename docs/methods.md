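# Methods

`speckleflow` detects arteriovenous-fistula (AVF) stenosis from B-mode
ultrasound cine loops by (1) compressing each loop into a low-rank
tensor decomposition, (2) reading the flow regime off the temporal
factor, and (3) classifying the factor sequences with a small
multi-input LSTM, evaluated by bootstrap AUROC. This note records the
model, the choices that were genuinely open, and what the synthetic
benchmark does and does not establish.

## Video tensors

A cine loop is a stack of grayscale frames organised as a third-order
tensor `X ∈ R^(I×J×K)` (rows × columns × frames). Ingestion keeps the
first 1000 frames at most (enough for at least one cardiac cycle at
clinical frame rates), converts color to gray with BT.601 luminance
weights, scales pixel codes to [0, 1] by the container's maximum code
value, and optionally crops to a rectangular region of interest (ROI)
around the vessel lumen. ROI coordinates are 0-based and half-open so
they compose with array slicing; the crop rectangle is recorded on the
cropped loop as provenance (in pre-crop coordinates). ROIs are supplied
per loop in a sidecar CSV; no automatic ROI detection is attempted.

## Canonical polyadic decomposition (ALS)

The CPD model is `X ≈ Σ_r λ_r a_r ∘ b_r ∘ c_r` with `R = 3` components
by default, fitted by alternating least squares on the Frobenius
objective. Conventions and numerical choices:

- Kolda–Bader unfoldings; the Khatri–Rao ordering is defined so that
  `X(1) = A · (C ⊙ B)ᵀ`, which the normal equations rely on.
- Initialisation: leading mode-n singular vectors (HOSVD init); random
  Gaussian columns only when the rank exceeds a mode size. Fixed seed →
  reproducible output.
- After each sweep, factor columns are rescaled to unit norm with the
  scale absorbed into λ, removing the scale indeterminacy.
- Convergence: relative decrease of the relative reconstruction error
  below `tol` (default 1e-8, library default `max_iter` 500). Hitting
  `max_iter` logs a warning but is not an error — speckle tensors are
  not exactly low-rank and plateau rather than converge.
- The objective is evaluated per sweep through the Gram-matrix identity
  `‖X−X̂‖² = ‖X‖² − 2⟨X, X̂⟩ + ‖X̂‖²` (the mode-3 MTTKRP is reused), which
  avoids forming the dense reconstruction. That identity loses about
  eight digits to cancellation near exact recovery, so whenever it
  reports an error below 1e-4 the explicit residual is recomputed; only
  small near-noiseless tensors ever reach that regime, so the cost is
  negligible.
- Determinism of reported factors: components are sorted by
  non-increasing λ; each temporal column's largest-magnitude entry is
  made positive by a joint A/C sign flip, then each spatial-row column's
  by a joint A/B flip.
- Degenerate inputs: zero tensors and non-finite values are rejected; a
  tiny ridge (1e-12·I) guards rank-deficient Gram matrices.

The pipeline itself runs ALS at `tol = 1e-5`, `max_iter = 150`: on
speckle video the objective plateaus (relative error ≈ 0.13–0.18) long
before stricter tolerances are reachable, and the factors are stable
well before that point.

## Tucker decomposition (truncated HOSVD)

`X ≈ G ×1 A ×2 B ×3 C` with the mode-n factor equal to the leading
left singular vectors of the mode-n unfolding and core
`G = X ×1 Aᵀ ×2 Bᵀ ×3 Cᵀ`. The squared truncation error respects the
classical bound by the sum of discarded squared singular values. Tucker
is selectable as the feature extractor (`decomposition="tucker"`), but
CPD is the default: the pipeline's three classifier inputs map naturally
onto the three rank-1 component families.

## Spectral analysis of the temporal factor

Each column of the mode-3 (frame) factor is a temporal signal sampled at
the cine-loop frame rate. Its spectrogram uses a 128-sample Hann window
with 50% overlap by default and per-window mean removal (B-mode
components carry large DC offsets that would mask flow frequencies).
Two summaries operationalise qualitative visual signatures:

- `high_frequency_ratio`: fraction of total power above a cutoff.
  Disturbed post-stenotic flow decorrelates speckle quickly and is
  modulated at higher pulsatile frequencies, so its ratio is high across
  the whole recording; laminar flow stays low. The default cutoff of
  one quarter of Nyquist is a repository choice — no quantitative
  threshold separating "high" from "low" is established clinically.
- `detect_transient_peaks`: time bins whose total power exceeds
  `energy_factor` (default 5) times the median per-bin power, kept only
  when the run of consecutive hot bins is at most `max_span` (default 3)
  — recording artifacts are fleeting, whereas genuine disturbed flow
  elevates the spectrum for the entire loop and is deliberately not
  flagged.

## Labels, features, splits, normalization

Binary stenosis labels follow site-specific duplex-ultrasound criteria:
venous outflow — PSV < 50 or > 400 cm/s, or diameter < 3.5 mm;
anastomosis — PSV > 400 cm/s; arterial inflow — PSV > 400 cm/s,
bi/triphasic waveform, or volume flow < 300 ml/min. A missing
measurement simply cannot fire its criterion; a measurement with no
criterion-relevant field raises an error. When a diameter range is
recorded, the minimum is used (stenosis is a focal narrowing).

The classifier's three inputs are the three mode-factor sequences (two
spatial, one temporal), the only three per-video sequences a rank-R
decomposition yields; per-mode padding lengths make sense only under
this reading. The CPD weights are folded into the temporal sequence
(`C·diag(λ)`), keeping the spatial factors scale-free while preserving
component-magnitude information. An alternative mapping that replaces
the first input with the frequency-power profile of the temporal
columns is available (`mapping="spectral"`).

Splits are stratified by (site, label): within each stratum items are
shuffled by seed and allotted 60/20/20 with largest-remainder rounding,
so every stratum honours the global fractions to within one item.
Z-score statistics (per component, per channel, pooled over steps) and
per-component target lengths (the longest training sequence) derive
from the training split only; sequences are z-scored then right-padded
with zeros (the training mean) or right-truncated (head kept).
Standard deviations are floored at 1e-8 so constant channels normalize
to zero rather than exploding.

## Classifier

Three LSTMs with 8 cells each process the three sequences; the final
hidden states pass through tanh, are concatenated (24 units), then
Dense(32)+ReLU and a single sigmoid unit output the stenosis
probability. Training: class-weighted binary cross-entropy
(`w_c = N/(2·N_c)`, so the rarer class weighs more, normalised to mean
one), Adam with α=0.001, β₁=0.9, β₂=0.999, ε=1e-8, mini-batches of one,
at most 100 epochs, early stopping after 5 epochs without
validation-loss improvement, best-epoch weights restored. L1 and L2
penalties (0.01 each) apply to the LSTM kernel and recurrent matrices,
not biases and not the dense head.

The network is implemented directly on NumPy arrays (forward pass,
backpropagation through time, Adam); gradients are verified against
central finite differences in the test suite. Implementation choices:

- Initialisation: Glorot-uniform kernels, orthogonal recurrent blocks,
  forget-gate bias 1, all deterministic from one seed; the epoch
  shuffling stream is derived from the same seed.
- The extra tanh is applied to the LSTM's final hidden state (on top of
  the tanh internal to the cell), matching the described architecture.
- The early-stopping monitor is the full objective — validation
  cross-entropy plus the weight penalty — i.e. the same quantity the
  optimiser minimises, the convention of the major deep-learning
  frameworks. Empirically this matters: early in training the data term
  plateaus near ln 2 while weights shrink; monitoring the data term
  alone stops training during that warm-up.
- Zero-padded steps are processed as ordinary inputs (no masking),
  matching plain pad-or-truncate preprocessing.
- Reproducibility is bit-for-bit for a fixed seed on a fixed platform.

The parameter count is closed-form: `3·4H(R+H+1) + 3H·D + D + D + 1`
(H=8 cells, D=32 dense units; 1985 parameters for R=3 channels) and is
asserted in tests.

## Evaluation

AUROC uses the Mann–Whitney identity (ties count ½), which vectorises
over bootstrap resamples; it is cross-checked against
`sklearn.metrics.roc_auc_score` in tests. The bootstrap draws 10,000
resamples of size n (the test-set size) with replacement; resamples
containing a single class, where AUROC is undefined, are discarded and
counted (`n_skipped`) rather than redrawn, keeping "10,000 iterations"
interpretable. The confidence interval is the 2.5/97.5 percentile of
the retained samples. Two classifiers' bootstrap distributions are
compared with the classic equal-variance Student's t-test (Welch by
flag); comparing two zero-variance distributions is an error. The
confusion matrix thresholds probabilities at 0.5; PPV is TP/(TP+FP).

## Synthetic cine loops

No patient loops ship with the package, so a generator produces
labelled speckle videos with the statistical structure the method
exploits — not ultrasound physics. The speckle field is
low-pass-filtered Gaussian noise (grain σ = 1.5 px) evolving as an
advected AR(1) process: with ρ = 1 − decorrelation rate,
`s[k+1] = ρ·shift(s[k]) + √(1−ρ²)·fresh`, keeping the field stationary
with frame-lag correlation ρ. Each frame is intensity-modulated by
`1 + depth·sin(2π f_mod k / frame_rate)` (the pulsatile cycle) and
observed with additive Gaussian noise (σ = 0.01), clipped to [0, 1].

Flow presets (the benchmark's study conditions): laminar — advection
1 px/frame, decorrelation 0.02/frame, modulation 1 Hz at depth 0.2;
disturbed — decorrelation 0.25/frame, modulation 8 Hz at depth 0.4.
Frame rate 60 s⁻¹, 600 frames, 96×96 frames with a 20×20 lumen (a
tissue-dominated field of view, lumen ≈ 4% of pixels), 60 videos
balanced across classes and rotated round-robin over the three
recording sites (sites carry no distributional difference by default; a
per-site offset is configurable). Cohorts are byte-identical under a
fixed seed.

The full-frame condition surrounds the lumen with bright, sharp tissue
texture animated by label-independent acquisition dynamics: sub-pixel
tissue motion (slow breathing/probe drift at ≤1.5 Hz, cardiac-band
vibration at 4–12 Hz, broadband hand tremor) and gain fluctuations with
uniform, axial-ramp and lateral-ramp spatial profiles over 0.3–24 Hz
(probe-coupling and time-gain-compensation variation), each with a
per-recording random strength. Per pixel the tissue varies several-fold
less than the flow region, yet these dynamics dominate the rank-3
decomposition, for a structural reason worth recording: a CPD component
is an outer product, so what competes for the three component slots is
each structure's *rank-1-coherent* energy. The flow modulation rides
the near-rank-1 lumen-mean pattern and is therefore ideal bait for a
slot; spatially diffuse dynamics (texture motion), however large in
total energy, are not. The uniform and ramp gain profiles are exactly
outer products with coherent energy above the modulation's, so they
claim the slots; the motion terms mask residual modulation cross-talk
inside the same frequency band; and the per-recording strengths shuffle
the component ordering between videos. A perfectly static texture does
the opposite — it is absorbed into a single flat component and leaves
the flow components clean, which fails to reproduce how whole-image
analysis degrades in practice. Cropping to the lumen recovers the
underlying flow loop exactly, so the cropped and full-frame experiments
analyse the same flows with the same splits.

Artifacts are global brightness transients (`inject_artifact`):
`span` consecutive frames multiplied by a gain, emulating probe or
patient movement. Cohort-level random artifacts draw spans of 20–60
frames (a third of a second to a second at 60 fps) — long enough to
register against a 1–2 s analysis window, short enough to be fleeting —
and are off by default (`artifact_prob = 0`); tests inject them
explicitly.

What the synthetic benchmark does not show: the generator has no
acoustic point-spread function, attenuation, shadowing, out-of-plane
motion or Rayleigh amplitude statistics, and its two classes are
cleaner and better separated than clinical flow regimes. Passing the
benchmark demonstrates that the pipeline recovers a temporal-frequency
flow signature through decomposition, learning and evaluation — not
that clinical-grade accuracy would be achieved on real loops.

## Problem sizes and runtime

The end-to-end benchmark (60 videos × 96×96×600, two conditions,
rank-3 ALS per loop, LSTM training without hardware acceleration,
10,000-draw bootstrap) completes in roughly ten minutes on one CPU; the
decomposition of a single cropped-scale loop takes well under a second
and a full-frame loop a few seconds at the pipeline tolerance.
These sizes were chosen so the whole experiment is comfortably
desk-scale while leaving the qualitative contrast between conditions
large and stable.

## Known limitations

- ALS finds a local optimum; no restarts or line search are attempted.
- No constrained (non-negative) CPD, no rank selection: the rank is a
  configuration choice fixed at 3 by default.
- The classifier pools all three recording sites into one model with
  stratified splitting; per-site models are not implemented.
- Bootstrap resamples reuse one trained model's predictions; run-to-run
  training variance is outside the bootstrap's scope.
- Severity grading, automated ROI detection and attention-based
  sequence models are out of scope.
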