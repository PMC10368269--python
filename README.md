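# speckleflow

Detection of arteriovenous-fistula (AVF) stenosis from B-mode
ultrasound cine loops by tensor decomposition and recurrent
classification.

Haemodialysis patients depend on a patent AVF, and progressive stenosis
is the main cause of access failure. Duplex ultrasound surveillance is
routine but angle-dependent and a poor predictor of outcomes. The
speckle pattern in plain B-mode video, however, moves with the blood:
laminar flow advects and decorrelates it slowly, while disturbed
post-stenotic flow decorrelates it rapidly, shifting the temporal
spectrum towards high frequencies. `speckleflow` turns that signature
into a classifier:

1. **Tensor representation.** A cine loop (first ≤1000 frames, cropped
   to the vessel lumen) is a third-order tensor `X ∈ R^(I×J×K)`.
2. **Decomposition.** A rank-3 canonical polyadic decomposition (CPD),
   `X ≈ Σ_r λ_r a_r ∘ b_r ∘ c_r`, is fitted by alternating least
   squares; a Tucker decomposition via truncated HOSVD
   (`X ≈ G ×1 A ×2 B ×3 C`) is available as an alternative. The mode-3
   factor `C` is a set of temporal signals tracking speckle motion.
3. **Spectral analysis.** Short-time spectra of the temporal factor
   quantify the flow regime (`high_frequency_ratio`) and flag fleeting
   recording artifacts (`detect_transient_peaks`).
4. **Classification.** The three factor sequences feed a three-input
   LSTM network (8 cells per input, tanh, concatenation, Dense-32+ReLU,
   sigmoid), trained with class-weighted binary cross-entropy, Adam,
   L1+L2 = 0.01 on the LSTM weights, batch size 1, ≤100 epochs, early
   stopping with patience 5 — implemented from scratch on NumPy.
5. **Evaluation.** Test-set AUROC with a 10,000-iteration bootstrap
   (mean, SD, percentile CI) and Student's t-test between two
   classifiers' bootstrap distributions; confusion matrix and PPV.

Because no patient loops are published, the package ships a synthetic
speckle-video generator whose laminar/disturbed presets reproduce the
statistical structure above, including the two acquisition conditions
of interest: loops **cropped** to the lumen versus **full-frame** loops
where bright, slowly moving surrounding tissue dominates the image.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
import speckleflow as sf

# one disturbed-flow loop, 20x20 px, 10 s at 60 fps
loop = sf.generate_speckle_video(sf.DISTURBED_PRESET, shape=(20, 20),
                                 n_frames=600, frame_rate=60.0, seed=7)
X = sf.as_tensor(loop)                       # (20, 20, 600)
d = sf.cpd_als(X, rank=3, tol=1e-5, max_iter=150, seed=0)
print("weights:", np.round(d.weights, 1))
print("relative error:", round(d.final_objective, 3))

S = sf.spectrogram(d.factor_C[:, 0], fs=loop.frame_rate)
print("high-frequency ratio:", round(sf.high_frequency_ratio(S, cutoff=7.5), 3))

lam = sf.generate_speckle_video(sf.LAMINAR_PRESET, shape=(20, 20),
                                n_frames=600, frame_rate=60.0, seed=7)
d_lam = sf.cpd_als(sf.as_tensor(lam), rank=3, tol=1e-5, max_iter=150, seed=0)
S_lam = sf.spectrogram(d_lam.factor_C[:, 0], fs=60.0)
print("laminar ratio:   ", round(sf.high_frequency_ratio(S_lam, cutoff=7.5), 3))
```

prints

```
weights: [255.1  27.4  22.9]
relative error: 0.305
high-frequency ratio: 0.759
laminar ratio:    0.007
```

The leading component (λ₁ ≈ 255) carries the mean image and its
pulsatile brightness course; under disturbed flow 76% of that signal's
spectral power sits above one quarter of Nyquist (7.5 Hz here), versus
under 1% for laminar flow — the separation the classifier learns.

The full experiment — generate a 60-video cohort, decompose, split
60/20/20 stratified by site and label, train, and bootstrap the test
AUROC — is one call per condition:

```python
from speckleflow import CohortConfig, run_comparison, compare_bootstrap

cropped, full_frame = run_comparison(CohortConfig(seed=0), seed=1)
t, p = compare_bootstrap(cropped.bootstrap, full_frame.bootstrap)
print(f"cropped    AUROC {cropped.auroc:.2f}, bootstrap mean {cropped.bootstrap.mean:.2f}")
print(f"full-frame bootstrap mean {full_frame.bootstrap.mean:.2f}  (t={t:.1f}, p={p:.1g})")
```

prints (roughly ten minutes on one CPU)

```
cropped    AUROC 1.00, bootstrap mean 1.00
full-frame bootstrap mean 0.55  (t=226.7, p=0)
```

Cropping to the lumen before decomposition is what makes the flow
signature reach the classifier; on full-frame loops the surrounding
tissue dominates the low-rank components and performance collapses —
the package's central qualitative finding.

There is also a small CLI: `speckleflow simulate --out DIR` writes a
synthetic cohort as PNG frame stacks plus a manifest CSV, and
`speckleflow train --manifest M --out DIR` runs the pipeline on any
manifest of labelled loops.

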