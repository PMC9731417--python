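# pcgfusion

Classification of heart-valve sounds from phonocardiogram (PCG) recordings
via adaptive empirical mode decomposition (EMD) and a 40-dimensional fused
feature vector.

Auscultation distinguishes valve disorders — aortic stenosis (AS), mitral
stenosis (MS), mitral regurgitation (MR), mitral valve prolapse (MVP) — from
normal heart sounds (NHS) by the timing and frequency content of the S1/S2
sounds and of murmurs between them. `pcgfusion` implements a complete
signal-to-decision pipeline for this problem, for researchers working with
labelled heart-sound corpora at a 2205 Hz sampling rate:

1. **EMD** — the recording s(t) is sifted into intrinsic mode functions
   (IMFs) c₁..c_L plus a residue r, with s(t) = Σᵢ cᵢ(t) + r(t) exact.
2. **IMF screening** — noisy modes are rejected by one of two adaptive
   rules: *Corr & RMSE* (keep layer i ≤ L−1 when Corrᵢ ≥ λ and RMSEᵢ ≤ δ,
   where λ = (Σᵢ₌₁^{L−1} Corrᵢ)/(L−1) and δ likewise), or the *adaptive
   Hausdorff-distance* rule (keep layer i ≤ 7 when HDᵢ ≤ ε with
   ε = (Σᵢ₌₁^{min(7,L)} HDᵢ)/7, HD the bidirectional Hausdorff distance
   between the layer and the source embedded as point sets).
3. **Reconstruction** — the kept layers are summed into a denoised
   sub-signal.
4. **Feature fusion** — 40 named features per record: 4 cardiac reserve
   times (T1, T2, T11, T12 from S1/S2 segmentation), 21 time-domain
   statistics, 11 spectral/instantaneous features, 4 entropies.
5. **Feature ranking** — mRMR, KCCA-gated mRMR, QPFS, MIC, tree-ensemble
   importance, RFECV.
6. **Evaluation** — the top-k ranked features are fed incrementally into a
   random forest / k-NN / decision tree under stratified 10-fold
   cross-validation, reporting accuracy, Cohen's κ, and correct/error
   counts.

A bundled synthetic PCG generator (Gabor S1/S2 bursts, class-specific
murmurs, controlled SNR, exact ground truth) makes every stage testable
without downloading clinical data.

## Worked example

```python
import numpy as np
from pcgfusion import (default_class_specs, generate_corpus,
                       build_feature_matrix, tree_rank, incremental_curve)

specs = default_class_specs(snr=15.0, duration=1.5)       # 5 classes
records, manifest, truths = generate_corpus(specs, 20, seed=7)  # 100 records

M = build_feature_matrix(records, method="adaptive_hd")   # EMD + HD screening
ranking = tree_rank(M, seed=0)
result = incremental_curve(M, ranking, classifier="rf", folds=10, seed=0)
print(f"best accuracy {result.best_accuracy:.2f} with top-{result.best_k} "
      f"features, kappa {result.kappa:.3f}")
```

Output:

```
best accuracy 0.93 with top-16 features, kappa 0.912
```

i.e. with adaptive-Hausdorff reconstruction and the fused feature set, the
forest separates the five synthetic valve-sound classes at 93 % pooled
10-fold CV accuracy using the 16 best-ranked of the 40 features; κ ≈ 0.91
says the agreement is far above the 20 % chance level.

The same pipeline is scriptable from the shell:

```sh
pcg synth --n 20 --snr 15 --seed 7 --out corpus/
pcg features --manifest corpus/manifest.tsv --out features.csv --method adaptive_hd
pcg evaluate --table features.csv --ranker tree --classifier rf --folds 10 --seed 0
```

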