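# Methods

## Problem setting

Resting-state fMRI classifiers for autism spectrum disorder (ASD) versus
neurotypical controls (NC) generalize poorly across imaging sites: scanner
hardware and acquisition protocols shift the distribution of connectivity
features site by site, so a model pooled over several sites often fails on a
site it has never seen. `connsiam` implements a similarity-measure approach
to this problem: instead of learning a decision boundary over pooled
subjects, it learns a *similarity function* between a subject and class
exemplars drawn from a single, fixed **baseline site**, trained so that the
comparison transfers across sites.

## Feature extraction: dynamic functional connectivity

Each subject is represented by ROI-averaged BOLD time series
(T timepoints × R regions; R = 116 for the AAL parcellation). A sliding
window of length M timepoints and stride s cuts the series into
K = ⌊(T − M)/s⌋ + 1 overlapping segments; trailing timepoints that do not
fill a window are dropped, never padded. Within window k the connectivity
between regions i and j is the Pearson correlation of their in-window
samples:

    FC_ij(k) = Σ_m (x_i^m − x̄_i)(x_j^m − x̄_j)
               / sqrt( Σ_m (x_i^m − x̄_i)² · Σ_m (x_j^m − x̄_j)² )

The ordered collection of window matrices is the dynamic functional
connectivity network; its elementwise mean is the subject's connectivity
estimate, and the upper triangle (row-major, i < j) is vectorized into the
feature vector of length R(R−1)/2 — 6670 features at R = 116.

Numerical choices:

* **M and s are not method constants.** Defaults are M = 30 timepoints and
  s = 1, common sliding-window values; everything downstream is agnostic to
  them.
* **Zero-variance windows.** Pearson correlation is undefined for a
  constant signal; the implementation returns 0 for such edges and logs a
  warning instead of propagating NaN into the mean matrix — a constant ROI
  signal carries no correlation evidence.
* A Fisher z-transform flag exists but is **off** by default; the model
  consumes raw correlations.

## The similarity model

The twin ("Siamese") network applies one shared encoder
f_θ : R^{R(R−1)/2} → R^d to both members of a pair — parameter sharing is an
invariant of the architecture, not an option. The encoder is an
autoencoder-style MLP (encoder half, default widths 512→128 at the
6670-dimensional input) followed by fully connected layers down to the
embedding (default 64). Pair similarity is scored by the L1 distance
between embeddings mapped through a sigmoid,

    dist(x̂₁, x̂₂) = ‖x̂₁ − x̂₂‖₁,    out = σ(dist),

and trained with the squared-error pair loss L = ½(out − y)², where y = 0
for a same-category pair and y = 1 otherwise. Because the output is
monotone **increasing** in the distance, a *lower* output means a *more
similar* pair.

Design points that were genuinely open:

* **Sigmoid range.** Over nonnegative distances σ(d) ∈ [0.5, 1), so the
  y = 0 target is unreachable in the literal formulation. The default stays
  literal — training still contracts same-class distances toward 0 (output
  toward 0.5), and classification uses the argmin of the two outputs, so the
  offset cancels. An opt-in affine head σ(a·d + b) with learnable a, b
  restores the full (0, 1) range.
* **Loss argument.** The pair loss is applied to the sigmoid output (the
  reading consistent with y ∈ {0,1} and the (0,1) mapping); a
  `loss_on_raw_distance` flag applies it to the raw L1 distance instead.
* **Autoencoder reconstruction.** Whether the encoder is trained with a
  reconstruction objective is ambiguous; both are supported. The mirrored
  decoder and an optional reconstruction penalty
  (`reconstruction_weight · ½·mean((x̂ − x)²)` over every forwarded batch)
  are implemented but the weight defaults to 0.
* **Standardization.** Features are z-scored per dimension using statistics
  of the training sites plus the baseline site only (L1 distances are
  scale-sensitive); the statistics travel with the checkpoint.
* **Initialization.** Fan-in uniform, with the final embedding layer scaled
  by 0.1 so that initial pair distances fall in the responsive region of
  the sigmoid rather than its saturated tail.

All gradients are derived by hand and computed in numpy (the chain is
short: σ′ = out(1−out), ∂‖e−p‖₁/∂e = sign(e−p), dense backprop through the
MLP); a finite-difference test verifies every parameter path, including the
affine head, the decoder, and the prototype route.

## Few-shot training with baseline-site prototypes

Sites are partitioned into K training sites, one baseline site, and
held-out target sites. The class prototypes are the *mean embeddings* of
the baseline site's NC and ASD subjects under the **current** parameters —
they are recomputed at every step, and prototype objects carry the model
version they were computed under so stale prototypes are rejected rather
than silently reused. The prototype is part of the computation graph:
gradient flows through the baseline branch of the twin network as well.

Within each training site, 70% of subjects (stratified by class,
round-half-up per class, seeded) form the meta-training set; the remaining
30% form the meta-test set, which is scored during training but never
differentiated through (verified by comparing parameters of runs with and
without meta-evaluation).

Pairing scheme: every meta-training sample forms exactly two pairs — with
its own-class prototype (y = 0) and with the other-class prototype (y = 1) —
giving balanced pair labels by construction. The per-site loss is the mean
over those 2n pairs (so the summed total weights sites equally regardless
of size), and the total objective is the plain **sum** over the K sites:

    L_total = Σ_{k=1}^{K} L_k

Optimization is full-batch (sites are small) seeded **Adam** at learning
rate 1e-3 for 500 steps by default. Plain SGD is available, but at these
step counts it makes negligible progress on the sigmoid-of-distance
objective, whose gradients are small when outputs sit near 0.5 or saturate
near 1; Adam's per-parameter scaling converges within ~100 steps on the
default benchmark, matching the intended rapid-convergence behaviour.

## Target-site evaluation

Per unseen target site: (1) equalize class counts by seeded random removal
from the majority class; (2) draw a seeded support set of N shots per class
(default 5 — "a few subjects"); (3) fine-tune *all* parameters of a fresh
copy of the model for `fine_tune_steps` (default 50) on the support-vs-
prototypes loss (a freeze option exists for ablation); (4) recompute the
baseline prototypes under the fine-tuned parameters; (5) classify every
remaining query: predict NC iff the output against the NC prototype is
strictly smaller, with exact ties going to ASD. Support subjects are never
scored (audited by subject id in every run).

Metrics: accuracy, precision, and F1 with **ASD as the positive class**
(diagnosis convention; the choice is logged). Zero-denominator conventions:
precision := 0 when there are no positive predictions; F1 := 0 when
precision + recall = 0; both log a warning. A pooled nearest-class-mean
classifier over the raw features is included as the built-in comparison
baseline for the multi-site pooling failure mode.

## Synthetic multi-site generator

The generator emulates the two phenomena the pipeline must separate, on the
scale of the latent correlation structure (the quantity the features
estimate), which makes statistical power predictable:

* a **shared base correlation matrix** across all sites and classes, drawn
  from a rank-3 factor model (realistic moderate correlations, PSD by
  construction);
* a **group effect**: an additive shift δ on a fixed, seed-chosen set of
  edges, applied to the ASD class only;
* **site heterogeneity**: i.i.d. Gaussian edge offsets (SD
  `site_effect_sd`) applied identically to both classes within a site —
  the scanner/protocol shift that moves both groups together;
* subject series are T i.i.d. draws from N(0, Σ_target) plus independent
  observation noise (SD `noise_sd`), which attenuates observed correlations
  by 1/(1 + noise_sd²).

Perturbed targets are repaired to valid correlation matrices by clipping
negative eigenvalues to 1e-6, reconstructing, and re-normalizing the
diagonal (iterated up to 5 rounds; failure raises with advice to shrink the
perturbations).

Default benchmark conditions: 7 sites (4 training + 1 baseline + 2
targets), 20 subjects per class per site, R = 20 regions, T = 150
timepoints, δ = 0.4 on 20 edges (~10% of the edge set, reflecting a
distributed but sparse connectivity difference), site-offset SD 0.1,
noise SD 0.3. R = 20 rather than 116 keeps the desk-scale benchmark fast;
the 116-region feature dimension (6670) is exercised separately.

What the generator does **not** model: hemodynamic response, temporal
autocorrelation of BOLD noise, motion artifacts, missing timepoints, age or
sex structure, or class imbalance (sites are balanced by construction;
the balancing step is still exercised). Consequently, passing benchmarks
demonstrate that the pipeline recovers a controlled group effect under
controlled site shifts — not that it attains any particular accuracy on
real multi-site cohorts, where effects are weaker and heterogeneity richer.
On these synthetic conditions the class effect is strong relative to
estimation noise, so benchmark accuracies sit near the ceiling rather than
in the 60–70% range typical of real data.

## Reproducibility

Every random choice — simulation, splits, balancing, support sampling,
initialization — flows from a single integer seed through named substreams
(`SeedSequence` keyed by a CRC of the substream name), so runs are
bit-reproducible end to end; the determinism check compares metrics files
byte for byte across repeated pipeline runs.

## Known limitations

* The L1-distance head makes distances grow with embedding dimension;
  very large embeddings push initial outputs into sigmoid saturation
  (mitigated, not eliminated, by the small-output initialization).
* Fine-tuning with very few shots can overfit the support set; steps and
  learning rate are deliberately small by default.
* The literal sigmoid head cannot emit outputs below 0.5; calibrated
  similarity *probabilities* require the affine head.
* The generator's additive site model is one of several plausible
  heterogeneity mechanisms (multiplicative or rotational shifts are not
  implemented).
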