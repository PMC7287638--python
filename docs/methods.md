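# Methods

`fmgdecode` implements joint hand-gesture classification and finger-angle
regression from a force-myography (FMG) wristband: ten barometric pressure
sensors around the wrist sense muscle/tendon deformation while a single
finger flexes and extends at the metacarpophalangeal (MCP) joint. One model
with a shared trunk and two parallel heads predicts, per sliding window,
which finger is moving (5 classes, thumb..pinky) and its current MCP angle.

## Synthetic wristband cohort

No public wristband dataset accompanies this problem setting, so the package
ships a generative stand-in that reproduces the *statistical structure* the
method assumes rather than any physiology:

* **Protocol.** Per trial, five contiguous equal-length segments in the fixed
  order thumb, index, middle, ring, pinky; one finger moves per segment.
  Defaults: 5 s per finger at 40 Hz → 1000 samples/trial, 10 trials/subject,
  10 subjects → 100,000 samples. Thumb range 0–55°, other fingers 0–90°,
  with an optional per-subject attenuation factor in [0.85, 1.0] emulating
  subjects who cannot reach nominal full flexion.
* **Angle trajectory.** Raised cosine θ(t) = A/2·(1 − cos(2π f t + φ)) with a
  per-segment frequency drawn uniformly from 0.4–0.6 Hz (self-selected pace)
  and a per-trial uniform phase.
* **Sensor model.** pressures = baseline + C · g(θ/A) + random-walk drift +
  Gaussian noise, with g(u) = tanh(1.5u)/tanh(1.5), a fixed monotone
  saturating map with g(0)=0, g(1)=1. Each finger couples strongly
  (strength ≈ 1 pressure unit, jittered ±20% per subject) to a distinct pair
  of channels, with uniform crosstalk (×0.1) onto the rest, so
  class-conditional channel patterns are distinct and the angle is
  identifiable from the active channels. Coupling is fixed across a
  subject's trials and varies between subjects.
* **Noise defaults.** noise_sd = 0.05 and drift_sd = 0.005 per step against
  an O(1) signal: a clean-but-noisy regime consistent with high-sensitivity,
  high-linearity barometric sensing. The literature source for the protocol
  gives no noise magnitudes; these are package choices, exposed in
  `SimConfig`.
* **Seeding.** All randomness derives from one root seed through
  `SeedSequence([seed, subject, trial])`, so any trial is reproducible in
  isolation and whole cohorts are bit-stable.

What the simulator does **not** emulate: biomechanical tendon coupling,
multi-finger gestures, sensor placement shift between sessions, rest
transitions between segments (segments abut directly), or non-stationary
artifacts. Passing tests on this cohort demonstrate that the pipeline's
machinery behaves as specified under its own assumptions — not that the
headline numbers transfer to real wristband recordings.

## Movement-image augmentation

An arrangement is an ordered channel-index sequence; expanding an L×N signal
by it yields L×M with every listed channel column copied in order, so that
chosen channel pairs become spatially adjacent for 2-D convolution. Two
modes:

* `paper_fixture` — the published 42-element sequence for N=10 (and
  [1,2,3,1] for the 3-channel worked example), reproduced verbatim. Note:
  the published sequence misses four adjacencies — (2,7), (3,8), (4,9),
  (5,10) — despite its stated goal of pair-completeness. The fixture is kept
  byte-exact deliberately; it is the sequence the reference results used.
* `pair_complete` — a deterministic Eulerian path on the complete channel
  pair graph (Hierholzer, smallest-neighbour rule; for even N, (N−2)/2
  duplicated edges pair up interior vertices so a path from 1 to N exists).
  Every unordered pair is adjacent at least once with minimal duplication:
  length 2 for N=2, 8 for N=4 (provably minimal), 50 for N=10.

Windows slide along time with unit step. A length-Ls series yields **Ls − w**
windows with start offsets 1..Ls−w: one fewer than the mathematical
Ls − w + 1, matching the published counts (958 per 1000-sample trial,
8958 for nine concatenated trials at w = 42) while keeping the final sample
— the angle target of the last image — inside the last window. Each window
is labelled by its modal finger class (ties break toward the class whose
last occurrence is latest, consistent with the last-time-step angle
convention) and targets the final row's angle. Sensors and angles are
standardized to zero mean, unit variance (population convention,
configurable), with statistics fitted on the training split of each fold
only — test trials never contribute, which the provenance fields make
auditable. Zero-variance channels fall back to sd = 1 with a logged warning.

In `concat_mode="paper"` the training trials of a fold are concatenated in
trial-id order before windowing (reproducing the 9000 − 42 training count);
`per_trial` mode never lets windows cross trial boundaries.

## Dual-output models

All deep models share: trunk → dense(32, ReLU) → two parallel dense heads —
K-way softmax for the gesture and one linear unit for the angle — trained
jointly by minimizing w_c·crossentropy + w_r·MSE (default w_r:w_c = 4:1)
with RMSprop (ρ = 0.9, ε = 1e−7), batch size 32, 10 epochs, no validation
split or early stopping.

* `cnn_aug` — 42×42×1 movement image → conv(32, 3×3, ReLU, same padding) →
  maxpool 2×2 → conv(32, 3×3, ReLU) → maxpool 2×2 → flatten (3200).
* `cnn_noaug` — identical layers on the raw 10×10 window; flatten is 128.
  (No standard padding scheme yields a 128-wide flatten from a 42×42 input
  with these layers; the honest per-architecture size is always reported via
  `flatten_dim`.)
* `gru` — 10 time steps × 10 channels → one GRU layer (32 units, input
  dropout 0.2, recurrent dropout 0.2; masks drawn per batch and shared
  across time steps) → the same dense tail and heads.

The layers, reverse-mode gradients and RMSprop are implemented directly in
NumPy (`fmgdecode.nn`), float32 throughout, with one seeded generator
driving initialization (Glorot uniform), shuffling and dropout — training is
bit-reproducible on a given machine. Gradients are verified against central
finite differences in the test suite. Cross-entropy clips probabilities at
ε = 1e−7. Same padding was chosen because it reproduces the 128-wide flatten
of the 10×10 model and keeps spatial dims even for pooling; pooling uses
floor division and degenerates to identity when both spatial dims are
below 2 (needed for the very small images of low-k channel ablations).

**Learning rate.** The reference training recipe fixes the optimizer, batch
size and epoch count but not the learning rate. At the conventional 0.001
the joint loss has not converged within the fixed 10-epoch budget (training
R² ≈ 0.95 on a noiseless fold); 0.002 converges (training R² ≈ 0.98) and
0.005 over-shoots the regression head. The package default is therefore
0.002, exposed in `DualModelConfig.learning_rate`.

## Shallow baselines and sensor importance

SVC (RBF, C=5, γ=0.1), SVR (RBF, C=10, γ=0.1), random-forest classifier
(100 trees, √n_features) and regressor (60 trees, log₂ n_features) consume
raw per-time-step standardized 10-d sensor vectors — no windowing, matching
the per-sensor attribution that the importance analysis requires. Sensor
importance: per subject, normalized impurity importances from the forest
classifier (α_c) and regressor (α_r) are averaged elementwise (α), subject
α's are averaged across the cohort, and channels are ranked descending
(ties toward the lower channel index; a permutation-importance mode is
available). The top-k channels define the k-sensor ablation: the cohort is
restricted to those channels, a pair-complete arrangement is rebuilt for
them (the published fixture applies only at k=10; k=1 falls back to the
identity arrangement since a single channel has no pairs), and the full
cross-validation is re-run per k.

## Evaluation

Leave-one-trial-out cross-validation per subject: every trial is the test
set exactly once, folds ordered by trial id, standardization (and, in strict
mode, importances) fitted inside each fold's training data only. Metrics:
accuracy n_correct/n_total, R² = 1 − SS_res/SS_tot (computed on the
standardized angle scale; R² is invariant to the common affine rescaling),
and K×K confusion counts. Subject score = unweighted mean over folds; cohort
summary = mean ± sd across subjects.

Model comparison uses the Wilcoxon signed-rank test (the standard
nonparametric paired comparison): zero differences dropped with the count
logged, average ranks on ties, exact two-sided p for up to 25 nonzero pairs
via the rank-sum generating function (equivalent to enumerating all 2^m sign
assignments; doubled ranks keep the convolution integral), tie-corrected
normal approximation beyond. Significance threshold 0.05.

## Problem sizes in the test suite

The bundled acceptance experiments run scaled-down cohorts chosen as package
defaults for desk-scale verification: the noiseless recovery experiment uses
2 subjects × 3 trials with 1500-sample trials (7.5 s per finger); the
noise-robustness comparison uses 2.5 s segments (500-sample trials) over
three seeds; harness-level tests use 1.5 s segments. Full-protocol cohorts
(10 × 10 × 1000) are a single `SimConfig()` away and only cost wall-clock
time.

## Known limitations

* Windows that straddle a finger-segment boundary carry a modal label that
  flips when the boundary crosses row 21 of the 42-row window. Locating that
  flip to ±1 row exceeds the temporal resolution the two pooling stages
  leave the CNN, so residual test errors concentrate in a narrow band
  (± ≈ 5 rows) around the four per-trial segment transitions even on
  noiseless data; per-window accuracy saturates around 98–99% on short
  cohorts for this structural reason, not because of sensor noise.
* The GRU baseline shares the trainer but is the slowest to converge at
  10 epochs, mirroring its reference role as the weakest deep baseline.
* Kernel baselines scale quadratically in training samples; an optional
  seeded subsample (`ShallowConfig.subsample`, off by default, logged when
  used) bounds their cost on large cohorts.
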