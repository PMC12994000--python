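# Methods

## The model

`dqnencode` implements voxel-wise *encoding models* for continuous
visuomotor tasks: a layered value network (a deep Q-network, DQN) acts as a
fixed nonlinear feature map from game screens to unit activations, and a
linear model maps those activations onto each voxel's BOLD time series.
For voxel *v* with response $y_v \in \mathbb{R}^N$ and design
$X \in \mathbb{R}^{N \times P}$ of processed unit activations, the fit is
the lasso

$$\hat\beta_v = \arg\min_\beta \tfrac{1}{2N}\lVert y_v - X\beta\rVert_2^2
  + \lambda\lVert\beta\rVert_1 ,$$

with no intercept (all variables standardized). Prediction accuracy is the
Pearson correlation between predicted and measured held-out time series,
cross-validated over scanning sessions.

## Stimulus states and feature extraction

Raw grayscale frames at 45 Hz become *states* by taking the element-wise
maximum of consecutive frames (flicker suppression on alternating-frame
renderers) and resizing to 84×84. Resizing uses exact block averaging when
the source dimensions are integer multiples of 84 (deterministic,
area-style) and anti-aliased resampling otherwise. Each network input is a
stack of 4 consecutive states; the first three stacks of a session repeat
the initial state so the feature series keeps the state series' length
(the alternative — dropping the first three states — would desynchronize
features and logs).

Three architectures are provided, differing after the shared stack of
three valid-padding ReLU convolutions (32×8×8 stride 4, 64×4×4 stride 2,
64×3×3 stride 1; on 84×84 input the spatial sizes are 20, 9, 7). The
kernel/stride values are the standard ones for this input size — they are
the only valid-padding configuration consistent with those printed layer
shapes, which `conv_output_size` verifies:

* **feedforward** — fully connected 512-unit ReLU layer, linear Q-head;
* **dueling** — two 512-unit ReLU streams estimating state value and
  action advantages, recombined as $Q = V + A - \bar A$;
* **recurrent_dueling** — a single 512-unit LSTM cell between conv3 and
  the dueling streams. The hidden output is $h = o \odot \tanh(c)$, so
  recorded LSTM features lie in $[-1, 1]$; hidden and cell state are
  zeroed immediately *after* any time step flagged as an episode terminal,
  which makes post-terminal features exactly equal to a fresh forward pass
  (a property the tests assert bit-exactly).

The forward pass records every unit: conv activations post-ReLU,
fully-connected/stream activations, LSTM hidden outputs, and Q-values.
It is implemented in NumPy (stride-trick convolution lowered to BLAS
matmuls, explicit LSTM recurrence); streams here are short toy sessions,
and the explicit recurrence keeps the reset semantics auditable.
Reinforcement-learning training is out of scope: weights are loaded from
file or generated as seeded variance-scaled (He) initializations.

## Predictor pipeline

In order, per subject:

1. **Inactive-unit filter.** Units whose activation series is identically
   zero over the union of all sessions are dropped (rectified units can be
   permanently silent). Using the session union keeps predictor identity
   constant across cross-validation folds.
2. **Dual z-scoring.** Each unit series is z-scored over time (sample sd,
   n−1), then each time point across units. Temporal-first is the default
   so the across-unit pass acts on comparable scales; the order is a
   config switch. With a single predictor the across-unit pass is skipped
   (its sd is undefined).
3. **HRF convolution** at the 45 Hz stimulus rate with a canonical
   double-gamma kernel: gamma densities with (delay, dispersion) = (6 s,
   1 s) for the peak and (16 s, 1 s) for the undershoot, amplitude ratio
   6, 32 s support — the SPM convention. With shape $a = 6$ and unit
   scale, the peak density's mode sits at $a - 1 = 5$ s, which the unit
   oracle asserts.
4. **TR resampling.** Linear interpolation at acquisition times $k\,\mathrm{TR}$
   (TR = 0.987 s); volume counts follow the floor convention
   $\lfloor \text{duration}/\mathrm{TR} \rfloor$ (7 min → 425 volumes).
5. **High-pass filtering** by regression on an orthonormal discrete-cosine
   basis holding the constant and every component with period > 128 s
   (SPM-style drift removal; deterministic, and residuals are exactly
   orthogonal to the basis).
6. **Final temporal z-score**, so every design row enters the GLM with
   mean 0 and unit variance.

Voxel data are residualized by OLS against the six rigid-body motion
parameters plus the same DCT basis before modeling. Control designs reuse
stages 2–6 with raw (optionally block-averaged) pixels or per-button press
indicators as predictors; for these, "inactive" means zero-variance rather
than never-nonzero, since a constant pixel is nonzero but carries no
signal.

## Cross-validation and regularization

Five scanning sessions give a 5-fold CV where each session is held out
exactly once. Per fold, the lasso is fitted separately on each of the four
training sessions and the four coefficient vectors are averaged; the
held-out session is predicted as $X_{\text{test}}\bar\beta$. (The
alternative reading — concatenate the four sessions and fit once — is
available as `fit_mode="concatenate"`.) Zero-variance predictions (fully
shrunk models) score r = 0 with a warning rather than being dropped, which
keeps voxel maps complete and penalizes degenerate fits.

The regularization strength is shared across voxels: the mean CV
correlation is computed on a log-spaced grid over [0.005, 0.5], the
plateau is the longest contiguous run within 1% of the curve maximum, and
its midpoint is fixed. The default $\lambda = 0.07$ is the midpoint of the
[0.04, 0.1] plateau this procedure yields on the study-scale problem. The
solver is scikit-learn's cyclic coordinate descent, whose objective is
exactly the $1/(2N)$-scaled form above (stated because λ values are only
comparable under a fixed loss convention); tolerance 1e−6, at most 10⁴
sweeps, with non-convergence surfacing as a warning.

## Group statistics

Per-subject correlation maps are Fisher Z-transformed ($z = \operatorname{atanh} r$,
|r| = 1 clipped to 1−1e−7 with a logged warning) and tested voxel-wise
against zero with one-sample t-tests. Family-wise error is controlled by
Bonferroni over in-mask voxels — a deliberate, conservative substitute for
random-field theory, which requires smoothness estimates of real spatial
maps and is out of scope here. ROI contrasts use two-sample t-tests on
subject-level ROI means; factorial questions use repeated-measures ANOVA
with Greenhouse-Geisser-corrected degrees of freedom and partial η²
(backed by pingouin; a manual sum-of-squares oracle pins the
implementation in the tests). Custom contrasts are user-supplied zero-sum
weight vectors tested on within-subject contrast scores,
Bonferroni-adjusted. Plotting intervals use the Cousineau-Morey
normalization: remove each subject's mean, restore the grand mean, and
inflate the condition-wise CI half-width by $\sqrt{M/(M-1)}$ for M
conditions.

## Layer-to-hierarchy mapping

Each voxel surviving the group significance gate is assigned to the hidden
layer (conv1–3, lstm, layer4) whose layer-specific model predicted it
best; exact ties break toward the earlier layer (deterministic, and
conservative for hierarchy claims — float ties are rare and counted). Per
ROI, winner proportions over the five layers form a composition; the
early(conv1–3)/late(lstm, layer4) balance is analyzed as
$\log\left(\frac{p_1+p_2+p_3+\varepsilon}{p_4+p_5+\varepsilon}\right)$ with
symmetric pseudo-count $\varepsilon = 1/(2\,n_{\text{voxels}})$, and ROI
pairs are compared with paired t-tests across subjects, Bonferroni-
corrected. Subject-wise compositions are the default (the paired tests
require per-subject values); pooling voxels across subjects first is
available for visualization.

## Synthetic data

The generator's purpose is recoverable ground truth, so the generative
model is exactly the linear model the analysis assumes:

* **Toy game** — a ball bouncing on an 84×84 grid with a scripted paddle
  that occasionally freezes, a static textured playfield, episode
  terminals on misses, action/reward logs at 45 Hz; 7-minute sessions are
  18,900 frames, and every session ends with a terminal flag.
* **Layer features** — either real forward passes through seeded fixture
  weights, or smooth Gaussian-filtered series (0.5 s kernel) with the
  per-layer nonlinearity applied (ReLU for conv/fc, tanh for lstm) when
  the network itself is not under test.
* **BOLD** — each voxel draws 3 predictors (`sparsity`) from one
  designated layer's processed design, mixes them with Gaussian weights
  fixed across sessions, optionally adds per-voxel linear combinations of
  6 smooth motion series, and adds AR(1) noise with φ = 0.3 whose
  *marginal* variance is scaled to the requested SNR, so the correlation
  ceiling $\sqrt{\mathrm{SNR}/(1+\mathrm{SNR})}$ is exact by construction
  (equal signal and noise variance → ceiling $\sqrt{0.5} \approx 0.7071$).
* **ROIs** — disjoint rectangular slabs, one per source layer, mimicking
  a hierarchy.

What the generator does *not* emulate: real game dynamics and human play
statistics, scanner artifacts beyond AR(1) noise and linear motion
confounds, spatial autocorrelation between voxels, and nonlinearity or
hemodynamic variability in the BOLD response. Passing recovery tests
therefore demonstrate the correctness of the estimation machinery under
the model's own assumptions, not its adequacy for any particular real
dataset.

## Verification experiments and problem sizes

The acceptance-grade experiments (also run by `scripts/acceptance.py`) use
these sizes, chosen so the whole suite runs comfortably on one CPU:

* **Noise-free recovery** — 5 sessions × 200 volumes, 8 predictors built
  through the full pipeline, 3-sparse mixtures; mean r ≥ 0.99.
* **Noise ceiling** — 50 seeded repetitions at SNR 1 with AR(1) φ = 0.3;
  realized CV r within ±0.03 of $\sqrt{0.5}$. This experiment contains no
  motion stage: regressing smooth nuisance series out of y without
  projecting X onto the same complement (Frisch-Waugh) removes a
  non-negligible share of any temporally smooth signal, deflating r below
  the analytic ceiling for reasons unrelated to the estimator. The effect
  is real and visible in the hierarchy cohort, where motion is injected
  and removed end-to-end and ROI-mean r sits ≈ 0.1 below ceiling.
* **Hierarchy cohort** — 10 subjects, 5 ROIs × 200 voxels, SNR 1, motion
  amplitude 0.3; ≥ 90% of eligible voxels must be reassigned to their
  generating layer and the early/late log-ratio gradient must survive the
  paired Bonferroni tests.
* **Null safety** — 100 cohorts at vanishing SNR (10⁻⁶): at least 95 must
  produce zero FWE-significant voxels; plus 1000 null repetitions of the
  one-way rm-ANOVA, whose GG-corrected type-I rate must be 0.05 ± 0.02.

## Known limitations

* Bonferroni FWE is conservative relative to random-field or
  permutation-based correction; a max-statistic permutation option exists
  in scope but real-map smoothness modeling does not.
* The lasso's λ is shared across voxels by design (matching the plateau
  procedure); per-voxel tuning is deliberately not provided.
* The synthetic motion model (smooth Gaussian processes) is harsher than
  real motion for the residualization stage, as noted above.
* Greenhouse-Geisser is always applied; no Huynh-Feldt fallback.
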