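# Methods

`dissomap` predicts the in vitro dissolution profile of HPMC matrix
sustained-release tablets from chemical images of the tablet surface. This
note describes the models, the synthetic benchmark, the numerical choices
and the limits of what the tests demonstrate.

## Problem and pipeline

Drug release from a hydroxypropyl methylcellulose (HPMC) matrix tablet is
governed mainly by two formulation variables: the HPMC content (more
polymer → a stronger gel layer → slower release) and the HPMC particle
size (coarser polymer hydrates into a less coherent gel → faster release).
Both are visible in a chemical image of the tablet surface. The pipeline,
run independently for Raman and NIR imaging, is

1. **Preprocessing.** Raman: Savitzky–Golay smoothing (window 15, 2nd-order
   polynomial), asymmetric-least-squares Whittaker baseline subtraction
   (λ = 10 000, p = 0.001) to remove the fluorescence background, then
   total-area normalization. NIR: Savitzky–Golay first derivative (window
   15, 2nd order). Pure-component spectra receive the identical treatment —
   a requirement for the unmixing step to be consistent.
2. **CLS unmixing.** Classical least squares treats each preprocessed pixel
   spectrum as a linear combination of the five preprocessed
   pure-component spectra (drug, HPMC, MCC, lactose, magnesium stearate)
   and solves for per-pixel abundances; the HPMC plane × 100 is the
   concentration map (31×31 pixels for Raman, 48×48 for NIR, both covering
   ≈1200×1200 µm²). Abundances are unconstrained least squares with
   negatives clamped to zero; no closure constraint is imposed, so
   systematic bias stays visible. The *mean-shift correction* (adding the
   mean bias against reference values) is applied for reporting only,
   never to model inputs — a trained network absorbs a constant bias.
3. **Feature extraction.** Two scalars per tablet: the arithmetic mean of
   the HPMC map, and a particle-size estimate from a small CNN regressor.
4. **Dissolution ANN.** A feedforward network with inputs (mean HPMC
   concentration, particle size), one tanh hidden layer of 1–10 neurons,
   and 37 linear outputs — one per point of the dissolution schedule
   (2, 5, 10, 15, 30, 45, 60 min, then every 30 min to 960 min).
5. **Evaluation.** f2 similarity factor with the 85% truncation rule, RMSE
   and R² against the measured (synthetic ground-truth) profiles of the 8
   validation formulations.

## Dissolution metrics

f2 = 50·log₁₀(100·[1 + (1/n)Σ wₜ(Rₜ−Tₜ)²]^(−1/2)) with the reference
profile R and test profile T; f2 = 100 for identical profiles and ≥ 50 is
the conventional similarity threshold. The −1/2 exponent is the regulatory
form (it makes f2 decrease with disagreement). Before f2, points after the
*reference* exceeds 85% release are dropped except the first such point;
truncation is keyed to the measured profile, following regulatory practice.
RMSE = √(Σ(Rₜ−Tₜ)²/n) and R² = 1 − Σ(Tₜ−Rₜ)²/Σ(Rₜ−R̄)² are computed on the
full 37-point grid without truncation. Default weights wₜ = 1.

## Particle-size CNN

Input: one single-channel concentration map in w/w% (divided by 100).
Target: the sieve label in µm — 45, 63, 100 or 150, the pore size of the
smallest sieve the HPMC fraction passed — z-scored during training.
Architecture: two blocks of convolution → ReLU → dropout (0.2) → batch
normalization → average pooling, with 8 and 16 filters, 3×3 and 5×5
kernels, and pools of 2 then 9; the second pool is nearly global, reducing
the feature maps to channel-wise texture statistics before a 16-unit dense
layer and the scalar output. This keeps the parameter count near 4k: with
only 96 training maps, wider heads memorize the training tablets and lose
~2× held-out accuracy. Training: Adam on MSE, batch 16, max 100 epochs,
staircase learning rate lr(e) = 0.001·0.9^⌊(e−1)/10⌋, validation loss
recorded every 5 epochs. Inference clips predictions to [22.5, 200] µm so
the downstream ANN only sees sizes in its trained domain. The CNN is
implemented directly on numpy (im2col convolutions, analytic backprop):
the tensors are tiny and the from-scratch implementation keeps training
bit-reproducible for a fixed seed.

Calibration tablets are split 96/16 into training and early-feedback
validation, stratified by formulation; one CNN per modality (31×31 and
48×48 inputs), no weight sharing, no augmentation.

## Bayesian-regularized ANN

The dissolution network is trained by Levenberg–Marquardt on the
regularized objective F = β·E_D + α·E_W (E_D the summed squared residuals
in standardized units, E_W the summed squared weights), with MacKay
evidence updates after each accepted step: γ = N − 2α·tr(H⁻¹),
α = γ/(2E_W), β = (n_res − γ)/(2E_D), where H = 2β·JᵀJ + 2α·I and γ is the
effective number of parameters. Inputs and outputs are z-scored on the
training statistics (tanh saturates otherwise). Training stops at 1000
epochs, when the objective-gradient infinity norm falls below 1e−7, or
when the LM damping exceeds 1e10 (no descent direction left). Because the
network has at most 437 weights, JᵀJ and Jᵀr are assembled in closed form
from the two-layer structure — the full Jacobian is never materialized —
which makes a 100-model restart ensemble a matter of seconds.

Model selection: for each hidden width 1–10, several independently seeded
runs are trained and each model is scored by the arithmetic-mean f2 (with
truncation) of its predictions over all validation tablets; the best
scoring model wins. The package default is 10 restarts per width (a
desk-scale setting whose selection behaviour matches the full protocol);
`paper_scale=True` raises it to 100. The orchestration default caps LM at
150 epochs per run — convergence on these smooth two-input targets occurs
well before that — while `train_bayesreg` itself defaults to the full 1000.
Predictions are clamped to [0, 110]% with no monotonicity forcing.

## Synthetic benchmark

The generator reproduces the study conditions end to end; every stage of
the pipeline is tested against its ground truth.

* **Design grid.** 36 compositions: 8 w/w% drug, 20% MCC, 2% MgSt, lactose
  balance; HPMC at 7 levels (10–30%) × 4 sieve fractions (<45, 45–63,
  63–100, 100–150 µm) for 28 calibration designs, plus 8 validation
  designs off the calibration grid. Four replicate tablets per composition
  (112 calibration + 32 validation records); replicates get 1% relative
  Gaussian jitter on the HPMC fraction (filler rebalanced).
* **Spectra.** Raman: 4–7 Gaussian peaks of width 2–5 bands on a 320-band
  axis (200–1800 cm⁻¹); NIR: 3–5 broad peaks of width 15–45 bands on a
  240-band axis (4000–7800 cm⁻¹). Band counts are reduced relative to
  instrument resolution to keep the 144-record benchmark desk-scale; CLS
  operates identically at any band count above the component count. The
  MCC spectrum is constructed as a nonnegative shape mixture whose Pearson
  correlation with HPMC equals `similarity_target` (default 0.9, solved by
  bisection) — the HPMC/MCC near-collinearity is the core difficulty of
  the unmixing problem and is a controlled knob. Raman libraries are
  rescaled to equal baseline-corrected signal area (an intensity
  calibration; exact, because the AsLS baseline is positively
  homogeneous).
* **Maps.** HPMC placed as non-overlapping disks, diameter uniform over
  the sieve interval (≥15 µm floor: finer particles are unresolvable at
  the 25–40 µm pixel pitch), rasterized with 5×5 sub-pixel sampling, until
  the realized HPMC area fraction is within 0.02 of the design fraction
  (area fraction is the w/w proxy; equal densities assumed). Remaining
  surface is the homogeneous mixture of the other four components.
* **Cubes.** Pixel spectrum = fraction-weighted sum of pure spectra + a
  smooth baseline scaled by the local MCC fraction (Raman: a 4th-order
  polynomial fluorescence-like hump, amplitude 0.5 — MCC is the dominant
  fluorophore here; NIR: a gentle linear slope, amplitude 0.1) + i.i.d.
  Gaussian noise (σ = 0.01 ≈ 1–3% of peak intensity).
* **Dissolution.** Weibull release F(t) = 100·(1 − exp(−(t/τ)^0.9)) with
  τ = 300 min·(c/0.20)^1.2·(45/d_mid)^0.5, c the HPMC fraction and d_mid
  the sieve midpoint (22.5 µm for <45): strictly slower with more HPMC,
  faster with coarser HPMC, spanning the 16 h window. Measured profiles
  add ±3σ-truncated Gaussian noise (σ = 1%), then are clipped to [0, 100]
  and made non-decreasing, as cumulative release must be.
* **Seeds.** All randomness derives from one master seed via SeedSequence
  spawning; datasets and full experiment reports are byte-reproducible.

What the generator does **not** emulate: detector physics and line shapes,
cosmic-ray spikes, focus/scatter artefacts, 3-D tablet structure (surface
maps only), response-factor differences between components, and any
systematic difference between the imaged tablet face and the tablets that
are dissolution-tested. Passing tests therefore demonstrate that the
algorithms are implemented correctly and that the pipeline recovers known
structure under realistic noise — not that the accuracy figures transfer
to measured spectra.

## Numerical choices and degenerate inputs

* Savitzky–Golay uses band-index units (no physical Δ scaling — CLS is
  invariant when the library is treated identically) and least-squares
  polynomial edge fits (scipy's `interp` mode; no padded intensity).
* The AsLS baseline iterates weighted banded solves (second-difference
  penalty; `solveh_banded`) to a weight-pattern fixed point, max 50
  iterations, with a secondary stop when the baseline itself moves less
  than 1e−10 of the signal scale (on near-flat inputs the binary weights
  can flip on numerical noise forever); non-convergence is logged and the
  last iterate returned.
* Normalization raises a degenerate-input error below area 1e−6 (a
  baseline-corrected flat spectrum is all noise — no direction to keep).
* `fit_cls` raises on numerical rank < K (e.g. duplicated spectra) and
  logs a warning above condition number 1e6.
* LM escalates damping ×10 on rejected steps (÷10 on accepts, μ₀ = 0.005);
  a Cholesky failure escalates damping rather than aborting; γ is clipped
  to (0, N].
* Ensemble runs that fail score −∞ and stay in the score table with their
  error; selection requires at least one success.
* Ties in the modality win count split 0.5/0.5.

## Known limitations

* The CNN reads texture from *clean* concentration maps well; under heavy
  spectral noise or stronger HPMC–MCC correlation its size estimate
  degrades gracefully but is not recalibrated.
* The 100–150 µm class sits at the clip ceiling of what 31×31 maps resolve
  (a 150 µm particle is <4 pixels wide at 40 µm pitch).
* Bayesian regularization uses the Gauss–Newton Hessian approximation in
  the evidence update, as is conventional; no full-Hessian path exists.
* The f2-based selection reuses the validation set that the reported
  metrics are computed on — deliberately mirroring the study protocol
  rather than best statistical practice.
* Only the Levenberg–Marquardt trainer is implemented for the ANN; there
  is no first-order fallback path.
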