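# Methods

This note records the model as implemented, the conventions and numerical
choices behind it, what the synthetic data does and does not emulate, and the
known limitations.

## Wavelet downsampling

One level of a separable, periodized 2D discrete wavelet transform replaces
pooling. Analysis filtering along one axis is

    y[k] = Σ_i f_i · x[(2k + i) mod N],

circular extension followed by keeping even-indexed outputs. Periodization is
used because it is the only standard boundary mode that yields exactly
H/2 × W/2 coefficients for every supported filter length; inputs with an odd
side are rejected rather than padded (the CLI resizes images to a multiple of
16 up front). Rows are transformed first, then columns, and "LH" names the
row-high-pass/column-low-pass (horizontal detail) band.

Low-pass coefficients come from the standard published tables (the
PyWavelets convention, with the analysis filter flipped into convolution
orientation); both high-pass filters are *derived* by the quadrature-mirror
recurrence `h_i = (−1)^i l̃_{2n+1−i}` from the dual low-pass. For filter
length L the index window n = L/2 − 1 is the unique choice keeping all
indices valid. The derived filters agree with the published high-pass tables
up to the documented reversal/sign convention, and `validate_bank` reports
the residuals of every identity (orthonormality `Σl² = 1`, DC gain
`Σl = √2`, QMF cross-product `Σ l_i h_i = 0`, and the biorthogonal dual-delta
`Σ_k l_k l̃_{k+2m} = δ(m)`); all are below 1e−10 for every registered
wavelet.

Normalization is orthonormal, so one 2D level maps a constant c to a
constant 2c and conserves energy exactly for orthogonal families. Synthesis
uses the dual pair with the same phase, giving perfect reconstruction to
machine precision (orthogonal) or ~1e−12 (biorthogonal); the inverse
transform exists only for verification and visualisation — the network never
reconstructs. Because decimated circulant operators for feature-map sides
are small, the transform is implemented as two cached matrix products per
subband, which also makes the LL-pooling layer a plain linear operator whose
gradient is the transposed filtering.

The registry is restricted to haar, db2–db7, sym2–sym7 and the
bior/rbio {1.1, 2.2, 3.3, 4.4} variants — the families the method was
evaluated over; one wavelet is used at all four encoder levels. The scale S
of the orthogonal families is read as the vanishing-moment order (filter
length 2S), and db1/sym1 coincide with haar.

## Residual attention gate

Both inputs are projected by biased 1×1 convolutions to a common
intermediate width (chosen equal to the skip channel count, keeping gate
capacity proportional to depth), batch-normalized per branch, summed, passed
through ReLU, projected to one channel by a biased 1×1 convolution and
squashed by a sigmoid. The single-channel coefficient α is broadcast across
all skip channels: `x^o = (1 + α)·x^l`. The exact normalization placement in
the original description is ambiguous; the per-branch-then-sum ordering used
here is documented, not claimed to match bit for bit. Because α ∈ (0, 1) the
gate only scales the skip between 1× and 2× — it cannot zero a feature, which
is the point of the residual term.

## Architecture

Depth 4; channel ladder base×(1, 2, 4, 8) with a base×16 bottleneck (the
64…1024 ladder at base 64). The gating feature is the decoder feature
*after* its upsample block, so gate inputs share both spatial size and
channel count. Gated skips are concatenated with the decoder feature and
fused by a conv block (classic U-Net convention; summation would also fit
the text but concatenation matches the stated 64–512 gate output widths).
Bilinear upsampling uses half-pixel centres with edge clamping, implemented
as separable interpolation matrices. Batch normalization uses biased batch
variance, momentum 0.1, and running statistics in evaluation mode.
Convolutions are Kaiming-uniform initialized (bound √(6/fan_in)), biases
zero, all seed-controlled. The head is a 1×1 convolution plus sigmoid; all
losses consume probabilities, not logits.

Replacing wavelet pooling by 2×2 max pooling (`downsample="maxpool"`) or
disabling the gates (`use_attention=False`) changes no shape contract, and
the wavelet choice never changes the parameter count. Parameter counts are
reported (`WRANet.param_count()`) but not asserted against any published
figure, since block internals are under-specified in the source description.

The whole network runs on a small reverse-mode autodiff engine over NumPy
arrays (`wranet.autograd`); 3×3 convolution is im2col + GEMM with an
explicit adjoint, and parameters are float32 while all wavelet/filter-bank
mathematics is float64.

## Objectives and metrics

`L = α·L_BCE + β·L_Dice` with defaults α = 0.4, β = 0.6. Probabilities are
clamped to [1e−7, 1 − 1e−7] before logarithms. The Dice smoothing factor
defaults to λ = 1.0 (the most common choice; the source leaves it unstated)
and is exposed in `LossConfig`. Training Dice uses soft probabilities;
evaluation metrics binarize at 0.5. On an image where ground truth and
prediction are both empty all four metrics are 1; where exactly one is
empty, all are 0. Metrics are averaged per image (macro) by default, with a
pooled-count (micro) mode behind a flag. Note the documented degeneracy of
the soft Dice loss: a perfectly predicted empty mask scores loss 1, one
reason the BCE term is kept in the mixture.

## Synthetic data

Each sample is a smooth textured background (Gaussian-filtered noise,
amplitude 0.08, base level ≈ 0.15–0.2) with 1–3 bright deformed ellipses:
axis ratio 0.7–1.3, boundary radius modulated by three sinusoidal harmonics
(amplitudes ≤ 0.12), brightness 0.65–0.9 with a soft radial profile, plus
additive Gaussian noise (σ = 0.03 by default; checkerboard and salt-pepper
models are available — the checkerboard pattern is pure Nyquist content that
a Haar low-pass removes exactly). The blob footprint is the mask. Lesion
diameters default to 8–20 px at 64×64; presets map the clinical size strata
(> 7 mm, 3–7 mm, < 3 mm) at a fixed scale of 2 px/mm, clipped at 3 px so a
lesion is always resolvable. Masks are guaranteed non-empty with foreground
fraction in (0, 0.5) unless `allow_empty` is set; degenerate draws are
resampled. Generation is fully deterministic under the spec seed.

What the generator does *not* emulate: MRA physics, vessel trees, partial
voluming, realistic polyp texture, or inter-scanner variation. Passing the
end-to-end tests therefore shows that the implementation optimizes its
objective and that the architecture can learn blob-on-texture segmentation;
it says nothing quantitative about clinical data.

## Training

Adam with β₁ = 0.9, β₂ = 0.999, eps = 1e−8, weight decay 5e−4 (L2 folded
into the gradient), learning rate 1e−4, batch size 4, 200 epochs, constant
schedule — the published configuration — are the estimator defaults; all are
overridable. Shuffling, initialization and data generation share one seeded
generator, so a (seed, config, data) triple fully determines the run. A
non-finite loss aborts with a diagnostic. When a validation fraction is set,
the best-validation-Dice parameters are restored at the end of fit and a
per-epoch history is kept. Both a 70/30-style holdout and k-fold
cross-validation are supported (the source describes both; the CLI exposes
`--val-fraction` and `cv`).

The repository's own experiments are scaled down to CPU size as a design
choice: 200 synthetic 64×64 images, base 16 channels, sym6, hybrid loss,
10 epochs at learning rate 1e−3 (the tiny network trains stably at a rate
ten times the full-scale default, and reaches its plateau within ten
epochs). Under those conditions held-out Dice is ≈ 0.98–1.0 versus 0 for
the all-background predictor; `scripts/acceptance.py` recomputes this
end to end.

## Known limitations

* Single-level DWT only; no stationary/packet transforms or learned filters.
* Binary segmentation only; no Hausdorff/boundary metrics.
* The NumPy engine is CPU-bound and single-device; full-scale (base 64,
  256×256, 200-epoch) training is out of reach here — the full-size network
  is exercised for shape/gradient contracts, not trained to convergence.
* pywt is used for coefficient tables only; its transform routines appear
  solely as an independent cross-check in tests (its decimation phase
  differs by the documented convention for asymmetric filters).
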