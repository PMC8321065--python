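# Methods

## Data model and representations

A subject's scan is a real 4D grid (H, W, D, T): three spatial voxel
axes and T time frames of BOLD signal.  A parcellation atlas is an
integer 3D grid on the same voxel lattice; 0 is background, the N
distinct nonzero labels are regions, and every ROI-indexed structure
orders regions by ascending label.  The package assumes the scan and
atlas already share one grid (registration and other neuroimage
preprocessing happen upstream); grid mismatches are hard errors, never
resampled.

Two derived representations feed the classifier:

* **ROI mean time series** (N × T): for each region, the arithmetic
  mean of its voxels' series, per frame.
* **Connectivity fingerprint** (H, W, D, N): the Pearson correlation
  of every voxel's series with every region's mean series.  It is
  computed on the (H·W·D, T) unfold of the scan (C-order voxel
  linearisation — an internal choice that never leaks into outputs)
  and stored re-folded to the spatial grid so the 3D network can use
  the region axis as its input channels.
* **Connectivity vector** (length N(N−1)/2): the strict upper triangle
  of the N × N inter-regional correlation matrix, row-major over pairs
  (i, j), i < j.  The lower triangle and unit diagonal are redundant
  and dropped; at N = 116 this leaves 6670 features.

Correlations are raw Pearson coefficients; no Fisher z-transform is
applied.  A zero-variance series (constant voxel, empty background)
correlates 0 with everything by convention rather than NaN, keeping
the networks finite; results are clipped to [−1, 1] against rounding.

## Architectures

The image branch is an 18-layer residual network with every 2D
convolution replaced by its 3D counterpart.  The fingerprint is
reshaped to (N, H, W, D) so regions are the input channels.  Stages at
full scale (116 channels, 61×73×61 grid):

| stage    | operator                                   | output           |
|----------|--------------------------------------------|------------------|
| conv1    | 5×5×5, 64, stride (2,2,2), pad 3           | 64 × 32×38×32    |
| max pool | 1×3×3, stride (1,2,2), pad (0,1,1)         | 64 × 32×19×16    |
| stage 1  | [1×3×3, 64] ×2 basic blocks, stride 1      | 64 × 32×19×16    |
| stage 2  | [1×3×3, 128] ×2, first stride (1,2,2)      | 128 × 32×10×8    |
| stage 3  | [3×3×3, 256] ×2, first stride (1,2,2)      | 256 × 32×5×4     |
| stage 4  | [3×3×3, 512] ×2, first stride (1,2,2)      | 512 × 32×3×2     |
| avg pool | global                                     | 512              |
| fc       | 512 → 2                                    | 2                |

Paddings are the unique smallest solutions of the output-size
arithmetic floor((L + 2p − k)/s) + 1 for this table: pad 3 for conv1,
(0,1,1) for the pool and the 1×3×3 convolutions, (1,1,1) for the
3×3×3 ones.  Each basic block is conv–BN–ReLU–conv–BN plus a shortcut
(projection by a 1×1×1 convolution at the block's stride whenever the
shape changes), with ReLU after the sum — the standard residual
design; the source description cites standard ResNet-18 without
spelling out normalisation, so batch normalisation is used after every
convolution and no dropout anywhere.  All channel counts and grid
sizes are configurable so a scaled-down model (e.g. 8 channels on a
16³ grid) trains on one CPU; the table above is asserted only at the
full-scale configuration.

The vector branch is an MLP 6670 → 100 → 100 → 100 → 2 with ReLU after
each hidden layer (687,502 parameters at full scale).

The fused classifier bypasses both output layers: it concatenates the
ResNet's 512-D post-pool feature with the MLP's 100-D last hidden
activation and passes the 612-D vector through four fully-connected
layers.  Only the head's final width (2) is fixed by the problem; the
intermediate widths default to 612 → 256 → 64 → 16 → 2 (monotone
tapering) and are configurable in `FusionConfig`.

## Training protocol

Phase I trains each encoder independently, from scratch, with
minibatch SGD (batch 8, momentum 0.9, weight decay 0 — unstated
upstream, so the minimal assumption), softmax cross-entropy, and a
step learning-rate schedule lr(e) = base · 0.1^floor(e/step):

* image branch: base 1e-2, 30 epochs, step 6;
* vector branch: base 1e-2, 50 epochs, step 5.

Phase II deep-copies the Phase-I encoder weights into the fused
network (bit-exact before the first step; the Phase-I networks are
left untouched), freshly initialises the head, and trains everything
end to end — at full scale with base 1e-5, 30 epochs, step 8.  There
is no validation split or early stopping: epoch counts are fixed.  The
train/test split is drawn uniformly at random once, persisted, and
reused by both phases, so no held-out subject influences any training
step.  Class balance is not enforced (a stratified option exists, off
by default).  Every source of randomness (split, initialisation,
per-epoch shuffling) derives from the run seed; with a fixed seed two
runs produce identical splits, batch orders, weights, and metrics.

The desk-scale profile used by the tests and the default pipeline
keeps the Phase-I recipe but shortens it (image branch ~10 epochs,
vector branch ~20–25), and runs Phase II at base 1e-3 for ~10–15
epochs: with tens of subjects the freshly-initialised head cannot move
at 1e-5 within a sensible budget.  The full-scale profile
(`full_scale_config()`) keeps the published values verbatim.

## Evaluation

The diagnosed condition is the positive class.  Accuracy, precision,
recall and F1 follow the standard confusion-table formulas; a metric
whose denominator is zero is reported as 0 with a warning so automated
runs always emit a complete report.  Note one published operating
point is internally inconsistent at three decimals: the harmonic mean
of precision 0.737 and recall 0.759 is 0.7478, which rounds to 0.748,
not the tabulated 0.749; the regression test for that row therefore
allows the 0.0015 rounding-propagation band while the other rows
reproduce exactly.

## Synthetic cohorts

The generator emulates exactly the structure the method assumes and
nothing more.  Each group g has a latent correlation matrix Σ_g: unit
diagonal, `base_corr` (default 0.2) off-diagonal, and
`base_corr ± effect_delta/2` (sign by group) on the designated effect
pairs.  Σ_g is projected to the nearest valid correlation matrix
(eigenvalue clipping at 1e-6, then re-normalisation to unit diagonal).
A subject's N latent series of length T are drawn from N(0, Σ_g) via
Cholesky; each voxel's series is its region's latent plus independent
N(0, `voxel_noise_sd`²) noise.  Atlases tile the grid into contiguous
near-cubic blocks (no background); the seed permutes block labels.

`modality_split` routes a fraction of the effect pairs to *fine*
(voxel-scale) structure: for a fine pair (a, b), half of region a's
voxels add +c·latent_b and half add −c (c = ±effect_delta/2 by group;
an odd middle voxel gets 0).  The halves cancel exactly in the region
mean, so fine effects are invisible to the ROI-pair vector but appear
as a group-dependent spatial pattern in the fingerprint — signal only
the image branch can use.  This is what lets the fused model
demonstrably improve on either single branch.

Default conditions (16³ grid, 8 regions, T = 120, 20 subjects per
group, effect_delta 0.6, noise sd 0.5) give a strongly separable
cohort on which the full pipeline reaches held-out accuracy ≥ 0.9 in
minutes on one CPU.  The complementarity experiment instead uses a
deliberately unsaturated regime (12³, 6 regions, T = 80, delta 0.3,
split 0.5): at the strong settings each single branch already scores
1.0 and the ablation ordering would be unfalsifiable.  What the
generator does **not** model: haemodynamic response convolution,
temporal autocorrelation, multi-site batch effects, motion artifacts,
realistic anatomy.  Passing tests therefore show the pipeline
correctly exploits group differences in correlation structure — not
that it reaches any particular accuracy on real multi-site data.

## Explanations

Grad-CAM at a chosen convolutional stage: per-channel weights are the
spatial mean of the class score's gradient at that stage; the map is
the ReLU of the weighted activation sum, trilinearly upsampled
(cell-centre interpolation) to the brain grid and max-normalised to
[0, 1] (an all-zero map is allowed and flagged).  The default stage is
the last residual stage, standard practice.  Attribution runs through
the image branch only — the vector branch has no spatial layout — a
documented limitation.  An input-gradient mode (summed absolute
gradient of the class score w.r.t. the fingerprint) provides
voxel-resolution attribution; the localisation test uses it because at
a 16³ desk-scale grid the deep stages retain almost no spatial
resolution (e.g. 9×1×1), which makes layer-level maps unreliable
there.  On one geometric point this implementation is deliberate: all
three activation axes after the channel reduction are spatial (the
region axis is consumed by the channel sum), so all three are
upsampled; no activation axis is averaged away.  Overlays blend the
heat (a "hot" colormap, weight = alpha·heat) over the grayscale
anatomy so zero heat reproduces the anatomy exactly.

## Numerical choices

* Network arithmetic in float32; connectome construction, CAM
  post-processing and metrics in float64.  Volumes are stored float32.
* Convolution is chunked im2col + GEMM (≤ ~120 MB per buffer), so a
  full-scale forward pass fits comfortably in memory and takes a few
  seconds on one CPU; gradients use slice-wise scatter-add.  Backward
  correctness is pinned by finite-difference tests, not by symmetry of
  the code.
* Batch-norm running statistics update with momentum 0.1 and the
  unbiased variance; evaluation mode uses the running values, which is
  also the mode used for prediction and Grad-CAM.
* Zero-variance correlation = 0; correlations clipped to [−1, 1];
  softmax computed with max subtraction; cross-entropy on float64.
* Ties in max pooling resolve to the first window element (argmax
  convention), fixed and deterministic.

## Known limitations

* The synthetic generator's simplifications above; in particular
  fine-pair modulation is a stylised stand-in for sub-regional
  functional heterogeneity.
* Single-device, single-threaded training only; no data augmentation,
  cross-validation, or hyperparameter search.
* Published headline numbers on the real multi-site cohort (accuracy
  0.74, recall 0.95) are out of reach at desk scale by design: they
  require the external dataset and long training; the package instead
  verifies the architecture, protocol, and qualitative behaviour.
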