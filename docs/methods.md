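# Methods

This note records the models, the defaults and the genuinely open design
choices behind `wedgenet`, in the spirit of a package methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Forward model and geometry

A slice is a square `[0,1]` image whose support lies strictly inside the
inscribed circle of the grid (content outside the circle is not measurable
by a rotating parallel-beam geometry; the projector warns if it is present).
Tilt grids are uniform, span exactly one half-turn (`max − min + step =
180°`) and default to `−90..+89°` in 1° steps.  Sinograms are stored rows =
angles, columns = detector bins, one bin per pixel column; this orientation
convention is fixed project-wide.

The discrete Radon transform is computed by rotate-and-sum using the same
rotation center as `skimage.transform.radon` (so `iradon`/`iradon_sart`
invert it directly) but with cubic-spline interpolation: on
piecewise-constant phantoms, linear interpolation loses per-row mass at the
~2×10⁻³ relative level while the cubic projector stays at a few 10⁻⁴, which
is what makes a per-row mass-conservation oracle at 10⁻³ usable.  The cost
of cubic splines is small ringing: line integrals can undershoot zero by a
fraction of a percent.  `normalize_sinogram` therefore stays exactly linear
and invertible (dividing by the detector bin count, the largest possible
line integral of a `[0,1]` image), and the clipping to `[0,1]` happens only
in the network-facing dataset builder.

A missing wedge is parameterized by the **total** missing degrees; a 45°
wedge on the default grid removes exactly the 45 rows with `|θ| > 67.5°`.
Missing rows are zero-padded for the networks but **excluded** from the
classical solvers: a zero row is a false constraint for SART/TVM, and
contributes nothing to filtered back projection anyway.

## Phantoms and augmentation

The synthetic corpus emulates cross-sections of faceted or rounded
nanocrystals: 1–64 random filled disks and convex polygons per image,
per-shape uniform intensity in `[0.2, 1.0]`, overlaps resolved by maximum
(flat regions with sharp edges), everything clipped two pixels inside the
inscribed circle so interpolation cannot push mass out.  Image size defaults
to 128×128 (no canonical size exists for this kind of corpus; 128 keeps a
180-view sinogram tractable on a CPU) and is configurable.  Augmentation
applies, in a fixed order: pad-resize (shrink by 1/√2 so any rotation stays
on the grid), seeded random rotation, flips, a small random affine
(scale/shear within ±5% by default), and additive Gaussian noise (σ = 0.01
default) clipped back to `[0,1]`.  Interpolation is bilinear with zero
padding, because the projector assumes zero background.  Libraries are
written as float32 TIFFs with a JSON manifest; a 10:1 train/validation split
mirrors a 50,000/5,000 split at full scale.

## Classical baselines

* **WBP** — Ram-Lak ramp filtering (Hann apodization by flag) and back
  projection over the acquired angles, via `skimage.transform.iradon`.
* **SART** — zero initial estimate, relaxed residual back-distribution via
  `iradon_sart`; defaults 20 iterations, relaxation 0.15 (common literature
  values; these methods are known to need manual tuning, so the defaults are
  documented, recorded in provenance, and not tuned per image).
* **TVM** — SART sweeps alternated with descent on isotropic total
  variation.  The TV step length is `tv_weight` times the norm of the last
  data update divided by the number of inner steps, with backtracking
  halving so no inner step ever increases TV; `tv_weight = 0` reduces
  exactly to SART.  Defaults: 30 outer iterations, 10 inner steps, weight
  0.1.

Reconstructions are deliberately **not** clipped to `[0,1]`: WBP overshoot
is informative for the de-artifact network; clipping happens only at
metric/export time.

## Networks

No deep-learning framework is assumed: `wedgenet.nn` is a small float32
layer library (conv2d with stride/dilation via im2col, group/batch norm,
leaky ReLU, pooling, linear) with hand-written backward passes, verified by
finite-difference tests, plus Adam and RMSprop.

* **Inpainting generator** — RRDB backbone: feature conv, `n_blocks`
  residual-in-residual dense blocks (three 5-conv dense blocks each, 0.2
  residual scaling), trunk conv with a global residual, one dilated conv
  (dilation 2) to widen the receptive field, output conv.  No normalization
  and no pooling, so inference is deterministic and full-resolution.
  Defaults: 8 blocks (23 mirrors the original RRDB source scale), feature
  depth 64, growth 32.
* **Inpainting discriminator** — conditional (candidate sinogram stacked
  with the masked input), asymmetric 5×3 input kernel (sinograms are
  angles × bins, not square), then a slow path (5 strided dilated conv/GN
  blocks) and a fast path (3 strided blocks); pooled features concatenated
  into one scalar score.  Group normalization with 4 groups, feature depth
  64.  The exact published layer stack for this dual-path design is not
  available; depths and kernels are configurable and these defaults are the
  package's own.
* **De-artifact generator** — U-net, depth 4, base 64 channels, channel
  doubling, skips at every level, batch normalization, nearest-neighbour
  upsampling; it predicts a **residual** added to its input, so an untrained
  model is near-identity and clean inputs are safe by construction.  Inputs
  are standardized per image (WBP output is unbounded) and de-standardized
  on output.
* **De-artifact discriminator** — conditional dilated conv stack with batch
  normalization and a global max-pool reduction before the scalar score.

## Losses and training

Joint generator loss `MSE + λ_adv · adv` with `λ_adv = 5e-3` (MSE-dominant;
the adversarial term sharpens but must not destabilize a regression) —
`λ_adv` is configurable and logged, and 0 reduces the total exactly to MSE.
The adversarial form is relativistic-average least-squares (each class
scored against the batch mean of the other, targets ±1); a plain LSGAN
switch exists.  The relativistic means need at least two samples per class;
smaller batches are rejected.  MSE is computed over the full sinogram, not
only the missing rows: the ground truth is the complete sinogram, and
full-frame MSE also regularizes the acquired region before compositing
copies the measurements back in.

Optimizers: generator Adam (betas 0.9/0.999), discriminator RMSprop (alpha
0.99, momentum 0), both at base LR 4e-4 with weight decay 1e-4, updated 1:1
per batch.  The LR schedule is 1-based in epochs: warmup 1e-4 / 2e-4 / 4e-4
over epochs 1–3, plateau, ×0.1 entering epochs 20 and 28 of a 30-epoch run;
the schedule function is asserted directly in the tests.  Smoke-scale runs
use a constant LR override instead, because a 30-epoch schedule is
meaningless over a few hundred steps.

Checkpoints embed the architecture config and all state (including batch-norm
running statistics) in a single `.npz`; a reloaded generator reproduces its
validation numbers exactly.  The de-artifact training corpus uses inpainting
checkpoints spread over training (defaults at roughly 1/6, 1/2 and the end)
because later checkpoints inpaint more strongly and the spread improves
robustness; the inpainted subset is split round-robin across them.

## Metrics

PSNR/SSIM/RMSE follow the 8-bit display convention: the `[0,1]` reference is
mapped to 0–255, the test image is clipped to the reference range and mapped
identically, and PSNR = 10·log₁₀(255²/MSE) with a `+inf` sentinel for
identical images.  SSIM uses the standard 11×11 Gaussian window (σ 1.5) and
published stabilizers.  NIQE is fitted on the pristine phantom library
rather than natural photographs — a documented deviation that turns it into
"distance from artifact-free phantom statistics", which is the comparison
the evaluation needs.  Implementation: MSCN coefficients (Gaussian window σ
= 7/6), generalized-Gaussian and four asymmetric-GGD moment fits per patch
at two scales (36 features), patch size 32, sharp-patch selection at 75% of
peak contrast during fitting, and a Mahalanobis-type distance between
Gaussian feature models.  Two robustness choices: the image is globally
centered before MSCN (making the score exactly offset-invariant instead of
merely approximately), and the AGGD left/right split uses a ±1e-8 dead zone
because flat phantom backgrounds produce exact-zero MSCN coefficients whose
sign is numerical noise.  Ma's score is a separately trained learned metric
and is treated as a pluggable input to `PI = ((10 − Ma) + NIQE)/2`; the
built-in stub returns 5.0 and flags every report that uses it.

## Desk-scale (smoke) conditions

Full-scale training (a corpus of tens of thousands of images and the
30-epoch schedule, i.e. GPU territory) is out of reach of a single-CPU test
run, so the shipped tests and the acceptance script train at a fixed desk
scale chosen once: 64×64 phantoms,
a 3° grid (60 views), 45° wedge, 36 training + 20 held-out phantoms, a
2-block RRDB (depth 16, growth 8) trained for 200 generator steps, and a
depth-3 U-net (base 16) trained for 400 steps on a 72-pair recipe corpus, at
constant LR 1e-3.  What passing at this scale shows: the forward model and
its inversion are correct, the losses and schedules are implemented as
specified, both GANs genuinely learn (inpainting beats zero-fill on held-out
data; the joint reconstruction beats missing-wedge WBP and SART in mean
SSIM; clean inputs are not degraded), and the whole pipeline is
deterministic from one seed.  What it does not show: the published-scale
quality numbers, behaviour on natural-texture corpora, or robustness to real
(noisy, misaligned) tilt series — the synthetic generator has no detector
noise or alignment errors by design.

## Known limitations

* The cubic-spline projector rings slightly below zero at sharp edges;
  consumers who need strictly nonnegative sinograms should use the dataset
  builder's clipped output.
* NIQE fitted on phantoms is not comparable in absolute value to NIQE
  fitted on natural images; only within-corpus comparisons are meaningful.
* The numpy training core is single-threaded and CPU-bound; it is meant for
  reproducible desk-scale experiments, not production-scale training.
* SART/TVM baseline numbers depend on their iteration/relaxation settings,
  which are recorded in provenance but have no canonical published values.
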